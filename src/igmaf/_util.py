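"""Small shared helpers: nucleotide alphabet, translation, array codecs."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

NT = "ACGT"
NT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string (length divisible by 3)."""
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    return str(Seq(nt).translate())


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def random_nt(rng: np.random.Generator, length: int) -> str:
    return array_to_seq(NT_BYTES[rng.integers(0, 4, size=length)])


def random_codons(rng: np.random.Generator, n: int, avoid_stops: bool = True) -> str:
    """Random in-frame codon string, optionally rejecting stop codons."""
    out = []
    while len(out) < n:
        codon = random_nt(rng, 3)
        if avoid_stops and codon in STOP_CODONS:
            continue
        out.append(codon)
    return "".join(out)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def sliding_mismatches(target: str, query: str) -> np.ndarray:
    """Mismatch count of `query` against every offset of `target` (numpy)."""
    t = seq_to_array(target)
    q = seq_to_array(query)
    if len(t) < len(q):
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(t, len(q))
    return (windows != q).sum(axis=1)


def check_nt(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{what} is empty")
    if set(seq) - set(NT):
        bad = sorted(set(seq) - set(NT))
        raise ValueError(f"{what} contains non-ACGT characters: {bad}")


def mean_phred(qual: str) -> float:
    return float(np.mean(seq_to_array(qual))) - 33.0
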