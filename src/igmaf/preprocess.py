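"""Read merging, quality/length filtering, and MAF read-layout parsing.

A merged MAF read is ``FID + insert + revcomp(RID)`` where the insert ends
in a subclass-specific constant-region prefix.  Parsing strips the two UIDs
and verifies that one of the configured constant-prefix anchors is present
(within 2 mismatches) near the 3' end of the insert; reads whose UIDs
contain N are rejected because an ambiguous base would fragment a true RID
group.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import mean_phred, revcomp, seq_to_array, sliding_mismatches


class InputError(ValueError):
    pass


@dataclass
class LayoutConfig:
    """Read-layout description shared by the simulator, parser and annotator."""

    fid_length: int = 10
    rid_length: int = 12
    constant_anchors: dict[str, str] = field(default_factory=dict)  # label -> anchor seq
    anchor_max_mismatch: int = 2
    anchor_search_window: int = 80  # anchors searched in the last N nt of the insert
    min_insert: int = 50
    primer_footprint: tuple[int, int] = (0, 21)  # V-region nt masked for SHM

    @classmethod
    def from_layout(cls, layout, fid_length: int = 10, rid_length: int = 12,
                    anchor_length: int = 15, **kw) -> "LayoutConfig":
        anchors = {
            label: seq[:anchor_length]
            for label, seq in layout.constant_prefixes.items()
        }
        return cls(fid_length=fid_length, rid_length=rid_length,
                   constant_anchors=anchors, **kw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "fid_length": self.fid_length,
            "rid_length": self.rid_length,
            "constant_anchors": dict(self.constant_anchors),
            "anchor_max_mismatch": self.anchor_max_mismatch,
            "anchor_search_window": self.anchor_search_window,
            "min_insert": self.min_insert,
            "primer_footprint": list(self.primer_footprint),
        }
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LayoutConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["primer_footprint"] = tuple(data.get("primer_footprint", (0, 21)))
        return cls(**data)


@dataclass
class ParsedRead:
    read_id: str
    fid: str
    rid: str
    insert: str
    qualities: str  # Phred+33 for the insert
    mean_q: float

    @property
    def orientation_normalized(self) -> bool:
        return True


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------

def merge_pairs(
    r1: Iterable[tuple[str, str, str]],
    r2: Iterable[tuple[str, str, str]],
    min_overlap: int = 15,
    max_mismatch_fraction: float = 0.1,
) -> tuple[list[tuple[str, str, str]], dict]:
    """Merge read pairs by best-scoring 3' overlap.

    R2 is reverse-complemented, the best overlap (matches minus mismatches)
    of length >= ``min_overlap`` is taken, and at overlap mismatches the
    higher-quality base wins.  Pairs with no acceptable overlap are dropped
    and counted.
    """
    merged: list[tuple[str, str, str]] = []
    stats = Counter(merged=0, unmerged=0)
    for (id1, seq1, q1), (id2, seq2, q2) in zip(r1, r2):
        if id1 != id2:
            raise InputError(f"desynchronized read ids: {id1!r} vs {id2!r}")
        seq2rc, q2rc = revcomp(seq2), q2[::-1]
        a1, qa1 = seq_to_array(seq1), seq_to_array(q1)
        a2, qa2 = seq_to_array(seq2rc), seq_to_array(q2rc)
        best = None
        max_ov = min(len(seq1), len(seq2rc))
        for ov in range(min_overlap, max_ov + 1):
            t1, t2 = a1[len(a1) - ov :], a2[:ov]
            mism = int((t1 != t2).sum())
            if mism / ov > max_mismatch_fraction:
                continue
            score = ov - 2 * mism
            if best is None or score > best[0]:
                best = (score, ov, mism)
        if best is None:
            stats["unmerged"] += 1
            continue
        _, ov, _ = best
        head = a1[: len(a1) - ov]
        qhead = qa1[: len(qa1) - ov]
        o1, o2 = a1[len(a1) - ov :].copy(), a2[:ov]
        oq1, oq2 = qa1[len(qa1) - ov :].copy(), qa2[:ov]
        take2 = oq2 > oq1
        o1[take2] = o2[take2]
        oq1[take2] = oq2[take2]
        tail = a2[ov:]
        qtail = qa2[ov:]
        merged_seq = np.concatenate([head, o1, tail]).tobytes().decode()
        merged_qual = np.concatenate([qhead, oq1, qtail]).tobytes().decode()
        merged.append((id1, merged_seq, merged_qual))
        stats["merged"] += 1
    return merged, dict(stats)


# ---------------------------------------------------------------------------
# Quality / length filter
# ---------------------------------------------------------------------------

def quality_length_filter(
    reads: Iterable[tuple[str, str, str]],
    min_mean_q: float = 25.0,
    length_range: tuple[int, int] = (300, 600),
) -> tuple[list[tuple[str, str, str]], dict]:
    """Keep reads with mean Phred >= ``min_mean_q`` and length in range."""
    kept: list[tuple[str, str, str]] = []
    counts = Counter(kept=0, quality=0, length=0)
    lo, hi = length_range
    for read in reads:
        _, seq, qual = read
        if not (lo <= len(seq) <= hi):
            counts["length"] += 1
            continue
        if mean_phred(qual) < min_mean_q:
            counts["quality"] += 1
            continue
        kept.append(read)
        counts["kept"] += 1
    return kept, dict(counts)


# ---------------------------------------------------------------------------
# Layout parsing
# ---------------------------------------------------------------------------

def parse_layout(
    read: tuple[str, str, str], config: LayoutConfig
) -> ParsedRead | tuple[str, str]:
    """Parse one read into (FID, insert, RID); returns ``(read_id, reason)``
    on rejection."""
    read_id, seq, qual = read
    f, r = config.fid_length, config.rid_length
    if len(seq) < f + r + config.min_insert:
        return (read_id, "too_short")
    fid = seq[:f]
    rid = revcomp(seq[-r:])
    insert = seq[f : len(seq) - r]
    iqual = qual[f : len(qual) - r]
    if "N" in fid or "N" in rid:
        return (read_id, "ambiguous_uid")
    if config.constant_anchors:
        window = insert[-config.anchor_search_window :]
        found = False
        for anchor in config.constant_anchors.values():
            mism = sliding_mismatches(window, anchor)
            if len(mism) and mism.min() <= config.anchor_max_mismatch:
                found = True
                break
        if not found:
            return (read_id, "no_constant_anchor")
    return ParsedRead(
        read_id=read_id, fid=fid, rid=rid, insert=insert,
        qualities=iqual, mean_q=mean_phred(iqual),
    )


def parse_reads(
    reads: Iterable[tuple[str, str, str]], config: LayoutConfig
) -> tuple[list[ParsedRead], dict]:
    parsed: list[ParsedRead] = []
    rejects: Counter = Counter()
    for read in reads:
        result = parse_layout(read, config)
        if isinstance(result, ParsedRead):
            parsed.append(result)
        else:
            rejects[result[1]] += 1
    return parsed, dict(rejects)


def write_parsed_table(parsed: Sequence[ParsedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tfid\trid\tinsert\tqualities\tmean_q\n")
        for p in parsed:
            fh.write(f"{p.read_id}\t{p.fid}\t{p.rid}\t{p.insert}\t{p.qualities}\t{p.mean_q:.3f}\n")


def read_parsed_table(path: str | Path) -> list[ParsedRead]:
    parsed = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            read_id, fid, rid, insert, qualities, mean_q = line.rstrip("\n").split("\t")
            parsed.append(ParsedRead(read_id, fid, rid, insert, qualities, float(mean_q)))
    return parsed


def write_stats(stats: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats, indent=2, sort_keys=True))
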