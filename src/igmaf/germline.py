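"""Germline V/J/constant segment references.

Loads IMGT-style FASTA references, resolves the conserved CDR3 anchor
coordinates (Cys-104 on V segments, Trp-118 on J segments), and indexes
segments by name for downstream annotation.  Coordinates are 0-based,
intervals half-open, plus strand only.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import NT_BYTES, check_nt, random_codons, random_nt, translate

SUBCLASS_LABELS = ("IgM", "IgG1", "IgG2", "IgG3", "IgG4", "IgA")

_FAMILY_RE = re.compile(r"^(IGH[VJ]\d+)")
_NAME_RE = re.compile(r"^IGH[VJ]\d+(-[\w.]+)?(\*\d+)?$")


class GermlineError(ValueError):
    pass


def family_of(name: str) -> str:
    """Gene family of a V or J segment name: locus prefix + leading group number.

    ``"IGHV1-8*01" -> "IGHV1"``, ``"IGHJ6*03" -> "IGHJ6"``.
    """
    if not _NAME_RE.match(name):
        raise GermlineError(f"segment name {name!r} does not match IGH[VJ] naming")
    return _FAMILY_RE.match(name).group(1)


def strip_allele(name: str) -> str:
    """Gene-level identity: drop the ``*NN`` allele suffix."""
    return name.split("*", 1)[0]


@dataclass
class GermlineSegment:
    """One germline segment with its CDR3 anchor coordinate.

    ``anchor_offset`` is the 0-based offset of the first nt of the conserved
    anchor codon: Cys-104 for V segments, Trp-118 for J segments; None for
    constant segments.
    """

    name: str
    kind: str  # V, J or C
    sequence: str
    anchor_offset: int | None = None
    subclass_label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("V", "J", "C"):
            raise GermlineError(f"kind must be V, J or C, got {self.kind!r}")
        check_nt(self.sequence, f"segment {self.name}")
        if self.sequence != self.sequence.upper():
            raise GermlineError(f"segment {self.name}: sequence must be uppercase")
        if self.kind == "V":
            if self.anchor_offset is None:
                raise GermlineError(f"V segment {self.name} lacks an anchor offset")
            if self.anchor_offset + 3 > len(self.sequence):
                raise GermlineError(f"{self.name}: anchor codon exceeds sequence")
            if self.anchor_codon not in ("TGT", "TGC"):
                raise GermlineError(
                    f"{self.name}: anchor codon {self.anchor_codon} is not Cys"
                )
        elif self.kind == "J":
            if self.anchor_offset is None:
                raise GermlineError(f"J segment {self.name} lacks an anchor offset")
            if self.anchor_codon != "TGG":
                raise GermlineError(
                    f"{self.name}: anchor codon {self.anchor_codon} is not Trp"
                )
        elif self.kind == "C":
            if self.subclass_label is not None and self.subclass_label not in SUBCLASS_LABELS:
                raise GermlineError(
                    f"{self.name}: unknown subclass {self.subclass_label!r}"
                )

    @property
    def anchor_codon(self) -> str | None:
        if self.anchor_offset is None:
            return None
        return self.sequence[self.anchor_offset : self.anchor_offset + 3]

    @property
    def family(self) -> str | None:
        if self.kind in ("V", "J"):
            return family_of(self.name)
        return None

    @property
    def gene(self) -> str:
        return strip_allele(self.name)


@dataclass
class GermlineDatabase:
    """V/J/C segments keyed by name."""

    v_segments: dict[str, GermlineSegment] = field(default_factory=dict)
    j_segments: dict[str, GermlineSegment] = field(default_factory=dict)
    c_segments: dict[str, GermlineSegment] = field(default_factory=dict)

    @classmethod
    def from_segments(cls, segments: Iterable[GermlineSegment]) -> "GermlineDatabase":
        db = cls()
        for seg in segments:
            db.add(seg)
        return db

    def add(self, seg: GermlineSegment) -> None:
        table = {"V": self.v_segments, "J": self.j_segments, "C": self.c_segments}[seg.kind]
        if seg.name in table:
            raise GermlineError(f"duplicate segment name {seg.name!r}")
        table[seg.name] = seg

    def require_annotatable(self) -> None:
        if not self.v_segments or not self.j_segments:
            raise GermlineError("annotation requires at least one V and one J segment")

    def all_sequences(self) -> list[str]:
        return [
            s.sequence
            for table in (self.v_segments, self.j_segments, self.c_segments)
            for s in table.values()
        ]

    def constant_prefixes(self, length: int | None = None) -> dict[str, str]:
        """Subclass label -> 5' constant-region sequence (optionally truncated)."""
        out = {}
        for seg in self.c_segments.values():
            label = seg.subclass_label or seg.name
            out[label] = seg.sequence if length is None else seg.sequence[:length]
        return out


def scan_v_anchor(sequence: str) -> int | None:
    """Offset of the last in-frame Cys codon (frame anchored at position 0)."""
    hit = None
    for i in range(0, len(sequence) - 2, 3):
        if sequence[i : i + 3] in ("TGT", "TGC"):
            hit = i
    return hit


def scan_j_anchor(sequence: str) -> int | None:
    """Offset of the first Trp codon of a W-G-x-G motif (any phase)."""
    for i in range(0, len(sequence) - 11):
        if (
            sequence[i : i + 3] == "TGG"
            and sequence[i + 3 : i + 5] == "GG"
            and sequence[i + 9 : i + 11] == "GG"
        ):
            return i
    return None


def read_anchor_spec(path: str | Path) -> dict[str, int]:
    """Two-column TSV (name, 0-based offset) -> mapping."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise GermlineError(f"anchor spec row {row!r} is not two columns")
            out[row[0]] = int(row[1])
    return out


def load_germline_fasta(
    path: str | Path,
    kind: str,
    anchor_spec: Mapping[str, int] | str | Path | None = "scan",
    subclass_map: Mapping[str, str] | None = None,
) -> tuple[list[GermlineSegment], list[tuple[str, str]]]:
    """Load one FASTA of germline segments of a single kind.

    ``anchor_spec`` is either a mapping name -> 0-based anchor offset, a path
    to a two-column TSV of the same, or ``"scan"`` to resolve anchors by motif
    scan (V: last in-frame Cys codon; J: first Trp of the W-G-x-G motif).

    Returns ``(segments, excluded)`` where ``excluded`` lists
    ``(record_id, reason)`` for records that failed anchor resolution or
    validation.  Raises on unreadable/empty files and duplicate names.
    """
    if isinstance(anchor_spec, (str, Path)) and anchor_spec != "scan":
        anchor_spec = read_anchor_spec(anchor_spec)

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GermlineError(f"{path}: empty or non-FASTA file")

    segments: list[GermlineSegment] = []
    excluded: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        name = rec.id
        if not name or not len(rec.seq):
            raise GermlineError(f"{path}: record with empty id or sequence")
        if name in seen:
            raise GermlineError(f"{path}: duplicate segment name {name!r}")
        seen.add(name)
        seq = str(rec.seq).upper()

        anchor: int | None = None
        if kind in ("V", "J"):
            if anchor_spec == "scan":
                anchor = scan_v_anchor(seq) if kind == "V" else scan_j_anchor(seq)
                if anchor is None:
                    excluded.append((name, "anchor_not_found"))
                    continue
            else:
                anchor = anchor_spec.get(name) if anchor_spec else None
                if anchor is None:
                    excluded.append((name, "anchor_not_specified"))
                    continue
        subclass = subclass_map.get(name) if subclass_map else _guess_subclass(name)
        try:
            seg = GermlineSegment(
                name=name,
                kind=kind,
                sequence=seq,
                anchor_offset=anchor,
                subclass_label=subclass if kind == "C" else None,
            )
        except GermlineError as exc:
            excluded.append((name, str(exc)))
            continue
        segments.append(seg)
    return segments, excluded


_SUBCLASS_BY_PREFIX = {
    "IGHM": "IgM",
    "IGHG1": "IgG1",
    "IGHG2": "IgG2",
    "IGHG3": "IgG3",
    "IGHG4": "IgG4",
    "IGHA": "IgA",
}


def _guess_subclass(name: str) -> str | None:
    stem = strip_allele(name)
    for prefix, label in _SUBCLASS_BY_PREFIX.items():
        if stem.startswith(prefix):
            return label
    return None


def write_fasta(segments: Iterable[GermlineSegment], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s.sequence), id=s.name, description="")
        for s in segments
    ]
    SeqIO.write(recs, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# Synthetic reference database
# ---------------------------------------------------------------------------

# Family sizes for the synthetic database: 48 V genes spread over the seven
# human IGHV families, echoing the breadth of the functional repertoire.
_SYNTH_V_FAMILY_SIZES = {1: 10, 2: 4, 3: 16, 4: 10, 5: 3, 6: 2, 7: 3}


def synthetic_igh_database(
    seed: int = 0,
    n_j: int = 6,
    v_length: int = 294,
    j_length: int = 48,
    c_length: int = 36,
) -> GermlineDatabase:
    """Generate a synthetic human-IGH-like germline database.

    The segments are random sequences with the structural features the
    toolkit relies on (in-frame V ending in a Cys anchor codon, J starting
    with a W-G-x-G motif, constant prefixes that are pairwise well separated
    so subclass assignment is unambiguous).  They are *synthetic* stand-ins
    for an IMGT reference set and carry no biological sequence content.
    """
    rng = np.random.default_rng(seed)
    segments: list[GermlineSegment] = []

    for fam, n_in_fam in _SYNTH_V_FAMILY_SIZES.items():
        for i in range(n_in_fam):
            name = f"IGHV{fam}-{i + 1}*01"
            # in-frame body without internal Cys in the last codons, ending TGT
            body = random_codons(rng, v_length // 3 - 1)
            seq = body + "TGT"
            # ensure the scan anchor is the terminal codon
            segments.append(
                GermlineSegment(name, "V", seq, anchor_offset=v_length - 3)
            )

    for j in range(1, n_j + 1):
        tail_len = j_length - 12
        tail = random_codons(rng, tail_len // 3)
        mid = random_codons(rng, 1)
        seq = "TGGGG" + random_nt(rng, 1) + mid + "GG" + random_nt(rng, 1) + tail
        segments.append(GermlineSegment(f"IGHJ{j}*01", "J", seq, anchor_offset=0))

    c_names = {
        "IgM": "IGHM*01",
        "IgG1": "IGHG1*01",
        "IgG2": "IGHG2*01",
        "IgG3": "IGHG3*01",
        "IgG4": "IGHG4*01",
        "IgA": "IGHA*01",
    }
    c_seqs: list[str] = []
    for label, name in c_names.items():
        while True:
            cand = random_nt(rng, c_length)
            if all(_hamming_arr(cand, prev) >= 6 for prev in c_seqs):
                break
        c_seqs.append(cand)
        segments.append(GermlineSegment(name, "C", cand, subclass_label=label))

    return GermlineDatabase.from_segments(segments)


def _hamming_arr(a: str, b: str) -> int:
    return int(
        (np.frombuffer(a.encode(), np.uint8) != np.frombuffer(b.encode(), np.uint8)).sum()
    )
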