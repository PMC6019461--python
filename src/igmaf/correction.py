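"""MAF error and bias correction.

Error correction: reads are grouped by their RID (one group per cDNA
molecule), and groups with at least ``min_reads_for_consensus`` reads
(default 3) are collapsed to a per-position majority-vote consensus.
Smaller groups are passed through as their highest-quality read rather than
discarded; a strict mode drops them instead.

Bias correction: the number of molecules per clone is the number of RIDs,
and residual amplification bias is removed using the FID:RID ratio — clones
preferentially amplified by the multiplex primer set accumulate more
distinct FIDs per RID, so their molecular counts are scaled down by the
ratio of their amplification ratio to the dataset average.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import array_to_seq, seq_to_array
from .preprocess import ParsedRead


@dataclass
class UIDGroup:
    rid: str
    member_reads: list[ParsedRead]
    consensus: str | None = None
    status: str | None = None  # consensus_built | low_coverage_passthrough

    @property
    def distinct_fids(self) -> int:
        return len({r.fid for r in self.member_reads})

    @property
    def size(self) -> int:
        return len(self.member_reads)


@dataclass
class CorrectedRecord:
    sequence: str
    read_count: int
    rid_count: int
    fid_count: int
    provenance: str  # corrected | passthrough


@dataclass
class CloneAbundance:
    key: str
    rid_count: int
    fid_rid_pairs: int
    amplification_ratio: float
    corrected_count: float
    corrected_frequency: float


@dataclass
class GroupingReport:
    n_groups: int
    size_histogram: dict[int, int]
    n_absorbed: int = 0


def group_by_rid(
    reads: Iterable[ParsedRead], merge_near_rids: bool = False
) -> tuple[list[UIDGroup], GroupingReport]:
    """Exact-match RID grouping; optionally absorb singleton RIDs that lie
    within Hamming distance 1 of a group with >= 3 reads."""
    table: dict[str, list[ParsedRead]] = defaultdict(list)
    for read in reads:
        table[read.rid].append(read)

    n_absorbed = 0
    if merge_near_rids:
        big = {rid for rid, members in table.items() if len(members) >= 3}
        # enumerate all distance-1 neighbors of big RIDs for O(1) lookup
        neighbor_of: dict[str, str] = {}
        for rid in big:
            for i, orig in enumerate(rid):
                for b in "ACGT":
                    if b != orig:
                        neighbor_of.setdefault(rid[:i] + b + rid[i + 1 :], rid)
        for rid in [r for r, m in table.items() if len(m) == 1]:
            target = neighbor_of.get(rid)
            if target is not None and target in table:
                table[target].extend(table.pop(rid))
                n_absorbed += 1

    groups = [UIDGroup(rid=rid, member_reads=members) for rid, members in sorted(table.items())]
    hist = Counter(g.size for g in groups)
    return groups, GroupingReport(len(groups), dict(hist), n_absorbed)


def build_consensus(group: UIDGroup, min_reads_for_consensus: int = 3) -> CorrectedRecord:
    """Majority-vote consensus of a UID group.

    With >= ``min_reads_for_consensus`` members: restrict to reads of the
    modal insert length (ties broken toward the longer length), take the
    per-position majority base, and break ties by the highest summed Phred
    for the tied base (then alphabetically).  Below the threshold the group
    passes through as its highest-mean-quality member.
    """
    if not group.member_reads:
        raise ValueError("empty UID group")
    members = group.member_reads
    if len(members) >= min_reads_for_consensus:
        lengths = Counter(len(r.insert) for r in members)
        modal = max(lengths.items(), key=lambda kv: (kv[1], kv[0]))[0]
        voting = [r for r in members if len(r.insert) == modal]
        seqs = np.stack([seq_to_array(r.insert) for r in voting])
        quals = np.stack([seq_to_array(r.qualities) for r in voting]).astype(np.int64) - 33
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        counts = np.stack([(seqs == b).sum(axis=0) for b in bases])
        qsums = np.stack([((seqs == b) * quals).sum(axis=0) for b in bases])
        # composite score: count dominates, then summed Phred, then A<C<G<T
        pref = np.arange(3, -1, -1)[:, None]
        score = counts * 1_000_000 + qsums * 8 + pref
        winner = score.argmax(axis=0)
        consensus = array_to_seq(bases[winner])
        group.consensus = consensus
        group.status = "consensus_built"
        provenance = "corrected"
        sequence = consensus
    else:
        rep = max(members, key=lambda r: (r.mean_q, r.read_id))
        group.consensus = None
        group.status = "low_coverage_passthrough"
        provenance = "passthrough"
        sequence = rep.insert
    return CorrectedRecord(
        sequence=sequence,
        read_count=len(members),
        rid_count=1,
        fid_count=group.distinct_fids,
        provenance=provenance,
    )


def correct_dataset(
    groups: Sequence[UIDGroup],
    min_reads_for_consensus: int = 3,
    strict: bool = False,
) -> list[CorrectedRecord]:
    """Consensus per group, aggregated by identical sequence.

    ``strict`` drops low-coverage groups instead of passing them through.
    The sum of ``rid_count`` over the output equals the number of retained
    groups.
    """
    by_seq: dict[str, CorrectedRecord] = {}
    for group in groups:
        rec = build_consensus(group, min_reads_for_consensus)
        if strict and rec.provenance == "passthrough":
            continue
        agg = by_seq.get(rec.sequence)
        if agg is None:
            by_seq[rec.sequence] = rec
        else:
            agg.read_count += rec.read_count
            agg.rid_count += rec.rid_count
            agg.fid_count += rec.fid_count
            if rec.provenance == "corrected":
                agg.provenance = "corrected"
    return sorted(by_seq.values(), key=lambda r: (-r.rid_count, r.sequence))


def bias_correct(
    abundances: Mapping[str, tuple[int, int]] | Sequence[tuple[str, int, int]],
) -> list[CloneAbundance]:
    """FID:RID normalization of clone abundances.

    Input: clone key -> (rid_count R, fid_rid_pairs F).  Per clone the
    amplification ratio is a = F/R; with the dataset average ratio
    a_bar = sum(F)/sum(R), the corrected molecular count is R * a_bar / a,
    i.e. over-amplified clones are scaled down.  Under uniform amplification
    the correction is the identity.
    """
    if isinstance(abundances, Mapping):
        items = [(k, r, f) for k, (r, f) in abundances.items()]
    else:
        items = list(abundances)
    if not items:
        return []
    for key, r, f in items:
        if r < 1:
            raise ValueError(f"clone {key!r}: rid_count must be >= 1")
    total_r = sum(r for _, r, _ in items)
    total_f = sum(f for _, _, f in items)
    a_bar = total_f / total_r
    out = []
    for key, r, f in items:
        a = f / r
        corrected = r * (a_bar / a) if a > 0 else float(r)
        out.append(CloneAbundance(key, r, f, a, corrected, 0.0))
    total_corr = sum(c.corrected_count for c in out)
    for c in out:
        c.corrected_frequency = c.corrected_count / total_corr
    return out


def write_corrected_table(records: Sequence[CorrectedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tread_count\trid_count\tfid_count\tprovenance\n")
        for r in records:
            fh.write(f"{r.sequence}\t{r.read_count}\t{r.rid_count}\t{r.fid_count}\t{r.provenance}\n")


def read_corrected_table(path: str | Path) -> list[CorrectedRecord]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            seq, rc, uc, fc, prov = line.rstrip("\n").split("\t")
            out.append(CorrectedRecord(seq, int(rc), int(uc), int(fc), prov))
    return out
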