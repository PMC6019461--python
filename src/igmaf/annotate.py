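"""Germline V/J assignment, CDR3 extraction, SHM counting, isotype calls,
and spike-in separation.

Alignment is semi-global (the full germline segment against an infix of the
read) with unit edit costs, computed with edlib; the best-scoring segment
wins, ties broken by fewest mismatches and then lexicographic name.  A call
is rejected when the edit distance exceeds ``max_edit_fraction`` of the
segment length, which reliably separates true rearrangements (a few percent
divergence even at high SHM) from random sequence (~40-50%).

The CDR3 is anchor-inclusive: from the first nt of the V Cys codon through
the last nt of the J Trp codon.  SHM is counted as nt substitutions in the
aligned V and J regions outside the junction and outside the
multiplex-primer footprint (template bases under the primer are overwritten
during amplification and thus unobservable); indels are reported separately
and excluded from the count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from ._util import seq_to_array, sliding_mismatches, translate
from .correction import CorrectedRecord
from .germline import GermlineDatabase, GermlineSegment, strip_allele
from .preprocess import LayoutConfig
from .standards import SpikeInSet, levenshtein

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class Alignment:
    """Semi-global alignment of one germline segment against a read infix."""

    name: str
    edit_distance: int
    n_mismatches: int
    n_indels: int
    query_span: tuple[int, int]  # in germline coordinates, half-open
    target_span: tuple[int, int]  # in read coordinates, half-open
    mismatch_target_positions: list[int]
    mismatch_query_positions: list[int]
    query_to_target: dict[int, int]  # germline offset -> read offset (matches/mismatches)


def _align_segment(query: str, target: str) -> dict | None:
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    return res


def _canonicalize_ops(ops: list[tuple[int, str]]) -> list[tuple[int, str]]:
    """Rewrite adjacent I/D pairs as mismatches (equal edit cost, but the
    substitution reading is the canonical one for SHM counting)."""
    out: list[tuple[int, str]] = []
    i = 0
    while i < len(ops):
        if i + 1 < len(ops) and {ops[i][1], ops[i + 1][1]} == {"I", "D"}:
            a, b = ops[i], ops[i + 1]
            k = min(a[0], b[0])
            out.append((k, "X"))
            for length, op in (a, b):
                if length - k > 0:
                    out.append((length - k, op))
            i += 2
        else:
            out.append(ops[i])
            i += 1
    return out


def _parse_alignment(name: str, query: str, res: dict, target_offset: int = 0,
                     target: str | None = None) -> Alignment:
    start, end = res["locations"][0]
    cigar = res["cigar"]
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    cigar_indels = sum(n for n, op in ops if op in ("I", "D"))
    # Substitution-preferred reading: among same-length windows near the
    # edlib location, take the one with minimal Hamming distance.  It is used
    # whenever it is consistent with the edit alignment (optimal edit paths
    # are not unique, and edlib freely trades clustered substitutions for
    # indels, which would corrupt SHM counts on indel-free data).
    if target is not None:
        Lq, Lt = len(query), len(target)
        if Lt >= Lq:
            qa = seq_to_array(query)
            ta = seq_to_array(target)
            candidates = range(
                max(0, min(start, end + 1 - Lq) - cigar_indels - 1),
                min(Lt - Lq, max(start, end + 1 - Lq) + cigar_indels + 1) + 1,
            )
            best_s, best_mism = None, None
            for s in candidates:
                mism = int((qa != ta[s : s + Lq]).sum())
                if best_mism is None or mism < best_mism:
                    best_s, best_mism = s, mism
            if best_mism is not None and best_mism <= res["editDistance"] + cigar_indels:
                s = best_s
                window = ta[s : s + Lq]
                mism_idx = np.nonzero(qa != window)[0]
                return Alignment(
                    name=name,
                    edit_distance=res["editDistance"],
                    n_mismatches=int(best_mism),
                    n_indels=0,
                    query_span=(0, Lq),
                    target_span=(target_offset + s, target_offset + s + Lq),
                    mismatch_target_positions=[target_offset + s + int(i) for i in mism_idx],
                    mismatch_query_positions=[int(i) for i in mism_idx],
                    query_to_target={q: target_offset + s + q for q in range(Lq)},
                )
    qpos, tpos = 0, start
    mism_t, mism_q = [], []
    q2t: dict[int, int] = {}
    n_mm = n_indel = 0
    for length, op in _canonicalize_ops(ops):
        if op in ("=", "M"):
            for k in range(length):
                q2t[qpos + k] = tpos + k
            qpos += length
            tpos += length
        elif op == "X":
            for k in range(length):
                q2t[qpos + k] = tpos + k
                # a canonicalized I/D pair can align equal bases; only count
                # genuine substitutions
                if target is None or query[qpos + k] != target[tpos + k]:
                    mism_q.append(qpos + k)
                    mism_t.append(target_offset + tpos + k)
                    n_mm += 1
            qpos += length
            tpos += length
        elif op == "I":  # insertion in query (base in germline absent from read)
            n_indel += length
            qpos += length
        elif op == "D":  # deletion: extra read bases
            n_indel += length
            tpos += length
    return Alignment(
        name=name,
        edit_distance=res["editDistance"],
        n_mismatches=n_mm,
        n_indels=n_indel,
        query_span=(0, qpos),
        target_span=(target_offset + start, target_offset + end + 1),
        mismatch_target_positions=mism_t,
        mismatch_query_positions=[q for q in mism_q],
        query_to_target={q: target_offset + t for q, t in q2t.items()},
    )


def _assign(
    seq: str,
    segments: Mapping[str, GermlineSegment],
    max_edit_fraction: float,
    target_offset: int = 0,
) -> Alignment | None:
    hits: list[tuple[int, str, dict]] = []
    for name in sorted(segments):
        res = _align_segment(segments[name].sequence, seq)
        if res is not None:
            hits.append((res["editDistance"], name, res))
    if not hits:
        return None
    best_d = min(h[0] for h in hits)
    tied = [h for h in hits if h[0] == best_d]
    if len(tied) == 1:
        _, name, res = tied[0]
    else:
        # ties broken by fewest mismatches, then lexicographic name
        parsed = [
            (_parse_alignment(n, segments[n].sequence, r).n_mismatches, n, r)
            for _, n, r in tied
        ]
        _, name, res = min(parsed, key=lambda h: (h[0], h[1]))
    if res["editDistance"] > max_edit_fraction * len(segments[name].sequence):
        return None
    return _parse_alignment(name, segments[name].sequence, res, target_offset, target=seq)


def assign_v(
    seq: str, v_segments: Mapping[str, GermlineSegment], max_edit_fraction: float = 0.2
) -> Alignment | None:
    """Best germline V over the read; None when no segment clears the floor."""
    if not v_segments:
        raise ValueError("empty V database")
    return _assign(seq, v_segments, max_edit_fraction)


def assign_j(
    seq: str,
    j_segments: Mapping[str, GermlineSegment],
    search_from: int = 0,
    max_edit_fraction: float = 0.25,
) -> Alignment | None:
    """Best germline J on the region 3' of ``search_from`` (typically just
    past the V anchor, so the junction stays covered by both alignments)."""
    if not j_segments:
        raise ValueError("empty J database")
    sub = seq[search_from:]
    if not sub:
        return None
    return _assign(sub, j_segments, max_edit_fraction, target_offset=search_from)


def extract_cdr3(
    seq: str,
    v: GermlineSegment,
    j: GermlineSegment,
    v_aln: Alignment,
    j_aln: Alignment,
) -> tuple[str | None, str | None, bool, str | None]:
    """(cdr3_nt, cdr3_aa, productive, failure_reason).

    The junction spans the read positions aligned to the V anchor codon
    through the end of the J anchor codon, inclusive.  Out-of-frame or
    stop-containing junctions are flagged nonproductive.
    """
    va = v_aln.query_to_target.get(v.anchor_offset)
    jw_last = j_aln.query_to_target.get(j.anchor_offset + 2)
    if va is None or jw_last is None:
        return None, None, False, "cdr3_fail"
    cdr3_nt = seq[va : jw_last + 1]
    if len(cdr3_nt) % 3 != 0:
        return cdr3_nt, None, False, "out_of_frame"
    aa = translate(cdr3_nt)
    if "*" in aa:
        return cdr3_nt, aa, False, "stop_codon"
    return cdr3_nt, aa, True, None


def count_shm(
    v: GermlineSegment,
    j: GermlineSegment,
    v_aln: Alignment,
    j_aln: Alignment,
    primer_footprint: tuple[int, int] = (0, 21),
) -> tuple[int, int]:
    """(shm_count, n_indels): substitutions vs germline V+J outside the
    junction and the primer footprint; indels reported separately."""
    lo, hi = primer_footprint
    shm = sum(
        1
        for q in v_aln.mismatch_query_positions
        if q < v.anchor_offset and not (lo <= q < hi)
    )
    shm += sum(1 for q in j_aln.mismatch_query_positions if q >= j.anchor_offset + 3)
    return shm, v_aln.n_indels + j_aln.n_indels


def assign_isotype(
    insert: str,
    constant_prefixes: Mapping[str, str],
    ambiguity_margin: int = 2,
) -> str:
    """Best Hamming match of the read's constant prefix; 'ambiguous' when the
    best and second-best references are separated by < ``ambiguity_margin``."""
    scores = []
    for label in sorted(constant_prefixes):
        ref = constant_prefixes[label]
        if len(insert) < len(ref):
            continue
        observed = insert[-len(ref) :]
        d = int((seq_to_array(observed) != seq_to_array(ref)).sum())
        scores.append((d, label))
    if not scores:
        return "ambiguous"
    scores.sort()
    if len(scores) > 1 and scores[1][0] - scores[0][0] < ambiguity_margin:
        return "ambiguous"
    return scores[0][1]


def find_identifier(seq: str, identifier: str, max_mismatch: int = 1) -> bool:
    mism = sliding_mismatches(seq, identifier)
    return bool(len(mism)) and int(mism.min()) <= max_mismatch


def separate_spikeins(
    records: pd.DataFrame,
    identifier: str,
    standards: SpikeInSet | None = None,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Mark spike-in records (identifier found within <= 1 mismatch) and match
    each to the standard with the nearest CDR3 a.a. sequence."""
    records = records.copy()
    is_spike = records["sequence"].map(lambda s: find_identifier(s, identifier, max_mismatch))
    records["is_spikein"] = is_spike
    matched = [None] * len(records)
    if standards is not None:
        std_list = list(standards.standards)
        for i, (flag, aa) in enumerate(zip(is_spike, records["junction_aa"])):
            if not flag:
                continue
            if aa is None or (isinstance(aa, float) and np.isnan(aa)):
                continue
            best = min(std_list, key=lambda s: (levenshtein(aa, s.cdr3_aa), s.standard_id))
            matched[i] = best.standard_id
    records["matched_standard_id"] = matched
    return records


@dataclass
class AnnotatedRearrangement:
    sequence_id: str
    sequence: str
    v_call: str | None
    j_call: str | None
    junction: str | None
    junction_aa: str | None
    productive: bool
    shm_count: int | None
    n_indels: int | None
    subclass: str
    read_count: int
    rid_count: int
    fid_count: int
    replicate_id: int | None = None
    fail_reason: str | None = None

    @property
    def v_gene(self) -> str | None:
        return strip_allele(self.v_call) if self.v_call else None

    @property
    def j_gene(self) -> str | None:
        return strip_allele(self.j_call) if self.j_call else None


#: AIRR Rearrangement column order used by :func:`to_airr_table`
AIRR_COLUMNS = [
    "sequence_id", "sequence", "v_call", "j_call", "v_gene", "j_gene",
    "junction", "junction_aa", "productive", "shm_count", "n_indels",
    "subclass", "duplicate_count", "consensus_count", "fid_count",
    "replicate_id", "fail_reason",
]


def annotate_records(
    records: Sequence[CorrectedRecord],
    db: GermlineDatabase,
    config: LayoutConfig | None = None,
    max_edit_fraction: float = 0.2,
    replicate_id: int | None = None,
) -> pd.DataFrame:
    """Annotate corrected records; returns an AIRR-flavored DataFrame.

    Records with no V or J call are kept with ``fail_reason`` set and are
    excluded from clonotyping by the ``productive`` flag.
    """
    db.require_annotatable()
    footprint = config.primer_footprint if config else (0, 21)
    c_prefixes = db.constant_prefixes()
    rows = []
    for i, rec in enumerate(records):
        seq = rec.sequence
        row = dict(
            sequence_id=f"seq-{i + 1}",
            sequence=seq,
            v_call=None, j_call=None, v_gene=None, j_gene=None,
            junction=None, junction_aa=None, productive=False,
            shm_count=None, n_indels=None,
            subclass=assign_isotype(seq, c_prefixes),
            duplicate_count=rec.read_count,
            consensus_count=rec.rid_count,
            fid_count=rec.fid_count,
            replicate_id=replicate_id,
            fail_reason=None,
        )
        v_aln = assign_v(seq, db.v_segments, max_edit_fraction)
        if v_aln is None:
            row["fail_reason"] = "no_v_call"
            rows.append(row)
            continue
        v = db.v_segments[v_aln.name]
        # J search starts after the V anchor so the junction stays covered
        anchor_t = v_aln.query_to_target.get(v.anchor_offset)
        search_from = (anchor_t + 3) if anchor_t is not None else v_aln.target_span[1]
        j_aln = assign_j(seq, db.j_segments, search_from=search_from)
        if j_aln is None:
            row.update(v_call=v_aln.name, v_gene=strip_allele(v_aln.name),
                       fail_reason="no_j_call")
            rows.append(row)
            continue
        j = db.j_segments[j_aln.name]
        cdr3_nt, cdr3_aa, productive, fail = extract_cdr3(seq, v, j, v_aln, j_aln)
        shm, n_indels = count_shm(v, j, v_aln, j_aln, footprint)
        row.update(
            v_call=v_aln.name, j_call=j_aln.name,
            v_gene=strip_allele(v_aln.name), j_gene=strip_allele(j_aln.name),
            junction=cdr3_nt, junction_aa=cdr3_aa, productive=productive,
            shm_count=shm, n_indels=n_indels, fail_reason=fail,
        )
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["sequence_id", "sequence", "v_call", "j_call", "v_gene",
                     "j_gene", "junction", "junction_aa", "productive",
                     "shm_count", "n_indels", "subclass", "duplicate_count",
                     "consensus_count", "fid_count", "replicate_id", "fail_reason"]
        )
    return pd.DataFrame(rows)


def write_airr_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_airr_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=[""], dtype={"junction": "object", "junction_aa": "object"})
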