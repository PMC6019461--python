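"""Design and validation of synthetic spike-in standards.

Each standard is a full antibody-like VDJ open reading frame built from a
germline V and J segment plus a designed CDR3, flanked by a conserved 5'
(singleplex primer) region, a leader, a non-coding synthetic identifier (for
separating spike-ins from biological reads), and a subclass-specific
constant-region prefix.  A standard set enforces two separability rules:

* every CDR3 amino-acid sequence is unique, and
* every pair of CDR3 nucleotide sequences is at least
  ``min_cdr3_nt_distance`` Levenshtein edits apart (default 9), so that no
  realistic accumulation of PCR/sequencing errors can convert one standard's
  CDR3 into another's.

A subset of standards carries designed V-region point substitutions that
mimic somatic hypermutation (substitutions only, never indels), placed
outside the conserved anchor codon and the multiplex-primer footprint.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from ._util import check_nt, random_codons, random_nt, translate
from .germline import GermlineDatabase, GermlineSegment


class DesignError(ValueError):
    pass


class CapacityError(DesignError):
    """Raised when rejection sampling cannot satisfy the distance constraint."""


def levenshtein(a: str, b: str) -> int:
    """Minimal number of insertions, deletions and substitutions a -> b."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class StandardLayout:
    """Structural layout shared by all standards in a set."""

    conserved_5p: str
    leader: str
    synthetic_identifier: str
    constant_prefixes: dict[str, str]

    def __post_init__(self) -> None:
        check_nt(self.conserved_5p, "conserved_5p")
        check_nt(self.leader, "leader")
        check_nt(self.synthetic_identifier, "synthetic_identifier")
        if not self.constant_prefixes:
            raise DesignError("constant_prefixes must be non-empty")
        for label, seq in self.constant_prefixes.items():
            check_nt(seq, f"constant prefix {label}")

    def identifier_absent_from(self, db: GermlineDatabase) -> bool:
        return all(
            self.synthetic_identifier not in seq for seq in db.all_sequences()
        )


def default_layout(
    db: GermlineDatabase,
    seed: int = 0,
    conserved_5p_length: int = 24,
    leader_length: int = 30,
    identifier_length: int = 21,
    constant_prefix_length: int = 36,
) -> StandardLayout:
    """Build a layout whose synthetic identifier is absent from ``db``."""
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        ident = random_nt(rng, identifier_length)
        layout = StandardLayout(
            conserved_5p=random_nt(rng, conserved_5p_length),
            leader=random_nt(rng, leader_length),
            synthetic_identifier=ident,
            constant_prefixes=db.constant_prefixes(constant_prefix_length),
        )
        if layout.identifier_absent_from(db):
            return layout
    raise DesignError("could not find an identifier absent from the database")


@dataclass
class SpikeInStandard:
    """One designed synthetic clone."""

    standard_id: str
    v_name: str
    j_name: str
    cdr3_nt: str
    cdr3_aa: str
    designed_mutations: list[tuple[int, str, str]]  # (v offset, original, new)
    full_sequence: str
    relative_concentration: float
    subclass_label: str = "IgG1"

    def mutated_v(self, v: GermlineSegment) -> str:
        """The V-region sequence with designed substitutions applied."""
        seq = list(v.sequence)
        for pos, orig, new in self.designed_mutations:
            if not (0 <= pos < len(seq)):
                raise DesignError(f"{self.standard_id}: mutation offset {pos} outside V")
            if seq[pos] != orig:
                raise DesignError(
                    f"{self.standard_id}: mutation at {pos} expects {orig}, V has {seq[pos]}"
                )
            seq[pos] = new
        return "".join(seq)


@dataclass
class SpikeInSet:
    standards: list[SpikeInStandard]
    layout: StandardLayout
    min_cdr3_nt_distance: int = 9

    def __iter__(self):
        return iter(self.standards)

    def __len__(self) -> int:
        return len(self.standards)

    def by_id(self) -> dict[str, SpikeInStandard]:
        return {s.standard_id: s for s in self.standards}

    def manifest(self) -> dict[str, float]:
        return {s.standard_id: s.relative_concentration for s in self.standards}


def pairwise_cdr3_distances(spike_set: SpikeInSet, level: str = "nt") -> np.ndarray:
    """Symmetric Levenshtein distance matrix over all CDR3s (nt or aa)."""
    if level not in ("nt", "aa"):
        raise DesignError(f"level must be 'nt' or 'aa', got {level!r}")
    seqs = [
        s.cdr3_nt if level == "nt" else s.cdr3_aa for s in spike_set.standards
    ]
    n = len(seqs)
    if n == 0:
        raise DesignError("empty standard set")
    mat = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = levenshtein(seqs[i], seqs[j])
            mat[i, j] = mat[j, i] = d
    return mat


def assemble_full_sequence(
    layout: StandardLayout,
    v: GermlineSegment,
    j: GermlineSegment,
    cdr3_nt: str,
    designed_mutations: Sequence[tuple[int, str, str]],
    subclass_label: str,
) -> str:
    """conserved_5p + leader + mutated V (to anchor) + CDR3 + J (after anchor)
    + identifier + constant prefix.

    The CDR3 starts with the V anchor (Cys) codon and ends with the J anchor
    (Trp) codon, so the full V and J germline sequences appear verbatim in
    the assembly (modulo designed mutations).
    """
    v_seq = list(v.sequence)
    for pos, orig, new in designed_mutations:
        if v_seq[pos] != orig:
            raise DesignError(f"mutation at {pos} expects {orig}")
        v_seq[pos] = new
    v_mut = "".join(v_seq)
    return (
        layout.conserved_5p
        + layout.leader
        + v_mut[: v.anchor_offset]
        + cdr3_nt
        + j.sequence[j.anchor_offset + 3 :]
        + layout.synthetic_identifier
        + layout.constant_prefixes[subclass_label]
    )


def _random_cdr3(
    rng: np.random.Generator,
    v: GermlineSegment,
    j: GermlineSegment,
    aa_length: int,
) -> tuple[str, str]:
    """Random in-frame CDR3 starting at the V Cys codon, ending at the J Trp."""
    if aa_length < 3:
        raise DesignError("CDR3 must be at least 3 a.a. (C...W)")
    first = v.anchor_codon  # TGT/TGC
    last = j.sequence[j.anchor_offset : j.anchor_offset + 3]  # TGG
    middle = random_codons(rng, aa_length - 2)
    nt = first + middle + last
    return nt, translate(nt)


def design_standard_set(
    db: GermlineDatabase,
    layout: StandardLayout,
    n_clones: int = 85,
    v_usage_plan: Mapping[str, int] | None = None,
    cdr3_length_range: tuple[int, int] = (10, 20),
    min_cdr3_nt_distance: int = 9,
    shm_plan: Mapping[str, int] | None = None,
    n_shm_standards: int | None = None,
    primer_footprint: tuple[int, int] = (0, 21),
    seed: int = 0,
    max_rejections: int = 100_000,
) -> SpikeInSet:
    """Design a spike-in set by rejection sampling of CDR3 junctions.

    ``v_usage_plan`` maps V segment name to the number of clones built on it;
    by default the requested ``n_clones`` are spread round-robin over all V
    segments in the database.  ``shm_plan`` maps standard_id -> number of
    designed V substitutions; by default a fraction of standards
    (``n_shm_standards``, default 39 of 85, scaled for other set sizes)
    receives 1-12 designed substitutions placed outside the anchor codon and
    the multiplex-primer footprint.  Relative pool concentrations default to
    a log-uniform draw spanning two orders of magnitude, normalized to 1.
    Deterministic for fixed seed.
    """
    db.require_annotatable()
    rng = np.random.default_rng(seed)

    if v_usage_plan is None:
        v_names = sorted(db.v_segments)
        v_usage_plan = {}
        for i in range(n_clones):
            name = v_names[i % len(v_names)]
            v_usage_plan[name] = v_usage_plan.get(name, 0) + 1
    else:
        for name in v_usage_plan:
            if name not in db.v_segments:
                raise DesignError(f"v_usage_plan references unknown V {name!r}")
        if sum(v_usage_plan.values()) != n_clones:
            raise DesignError("v_usage_plan counts must sum to n_clones")

    j_names = sorted(db.j_segments)
    subclasses = sorted(layout.constant_prefixes)
    lo, hi = cdr3_length_range
    if lo > hi or lo < 3:
        raise DesignError(f"invalid cdr3_length_range {cdr3_length_range}")

    # assignment order: interleave V genes so ids are stable
    v_order: list[str] = []
    plan = dict(v_usage_plan)
    while len(v_order) < n_clones:
        for name in sorted(plan):
            if plan[name] > 0:
                v_order.append(name)
                plan[name] -= 1

    if n_shm_standards is None:
        n_shm_standards = int(round(n_clones * 39 / 85))
    shm_indices = set(
        rng.choice(n_clones, size=min(n_shm_standards, n_clones), replace=False).tolist()
    )

    accepted_nt: list[str] = []
    accepted_aa: set[str] = set()
    standards: list[SpikeInStandard] = []
    for idx in range(n_clones):
        std_id = f"STD-{idx + 1:03d}"
        v = db.v_segments[v_order[idx]]
        j = db.j_segments[j_names[int(rng.integers(len(j_names)))]]
        for attempt in range(max_rejections):
            aa_len = int(rng.integers(lo, hi + 1))
            cdr3_nt, cdr3_aa = _random_cdr3(rng, v, j, aa_len)
            if cdr3_aa in accepted_aa:
                continue
            if all(
                levenshtein(cdr3_nt, prev) >= min_cdr3_nt_distance
                for prev in accepted_nt
            ):
                break
        else:
            raise CapacityError(
                f"could not satisfy min CDR3 nt distance {min_cdr3_nt_distance} "
                f"at clone index {idx} after {max_rejections} rejections"
            )

        if shm_plan is not None:
            n_mut = shm_plan.get(std_id, 0)
        else:
            n_mut = int(rng.integers(1, 13)) if idx in shm_indices else 0
        mutations = _design_mutations(rng, v, n_mut, primer_footprint)

        subclass = subclasses[int(rng.integers(len(subclasses)))]
        full = assemble_full_sequence(layout, v, j, cdr3_nt, mutations, subclass)
        standards.append(
            SpikeInStandard(
                standard_id=std_id,
                v_name=v.name,
                j_name=j.name,
                cdr3_nt=cdr3_nt,
                cdr3_aa=cdr3_aa,
                designed_mutations=mutations,
                full_sequence=full,
                relative_concentration=0.0,
                subclass_label=subclass,
            )
        )
        accepted_nt.append(cdr3_nt)
        accepted_aa.add(cdr3_aa)

    # non-uniform pool: log-uniform across two orders of magnitude
    raw = 10.0 ** rng.uniform(-2.0, 0.0, size=n_clones)
    conc = raw / raw.sum()
    for s, c in zip(standards, conc):
        s.relative_concentration = float(c)

    return SpikeInSet(standards, layout, min_cdr3_nt_distance)


def _design_mutations(
    rng: np.random.Generator,
    v: GermlineSegment,
    n_mut: int,
    primer_footprint: tuple[int, int],
) -> list[tuple[int, str, str]]:
    """Unique substitution positions outside anchor codon and primer footprint."""
    if n_mut == 0:
        return []
    lo = primer_footprint[1]
    hi = v.anchor_offset  # anchor codon excluded
    candidates = np.arange(lo, hi)
    if n_mut > len(candidates):
        raise DesignError(f"cannot place {n_mut} mutations in {len(candidates)} positions")
    positions = sorted(rng.choice(candidates, size=n_mut, replace=False).tolist())
    muts = []
    for pos in positions:
        orig = v.sequence[pos]
        alternatives = [b for b in "ACGT" if b != orig]
        muts.append((int(pos), orig, alternatives[int(rng.integers(3))]))
    return muts


@dataclass
class ValidationReport:
    passed: bool
    violations: list[tuple[str, str, str]] = field(default_factory=list)  # (id, rule, detail)

    def rules_violated(self) -> set[str]:
        return {rule for _, rule, _ in self.violations}


def validate_standard_set(spike_set: SpikeInSet, db: GermlineDatabase) -> ValidationReport:
    """Check every set- and standard-level invariant; violations are report
    content, not exceptions."""
    violations: list[tuple[str, str, str]] = []

    def add(std_id: str, rule: str, detail: str = "") -> None:
        violations.append((std_id, rule, detail))

    layout = spike_set.layout
    if not layout.identifier_absent_from(db):
        add("*", "identifier_in_germline", "synthetic identifier occurs in a germline sequence")

    aa_seen: dict[str, str] = {}
    for s in spike_set.standards:
        try:
            aa = translate(s.cdr3_nt)
        except ValueError:
            add(s.standard_id, "cdr3_frame", "cdr3_nt length not divisible by 3")
            aa = None
        if aa is not None and aa != s.cdr3_aa:
            add(s.standard_id, "cdr3_translation", f"{aa} != {s.cdr3_aa}")
        if not (s.cdr3_aa.startswith("C") and s.cdr3_aa.endswith("W")):
            add(s.standard_id, "cdr3_anchors", s.cdr3_aa)
        if s.cdr3_aa in aa_seen:
            add(s.standard_id, "cdr3_aa_uniqueness", f"duplicate of {aa_seen[s.cdr3_aa]}")
        else:
            aa_seen[s.cdr3_aa] = s.standard_id

        v = db.v_segments.get(s.v_name)
        j = db.j_segments.get(s.j_name)
        if v is None or j is None:
            add(s.standard_id, "unknown_segment", f"{s.v_name}/{s.j_name}")
            continue

        positions = [m[0] for m in s.designed_mutations]
        if len(set(positions)) != len(positions):
            add(s.standard_id, "mutation_positions_unique", str(positions))
        if any(not (0 <= p < len(v.sequence)) for p in positions):
            add(s.standard_id, "mutation_positions_in_v", str(positions))
            continue

        try:
            expected = assemble_full_sequence(
                layout, v, j, s.cdr3_nt, s.designed_mutations, s.subclass_label
            )
        except (DesignError, KeyError) as exc:
            add(s.standard_id, "assembly", str(exc))
            continue
        if expected != s.full_sequence:
            add(s.standard_id, "v_region_matches_germline",
                "full sequence differs from layout assembly with declared mutations")

        for part_name, part in (
            ("conserved_5p", layout.conserved_5p),
            ("cdr3", s.cdr3_nt),
            ("identifier", layout.synthetic_identifier),
            ("constant_prefix", layout.constant_prefixes.get(s.subclass_label, "")),
        ):
            if part and part not in s.full_sequence:
                add(s.standard_id, f"layout_contains_{part_name}", "")

    if spike_set.standards:
        total = sum(s.relative_concentration for s in spike_set.standards)
        if abs(total - 1.0) > 1e-9:
            add("*", "concentration_sum", f"sum={total!r}")
        if len(spike_set.standards) > 1:
            dmat = pairwise_cdr3_distances(spike_set, level="nt")
            off = dmat[np.triu_indices(len(dmat), k=1)]
            if off.min() < spike_set.min_cdr3_nt_distance:
                add("*", "min_cdr3_nt_distance",
                    f"min pairwise distance {int(off.min())} < {spike_set.min_cdr3_nt_distance}")

    return ValidationReport(passed=not violations, violations=violations)


# ---------------------------------------------------------------------------
# Pool manifest and sequence output
# ---------------------------------------------------------------------------

def write_pool_manifest(spike_set: SpikeInSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("standard_id\trelative_concentration\n")
        for s in spike_set.standards:
            fh.write(f"{s.standard_id}\t{s.relative_concentration:.12g}\n")


def read_pool_manifest(path: str | Path, tolerance: float = 1e-6) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("standard_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DesignError(f"manifest line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                out[parts[0]] = float(parts[1])
            except ValueError:
                raise DesignError(f"manifest line {lineno}: bad concentration {parts[1]!r}")
    total = sum(out.values())
    if abs(total - 1.0) > tolerance:
        raise DesignError(f"manifest concentrations sum to {total}, expected 1")
    return out


def write_layout_yaml(layout: StandardLayout, path: str | Path) -> None:
    import yaml

    Path(path).write_text(
        yaml.safe_dump(
            {
                "conserved_5p": layout.conserved_5p,
                "leader": layout.leader,
                "synthetic_identifier": layout.synthetic_identifier,
                "constant_prefixes": dict(layout.constant_prefixes),
            }
        )
    )


def read_layout_yaml(path: str | Path) -> StandardLayout:
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    return StandardLayout(**data)


def read_standards_fasta(
    path: str | Path,
    layout: StandardLayout,
    db: GermlineDatabase,
    manifest: Mapping[str, float] | None = None,
    min_cdr3_nt_distance: int = 9,
) -> SpikeInSet:
    """Reconstruct a SpikeInSet from its FASTA (ids and ``v=.. j=.. subclass=..``
    descriptions), the shared layout, and the germline database."""
    from Bio import SeqIO

    standards = []
    prefix_len = len(layout.conserved_5p) + len(layout.leader)
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        v = db.v_segments[fields["v"]]
        j = db.j_segments[fields["j"]]
        full = str(rec.seq)
        v_obs = full[prefix_len : prefix_len + v.anchor_offset]
        mutations = [
            (i, v.sequence[i], v_obs[i])
            for i in range(len(v_obs))
            if v_obs[i] != v.sequence[i]
        ]
        ident_pos = full.rindex(layout.synthetic_identifier)
        j_suffix_len = len(j.sequence) - (j.anchor_offset + 3)
        cdr3_nt = full[prefix_len + v.anchor_offset : ident_pos - j_suffix_len]
        conc = manifest.get(rec.id, 0.0) if manifest else 0.0
        standards.append(
            SpikeInStandard(
                standard_id=rec.id,
                v_name=v.name,
                j_name=j.name,
                cdr3_nt=cdr3_nt,
                cdr3_aa=translate(cdr3_nt),
                designed_mutations=mutations,
                full_sequence=full,
                relative_concentration=conc,
                subclass_label=fields.get("subclass", "IgG1"),
            )
        )
    return SpikeInSet(standards, layout, min_cdr3_nt_distance)


def write_standards_fasta(spike_set: SpikeInSet, path: str | Path) -> None:
    recs = []
    for s in spike_set.standards:
        desc = f"v={s.v_name} j={s.j_name} subclass={s.subclass_label}"
        recs.append(SeqRecord(Seq(s.full_sequence), id=s.standard_id, description=desc))
    seqio_write(recs, str(path), "fasta-2line")


def write_standards_genbank(
    spike_set: SpikeInSet, db: GermlineDatabase, path: str | Path
) -> None:
    """GenBank flat file with annotated layout features per standard."""
    layout = spike_set.layout
    recs = []
    for s in spike_set.standards:
        v = db.v_segments[s.v_name]
        rec = SeqRecord(Seq(s.full_sequence), id=s.standard_id, name=s.standard_id,
                        description=f"synthetic spike-in standard {s.standard_id}",
                        annotations={"molecule_type": "DNA"})
        pos = 0
        for label, length in (
            ("conserved_5p", len(layout.conserved_5p)),
            ("leader", len(layout.leader)),
            ("V_region", v.anchor_offset),
            ("CDR3", len(s.cdr3_nt)),
        ):
            rec.features.append(
                SeqFeature(FeatureLocation(pos, pos + length), type="misc_feature",
                           qualifiers={"label": [label]})
            )
            pos += length
        j = db.j_segments[s.j_name]
        j_len = len(j.sequence) - (j.anchor_offset + 3)
        for label, length in (
            ("J_region", j_len),
            ("identifier", len(layout.synthetic_identifier)),
            ("constant_prefix", len(layout.constant_prefixes[s.subclass_label])),
        ):
            rec.features.append(
                SeqFeature(FeatureLocation(pos, pos + length), type="misc_feature",
                           qualifiers={"label": [label]})
            )
            pos += length
        recs.append(rec)
    seqio_write(recs, str(path), "genbank")
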