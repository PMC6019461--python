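"""Synthetic Ig-seq data with the molecular amplification fingerprinting
(MAF) read structure.

The generative model mirrors the wet-lab protocol stage by stage:

1.  *Transcription / reverse transcription.*  Template molecules are drawn
    multinomially from a spike-in pool (by manifest concentration) and/or a
    simulated B-cell repertoire (by per-replicate cell counts).  Each cDNA
    molecule receives an independent uniform random reverse identifier (RID).
2.  *Multiplex PCR.*  Each molecule acquires ``1 + Poisson(lambda_v)``
    distinct forward identifiers (FIDs), with ``lambda_v`` proportional to
    the per-V-gene primer efficiency — so the FID:RID ratio encodes
    amplification bias.  PCR substitution errors are placed on a simulated
    amplification genealogy: an error introduced at cycle *c* is shared by
    all sequenced reads descending from that strand, so early-cycle errors
    produce correlated errors within a RID group (the hard case for
    consensus building).
3.  *Sequencing.*  The per-molecule read count is Poisson with mean
    proportional to the molecule's amplification yield; with
    ``min_one_read=False`` molecules can drop out entirely (the undersampled
    regime in which molecular counting itself becomes biased and FID
    normalization has something to correct).  Sequencing substitution errors
    are i.i.d. per base; bases carrying an injected sequencing error are
    written with Phred 15, all others with Phred 37.

Reads are emitted pre-merged as ``FID + insert + revcomp(RID)``; a paired
mode splits each read in two with a fixed overlap for merge testing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import NT_BYTES, array_to_seq, random_codons, revcomp, seq_to_array
from .germline import GermlineDatabase, GermlineSegment
from .standards import SpikeInSet, StandardLayout

Q_HIGH = chr(37 + 33)  # Phred 37
Q_LOW_BYTE = 15 + 33


class SimulationError(ValueError):
    pass


@dataclass
class SimulatorParams:
    """Knobs of the library-preparation and sequencing model.

    Defaults follow the protocol being emulated: 12-nt RID (theoretical
    diversity 4^12 ~ 1.7e7), 10-nt FID (~1.0e6), 20 first-PCR cycles.
    """

    n_transcripts: int = 1000
    rid_length: int = 12
    fid_length: int = 10
    pcr_cycles: int = 20
    pcr_error_rate: float = 1e-4  # substitutions per base per cycle
    seq_error_rate: float = 3e-3  # substitutions per base per read
    efficiency: Mapping[str, float] | None = None  # v_name -> (0, 1]
    fid_lambda_scale: float = 3.0  # lambda_v = scale * efficiency_v
    reads_per_molecule_mean: float = 10.0
    min_one_read: bool = True  # truncate read counts at >= 1
    spikein_fraction: float = 0.05  # of transcripts when mixing pool + repertoire
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pcr_error_rate", "seq_error_rate"):
            rate = getattr(self, name)
            if not (0 <= rate < 0.5):
                raise SimulationError(f"{name} must be in [0, 0.5), got {rate}")
        if self.rid_length < 6 or self.fid_length < 6:
            raise SimulationError("UID lengths must be >= 6")
        if self.n_transcripts < 1:
            raise SimulationError("n_transcripts must be >= 1")
        if self.reads_per_molecule_mean <= 0:
            raise SimulationError("reads_per_molecule_mean must be positive")
        if self.efficiency is not None:
            for v, e in self.efficiency.items():
                if not (0 < e <= 1):
                    raise SimulationError(f"efficiency[{v!r}] must be in (0, 1]")


@dataclass
class RepertoireParams:
    """Conditions of the simulated B-cell compartment.

    Naive (CD27-IgM+) defaults: single-variant IgM clones, ~0.2 mutations,
    each clone confined to one cellular replicate.  Memory (CD27+IgG+)
    defaults: clonally expanded lineages with ~22 mutations per variant and
    IgG subclass weights near the observed 5:3:1 IgG1:IgG2:IgG3 with IgG4
    nearly absent.  The protocol-scale aliquot is 200,000 cells in each of 5
    cellular replicates; simulations typically pass smaller values.
    """

    subset: str = "memory"  # naive | memory
    n_clones: int = 100
    clone_size_distribution: tuple = ("lognormal", 1.0, 1.0)  # or ("uniform_singletons",)
    shm_per_variant: float | None = None  # Poisson mean; default 0.2 naive / 22 memory
    variants_per_clonotype: tuple = ("poisson_plus_one", 2.0)
    subclass_weights: Mapping[str, float] | None = None
    n_replicates: int = 5
    cells_per_replicate: int = 200_000
    cdr3_aa_length: tuple[int, int] = (8, 24)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subset not in ("naive", "memory"):
            raise SimulationError(f"subset must be naive or memory, got {self.subset!r}")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")
        if self.shm_per_variant is None:
            self.shm_per_variant = 0.2 if self.subset == "naive" else 22.0
        if self.subclass_weights is None:
            if self.subset == "naive":
                self.subclass_weights = {"IgM": 1.0}
            else:
                self.subclass_weights = {"IgG1": 5.0, "IgG2": 3.0, "IgG3": 1.0, "IgG4": 0.05}
        weights = list(self.subclass_weights.values())
        if any(w < 0 for w in weights) or sum(weights) == 0:
            raise SimulationError("subclass weights must be non-negative, not all zero")


@dataclass
class Variant:
    """One VDJ nt variant of a clonal lineage."""

    sequence: str  # layout insert (V...J...constant prefix), pre-error
    shm_positions: list[int]
    subclass_label: str
    cell_counts: np.ndarray  # per replicate


@dataclass
class CloneLineage:
    clone_id: str
    v_name: str
    j_name: str
    cdr3_nt: str
    cdr3_aa: str
    variants: list[Variant]


@dataclass
class TrueMolecule:
    molecule_id: int
    source: str  # standard_id or clone_id
    replicate_id: int
    true_sequence: str
    rid: str
    subclass_label: str
    v_name: str
    j_name: str
    cdr3_aa: str


@dataclass
class SimulatedReads:
    """In-memory simulated dataset: reads plus complete ground truth."""

    reads: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    truth: pd.DataFrame  # read_id -> molecule ground truth
    molecules: list[TrueMolecule]
    rid_collisions: int = 0

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq, qual in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Repertoire generation
# ---------------------------------------------------------------------------

def _biological_insert(
    v: GermlineSegment,
    j: GermlineSegment,
    cdr3_nt: str,
    c_prefix: str,
    shm_positions: Sequence[int],
    rng: np.random.Generator,
) -> tuple[str, list[int]]:
    """Insert = V(to anchor) + CDR3 + J(after anchor) + constant prefix, with
    SHM substitutions applied in the V/J regions outside the anchors."""
    body = v.sequence[: v.anchor_offset] + cdr3_nt + j.sequence[j.anchor_offset + 3 :]
    arr = seq_to_array(body)
    applied = []
    for pos in shm_positions:
        orig = arr[pos]
        choices = NT_BYTES[NT_BYTES != orig]
        arr[pos] = choices[rng.integers(3)]
        applied.append(int(pos))
    return array_to_seq(arr) + c_prefix, applied


def generate_repertoire(
    db: GermlineDatabase,
    params: RepertoireParams,
    primer_footprint: tuple[int, int] = (0, 21),
) -> list[CloneLineage]:
    """Simulate clonal lineages with junctions, SHM, subclasses, and
    per-replicate cell counts.

    Naive subset: one variant per clone, the clone's cells confined to a
    single replicate.  Memory subset: clone sizes follow
    ``clone_size_distribution``, cells spread multinomially over replicates,
    and each lineage carries ``variants_per_clonotype`` distinct nt variants.
    SHM substitutions land in the V/J regions outside the anchor codons and
    outside the multiplex-primer footprint.
    """
    db.require_annotatable()
    rng = np.random.default_rng(params.seed)
    v_names = sorted(db.v_segments)
    j_names = sorted(db.j_segments)
    c_prefixes = db.constant_prefixes()
    labels = sorted(params.subclass_weights)
    probs = np.array([params.subclass_weights[l] for l in labels], dtype=float)
    probs /= probs.sum()

    clones: list[CloneLineage] = []
    for ci in range(params.n_clones):
        v = db.v_segments[v_names[int(rng.integers(len(v_names)))]]
        j = db.j_segments[j_names[int(rng.integers(len(j_names)))]]
        lo, hi = params.cdr3_aa_length
        aa_len = int(np.clip(round(rng.normal(15, 3)), lo, hi))
        cdr3_nt = (
            v.anchor_codon
            + random_codons(rng, aa_len - 2)
            + j.sequence[j.anchor_offset : j.anchor_offset + 3]
        )
        from ._util import translate

        cdr3_aa = translate(cdr3_nt)

        if params.subset == "naive":
            n_variants = 1
        else:
            kind, *args = params.variants_per_clonotype
            if kind == "fixed":
                n_variants = int(args[0])
            elif kind == "poisson_plus_one":
                n_variants = 1 + int(rng.poisson(args[0]))
            else:
                raise SimulationError(f"unknown variants_per_clonotype {kind!r}")

        # mutable positions: V outside footprint and anchor, J after anchor codon
        v_positions = np.arange(primer_footprint[1], v.anchor_offset)
        j_start = v.anchor_offset + len(cdr3_nt)
        j_positions = np.arange(j_start, j_start + len(j.sequence) - (j.anchor_offset + 3))
        mutable = np.concatenate([v_positions, j_positions])

        if params.subset == "naive":
            total_cells = 1
            if params.clone_size_distribution[0] == "lognormal":
                mu, sigma = params.clone_size_distribution[1:]
                total_cells = max(1, int(round(rng.lognormal(mu, sigma))))
            rep = int(rng.integers(params.n_replicates))
            cell_matrix = np.zeros((1, params.n_replicates), dtype=np.int64)
            cell_matrix[0, rep] = total_cells
        else:
            if params.clone_size_distribution[0] == "uniform_singletons":
                total_cells = n_variants
            else:
                mu, sigma = params.clone_size_distribution[1:]
                total_cells = max(n_variants, int(round(rng.lognormal(mu, sigma) * n_variants)))
            # cells split over (variant, replicate) cells uniformly
            flat = rng.multinomial(
                total_cells, np.full(n_variants * params.n_replicates,
                                     1.0 / (n_variants * params.n_replicates))
            )
            cell_matrix = flat.reshape(n_variants, params.n_replicates)
            # guarantee each variant exists somewhere
            for vi in range(n_variants):
                if cell_matrix[vi].sum() == 0:
                    cell_matrix[vi, int(rng.integers(params.n_replicates))] = 1

        variants: list[Variant] = []
        for vi in range(cell_matrix.shape[0]):
            n_shm = int(rng.poisson(params.shm_per_variant))
            n_shm = min(n_shm, len(mutable))
            positions = rng.choice(mutable, size=n_shm, replace=False).tolist() if n_shm else []
            label = labels[int(rng.choice(len(labels), p=probs))]
            seq, applied = _biological_insert(
                v, j, cdr3_nt, c_prefixes[label], positions, rng
            )
            variants.append(
                Variant(sequence=seq, shm_positions=sorted(applied),
                        subclass_label=label, cell_counts=cell_matrix[vi])
            )

        clones.append(
            CloneLineage(
                clone_id=f"CL-{ci + 1:05d}",
                v_name=v.name,
                j_name=j.name,
                cdr3_nt=cdr3_nt,
                cdr3_aa=cdr3_aa,
                variants=variants,
            )
        )
    return clones


# ---------------------------------------------------------------------------
# Reverse transcription + RID tagging
# ---------------------------------------------------------------------------

def transcribe_and_tag(
    params: SimulatorParams,
    pool: SpikeInSet | None = None,
    manifest: Mapping[str, float] | None = None,
    repertoire: Sequence[CloneLineage] | None = None,
) -> tuple[list[TrueMolecule], int]:
    """Draw template molecules and attach one random RID to each.

    Returns ``(molecules, rid_collisions)``; the collision count is the
    number of molecules whose RID duplicates an earlier molecule's RID.
    """
    if pool is None and repertoire is None:
        raise SimulationError("need a spike-in pool and/or a repertoire")
    rng = np.random.default_rng(params.seed)

    sources: list[tuple[str, str, int, str, str, str, str]] = []
    weights: list[float] = []
    # (source_id, sequence, replicate, subclass, v, j, cdr3_aa)
    if pool is not None:
        man = manifest if manifest is not None else pool.manifest()
        total = sum(man.values())
        if abs(total - 1.0) > 1e-6:
            raise SimulationError(f"manifest concentrations sum to {total}, expected 1")
        frac = params.spikein_fraction if repertoire is not None else 1.0
        for s in pool.standards:
            sources.append(
                (s.standard_id, s.full_sequence, 0, s.subclass_label,
                 s.v_name, s.j_name, s.cdr3_aa)
            )
            weights.append(man[s.standard_id] * frac)
    if repertoire is not None:
        cell_total = sum(
            v.cell_counts.sum() for cl in repertoire for v in cl.variants
        )
        frac = 1.0 - params.spikein_fraction if pool is not None else 1.0
        for cl in repertoire:
            for v in cl.variants:
                for rep, n_cells in enumerate(v.cell_counts):
                    if n_cells > 0:
                        sources.append(
                            (cl.clone_id, v.sequence, rep, v.subclass_label,
                             cl.v_name, cl.j_name, cl.cdr3_aa)
                        )
                        weights.append(frac * n_cells / cell_total)

    w = np.asarray(weights, dtype=float)
    w /= w.sum()
    counts = rng.multinomial(params.n_transcripts, w)

    expected_collisions = params.n_transcripts**2 / (4**params.rid_length)
    if expected_collisions > 1e-3:
        import warnings

        warnings.warn(
            f"RID collision probability non-negligible "
            f"(n^2/4^L = {expected_collisions:.2e}); collisions are counted",
            stacklevel=2,
        )

    molecules: list[TrueMolecule] = []
    seen_rids: set[str] = set()
    collisions = 0
    mol_id = 0
    for (src, seq, rep, label, v_name, j_name, cdr3_aa), n in zip(sources, counts):
        for _ in range(int(n)):
            rid = array_to_seq(NT_BYTES[rng.integers(0, 4, size=params.rid_length)])
            if rid in seen_rids:
                collisions += 1
            seen_rids.add(rid)
            molecules.append(
                TrueMolecule(
                    molecule_id=mol_id,
                    source=src,
                    replicate_id=rep,
                    true_sequence=seq,
                    rid=rid,
                    subclass_label=label,
                    v_name=v_name,
                    j_name=j_name,
                    cdr3_aa=cdr3_aa,
                )
            )
            mol_id += 1
    if not molecules:
        raise SimulationError("no molecules drawn")
    return molecules, collisions


# ---------------------------------------------------------------------------
# PCR amplification + sequencing
# ---------------------------------------------------------------------------

def _truncated_poisson(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1, elementwise."""
    out = rng.poisson(lam)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam[zero])
        zero = out == 0
    return out


def amplify_and_sequence(
    molecules: Sequence[TrueMolecule],
    params: SimulatorParams,
    out_prefix: str | Path | None = None,
) -> SimulatedReads:
    """Simulate multiplex PCR (FID tagging, genealogy-correlated PCR errors)
    and sequencing (Poisson read depth, i.i.d. substitution errors).

    If ``out_prefix`` is given, writes ``<prefix>.fastq`` and
    ``<prefix>.truth.tsv``.
    """
    if not molecules:
        raise SimulationError("molecules must be non-empty")
    rng = np.random.default_rng(params.seed + 1)

    eff = params.efficiency
    if eff is not None:
        for m in molecules:
            if m.v_name not in eff:
                raise SimulationError(f"no efficiency for V gene {m.v_name!r}")

    n_mol = len(molecules)
    eff_arr = np.array(
        [1.0 if eff is None else eff[m.v_name] for m in molecules], dtype=float
    )
    # distinct FIDs per molecule: 1 + Poisson(scale * efficiency)
    n_fids = 1 + rng.poisson(params.fid_lambda_scale * eff_arr)
    # read depth proportional to amplification yield (FID count)
    lam = params.reads_per_molecule_mean * n_fids / n_fids.mean()
    if params.min_one_read:
        n_reads = _truncated_poisson(rng, lam)
    else:
        n_reads = rng.poisson(lam)

    cycles = params.pcr_cycles
    reads: list[tuple[str, str, str]] = []
    truth_rows: list[tuple] = []
    for mi, mol in enumerate(molecules):
        n = int(n_reads[mi])
        if n == 0:
            continue
        fids = [
            array_to_seq(NT_BYTES[rng.integers(0, 4, size=params.fid_length)])
            for _ in range(int(n_fids[mi]))
        ]
        fid_choice = rng.integers(0, len(fids), size=n)

        insert = seq_to_array(mol.true_sequence)
        L = len(insert)
        mat = np.tile(insert, (n, 1))

        # PCR errors on the amplification genealogy: each read is a leaf of a
        # depth-`cycles` binary tree; strands created at cycle c (odd node
        # ids) carry fresh errors shared by all their sampled descendants.
        if params.pcr_error_rate > 0 and cycles > 0:
            mu = L * params.pcr_error_rate
            leaves = rng.integers(0, 2**cycles, size=n, dtype=np.int64)
            for c in range(1, cycles + 1):
                anc = leaves >> (cycles - c)
                new_strands = np.unique(anc[anc % 2 == 1])
                if len(new_strands) == 0:
                    continue
                n_mut = rng.poisson(mu, size=len(new_strands))
                for strand, k in zip(new_strands, n_mut):
                    if k == 0:
                        continue
                    rows = anc == strand
                    pos = rng.integers(0, L, size=k)
                    for p in pos:
                        choices = NT_BYTES[NT_BYTES != insert[p]]
                        mat[rows, p] = choices[rng.integers(3)]

        rid_rc = revcomp(mol.rid)
        for ri in range(n):
            full = np.concatenate(
                [seq_to_array(fids[fid_choice[ri]]), mat[ri], seq_to_array(rid_rc)]
            )
            qual = np.full(len(full), 37 + 33, dtype=np.uint8)
            if params.seq_error_rate > 0:
                k = rng.binomial(len(full), params.seq_error_rate)
                if k:
                    pos = rng.choice(len(full), size=k, replace=False)
                    for p in pos:
                        choices = NT_BYTES[NT_BYTES != full[p]]
                        full[p] = choices[rng.integers(3)]
                    qual[pos] = Q_LOW_BYTE
            read_id = f"r{mol.molecule_id}_{ri}"
            reads.append((read_id, array_to_seq(full), qual.tobytes().decode("ascii")))
            truth_rows.append(
                (read_id, mol.molecule_id, mol.source, mol.replicate_id,
                 mol.v_name, mol.j_name, mol.cdr3_aa, mol.true_sequence)
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "molecule_id", "source", "replicate_id",
                 "v_name", "j_name", "cdr3_aa", "true_sequence"],
    )
    result = SimulatedReads(reads=reads, truth=truth, molecules=list(molecules))
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        result.write_fastq(out_prefix.with_suffix(".fastq"))
        result.write_truth(out_prefix.with_suffix(".truth.tsv"))
    return result


def simulate_dataset(
    params: SimulatorParams,
    pool: SpikeInSet | None = None,
    manifest: Mapping[str, float] | None = None,
    repertoire: Sequence[CloneLineage] | None = None,
    out_prefix: str | Path | None = None,
) -> SimulatedReads:
    """transcribe_and_tag + amplify_and_sequence in one call."""
    molecules, collisions = transcribe_and_tag(
        params, pool=pool, manifest=manifest, repertoire=repertoire
    )
    result = amplify_and_sequence(molecules, params, out_prefix=out_prefix)
    result.rid_collisions = collisions
    return result


def split_paired(
    reads: Iterable[tuple[str, str, str]],
    read_length: int = 250,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Split merged reads into an R1/R2 pair with a fixed overlap.

    R1 is the first ``read_length`` bases; R2 is the reverse complement of
    the last ``read_length`` bases (qualities reversed accordingly).
    """
    r1, r2 = [], []
    for read_id, seq, qual in reads:
        k = min(read_length, len(seq))
        r1.append((read_id, seq[:k], qual[:k]))
        r2.append((read_id, revcomp(seq[-k:]), qual[-k:][::-1]))
    return r1, r2


def simulate_incidence(
    n_species: int,
    n_replicates: int,
    detection_prob: float,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Presence/absence incidence matrix under homogeneous detection.

    Each of ``n_species`` clonotypes is detected in each replicate
    independently with ``detection_prob``; rows never detected are dropped
    (they are the undetected richness an incidence estimator must recover).
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    mat = rng.random((n_species, n_replicates)) < detection_prob
    return mat[mat.any(axis=1)]
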