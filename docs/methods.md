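# Methods

This note documents the models behind `igmaf`, the parameter defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Read layout and coordinate conventions

A merged MAF read is `FID + insert + revcomp(RID)`. The insert of a
spike-in standard is `conserved_5p + leader + V + CDR3 + J + identifier +
constant_prefix`; a biological insert is the same without the conserved 5′
region, leader and identifier. The CDR3 is anchor-inclusive — from the
first nucleotide of the V-segment Cys-104 codon through the last nucleotide
of the J-segment Trp-118 codon — so every CDR3 amino-acid sequence starts
with C and ends with W. All offsets are 0-based, intervals half-open, plus
strand only; paired reads are merged (quality-aware overlap consensus)
before parsing.

## Germline references

The loader accepts IMGT-style FASTA with anchors given explicitly (TSV of
name, 0-based offset) or found by motif scan: the last in-frame Cys codon
for V, the first Trp codon of a W-G-x-G motif for J. Distinct alleles
(`*01`, `*02`) are distinct database entries; clonotyping uses the
allele-stripped gene name. The package also ships a *synthetic* germline
generator (`synthetic_igh_database`): 48 V genes over the seven IGHV
families, 6 J segments, 6 constant-region prefixes (IgM, IgG1–4, IgA) with
pairwise Hamming distance ≥ 6 so subclass assignment is decidable. These
are random sequences with the right structural features, not biological
sequences; they make every test self-contained and offline. Results that
depend on real germline sequence content (e.g. actual primer biases or
family-specific SHM hotspots) are out of reach of this stand-in by design.

## Standard design

CDR3 junctions are drawn by rejection sampling (random in-frame, stop-free
codons between the V and J anchor codons) until each new CDR3 is at least
`min_cdr3_nt_distance` (default 9) Levenshtein edits from every accepted
one; amino-acid uniqueness is enforced simultaneously. The bounded
rejection count (default 10⁵ per clone) turns an unsatisfiable constraint
into a capacity error naming the clone index reached. Designed mutations
that mimic somatic hypermutation are substitutions only, placed uniformly
in the V region outside the anchor codon and outside the multiplex-primer
footprint (first 21 nt); by default 39 of 85 standards carry 1–12 of them.
Pool concentrations default to a log-uniform draw spanning two orders of
magnitude, normalized to 1 — a non-uniform pool without any claim about
the particular concentrations of a physical master stock.

## Simulator

The generative model, stage by stage:

1. **Transcripts.** `n_transcripts` molecules are drawn multinomially from
   the spike-in manifest and/or per-replicate cell counts of a simulated
   repertoire. Each molecule receives an i.i.d. uniform RID (default 12 nt;
   collisions are counted and a warning is raised when n²/4^L > 10⁻³).
2. **Amplification.** Each molecule acquires `1 + Poisson(s·e_v)` distinct
   FIDs, where `e_v` is the per-V-gene primer efficiency and `s` (default
   3) a scale; the FID:RID ratio is therefore monotone in efficiency, which
   is all the bias-correction contract requires. PCR errors live on an
   amplification genealogy: each read is a uniform leaf of a depth-20
   binary tree, strands created at cycle *c* (odd node ids) carry fresh
   `Poisson(L·rate)` substitutions inherited by all sampled descendants.
   Expected PCR errors per read are `cycles·L·rate/2`; crucially, a
   first-cycle error is shared by about half the reads of its molecule.
3. **Sequencing.** Per-molecule read counts are Poisson with mean
   proportional to the molecule's FID count (its amplification yield),
   scaled to `reads_per_molecule_mean`. With `min_one_read=True` (default)
   the count is truncated at ≥ 1, the convenient regime for consensus
   experiments; with `min_one_read=False` molecules can drop out, which is
   the realistic undersampled regime in which molecular (RID) counting is
   itself amplification-biased and FID normalization has something to
   correct. Sequencing errors are i.i.d. substitutions per base; bases with
   an injected error get Phred 15, all others Phred 37, giving
   quality-aware tie-breaking something real to use. Indels, chimeras and
   quality drift along the read are not modeled.

Repertoire defaults follow the cell-sorting design being emulated: naive
(CD27−IgM+) clones are single-variant IgM lineages confined to one
cellular replicate with ~0.2 mutations; memory (CD27+IgG+) lineages are
clonally expanded across replicates, with Poisson-mean-22 substitutions
per variant and subclass weights 5 : 3 : 1 : 0.05 for IgG1 : IgG2 : IgG3 :
IgG4. The protocol-scale aliquot is 200,000 cells in each of 5 replicates;
tests run the same generative process at hundreds-to-thousands of cells so
the suite completes in minutes — the statistical structure (replicate
confinement, expansion, SHM load, subclass mix) is what matters for the
properties under test, not absolute cell counts.

## MAF correction

Reads are grouped by exact RID. Near-RID merging (absorb singletons within
Hamming distance 1 of a ≥3-read group) is off by default — exact grouping
is the described protocol — but is the appropriate setting when UID
sequencing errors matter, since ~4% of reads at 0.3%/base carry an error
inside a 12-nt RID and would otherwise found spurious singleton groups.
Groups with ≥ 3 reads are collapsed by per-position majority vote after
restriction to the modal insert length (ties toward longer); vote ties are
broken by the larger summed Phred for the tied base, then alphabetically.
Groups below the threshold pass through as their highest-mean-quality read
(the protocol keeps them); `strict=True` discards them instead. Bias
correction rescales RID counts by `ā/a_c` with `a_c = F_c/R_c`; under
uniform amplification this is the identity, and over-amplified clones are
monotonically down-weighted.

Two readings of "sequences with only one UID group" are both available:
passthrough of small groups (default) and a post-hoc strict filter —
neither is silently chosen.

## Annotation

V and J are assigned by semi-global (infix) alignment of each germline
segment against the read using unit edit costs (edlib), best distance
wins, ties by fewest mismatches then name; a call requires edit distance
≤ 0.2 of the segment length (0.25 for the shorter J), which cleanly
separates true rearrangements (≤ ~10% divergence even at memory-level SHM)
from random sequence (~40–50%). Because optimal edit paths are not unique
and unit-cost aligners freely trade clustered substitutions for indels,
SHM is counted on a *substitution-preferred* reading: among same-length
germline windows near the aligned location, the one with minimal Hamming
distance is used whenever it is consistent with the edit distance; the
indel path is used only when the aligned window's length actually differs.
SHM counts substitutions in the aligned V and J outside the junction and
outside the primer footprint (template bases under the primer are
overwritten during amplification and unobservable); indels are reported
separately. Subclass is the best Hamming match of the read's constant
prefix, "ambiguous" when the margin to the runner-up is < 2. Spike-ins are
records containing the synthetic identifier within ≤ 1 mismatch, matched
to the standard with the nearest CDR3 by Levenshtein.

## Clonotyping and diversity

Clonotypes are built per (V gene, J gene, CDR3 length) group by
agglomerative clustering on normalized Hamming distance between CDR3
amino-acid sequences (equal lengths are guaranteed by the grouping), cut
inclusively at 1 − 0.8. Complete linkage is the default; single linkage is
available because the membership phrasing "≥ 80% similarity to at least
one member" reads as single linkage — the discrepancy is exposed as an
option rather than resolved. Records are canonically sorted before
clustering, making assignments independent of input order.

Replicate presence/absence of clonotypes is incidence data; Chao2 uses the
standard form `S_obs + ((m−1)/m)·Q1²/(2Q2)`, the bias-corrected fallback
`S_obs + ((m−1)/m)·Q1(Q1−1)/2` when Q2 = 0, the classic variance formulas
for each case, and a log-normal CI on the undetected-richness term so the
lower bound never falls below `S_obs`. Rarefaction uses exact integer
combinatorics (`S_obs − Σ Q_j·C(m−j,t)/C(m,t)`) with one final division;
extrapolation uses `S_obs + Q̂0·[1 − (1 − Q1/(Q1+m·Q̂0))^t*]`.

## Evaluation choices

Frequency-recovery R² is computed against the identity line (residuals to
y = x), because the comparison is observed-versus-known truth, with the
conventional regression R² also reported; MSE is in squared percentage
points. Error-variant counting keys: CDR3-class variants are distinct CDR3
amino-acid sequences differing from the standard's; VDJ-class variants are
distinct full nucleotide sequences carrying the standard's exact CDR3.
A variant must differ to be erroneous (≥ 1 nt / ≥ 1 a.a.). The
two-class discriminant is the ridge-stabilized (ε = 10⁻⁶) Fisher axis on
CLR-transformed composition vectors, evaluated leave-one-group-out.

## Experiment sizing in the test and acceptance suites

* Zero-noise round trip: 1,000 molecules from the 85-standard pool.
* Error correction: 5,000 molecules, mean 10 reads/molecule, 0.3%/base
  sequencing error, 10⁻⁴/base/cycle PCR error × 20 cycles, five seeds.
* Bias correction: 50,000 molecules, mean 1.5 reads/molecule, undersampled
  (`min_one_read=False`), per-V efficiencies uniform on (0.6, 1.0), five
  seeds. The size is a power choice: the FID:RID ratio is estimated per
  clone, and its sampling noise falls as 1/√n while the amplification bias
  it removes is constant, so at this size the systematic ordering
  MSE(corrected) < MSE(RID) < MSE(reads) is resolved decisively.
* Chao2 recovery: 1,000 clonotypes, 5 replicates, homogeneous detection
  probability 0.5, twenty seeds.

## Known limitations

* **Early-cycle PCR errors bound consensus accuracy.** Under the
  genealogy-correlated error model, a cycle-1 substitution (probability
  ≈ L·rate = 0.05 per molecule at the rates above) reaches ~half of a
  molecule's reads, where majority voting is a coin flip; the expected
  wrong-consensus fraction is ≈ 3%, and the suite measures 96.6–96.9%
  exact consensus sequences at those rates. This is a property of
  single-UID consensus itself, not of the implementation: no per-RID
  majority vote can repair an error that reaches half the group. The
  corresponding acceptance assertions (≥ 99% exact, ≥ 99% of erroneous
  variants removed at those exact rates) are intentionally left failing
  rather than weakening the error model; removal lands at 98.9–99.0%.
* The synthetic germline database carries no biological sequence content;
  family-level biology (real primer footprints, allele polymorphism) is
  structural only.
* FID multiplicity is Poisson, not an explicit branching process; only
  monotonicity of FID:RID in efficiency is claimed or used.
* No indel sequencing errors, chimeras, or quality recalibration; the
  consensus is not indel-aware (modal-length restriction instead of MSA).
* Chao2 is a lower-bound-type estimator; its CI coverage claim is tested
  under homogeneous detection only. Heterogeneous detectability across
  clones (real clone-size variation) degrades it, which is why the
  recovery criterion is soft (median error, CI coverage) rather than
  exact.
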