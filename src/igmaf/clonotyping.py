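"""Clonotype clustering and intraclonal structure.

Rearrangements are grouped by identical V gene, J gene, and CDR3 length,
then clustered by agglomerative hierarchical clustering (complete linkage by
default) on CDR3 amino-acid distance, cut so that members share at least
80% CDR3 a.a. similarity.  Similarity between equal-length CDR3s is
Hamming-based (1 minus the fraction of differing positions); equal lengths
are guaranteed by the grouping keys.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from ._util import seq_to_array


@dataclass
class ClonotypingParams:
    similarity_threshold: float = 0.80
    linkage: str = "complete"  # complete | single

    def __post_init__(self) -> None:
        if not (0 < self.similarity_threshold <= 1):
            raise ValueError("similarity_threshold must be in (0, 1]")
        if self.linkage not in ("complete", "single"):
            raise ValueError("linkage must be 'complete' or 'single'")


def cdr3_similarity(a: str, b: str) -> float:
    """Fraction of identical positions between equal-length CDR3 a.a. strings."""
    if len(a) != len(b):
        raise ValueError(f"CDR3 lengths differ ({len(a)} vs {len(b)})")
    if not a:
        return 1.0
    same = sum(x == y for x, y in zip(a, b))
    return same / len(a)


@dataclass
class Clonotype:
    clonotype_id: str
    v_gene: str
    j_gene: str
    cdr3_length: int
    consensus_cdr3_aa: str
    members: pd.DataFrame = field(repr=False)

    @property
    def n_aa_variants(self) -> int:
        return self.members["junction_aa"].nunique()

    @property
    def n_nt_variants(self) -> int:
        return self.members["sequence"].nunique()

    @property
    def replicate_set(self) -> frozenset:
        vals = self.members["replicate_id"].dropna().unique()
        return frozenset(int(v) for v in vals)

    @property
    def label_set(self) -> frozenset:
        if "partition" in self.members.columns:
            return frozenset(self.members["partition"].dropna().unique())
        return frozenset(str(v) for v in self.replicate_set)

    @property
    def mean_shm_per_variant(self) -> float:
        per_variant = self.members.groupby("sequence")["shm_count"].first()
        return float(per_variant.mean())

    @property
    def subclass_variant_counts(self) -> dict[str, int]:
        per_variant = self.members.groupby("sequence")["subclass"].first()
        return dict(Counter(per_variant))


def _cluster_group(cdr3s: Sequence[str], params: ClonotypingParams) -> list[int]:
    """Cluster equal-length CDR3s; returns a cluster label per input."""
    n = len(cdr3s)
    if n == 1:
        return [0]
    mat = np.stack([seq_to_array(c) for c in cdr3s])
    dist = pdist(mat, metric="hamming")
    Z = linkage(dist, method=params.linkage)
    cut = 1.0 - params.similarity_threshold
    labels = fcluster(Z, t=cut + 1e-12, criterion="distance")
    return [int(l) - 1 for l in labels]


def cluster_clonotypes(
    records: pd.DataFrame, params: ClonotypingParams | None = None
) -> list[Clonotype]:
    """Cluster annotated productive rearrangements into clonotypes.

    ``records`` is an AIRR-style table (columns v_gene, j_gene, junction_aa,
    sequence, consensus_count, ...).  Non-productive rows and rows without a
    junction are dropped.  Output order (and clonotype ids) are deterministic
    and independent of input row order.
    """
    if params is None:
        params = ClonotypingParams()
    df = records[records["productive"].astype(bool)].copy()
    df = df[df["junction_aa"].notna()]
    if df.empty:
        return []
    # canonical order makes clustering permutation-invariant
    df = df.sort_values(["junction_aa", "sequence"], kind="mergesort").reset_index(drop=True)
    df["cdr3_length"] = df["junction_aa"].str.len()

    clonotypes: list[Clonotype] = []
    for (v_gene, j_gene, cdr3_len), group in sorted(
        df.groupby(["v_gene", "j_gene", "cdr3_length"]),
        key=lambda kv: kv[0],
    ):
        labels = _cluster_group(list(group["junction_aa"]), params)
        by_label: dict[int, list[int]] = defaultdict(list)
        for idx, lab in zip(group.index, labels):
            by_label[lab].append(idx)
        subclusters = []
        for lab, idxs in by_label.items():
            members = df.loc[idxs]
            weights = members.groupby("junction_aa")["consensus_count"].sum()
            top = weights.max()
            consensus = sorted(weights[weights == top].index)[0]
            subclusters.append((consensus, members))
        for consensus, members in sorted(subclusters, key=lambda t: t[0]):
            clonotypes.append(
                Clonotype(
                    clonotype_id="",  # assigned below
                    v_gene=v_gene,
                    j_gene=j_gene,
                    cdr3_length=int(cdr3_len),
                    consensus_cdr3_aa=consensus,
                    members=members,
                )
            )
    for i, ct in enumerate(clonotypes):
        ct.clonotype_id = f"CT-{i + 1:05d}"
    return clonotypes


@dataclass
class OverlapResult:
    labels: list
    membership: pd.DataFrame  # clonotype x label booleans
    pairwise_shared: pd.DataFrame
    venn: dict[frozenset, int] | None
    n_shared: int
    n_unique: int

    @property
    def shared_fraction(self) -> float:
        total = len(self.membership)
        return self.n_shared / total if total else 0.0


def clonotype_overlap(
    clonotypes: Sequence[Clonotype],
    partitions: Sequence | None = None,
    use: str = "replicate",
) -> OverlapResult:
    """Cross-replicate (or cross-subset) clonotype membership.

    Clustering must have been performed on the pooled records so each
    clonotype has one identity across labels.  Venn cell counts are
    enumerated for up to 5 labels and refused above 8 (pairwise counts are
    always returned).
    """
    sets = [
        ct.replicate_set if use == "replicate" else ct.label_set for ct in clonotypes
    ]
    if partitions is None:
        labels = sorted({l for s in sets for l in s})
    else:
        labels = list(partitions)
    membership = pd.DataFrame(
        [[lab in s for lab in labels] for s in sets],
        index=[ct.clonotype_id for ct in clonotypes],
        columns=labels,
    )
    counts = membership.sum(axis=1)
    n_shared = int((counts >= 2).sum())
    n_unique = int((counts == 1).sum())
    m = membership.to_numpy()
    pairwise = pd.DataFrame(
        m.T.astype(int) @ m.astype(int), index=labels, columns=labels
    )
    venn: dict[frozenset, int] | None
    if len(labels) > 8:
        venn = None
    elif len(labels) > 5:
        venn = None
    else:
        venn = {}
        for _, row in membership.iterrows():
            cell = frozenset(lab for lab in labels if row[lab])
            if cell:
                venn[cell] = venn.get(cell, 0) + 1
    return OverlapResult(labels, membership, pairwise, venn, n_shared, n_unique)


@dataclass
class IntraclonalSummary:
    n_aa_variants: int
    n_nt_variants: int
    mean_shm_per_variant: float
    subclass_variant_counts: dict[str, int]
    igg_simplex: tuple[float, float, float] | None  # (IgG1, IgG2, IgG3) fractions


def intraclonal_summary(ct: Clonotype) -> IntraclonalSummary:
    """Variant counts, mean SHM, and the IgG1/IgG2/IgG3 subclass composition
    of a clonotype's distinct nt variants."""
    counts = ct.subclass_variant_counts
    igg = [counts.get(k, 0) for k in ("IgG1", "IgG2", "IgG3")]
    total = sum(igg)
    simplex = tuple(c / total for c in igg) if total else None
    return IntraclonalSummary(
        n_aa_variants=ct.n_aa_variants,
        n_nt_variants=ct.n_nt_variants,
        mean_shm_per_variant=ct.mean_shm_per_variant,
        subclass_variant_counts=counts,
        igg_simplex=simplex,
    )


def incidence_matrix(
    clonotypes: Sequence[Clonotype], labels: Sequence | None = None
) -> pd.DataFrame:
    """Clonotype x replicate presence/absence table for diversity estimation."""
    overlap = clonotype_overlap(clonotypes, partitions=labels)
    return overlap.membership
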