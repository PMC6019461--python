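"""Spike-in-based accuracy metrics and repertoire-feature statistics.

Spike-in standards have known sequence and known pool concentration, so any
sequence assigned to a standard that differs from it is, by construction, an
error artifact.  Two error classes are counted per standard:

* CDR3 a.a. error variants — distinct CDR3 amino-acid sequences differing
  from the standard's CDR3 in at least one residue;
* VDJ nt error variants — distinct full-length nt sequences carrying the
  standard's exact CDR3 a.a. but differing in at least one nt.

Frequency recovery compares observed standard frequencies (by reads, by
RIDs, or after FID:RID bias correction) with the expected ones; R-squared
is computed against the identity line (the bias-free ideal), not a fitted
regression, and MSE is reported in squared percentage points.

Repertoire-feature statistics cover V-family usage, CDR3 length, SHM and
subclass distributions, the centered log-ratio (CLR) transform for
compositional vectors, a two-class Fisher linear discriminant with
leave-one-group-out evaluation, and Fisher's exact test for enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correction import bias_correct
from .germline import family_of
from .standards import SpikeInSet


# ---------------------------------------------------------------------------
# Error-variant counting
# ---------------------------------------------------------------------------

def assign_error_class(sequence: str, junction_aa: str | None, standard) -> str:
    """exact | cdr3_error_variant | vdj_nt_error_variant vs the matched standard."""
    if junction_aa != standard.cdr3_aa:
        return "cdr3_error_variant"
    if sequence != standard.full_sequence:
        return "vdj_nt_error_variant"
    return "exact"


@dataclass
class ErrorVariantReport:
    per_standard: pd.DataFrame  # standard_id, cdr3_errors, vdj_errors (+normalized)
    aligned_reads: int
    median_cdr3_errors: float
    median_vdj_errors: float
    median_cdr3_errors_per_100k: float
    median_vdj_errors_per_100k: float
    concentration_correlation: float | None = None

    def total(self, error_class: str) -> int:
        col = {"cdr3_error_variant": "cdr3_errors", "vdj_nt_error_variant": "vdj_errors"}[error_class]
        return int(self.per_standard[col].sum())


def error_variant_report(
    records: pd.DataFrame,
    standards: SpikeInSet,
    aligned_read_total: int | None = None,
    manifest: Mapping[str, float] | None = None,
) -> ErrorVariantReport:
    """Distinct erroneous variants per standard, raw and per 100,000 aligned
    reads.

    ``records`` must be spike-in records carrying ``matched_standard_id``,
    ``sequence``, ``junction_aa`` and ``duplicate_count``.  Distinct-variant
    keys: CDR3 class on the a.a. sequence, VDJ class on the full nt
    sequence.
    """
    by_id = standards.by_id()
    if aligned_read_total is None:
        aligned_read_total = int(records["duplicate_count"].sum())
    rows = []
    for std_id in sorted(by_id):
        std = by_id[std_id]
        sub = records[records["matched_standard_id"] == std_id]
        cdr3_variants = set()
        vdj_variants = set()
        for seq, aa in zip(sub["sequence"], sub["junction_aa"]):
            aa_val = aa if isinstance(aa, str) else None
            cls = assign_error_class(seq, aa_val, std)
            if cls == "cdr3_error_variant" and aa_val is not None:
                cdr3_variants.add(aa_val)
            elif cls == "vdj_nt_error_variant":
                vdj_variants.add(seq)
        rows.append((std_id, len(cdr3_variants), len(vdj_variants)))
    df = pd.DataFrame(rows, columns=["standard_id", "cdr3_errors", "vdj_errors"])
    scale = 100_000 / aligned_read_total if aligned_read_total else np.nan
    df["cdr3_errors_per_100k"] = df["cdr3_errors"] * scale
    df["vdj_errors_per_100k"] = df["vdj_errors"] * scale

    corr = None
    if manifest is not None:
        conc = df["standard_id"].map(manifest)
        total_err = df["cdr3_errors"] + df["vdj_errors"]
        if conc.notna().all() and total_err.std() > 0 and conc.std() > 0:
            corr = float(stats.pearsonr(conc, total_err)[0])

    return ErrorVariantReport(
        per_standard=df,
        aligned_reads=aligned_read_total,
        median_cdr3_errors=float(df["cdr3_errors"].median()),
        median_vdj_errors=float(df["vdj_errors"].median()),
        median_cdr3_errors_per_100k=float(df["cdr3_errors_per_100k"].median()),
        median_vdj_errors_per_100k=float(df["vdj_errors_per_100k"].median()),
        concentration_correlation=corr,
    )


def correction_efficacy(
    raw: ErrorVariantReport, corrected: ErrorVariantReport
) -> dict[str, float | None]:
    """Percent of erroneous distinct variants removed by correction, per
    class; None (n/a) when the raw total is zero."""
    out: dict[str, float | None] = {}
    for cls in ("cdr3_error_variant", "vdj_nt_error_variant"):
        raw_total = raw.total(cls)
        if raw_total == 0:
            out[cls] = None
        else:
            out[cls] = 100.0 * (1.0 - corrected.total(cls) / raw_total)
    return out


# ---------------------------------------------------------------------------
# Frequency recovery
# ---------------------------------------------------------------------------

@dataclass
class FrequencyRecoveryReport:
    mode: str
    table: pd.DataFrame  # standard_id, expected, observed
    r_squared: float  # vs the identity line
    r_squared_regression: float  # conventional Pearson r^2, for reference
    mse_pp2: float  # mean squared error in (percentage points)^2


def frequency_recovery(
    records: pd.DataFrame,
    expected: Mapping[str, float],
    mode: str = "rids",
) -> FrequencyRecoveryReport:
    """Observed vs expected standard frequencies.

    mode: ``reads`` (read counts), ``rids`` (molecular counts), or
    ``corrected`` (RID counts rescaled by the FID:RID amplification ratio).
    Standards absent from the records get observed frequency 0.
    """
    if mode not in ("reads", "rids", "corrected"):
        raise ValueError(f"unknown mode {mode!r}")
    grouped = records.groupby("matched_standard_id")
    if mode == "corrected":
        agg = grouped.agg(r=("consensus_count", "sum"), f=("fid_count", "sum"))
        observed_counts = {
            c.key: c.corrected_count
            for c in bias_correct([(i, int(r.r), int(r.f)) for i, r in agg.iterrows()])
        }
    else:
        col = "duplicate_count" if mode == "reads" else "consensus_count"
        observed_counts = grouped[col].sum().to_dict()

    ids = sorted(expected)
    obs = np.array([float(observed_counts.get(i, 0.0)) for i in ids])
    total = obs.sum()
    obs = obs / total if total > 0 else obs
    exp = np.array([expected[i] for i in ids], dtype=float)
    exp = exp / exp.sum()

    ss_res = float(((obs - exp) ** 2).sum())
    ss_tot = float(((exp - exp.mean()) ** 2).sum())
    r2_identity = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    if obs.std() > 0 and exp.std() > 0:
        r2_reg = float(stats.pearsonr(obs, exp)[0] ** 2)
    else:
        r2_reg = np.nan
    mse = float((((obs - exp) * 100.0) ** 2).mean())

    table = pd.DataFrame({"standard_id": ids, "expected": exp, "observed": obs})
    return FrequencyRecoveryReport(mode, table, r2_identity, r2_reg, mse)


# ---------------------------------------------------------------------------
# Repertoire feature summaries
# ---------------------------------------------------------------------------

def feature_summary(data, feature: str) -> pd.DataFrame:
    """Normalized distribution of a repertoire feature.

    ``data`` is either an AIRR-style DataFrame (records) or a sequence of
    clonotypes.  Features: v_family_usage, cdr3_length_dist, shm_dist,
    subclass_usage.  Fractions sum to 1; ambiguous subclass is its own
    category.
    """
    if isinstance(data, pd.DataFrame):
        if data.empty:
            raise ValueError("empty input")
        if feature == "v_family_usage":
            values = data["v_gene"].dropna().map(family_of)
        elif feature == "cdr3_length_dist":
            values = data["junction_aa"].dropna().str.len()
        elif feature == "shm_dist":
            values = data["shm_count"].dropna().astype(int)
        elif feature == "subclass_usage":
            values = data["subclass"]
        else:
            raise ValueError(f"unknown feature {feature!r}")
    else:
        clonotypes = list(data)
        if not clonotypes:
            raise ValueError("empty input")
        if feature == "v_family_usage":
            values = pd.Series([family_of(ct.v_gene) for ct in clonotypes])
        elif feature == "cdr3_length_dist":
            values = pd.Series([ct.cdr3_length for ct in clonotypes])
        elif feature == "shm_dist":
            values = pd.Series([ct.mean_shm_per_variant for ct in clonotypes])
        elif feature == "subclass_usage":
            values = pd.Series(
                [label for ct in clonotypes
                 for label, n in ct.subclass_variant_counts.items()
                 for _ in range(n)]
            )
        else:
            raise ValueError(f"unknown feature {feature!r}")
    counts = values.value_counts().sort_index()
    return pd.DataFrame({
        "category": counts.index,
        "count": counts.to_numpy(),
        "fraction": counts.to_numpy() / counts.sum(),
    })


# ---------------------------------------------------------------------------
# Compositional statistics
# ---------------------------------------------------------------------------

def clr_transform(X, pseudocount: float = 0.0) -> np.ndarray:
    """Centered log-ratio transform, row-wise; each output row sums to 0.

    ``pseudocount`` is added before taking logs so zero components can be
    handled; components must be positive afterwards.
    """
    arr = np.asarray(X, dtype=float)
    one_dim = arr.ndim == 1
    arr = np.atleast_2d(arr) + pseudocount
    if (arr <= 0).any():
        raise ValueError("components must be positive after pseudocount")
    logs = np.log(arr)
    out = logs - logs.mean(axis=1, keepdims=True)
    return out[0] if one_dim else out


@dataclass
class LDAResult:
    loadings: np.ndarray
    projections: np.ndarray
    class_means: tuple[float, float]
    holdout_predictions: np.ndarray | None = None
    holdout_accuracy: float | None = None


def _fisher_axis(X: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    sw = np.zeros((X.shape[1], X.shape[1]))
    for cls, mu in ((0, mu0), (1, mu1)):
        d = X[y == cls] - mu
        sw += d.T @ d
    sw /= max(len(X) - 2, 1)
    w = np.linalg.solve(sw + ridge * np.eye(X.shape[1]), mu1 - mu0)
    return w


def lda_axis(
    X,
    y,
    groups=None,
    ridge: float = 1e-6,
) -> LDAResult:
    """Two-class Fisher discriminant on CLR-transformed composition vectors.

    The axis is the ridge-stabilized solution of the pooled within-class
    covariance against the class-mean difference; samples are classified to
    the nearest class mean along the axis.  With ``groups`` (e.g. donor
    labels), each group is held out in turn, the axis refit on the rest, and
    the held-out samples predicted — leave-one-group-out validation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("lda_axis requires exactly two classes")
    yb = (y == classes[1]).astype(int)
    for cls in (0, 1):
        if (yb == cls).sum() < 2:
            raise ValueError("each class needs at least 2 samples")

    w = _fisher_axis(X, yb, ridge)
    proj = X @ w
    means = (float(proj[yb == 0].mean()), float(proj[yb == 1].mean()))

    preds = None
    acc = None
    if groups is not None:
        groups = np.asarray(groups)
        preds = np.empty(len(y), dtype=int)
        for g in np.unique(groups):
            train = groups != g
            if len(np.unique(yb[train])) < 2 or min(
                (yb[train] == 0).sum(), (yb[train] == 1).sum()
            ) < 2:
                raise ValueError(f"holdout split {g!r} leaves a degenerate training class")
            wg = _fisher_axis(X[train], yb[train], ridge)
            pg = X[train] @ wg
            m0, m1 = pg[yb[train] == 0].mean(), pg[yb[train] == 1].mean()
            ph = X[~train] @ wg
            preds[~train] = (np.abs(ph - m1) < np.abs(ph - m0)).astype(int)
        acc = float((preds == yb).mean())
    return LDAResult(
        loadings=w, projections=proj, class_means=means,
        holdout_predictions=preds, holdout_accuracy=acc,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2) or (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int64)
        if arr.shape != (2, 2) or (arr < 0).any():
            raise ValueError("table must be 2x2 non-negative integers")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])
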