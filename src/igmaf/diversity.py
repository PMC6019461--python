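"""Incidence-based clonal diversity across cellular replicates.

Because cellular replicates are processed independently, a clonotype seen in
two replicates must derive from at least two distinct cells; the pattern of
presence/absence across replicates is incidence data in the ecological
sense, with replicates as sampling units.  This module provides the Chao2
richness estimator (with its classic variance and a log-normal confidence
interval whose lower bound cannot fall below the observed richness),
sample-based rarefaction with exact combinatorics, Chao2-based
extrapolation, and accumulation curves.

Notation: m sampling units, S_obs observed clonotypes, Q_j the number of
clonotypes present in exactly j units (Q1 = uniques, Q2 = duplicates).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class DiversityError(ValueError):
    pass


@dataclass
class IncidenceCounts:
    m: int
    s_obs: int
    q: dict[int, int]  # j -> number of clonotypes present in exactly j units

    def __post_init__(self) -> None:
        if self.m < 1:
            raise DiversityError("need at least one replicate")
        if any(not (1 <= j <= self.m) for j in self.q):
            raise DiversityError("incidence class j must satisfy 1 <= j <= m")
        if sum(self.q.values()) != self.s_obs:
            raise DiversityError("sum of Q_j must equal S_obs")

    @property
    def q1(self) -> int:
        return self.q.get(1, 0)

    @property
    def q2(self) -> int:
        return self.q.get(2, 0)


@dataclass
class DiversityEstimate:
    estimator: str
    point: float
    se: float
    ci_lower: float
    ci_upper: float
    inputs: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=float))


def incidence_counts(matrix) -> IncidenceCounts:
    """Tally incidence frequency counts from a boolean clonotype x replicate
    matrix (ndarray or DataFrame).  Rows absent everywhere are an error."""
    arr = np.asarray(matrix, dtype=bool) if not isinstance(matrix, pd.DataFrame) else matrix.to_numpy(dtype=bool)
    if arr.ndim != 2 or arr.shape[0] == 0 or arr.shape[1] == 0:
        raise DiversityError("incidence matrix must be non-empty and 2-D")
    row_sums = arr.sum(axis=1)
    if (row_sums == 0).any():
        raise DiversityError("incidence matrix has an all-zero row")
    m = arr.shape[1]
    q: dict[int, int] = {}
    for j in range(1, m + 1):
        n = int((row_sums == j).sum())
        if n:
            q[j] = n
    return IncidenceCounts(m=m, s_obs=int(arr.shape[0]), q=q)


def chao2(counts: IncidenceCounts, small_sample_correction: bool = False) -> DiversityEstimate:
    """Chao2 incidence-based richness estimator with classic variance.

    Standard form: S_obs + ((m-1)/m) * Q1^2 / (2*Q2); when Q2 = 0 the
    bias-corrected fallback S_obs + ((m-1)/m) * Q1*(Q1-1)/2 is used.  With
    ``small_sample_correction`` the Q2 term becomes Q1*(Q1-1)/(2*(Q2+1)) in
    all cases.  The 95% CI uses the log-normal transformation on the
    undetected-richness term, so the lower bound is always >= S_obs.
    """
    if counts.m < 2:
        raise DiversityError("Chao2 requires at least 2 replicates")
    s, q1, q2, m = counts.s_obs, counts.q1, counts.q2, counts.m
    a = (m - 1) / m

    if small_sample_correction:
        point = s + a * q1 * (q1 - 1) / (2 * (q2 + 1))
        var = (
            a * q1 * (q1 - 1) / (2 * (q2 + 1))
            + a**2 * q1 * (2 * q1 - 1) ** 2 / (4 * (q2 + 1) ** 2)
            + a**2 * q1**2 * q2 * (q1 - 1) ** 2 / (4 * (q2 + 1) ** 4)
        )
    elif q2 > 0:
        point = s + a * q1**2 / (2 * q2)
        r = q1 / q2
        var = q2 * (a / 2 * r**2 + a**2 * r**3 + a**2 / 4 * r**4)
    else:
        point = s + a * q1 * (q1 - 1) / 2
        if q1 == 0:
            var = 0.0
        else:
            var = (
                a * q1 * (q1 - 1) / 2
                + a**2 * q1 * (2 * q1 - 1) ** 2 / 4
                - a**2 * q1**4 / (4 * point)
            )
    var = max(var, 0.0)
    se = math.sqrt(var)

    t = point - s
    if t <= 0 or var == 0:
        lower = upper = point
    else:
        k = math.exp(1.96 * math.sqrt(math.log(1.0 + var / t**2)))
        lower = s + t / k
        upper = s + t * k
    return DiversityEstimate(
        estimator="chao2" if not small_sample_correction else "chao2_small_sample",
        point=float(point), se=float(se),
        ci_lower=float(lower), ci_upper=float(upper),
        inputs={"m": m, "s_obs": s, "q1": q1, "q2": q2},
    )


def rarefy(counts: IncidenceCounts, t: int) -> float:
    """Expected richness in a random subset of t of the m replicates.

    E[S(t)] = S_obs - sum_j Q_j * C(m-j, t) / C(m, t), computed with exact
    integer combinatorics and one final division.
    """
    if not (1 <= t <= counts.m):
        raise DiversityError(f"t must be in [1, m]; got t={t}, m={counts.m}")
    m = counts.m
    num = 0
    for j, qj in counts.q.items():
        if m - j >= t:
            num += qj * math.comb(m - j, t)
    return counts.s_obs - num / math.comb(m, t)


def extrapolate(counts: IncidenceCounts, t_star: int) -> float:
    """Expected richness after t_star additional replicates (Chao2-based).

    S(m + t*) = S_obs + Q0_hat * [1 - (1 - Q1/(Q1 + m*Q0_hat))^t*], with
    Q0_hat the Chao2 estimate of undetected richness.  Flat at S_obs when
    Q1 = 0.
    """
    if t_star < 0:
        raise DiversityError("t_star must be >= 0")
    if t_star == 0:
        return float(counts.s_obs)
    if counts.q1 == 0:
        return float(counts.s_obs)
    q0 = chao2(counts).point - counts.s_obs
    if q0 <= 0:
        return float(counts.s_obs)
    frac = counts.q1 / (counts.q1 + counts.m * q0)
    return counts.s_obs + q0 * (1.0 - (1.0 - frac) ** t_star)


def accumulation_curve(
    matrix,
    mode: str = "exact_mean",
    n_permutations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Expected number of newly discovered clonotypes per added replicate.

    ``exact_mean`` differencing of the rarefaction curve; ``permutation``
    averages over random replicate orders (the two agree within Monte-Carlo
    error).
    """
    counts = incidence_counts(matrix)
    m = counts.m
    if mode == "exact_mean":
        values = [rarefy(counts, t) for t in range(1, m + 1)]
        return np.diff([0.0] + values)
    if mode == "permutation":
        arr = np.asarray(matrix, dtype=bool) if not isinstance(matrix, pd.DataFrame) else matrix.to_numpy(dtype=bool)
        rng = np.random.default_rng(seed)
        acc = np.zeros(m)
        for _ in range(n_permutations):
            order = rng.permutation(m)
            seen = np.zeros(arr.shape[0], dtype=bool)
            for step, col in enumerate(order):
                new = arr[:, col] & ~seen
                acc[step] += int(new.sum())
                seen |= arr[:, col]
        return acc / n_permutations
    raise DiversityError(f"unknown mode {mode!r}")


def read_incidence_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)


def write_incidence_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.astype(int).to_csv(path, sep="\t")
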