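"""Rank-based group statistics: Kruskal-Wallis, Dunn's post hoc, median CIs.

All tests use pooled mid-ranks with the standard tie correction; Dunn p-values
are two-sided normal with Bonferroni (default) or Holm adjustment across all
pairwise comparisons. Median confidence intervals are distribution-free order
statistic intervals from the binomial(n, 1/2) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupData",
    "KWResult",
    "DunnResult",
    "MedianCI",
    "kruskal_wallis",
    "dunn_posthoc",
    "median_ci",
]


@dataclass
class GroupData:
    """Named groups of real-valued measurements."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {
            str(k): np.asarray(v, dtype=np.float64) for k, v in self.groups.items()
        }
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for name, vals in self.groups.items():
            if vals.size == 0:
                raise ValueError(f"group {name!r} is empty")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"group {name!r} has non-finite values")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[float]]) -> "GroupData":
        return cls(groups=dict(mapping))

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.groups.values())


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p_value: float
    tie_correction_factor: float


@dataclass(frozen=True)
class DunnResult:
    """Pairwise comparison table with columns
    ``group_a, group_b, z, p_raw, p_adjusted`` and the adjustment name."""

    table: pd.DataFrame
    adjustment: str


@dataclass(frozen=True)
class MedianCI:
    median: float
    lower: float
    upper: float
    level: float
    achieved_coverage: float


def _ranks_and_ties(data: GroupData) -> tuple[dict[str, np.ndarray], float, float]:
    pooled = np.concatenate(list(data.groups.values()))
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    out: dict[str, np.ndarray] = {}
    start = 0
    for name, vals in data.groups.items():
        out[name] = ranks[start : start + len(vals)]
        start += len(vals)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    return out, tie_sum, float(len(pooled))


def kruskal_wallis(data: GroupData) -> KWResult:
    """Kruskal-Wallis H with tie correction and a chi-square p-value.

    ``H = [12 / (N(N+1)) * sum n_i * Rbar_i^2 - 3(N+1)] / C`` with tie factor
    ``C = 1 - sum(t^3 - t) / (N^3 - N)``.  Raises on degenerate data where all
    pooled values are identical (C = 0).
    """
    if data.n_total < 3:
        raise ValueError("need at least 3 observations in total")
    group_ranks, tie_sum, n = _ranks_and_ties(data)
    correction = 1.0 - tie_sum / (n**3 - n)
    if correction <= 0.0:
        raise ValueError("all values identical; Kruskal-Wallis is undefined")
    h = (
        12.0 / (n * (n + 1.0))
        * sum(len(r) * np.mean(r) ** 2 for r in group_ranks.values())
        - 3.0 * (n + 1.0)
    )
    h /= correction
    df = len(data.groups) - 1
    return KWResult(
        H=float(h),
        df=df,
        p_value=float(sps.chi2.sf(h, df)),
        tie_correction_factor=float(correction),
    )


def _adjust(p_raw: np.ndarray, method: str) -> np.ndarray:
    m = len(p_raw)
    if method == "none":
        return p_raw.copy()
    if method == "bonferroni":
        return np.minimum(1.0, p_raw * m)
    if method == "holm":
        order = np.argsort(p_raw, kind="mergesort")
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def dunn_posthoc(
    data: GroupData, adjust: Literal["bonferroni", "holm", "none"] = "bonferroni"
) -> DunnResult:
    """Dunn's pairwise rank-sum comparisons after Kruskal-Wallis.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - sum(t^3-t)/(12(N-1))) *
    (1/n_i + 1/n_j))`` with two-sided normal p-values, adjusted over all
    k(k-1)/2 pairs.
    """
    if data.n_total < 3:
        raise ValueError("need at least 3 observations in total")
    group_ranks, tie_sum, n = _ranks_and_ties(data)
    if tie_sum >= n**3 - n:
        raise ValueError("all values identical; Dunn's test is undefined")
    var_term = n * (n + 1.0) / 12.0 - tie_sum / (12.0 * (n - 1.0))
    rows = []
    for a, b in combinations(data.groups, 2):
        ra, rb = group_ranks[a], group_ranks[b]
        se = np.sqrt(var_term * (1.0 / len(ra) + 1.0 / len(rb)))
        z = (np.mean(ra) - np.mean(rb)) / se
        rows.append((a, b, float(z), float(2.0 * sps.norm.sf(abs(z)))))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    table["p_adjusted"] = _adjust(table["p_raw"].to_numpy(), adjust)
    return DunnResult(table=table, adjustment=adjust)


def median_ci(sample: Sequence[float], level: float = 0.95) -> MedianCI:
    """Distribution-free median confidence interval from order statistics.

    Endpoints ``(x_(l), x_(n+1-l))`` use the largest ``l`` whose two-sided
    binomial(n, 1/2) coverage reaches ``level``.  When even the full sample
    range cannot reach the level (small n), the range is returned with its
    achieved coverage so callers can flag it.
    """
    x = np.sort(np.asarray(sample, dtype=np.float64))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    if n == 1:
        return MedianCI(med, float(x[0]), float(x[0]), level, 0.0)

    def coverage(l: int) -> float:
        # P(x_(l) <= true median <= x_(n+1-l)) = 1 - 2 * P(Binom(n,1/2) <= l-1)
        return float(1.0 - 2.0 * sps.binom.cdf(l - 1, n, 0.5))

    best = None
    for l in range(n // 2, 0, -1):
        cov = coverage(l)
        if cov >= level:
            best = (l, cov)
            break
    if best is None:
        return MedianCI(med, float(x[0]), float(x[-1]), level, coverage(1))
    l, cov = best
    return MedianCI(med, float(x[l - 1]), float(x[n - l]), level, cov)
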