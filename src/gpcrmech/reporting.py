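"""Statistical comparisons and per-replica summary tables.

Replica-level quantities (window-mean distances, cross-section areas,
H-bond counts, internal-lipid fractions) are compared between conditions
with Welch's unequal-variance t-test for approximately normal quantities
and the two-sided Wilcoxon rank-sum test for spread/asymmetric ones
(H-bond counts, internalization).  No multiple-testing correction is
applied; raw p-values are reported.

The rank-sum test uses exact enumeration of all labelings when the pooled
sample is small (n_a + n_b ≤ 12) and the normal approximation with tie
correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, erfc, sqrt

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ReplicaSummary:
    """One row per replica: windowed means and the assigned state."""

    condition: str
    replica: int
    snapshot: int = 0
    d36_mean: float = np.nan
    d37_mean: float = np.nan
    cv_sum: float = np.nan  # d36 + d37
    area_0_20: float = np.nan  # Ų
    hbond_means: dict[str, float] = field(default_factory=dict)
    internal_fraction: float = np.nan
    state: str = ""

    def as_row(self) -> dict:
        row = {
            "condition": self.condition,
            "replica": self.replica,
            "snapshot": self.snapshot,
            "d36_mean": self.d36_mean,
            "d37_mean": self.d37_mean,
            "cv_sum": self.cv_sum,
            "area_0_20": self.area_0_20,
            "internal_fraction": self.internal_fraction,
            "state": self.state,
        }
        for pos, v in self.hbond_means.items():
            row[f"hbonds_{pos}"] = v
        return row


def summary_table(summaries: list[ReplicaSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])


def welch_ttest(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Unequal-variance t statistic and two-sided p (Welch–Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def _ranks_with_ties(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_v = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def ranksum_test(a, b, exact_limit: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration of all C(n_a+n_b, n_a) labelings of the pooled ranks
    when the total sample size is at most ``exact_limit``; otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 3 or n_b < 3:
        raise ValueError("each sample needs n >= 3")
    pooled = np.concatenate([a, b])
    ranks = _ranks_with_ties(pooled)
    w_obs = ranks[:n_a].sum()
    n = n_a + n_b
    if n <= exact_limit:
        mean_w = n_a * (n + 1) / 2.0
        dev_obs = abs(w_obs - mean_w)
        hits = 0
        for idx in combinations(range(n), n_a):
            w = ranks[list(idx)].sum()
            if abs(w - mean_w) >= dev_obs - 1e-12:
                hits += 1
        return hits / comb(n, n_a)
    mean_w = n_a * (n + 1) / 2.0
    tie_term = 0.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return 1.0
    z = (w_obs - mean_w) / sqrt(var_w)
    return erfc(abs(z) / sqrt(2.0))


def box_summary(values) -> tuple[float, float, float, float]:
    """(q1, median, q3, mean) with linear-interpolation quantiles."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(q1), float(med), float(q3), float(v.mean())


def cumulative_sampling_ns(
    n_snapshots: int = 3, n_replicas: int = 7, duration_ns: float = 90.0
) -> float:
    """Total sampling per condition: snapshots × replicas × run length (ns).

    With the study design (3 starting snapshots, 7 steered replicas each,
    90 ns per run) this is 1890 ns ≈ 1.9 μs per condition.
    """
    return n_snapshots * n_replicas * duration_ns
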