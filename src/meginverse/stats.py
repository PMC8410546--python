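"""Nonparametric repeated-measures statistics for algorithm comparisons.

Per-simulation (per-subject) metric tables — rows are simulations, columns
are algorithms — are compared with a Friedman test for an overall effect
of algorithm, Wilcoxon signed-rank tests for all pairwise contrasts, and
Benjamini-Hochberg FDR correction within each metric family.

The Friedman statistic uses within-row average ranks (ties shared):

    chi2 = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)

with an upper-tail chi-squared(k-1) p-value. For perfectly consistent
rankings chi2 = n (k-1) exactly. The Wilcoxon test drops zero differences
(Wilcoxon's original rule), enumerates all 2^n sign assignments exactly
for n <= 25, and uses the tie-corrected normal approximation above that.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats


@dataclass
class MetricTable:
    """Rows = simulations/subjects, columns = algorithms, one metric."""

    values: np.ndarray
    algorithms: list[str]
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("need >= 2 rows and >= 2 columns")
        if self.values.shape[1] != len(self.algorithms):
            raise ValueError("column count must match algorithm labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metric table must be complete and finite")


@dataclass
class StatsReport:
    metric: str
    friedman_chi2: float
    friedman_p: float
    pairwise: pd.DataFrame  # algo_a, algo_b, statistic, p_raw, p_adj, significant


def friedman_test(table: MetricTable | np.ndarray) -> tuple[float, float]:
    """Friedman chi-squared statistic and upper-tail p-value.

    Identical column values in every row give chi2 = 0, p = 1 (no effect,
    not an error).
    """
    values = table.values if isinstance(table, MetricTable) else np.asarray(table, dtype=float)
    n, k = values.shape
    ranks = scipy.stats.rankdata(values, axis=1)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    chi2 = max(chi2, 0.0)
    p = float(scipy.stats.chi2.sf(chi2, df=k - 1))
    return float(chi2), p


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped. Exact enumeration of all sign
    assignments for n <= 25 remaining pairs (ties handled by shared
    ranks); tie-corrected normal approximation otherwise. Returns
    (W = min signed-rank sum, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w = min(w_plus, w_minus)
    if n <= 25:
        # exact null over all 2^n equally likely sign assignments, computed
        # by dynamic programming on the (doubled, hence integer) ranks
        ranks2 = np.round(2 * ranks).astype(int)
        dist = np.zeros(ranks2.sum() + 1)
        dist[0] = 1.0
        for r in ranks2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: dist.size - r]
            dist = dist + shifted
        # dist[s] = number of assignments with 2*W+ = s
        sums = np.arange(dist.size)
        w2 = 2 * w
        total2 = ranks2.sum()
        mask = np.minimum(sums, total2 - sums) <= w2 + 1e-9
        p = float(dist[mask].sum() / 2**n)
    else:
        mean = n * (n + 1) / 4
        tie_groups = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24 - np.sum(tie_groups**3 - tie_groups) / 48
        z = (w - mean) / np.sqrt(var)
        p = float(2 * scipy.stats.norm.cdf(z))
    return float(w), float(min(p, 1.0))


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``p_(i) * m / i`` with a cumulative minimum applied from the largest
    p-value downward, clipped at 1, returned in the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0, 1)
    return out


def pairwise_report(table: MetricTable, alpha: float = 0.05) -> StatsReport:
    """Friedman test plus all C(k,2) Wilcoxon contrasts, BH-corrected
    within this metric family."""
    chi2, p_f = friedman_test(table)
    rows = []
    for i, j in itertools.combinations(range(len(table.algorithms)), 2):
        stat, p = wilcoxon_signed_rank(table.values[:, i], table.values[:, j])
        rows.append((table.algorithms[i], table.algorithms[j], stat, p))
    df = pd.DataFrame(rows, columns=["algo_a", "algo_b", "statistic", "p_raw"])
    df["p_adj"] = bh_fdr(df["p_raw"].to_numpy())
    df["significant"] = df["p_adj"] < alpha
    return StatsReport(metric=table.metric, friedman_chi2=chi2, friedman_p=p_f, pairwise=df)


def build_report(tables: list[MetricTable], alpha: float = 0.05) -> dict[str, StatsReport]:
    """One StatsReport per metric; BH applied within each metric family."""
    algos = None
    for t in tables:
        if algos is None:
            algos = t.algorithms
        elif t.algorithms != algos:
            raise ValueError("metric tables must share aligned algorithm columns")
    return {t.metric: pairwise_report(t, alpha) for t in tables}


def report_long_frame(reports: dict[str, StatsReport]) -> pd.DataFrame:
    """Long-format TSV-ready table across all metrics."""
    frames = []
    for metric, rep in reports.items():
        df = rep.pairwise.copy()
        df.insert(0, "metric", metric)
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["metric", "algo_a", "algo_b", "statistic", "p_raw", "p_adj", "significant"]
    )
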