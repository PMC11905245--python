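"""Paired group comparison for per-plan metric tables.

Plans come in matched triplets (one per arc-increment group A/B/C for
each patient), so between-group differences are tested with the paired
Wilcoxon signed-rank test.  Sample sizes here are small (n = 10), hence
the p-value is exact: the null distribution of the positive-rank sum is
built by enumerating all 2^m sign assignments (as a rank-sum
convolution, which is equivalent and fast).  Zero differences are
dropped before ranking; ties receive average ranks; above m = 25 a
normal approximation with continuity and tie corrections takes over.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class WilcoxonResult:
    p_value: float
    statistic: float  # positive-rank sum W+
    n_used: int       # pairs remaining after dropping zero differences
    method: str       # "exact" | "normal-approx" | "degenerate"
    degenerate: bool = False


def _exact_signed_rank_pmf(ranks2: np.ndarray) -> np.ndarray:
    """PMF of 2*W+ over all sign assignments, by convolution.

    ``ranks2`` holds the doubled ranks (integers even with average-rank
    ties).  Entry ``pmf[s]`` is the probability that the doubled
    positive-rank sum equals ``s`` under the exchangeable-sign null.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts / counts.sum()


def wilcoxon_signed_rank(x, y, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test of ``x`` vs ``y``.

    The two-sided p doubles the smaller tail (capped at 1).  All pairs
    with exactly zero difference are discarded; if none remain the
    result is the degenerate p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if x.size < 1:
        raise ValueError("need at least one pair")
    d = x - y
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        return WilcoxonResult(1.0, 0.0, 0, "degenerate", degenerate=True)

    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    if m <= exact_max_n:
        ranks2 = np.round(2.0 * ranks).astype(int)
        pmf = _exact_signed_rank_pmf(ranks2)
        s = int(round(2.0 * w_pos))
        cdf = float(pmf[: s + 1].sum())
        sf = float(pmf[s:].sum())
        p = min(1.0, 2.0 * min(cdf, sf))
        return WilcoxonResult(p, w_pos, m, "exact")

    mean = m * (m + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = m * (m + 1) * (2 * m + 1) / 24.0 - float(
        np.sum(tie_counts**3 - tie_counts)
    ) / 48.0
    delta = w_pos - mean
    # continuity correction pulls the statistic half a step toward the mean
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return WilcoxonResult(p, w_pos, m, "normal-approx")


def percent_reduction(reference_mean: float, comparison_mean: float,
                      ndigits: int | None = 1) -> float:
    """Percent by which ``comparison_mean`` falls below ``reference_mean``.

    ``100 * (ref - cmp) / ref``, rounded to one decimal by default
    (``ndigits=None`` returns full precision).
    """
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    value = 100.0 * (reference_mean - comparison_mean) / reference_mean
    return value if ndigits is None else round(value, ndigits)


@dataclass
class PairedMetricTable:
    """Per-metric group summary and pairwise tests (one table row)."""

    metric: str
    values: pd.DataFrame            # index: patient_id, columns: groups
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)


def holm_adjust(p_values: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment of a family of p-values."""
    items = sorted(p_values.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted, running = {}, 0.0
    for i, (key, p) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        adjusted[key] = running
    return {k: adjusted[k] for k in p_values}


def summarize_and_compare(
    metrics: pd.DataFrame,
    groups: tuple[str, ...] = ("A", "B", "C"),
    alpha: float = 0.05,
    holm: bool = False,
) -> dict[str, PairedMetricTable]:
    """Build group-summary tables with pairwise Wilcoxon p-values.

    Parameters
    ----------
    metrics
        One row per plan with columns ``patient_id``, ``group`` and one
        column per metric.  Every patient must appear exactly once per
        group (paired design).
    holm
        Apply the Holm correction within each metric's three
        comparisons.  Off by default: each comparison is judged at
        ``alpha`` on its own.
    """
    required = {"patient_id", "group"}
    if not required <= set(metrics.columns):
        raise ValueError(f"metrics table needs columns {sorted(required)}")
    counts = metrics.groupby(["patient_id", "group"]).size()
    for (pid, grp), c in counts.items():
        if c != 1:
            raise ValueError(f"patient {pid}: {c} plans in group {grp}, expected 1")
    patients = sorted(metrics["patient_id"].unique())
    for g in groups:
        present = set(metrics.loc[metrics["group"] == g, "patient_id"])
        missing = [p for p in patients if p not in present]
        if missing:
            raise ValueError(f"patient {missing[0]} has no plan in group {g}")

    pairs = [
        (groups[i], groups[j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    ]
    metric_cols = [c for c in metrics.columns if c not in required]
    out: dict[str, PairedMetricTable] = {}
    for col in metric_cols:
        wide = metrics.pivot(index="patient_id", columns="group", values=col)
        wide = wide.loc[patients, list(groups)]
        table = PairedMetricTable(metric=col, values=wide)
        for g in groups:
            table.means[g] = float(wide[g].mean())
            table.sds[g] = float(wide[g].std(ddof=1)) if len(wide) > 1 else 0.0
        for ga, gb in pairs:
            res = wilcoxon_signed_rank(wide[ga].to_numpy(), wide[gb].to_numpy())
            table.p_values[f"{ga}-{gb}"] = res.p_value
        if holm:
            table.p_values = holm_adjust(table.p_values)
        table.significant = {k: p < alpha for k, p in table.p_values.items()}
        out[col] = table
    return out


def comparison_frame(tables: dict[str, PairedMetricTable]) -> pd.DataFrame:
    """Flatten summary tables into one mean/SD/p-value DataFrame."""
    rows = []
    for name, t in tables.items():
        row: dict[str, float | str] = {"metric": name}
        for g, m in t.means.items():
            row[f"mean_{g}"] = m
            row[f"sd_{g}"] = t.sds[g]
        for pair, p in t.p_values.items():
            row[f"p_{pair}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")
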