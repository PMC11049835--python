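"""Nonparametric two-group comparison of per-cell metrics.

The group comparison follows standard practice for skewed, bounded
morphometry data: a two-sided Mann-Whitney U test plus distribution
summaries (median and the 2.5th-97.5th percentile range of per-cell
values).  Note the published summaries this package reproduces label that
range a "95% CI"; with the printed widths it can only be the per-cell
inter-percentile range, and it is computed as such here.

The U statistic is the conventional min(U_x, U_y) from midranks.  For
small samples without ties (n_x + n_y <= 12) the p-value is computed by
complete enumeration of rank assignments; otherwise by the normal
approximation with tie and continuity corrections.  Cells are pooled per
class across subjects (the analysis this mirrors did the same); a
per-subject summary is available for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MAX_N = 12


@dataclass
class MannWhitneyResult:
    u: float            # min(U_x, U_y)
    z: float            # normal-approximation deviate (continuity-corrected)
    p_two_sided: float
    exact: bool


@dataclass
class GroupComparison:
    metric: str
    n_low: int
    n_high: int
    u_statistic: float
    z_value: float
    p_two_sided: float
    median_low: float
    median_high: float
    interval_low: tuple[float, float]
    interval_high: tuple[float, float]

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "u_statistic": self.u_statistic,
            "z_value": self.z_value,
            "p_two_sided": self.p_two_sided,
            "median_low": self.median_low,
            "median_high": self.median_high,
            "q025_low": self.interval_low[0],
            "q975_low": self.interval_low[1],
            "q025_high": self.interval_high[0],
            "q975_high": self.interval_high[1],
        }


def _u_from_ranks(ranks_x: np.ndarray, n_x: int, n_y: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2)


def _exact_two_sided_p(u_x: float, n_x: int, n_y: int) -> float:
    """P(|U - mu| >= |u_x - mu|) by complete enumeration (no ties).

    Enumerates all C(n, n_x) assignments of the pooled ranks 1..n to group
    x; feasible for n <= EXACT_MAX_N.
    """
    n = n_x + n_y
    mu = n_x * n_y / 2
    dev = abs(u_x - mu)
    hits = 0
    base = n_x * (n_x + 1) / 2
    for ranks in combinations(range(1, n + 1), n_x):
        u = sum(ranks) - base
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / comb(n, n_x)


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test (midranks).

    Exact enumeration when n_x + n_y <= 12 and the pooled data have no
    ties; otherwise normal approximation with tie correction and a 0.5
    continuity correction.  All-tied data yield p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = _u_from_ranks(ranks[:n_x], n_x, n_y)
    u_y = n_x * n_y - u_x
    u = min(u_x, u_y)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()
    mu = n_x * n_y / 2

    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n_x * n_y / 12 * ((n + 1) - tie_term)
    if var <= 0:  # every observation tied
        return MannWhitneyResult(u=u, z=0.0, p_two_sided=1.0, exact=False)
    z = (u - mu + 0.5) / np.sqrt(var)

    if n <= EXACT_MAX_N and not has_ties:
        p = _exact_two_sided_p(u_x, n_x, n_y)
        return MannWhitneyResult(u=u, z=float(z), p_two_sided=float(p), exact=True)
    p = min(1.0, 2 * sps.norm.cdf(z))
    return MannWhitneyResult(u=u, z=float(z), p_two_sided=float(p), exact=False)


def summarize(values, percentiles: tuple[float, float] = (2.5, 97.5)):
    """Median and linear-interpolation percentile interval."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    lo, hi = np.percentile(values, percentiles)
    return float(np.median(values)), (float(lo), float(hi))


def compare_groups(measurements: pd.DataFrame, metric: str) -> GroupComparison:
    """Mann-Whitney comparison of a metric between low- and high-score
    classes, over QC-passing cells pooled across subjects."""
    ok = measurements[measurements["qc_pass"].astype(bool)]
    low = ok.loc[ok["class"] == "low", metric].to_numpy(dtype=float)
    high = ok.loc[ok["class"] == "high", metric].to_numpy(dtype=float)
    if low.size == 0 or high.size == 0:
        raise ValueError(
            f"both classes required; got {low.size} low / {high.size} high QC-passing cells"
        )
    res = mann_whitney_u(low, high)
    med_low, int_low = summarize(low)
    med_high, int_high = summarize(high)
    return GroupComparison(
        metric=metric,
        n_low=low.size,
        n_high=high.size,
        u_statistic=res.u,
        z_value=res.z,
        p_two_sided=res.p_two_sided,
        median_low=med_low,
        median_high=med_high,
        interval_low=int_low,
        interval_high=int_high,
    )


def per_subject_summary(measurements: pd.DataFrame, metrics=("itd", "cta")) -> pd.DataFrame:
    """Median of each metric per subject (QC-passing cells), for transparency
    about between-subject variation that the pooled test ignores."""
    ok = measurements[measurements["qc_pass"].astype(bool)]
    out = ok.groupby(["subject_id", "class"], as_index=False).agg(
        n_cells=("cell_id", "count"), **{m: (m, "median") for m in metrics}
    )
    return out
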