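from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from spermfish.stats import (
    compare_groups,
    mann_whitney_u,
    per_subject_summary,
    summarize,
)


def brute_force_mw(x, y):
    """Independent oracle: U by direct pair counting; exact two-sided p by
    enumerating every assignment of the pooled values to the two groups."""
    x, y = list(x), list(y)
    n_x, n_y = len(x), len(y)
    pooled = x + y
    mu = n_x * n_y / 2

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_of(x, y)
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n_x + n_y), n_x):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n_x + n_y) if i not in idx]
        total += 1
        if abs(u_of(xs, ys) - mu) >= dev - 1e-12:
            hits += 1
    return min(u_obs, n_x * n_y - u_obs), hits / total


class TestMannWhitney:
    def test_complete_separation_small_n(self):
        """x=[1,2,3] vs y=[4,5,6]: U=0 and exact p=2/20."""
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.p_two_sided == pytest.approx(0.1)
        assert res.exact

    def test_interleaved_small_n(self):
        """x=[1,4] vs y=[2,3]: U=2 (the null center), exact p=1."""
        res = mann_whitney_u([1, 4], [2, 3])
        assert res.u == 2
        assert res.p_two_sided == pytest.approx(1.0)

    def test_all_ties_p_one(self):
        res = mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert res.p_two_sided == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 1000), min_size=1, max_size=5),
        st.lists(st.integers(0, 1000), min_size=1, max_size=5),
    )
    def test_exact_path_equals_enumeration_oracle(self, x, y):
        if len(set(x + y)) < len(x) + len(y):
            return  # exact path only claims tie-free inputs
        res = mann_whitney_u(x, y)
        u_bf, p_bf = brute_force_mw(x, y)
        assert res.u == pytest.approx(u_bf)
        assert res.p_two_sided == pytest.approx(p_bf)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=1, max_size=8),
        st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=1, max_size=8),
    )
    def test_u_identity(self, x, y):
        """U(x,y) + U(y,x) = n_x * n_y."""
        res_xy = mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        u_x = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2
        u_y = ranks[len(x):].sum() - len(y) * (len(y) + 1) / 2
        assert u_x + u_y == pytest.approx(len(x) * len(y))
        assert res_xy.u == pytest.approx(min(u_x, u_y))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.8, 1, 30)
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(np.exp(x), np.exp(y))
        assert a.u == pytest.approx(b.u)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_matches_scipy_exact_and_approx(self):
        rng = np.random.default_rng(4)
        # exact path (no ties, small n)
        x = [0.11, 0.52, 0.93, 0.34]
        y = [0.25, 0.86, 0.47]
        ours = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p_two_sided == pytest.approx(ref.pvalue)
        # large-sample path with ties vs scipy's tie-corrected normal approx
        x = np.round(rng.normal(0, 1, 60), 1)
        y = np.round(rng.normal(0.5, 1, 45), 1)
        ours = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)


class TestSummarize:
    def test_median_simple(self):
        med, (lo, hi) = summarize([1, 2, 3, 4, 5])
        assert med == 3

    def test_constant_zero_width_interval(self):
        med, (lo, hi) = summarize([2.0] * 10)
        assert (med, lo, hi) == (2.0, 2.0, 2.0)

    def test_calibrated_preset_median(self, presets):
        rng = np.random.default_rng(7)
        draws = presets["low"].sample_cta(rng, size=10_000)
        med, _ = summarize(draws)
        assert med == pytest.approx(0.349, abs=0.01)


def _toy_measurements():
    rng = np.random.default_rng(0)
    n = 40
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(2 * n)],
            "subject_id": ["A"] * n + ["B"] * n,
            "class": ["low"] * n + ["high"] * n,
            "itd": np.r_[rng.uniform(0.3, 0.6, n), rng.uniform(0.1, 0.4, n)],
            "cta": np.r_[rng.uniform(0.25, 0.5, n), rng.uniform(0.1, 0.3, n)],
            "qc_pass": True,
            "qc_reason": "",
        }
    )


class TestCompareGroups:
    def test_separated_groups_significant(self):
        comp = compare_groups(_toy_measurements(), "cta")
        assert comp.p_two_sided < 1e-4
        assert comp.median_low > comp.median_high
        assert 0 <= comp.u_statistic <= comp.n_low * comp.n_high

    def test_identical_groups_not_significant(self):
        df = _toy_measurements()
        df.loc[df["class"] == "high", ["itd", "cta"]] = (
            df.loc[df["class"] == "low", ["itd", "cta"]].to_numpy()
        )
        comp = compare_groups(df, "itd")
        assert comp.p_two_sided > 0.8

    def test_missing_class_rejected(self):
        df = _toy_measurements()
        df["class"] = "low"
        with pytest.raises(ValueError):
            compare_groups(df, "itd")

    def test_qc_failures_excluded(self):
        df = _toy_measurements()
        df.loc[:10, "qc_pass"] = False
        comp = compare_groups(df, "itd")
        assert comp.n_low == int((df["qc_pass"] & (df["class"] == "low")).sum())

    def test_per_subject_summary_layout(self):
        out = per_subject_summary(_toy_measurements())
        assert set(out.columns) == {"subject_id", "class", "n_cells", "itd", "cta"}
        assert len(out) == 2
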