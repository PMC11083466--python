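"""Formula bias records, rank-sum test, and threshold summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from lfnc import (
    BreathingScenario,
    bias_threshold_summary,
    benaron_benitz_fio2,
    formula_differences,
    generate_dataset,
    rank_sum_test,
)


def brute_force_p(x, y):
    """Independent oracle: pairwise-count U over every re-assignment."""
    x, y = list(x), list(y)
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_of(sample_x, sample_y):
        return sum(
            1.0 if a > b else 0.5 if a == b else 0.0
            for a in sample_x for b in sample_y
        )

    mu = n1 * n2 / 2
    obs = abs(u_of(x, y) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        sx = [pooled[i] for i in idx]
        sy = [pooled[i] for i in range(n1 + n2) if i not in idx]
        total += 1
        if abs(u_of(sx, sy) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestRankSum:
    def test_separated_pairs_example(self):
        r = rank_sum_test([1, 2], [3, 4])
        assert r.u_statistic == 0
        assert r.p_value == pytest.approx(1 / 3)

    def test_swap_symmetry(self):
        a = rank_sum_test([1, 5, 7], [2, 3])
        b = rank_sum_test([2, 3], [1, 5, 7])
        assert b.u_statistic == pytest.approx(a.n1 * a.n2 - a.u_statistic)
        assert b.p_value == pytest.approx(a.p_value)

    def test_fully_tied_samples(self):
        r = rank_sum_test([5, 5, 5], [5, 5, 5])
        assert r.u_statistic == pytest.approx(4.5)
        assert r.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1, 2])

    def test_exact_matches_brute_force_all_small_shapes(self):
        # every (n1, n2) with n1 + n2 <= 8, data with and without ties
        rng = np.random.default_rng(2024)
        for n1 in range(1, 8):
            for n2 in range(1, 8 - n1 + 1):
                for _ in range(3):
                    x = rng.integers(0, 5, n1).astype(float)
                    y = rng.integers(0, 5, n2).astype(float)
                    r = rank_sum_test(x, y)
                    assert r.p_value == pytest.approx(
                        brute_force_p(x, y)
                    ), (x, y)

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_exact_p_properties(self, data):
        n1 = data.draw(st.integers(1, 5))
        n2 = data.draw(st.integers(1, 5))
        x = data.draw(st.lists(st.integers(0, 6), min_size=n1, max_size=n1))
        y = data.draw(st.lists(st.integers(0, 6), min_size=n2, max_size=n2))
        r = rank_sum_test(x, y)
        assert 0 < r.p_value <= 1
        assert 0 <= r.u_statistic <= n1 * n2

    def test_large_sample_uses_tie_corrected_normal(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        r = rank_sum_test(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert r.u_statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)


class TestFormulaDifferences:
    def test_unknown_formula_rejected(self, grid_dataset):
        with pytest.raises(ValueError):
            formula_differences(grid_dataset, "sabz")

    def test_self_comparison_is_zero(self):
        # dataset whose readings ARE the formula's predictions -> diff 0
        scen = BreathingScenario(10, 50, 500)
        pred = benaron_benitz_fio2(0.3, 500, 10).fio2_percent
        ds = pd.DataFrame(
            [{
                "vt_ml": 10, "rr_bpm": 50, "ti_ms": 500, "te_ms": 700,
                "mv_ml_min": scen.mv_ml_min, "flow_l_min": 0.3,
                "replicate": 1, "fio2_percent": pred,
            }]
        )
        d = formula_differences(ds, "benaron_benitz")
        assert d["diff_pp"].abs().max() < 1e-12

    def test_oracle_regime_zero_bias(self, oracle_geometry, square_wave):
        # no reservoir + square wave: the simulator IS Benaron-Benitz
        scens = [BreathingScenario(10, 50, 500), BreathingScenario(20, 40, 700)]
        ds = generate_dataset(
            scens, [0.1, 0.3], oracle_geometry, square_wave, noise_sd_pp=0.0,
            replicates=1,
        )
        d = formula_differences(ds, "benaron_benitz")
        assert d["diff_pp"].abs().max() < 0.1

    def test_bias_signs_at_low_mv(self, grid_dataset):
        # reservoir effect: Benaron-Benitz underestimates at MV 150 for low
        # flows; Finer overestimates
        bb = formula_differences(grid_dataset, "benaron_benitz")
        fi = formula_differences(grid_dataset, "finer")
        bb150 = bb[bb.mv_ml_min == 150].groupby("flow_l_min").diff_pp.mean()
        fi150 = fi[fi.mv_ml_min == 150].groupby("flow_l_min").diff_pp.mean()
        assert bb150[0.1] < 0 and bb150[0.3] < 0
        assert (fi150 > 0).all()

    def test_benaron_bias_shrinks_with_mv(self, grid_dataset):
        bb = formula_differences(grid_dataset, "benaron_benitz")
        prof = bb[bb.flow_l_min == 0.1].groupby("mv_ml_min").diff_pp.mean().abs()
        # |bias| at the lowest MV dwarfs the high-MV tail; adjacent bins mix
        # different (VT, Ti) compositions, so only anchor bins are compared
        assert prof.iloc[0] > 10 * prof.iloc[-1]
        assert prof.loc[150] > prof.loc[400] > prof.iloc[-1]

    def test_finer_overestimates_at_high_flow(self, grid_dataset):
        fi = formula_differences(grid_dataset, "finer")
        low_mv = fi[(fi.flow_l_min == 1.0) & (fi.mv_ml_min <= 1000)]
        assert (low_mv["diff_pp"] > 0).all()


class TestBiasThresholdSummary:
    def _records(self, mv, diffs, flow=0.1):
        return pd.DataFrame({
            "mv_ml_min": mv, "flow_l_min": flow,
            "formula_name": "benaron_benitz", "diff_pp": diffs,
        })

    def test_all_zero_bias_gives_smallest_grid_mv(self):
        mv = [150, 400, 700]
        s = bias_threshold_summary(self._records(mv, [0, 0, 0]), (3, 5))
        assert (s["min_mv_ml_min"] == 150).all()

    def test_decaying_bias_crosses_at_expected_grid_points(self):
        mv = [100, 200, 400, 600, 700, 1000]
        s = bias_threshold_summary(
            self._records(mv, [2000 / m for m in mv]), (3, 5)
        ).set_index("threshold_pp")
        assert s.loc[5.0, "min_mv_ml_min"] == 400      # 2000/400 = 5, inclusive
        assert s.loc[3.0, "min_mv_ml_min"] == 700      # next grid point above 666.7

    def test_constant_large_bias_has_no_threshold(self):
        s = bias_threshold_summary(self._records([150, 400], [10, 10]), (3, 5))
        assert s["min_mv_ml_min"].isna().all()

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            bias_threshold_summary(pd.DataFrame())
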