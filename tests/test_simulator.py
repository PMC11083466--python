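"""Gas-mixing simulator: oracles, conservation, monotonicity, protocol."""

import numpy as np
import pytest

from lfnc import (
    BreathingScenario,
    CannulaSetting,
    RigGeometry,
    WaveformSpec,
    effective_dead_space,
    generate_dataset,
    simulate_steady_state,
)

KEY = BreathingScenario(5, 30, 900)  # the low-MV reference scenario


def closed_form(flow_l_min, ti_ms, vt_ml):
    v = min(flow_l_min * 1000 / 60 * ti_ms / 1000, vt_ml)
    return 21 + 79 * v / vt_ml


class TestEffectiveDeadSpace:
    @pytest.mark.parametrize(
        "vt,expected", [(5, 4.2), (9.9, 4.2), (10, 5.2), (30, 5.2), (50, 5.2),
                        (60, 6.0), (80, 8.0)]
    )
    def test_rod_and_extension_rules(self, vt, expected):
        assert effective_dead_space(vt, RigGeometry()) == pytest.approx(expected)

    def test_zero_base_stays_zero(self, oracle_geometry):
        for vt in (5, 30, 80):
            assert effective_dead_space(vt, oracle_geometry) == 0.0

    def test_invalid_vt(self):
        with pytest.raises(ValueError):
            effective_dead_space(0, RigGeometry())


class TestFixedPoints:
    def test_no_flow_stays_at_room_air(self):
        r = simulate_steady_state(KEY, CannulaSetting(0.0))
        assert r.fio2_percent == pytest.approx(21.0, abs=1e-6)

    def test_washout_from_pure_oxygen(self):
        # between-run protocol: cannula off, FiO2 returns to 21%
        r = simulate_steady_state(
            KEY, CannulaSetting(0.0), initial_o2_fraction=1.0
        )
        assert r.fio2_percent == pytest.approx(21.0, abs=1e-6)
        assert r.per_breath_fio2[0] > r.per_breath_fio2[-1]


class TestClosedFormOracle:
    @pytest.mark.parametrize(
        "vt,rr,ti,flow",
        [(5, 30, 900, 0.1), (10, 60, 500, 0.3), (20, 40, 700, 0.5),
         (40, 50, 500, 1.0), (80, 80, 300, 1.0)],
    )
    def test_square_wave_no_reservoir_matches_benaron_benitz(
        self, vt, rr, ti, flow, oracle_geometry, square_wave
    ):
        # with no dead space and constant inspiratory flow above the cannula
        # flow, the simulator must reproduce the closed form
        assert flow * 1000 / 60 <= vt / (ti / 1000)  # oracle regime
        r = simulate_steady_state(
            BreathingScenario(vt, rr, ti), CannulaSetting(flow),
            oracle_geometry, square_wave,
        )
        assert r.fio2_percent == pytest.approx(closed_form(flow, ti, vt), abs=0.1)

    def test_reservoir_raises_fio2_above_closed_form(self):
        r = simulate_steady_state(KEY, CannulaSetting(0.1))
        assert closed_form(0.1, 900, 5) < r.fio2_percent <= 100.0


class TestConservationAndNumerics:
    @pytest.mark.parametrize(
        "scenario,flow,shape",
        [(KEY, 0.1, "passive"), (KEY, 1.0, "passive"),
         (BreathingScenario(80, 80, 300), 1.0, "half_sine"),
         (BreathingScenario(15, 50, 700), 0.5, "square")],
    )
    def test_oxygen_bookkeeping_conserved_every_step(self, scenario, flow, shape):
        r = simulate_steady_state(
            scenario, CannulaSetting(flow), waveform=WaveformSpec(shape)
        )
        assert r.mass_balance_error < 1e-9

    def test_lung_residual_does_not_move_steady_state(self):
        # no gas exchange: residual volume affects wash-in speed only
        a = simulate_steady_state(KEY, CannulaSetting(0.1))
        b = simulate_steady_state(
            KEY, CannulaSetting(0.1), RigGeometry(lung_residual_ml=60.0)
        )
        assert abs(a.fio2_percent - b.fio2_percent) < 0.05
        assert b.n_breaths > a.n_breaths  # but it does slow convergence

    def test_dt_convergence(self):
        a = simulate_steady_state(KEY, CannulaSetting(0.1))
        b = simulate_steady_state(
            KEY, CannulaSetting(0.1), waveform=WaveformSpec("passive", dt_ms=0.5)
        )
        assert abs(a.fio2_percent - b.fio2_percent) < 0.05

    def test_wash_in_trace_monotone_from_room_air(self):
        r = simulate_steady_state(KEY, CannulaSetting(0.3))
        assert r.per_breath_fio2[0] >= 21.0
        assert np.all(np.diff(r.per_breath_fio2) >= -1e-9)

    def test_nonconvergence_flagged(self):
        r = simulate_steady_state(KEY, CannulaSetting(0.1), max_breaths=5)
        assert not r.converged and r.n_breaths == 5

    def test_coarse_dt_rejected(self):
        with pytest.raises(ValueError):
            simulate_steady_state(
                BreathingScenario(5, 30, 300), CannulaSetting(0.1),
                waveform=WaveformSpec("passive", dt_ms=31.0),
            )


class TestMonotonicity:
    def test_nondecreasing_in_flow(self):
        f = [simulate_steady_state(KEY, CannulaSetting(fl)).fio2_percent
             for fl in (0.1, 0.3, 0.5, 1.0)]
        assert all(np.diff(f) >= -1e-9)

    def test_nonincreasing_in_vt(self):
        f = [
            simulate_steady_state(
                BreathingScenario(vt, 30, 900), CannulaSetting(0.1)
            ).fio2_percent
            for vt in (5, 10, 20, 40)
        ]
        assert all(np.diff(f) <= 1e-9)

    def test_nondecreasing_in_ti(self):
        f = [
            simulate_steady_state(
                BreathingScenario(10, 50, ti), CannulaSetting(0.3)
            ).fio2_percent
            for ti in (500, 700)
        ]
        assert f[0] <= f[1] + 1e-9


@pytest.fixture(scope="module")
def small_grid():
    return [BreathingScenario(20, 40, 500), BreathingScenario(40, 60, 500)]


class TestGenerateDataset:
    def test_row_count_and_columns(self, small_grid):
        ds = generate_dataset(small_grid, [0.1, 0.5], replicates=3, seed=1)
        assert len(ds) == 2 * 2 * 3
        assert list(ds.columns) == [
            "vt_ml", "rr_bpm", "ti_ms", "te_ms", "mv_ml_min",
            "flow_l_min", "replicate", "fio2_percent",
        ]
        assert set(ds["replicate"]) == {1, 2, 3}

    def test_zero_noise_makes_replicates_identical(self, small_grid):
        ds = generate_dataset(small_grid, [0.1], noise_sd_pp=0.0, seed=1)
        assert ds.groupby(["vt_ml", "flow_l_min"]).fio2_percent.nunique().eq(1).all()

    def test_seed_reproducibility(self, small_grid):
        a = generate_dataset(small_grid, [0.1], seed=42)
        b = generate_dataset(small_grid, [0.1], seed=42)
        c = generate_dataset(small_grid, [0.1], seed=43)
        assert a.equals(b)
        assert not a.equals(c)

    def test_replicate_noise_magnitude(self, small_grid):
        ds = generate_dataset(small_grid, [0.1], noise_sd_pp=0.15, seed=7)
        spread = ds.groupby(["vt_ml", "flow_l_min"]).fio2_percent.std()
        assert (spread < 1.0).all()  # bench replicate SDs were 0.1-0.2 pp

    def test_empty_scenarios_empty_output(self):
        assert generate_dataset([], [0.1]).empty
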