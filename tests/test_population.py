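"""Population dynamics: growth cap, dilution, snapshots, HSL."""

import numpy as np
import pytest
from scipy import stats

from telosen import (
    ExperimentConfig,
    InitialDistribution,
    LawParams,
    RngHub,
    compute_hsl,
    dilute,
    run_population_experiment,
    summarize_population,
)
from telosen.arrest import CYCLE_NOR, CYCLE_SEN, TYPE_A, TYPE_B
from telosen.population import ConfigError


def point_dist(value):
    return InitialDistribution(l_inf=value, l_mode=value, l_sup=value, l_0=0, l_1=1)


def cells_dict(L, T=None, C=None, gen=None):
    n = L.shape[0]
    return dict(
        L=L,
        T=T if T is not None else np.full(n, TYPE_A, dtype=np.int8),
        C=C if C is not None else np.full(n, CYCLE_NOR, dtype=np.int8),
        gen=gen if gen is not None else np.zeros(n, dtype=np.int32),
        anc=np.zeros(n, dtype=np.int16),
        ever_nta=np.zeros(n, dtype=bool),
        ever_nor_after=np.zeros(n, dtype=bool),
        t_div=np.zeros(n),
    )


class TestConfig:
    def test_defaults(self):
        cfg = ExperimentConfig()
        assert cfg.n_sat == 300_000
        assert cfg.n_dil == cfg.n_init

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentConfig(r_sat=0.5)
        with pytest.raises(ConfigError):
            ExperimentConfig(n_init=0)
        with pytest.raises(ConfigError):
            ExperimentConfig(n_init=10, r_sat=2, n_dil=100)


class TestGrowth:
    def test_immortal_doubling_matches_closed_form(
        self, immortal_params, constant_bank
    ):
        """With no arrests and constant 90-min cycles the count doubles
        every 90 min until the cap: N_sat is reached at the
        ceil(log2(r_sat))-th doubling and never exceeded."""
        cfg = ExperimentConfig(n_init=8, r_sat=64, n_days=1,
                               snapshot_interval_h=0.5)
        res = run_population_experiment(
            cfg, immortal_params, point_dist(300), constant_bank, RngHub(0)
        )
        sn = res.snapshots
        assert (sn["count"] <= cfg.n_sat).all()
        # exact doubling at each 90-min boundary before saturation
        expected_sat_time_h = np.ceil(np.log2(64)) * 1.5
        sat_times = sn[sn["count"] == cfg.n_sat]["time_h"]
        assert sat_times.min() == pytest.approx(expected_sat_time_h, abs=1e-9)
        at_3h = sn[np.isclose(sn["time_h"], 3.0)]["count"].iloc[0]
        assert at_3h == 8 * 4
        assert res.end_of_day_counts[0] == cfg.n_sat

    def test_cap_never_exceeded_with_defaults(self, params, bank, dist):
        cfg = ExperimentConfig(n_init=50, r_sat=20, n_days=3)
        res = run_population_experiment(cfg, params, dist, bank, RngHub(21))
        assert (res.snapshots["count"] <= cfg.n_sat).all()
        assert (res.end_of_day_counts <= cfg.n_sat).all()

    def test_replay_is_deterministic(self, params, bank, dist):
        cfg = ExperimentConfig(n_init=40, r_sat=25, n_days=2)
        a = run_population_experiment(cfg, params, dist, bank, RngHub(22))
        b = run_population_experiment(cfg, params, dist, bank, RngHub(22))
        assert a.snapshots.equals(b.snapshots)
        assert a.onsets.equals(b.onsets)

    def test_extinction_ends_run_early(self, bank):
        lethal = LawParams(p_accident=0.95)
        cfg = ExperimentConfig(n_init=20, r_sat=10, n_days=5)
        res = run_population_experiment(
            cfg, lethal, point_dist(300), bank, RngHub(23)
        )
        assert res.extinct
        assert res.extinction_time_h <= 5 * 24
        assert np.isfinite(res.hsl_hours())

    def test_generation_variance_grows_over_days(self, params, bank, dist):
        """Generational-age heterogeneity rises day over day."""
        cfg = ExperimentConfig(n_init=100, r_sat=50, n_days=4)
        res = run_population_experiment(cfg, params, dist, bank, RngHub(24))
        sn = res.snapshots
        day_rows = sn[np.isclose(sn["time_h"] % 24, 0) & (sn["time_h"] > 0)]
        gv = day_rows["gen_var"].to_numpy()
        gm = day_rows["gen_mean"].to_numpy()
        assert (np.diff(gm) > 0).all()
        assert gv[-1] > gv[0]

    def test_telomere_mode_and_mean_decrease_daily(self, params, bank, dist):
        cfg = ExperimentConfig(n_init=100, r_sat=100, n_days=4)
        res = run_population_experiment(cfg, params, dist, bank, RngHub(25))
        sn = res.snapshots
        day_rows = sn[np.isclose(sn["time_h"] % 24, 0) & (sn["time_h"] > 0)]
        assert (np.diff(day_rows["telo_mean"]) < 0).all()
        assert (np.diff(day_rows["telo_mode"]) <= 0).all()


class TestDilution:
    def test_retained_set_is_hypergeometric(self, rng):
        """Mark 300 of 1000 cells; across 500 independent dilutions to
        100 the marked count matches the hypergeometric law."""
        n, k, n_dil, reps = 1000, 300, 100, 500
        marked = np.zeros(n, dtype=bool)
        marked[:k] = True
        draws = np.array(
            [marked[dilute(n, n_dil, rng)].sum() for _ in range(reps)]
        )
        hyper = stats.hypergeom(n, k, n_dil)
        se = hyper.std() / np.sqrt(reps)
        assert abs(draws.mean() - hyper.mean()) < 3 * se

    def test_dilution_keeps_everyone_when_small(self, rng):
        assert len(dilute(50, 100, rng)) == 50

    def test_count_after_dilution_is_n_dil(self, params, bank, dist):
        cfg = ExperimentConfig(n_init=50, r_sat=30, n_days=2,
                               snapshot_interval_h=0.25)
        res = run_population_experiment(cfg, params, dist, bank, RngHub(26))
        sn = res.snapshots
        just_after = sn[np.isclose(sn["time_h"], 24.25)]
        # within 15 min of dilution at most a few divisions have fired
        assert just_after["count"].iloc[0] <= cfg.n_dil * 2
        assert res.end_of_day_counts[0] == cfg.n_sat


class TestSnapshots:
    def test_mode_tie_breaks_to_smallest(self):
        L = np.array(
            [np.full((2, 16), 200), np.full((2, 16), 100)], dtype=np.int16
        )
        row = summarize_population(cells_dict(L), 0.0)
        assert row["telo_mode"] == 100

    def test_fraction_and_min_statistics(self):
        L = np.full((10, 2, 16), 300, dtype=np.int16)
        L[0, 0, 0], L[1, 0, 0], L[2, 0, 0] = 30, 50, 70
        C = np.full(10, CYCLE_NOR, dtype=np.int8)
        C[:2] = CYCLE_SEN
        row = summarize_population(cells_dict(L, C=C), 1.0)
        assert row["frac_sen"] == pytest.approx(0.2)
        assert row["shortest_min"] == 30
        assert row["shortest_max"] == 300
        assert row["count"] == 10

    def test_empty_population_snapshot(self):
        L = np.zeros((0, 2, 16), dtype=np.int16)
        row = summarize_population(cells_dict(L), 5.0)
        assert row["count"] == 0
        assert np.isnan(row["telo_mean"])


class TestHsl:
    def test_interpolation_oracle(self):
        """Counts [N, N, N, 0.8N, 0.3N] cross half-saturation at
        96 + 24 * (0.8 - 0.5) / (0.8 - 0.3) = 110.4 h."""
        n_sat = 10_000
        counts = np.array([1, 1, 1, 0.8, 0.3]) * n_sat
        assert compute_hsl(counts, n_sat) == pytest.approx(110.4)

    def test_never_below_half_is_censored(self):
        assert compute_hsl([100, 100, 100], 100) == np.inf

    def test_scaling_counts_down_moves_hsl_earlier(self, rng):
        n_sat = 1000
        for _ in range(20):
            counts = n_sat * np.sort(rng.random(6))[::-1]
            a = compute_hsl(counts, n_sat)
            b = compute_hsl(counts * 0.5, n_sat)
            if np.isfinite(a):
                assert b <= a

    def test_first_day_below_uses_extinction_time(self):
        assert compute_hsl([10, 0], 1000, extinction_time_h=15.0) == 15.0
        assert compute_hsl([10, 5], 1000) == 24.0
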