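"""Lineage simulation, duration-based classification, arrest curves."""

import numpy as np
import pytest

from telosen import (
    InitialDistribution,
    LawParams,
    RngHub,
    arrest_generation_curves,
    classify_lineage,
    observed_type_b_proportion,
    simulate_lineage,
    simulate_lineages,
)
from telosen.arrest import CYCLE_NTA, CYCLE_SEN
from telosen.lineage import LineageBatch, LineageRecord


def point_dist(value):
    return InitialDistribution(l_inf=value, l_mode=value, l_sup=value, l_0=0, l_1=1)


def record_from_durations(durations, cycle_types=None):
    n = len(durations)
    return LineageRecord(
        generations=np.arange(n),
        cycle_types=np.asarray(
            cycle_types if cycle_types is not None else [0] * n
        ),
        durations=np.asarray(durations, dtype=float),
        shortest=np.full(n, 100),
        gen_first_nta=None,
        gen_sen=None,
        gen_death=n,
        death_cause="senescence",
        observed_type="A",
        is_M=False,
        truncated=False,
    )


class TestSimulateLineage:
    def test_threshold_start_gives_single_sen_cycle(self, bank):
        """Founders at 27 bp force senescence at generation 1; with
        p_death = 1 the terminal sequence has exactly one cycle."""
        params = LawParams(p_accident=0.0, p_death=1.0)
        rec = simulate_lineage(params, point_dist(27), bank, RngHub(4))
        assert rec.gen_sen == 1
        assert rec.gen_death == 2
        assert rec.death_cause == "senescence"
        assert list(rec.cycle_types) == [0, CYCLE_SEN]

    def test_pure_type_a_regime(self, bank, dist):
        """With the nta channel off every lineage stays type A and
        senescence onset coincides with the threshold crossing."""
        params = LawParams(b_nta=0.0, p_accident=0.0)
        batch = simulate_lineages(300, params, dist, bank, RngHub(5))
        observed_b, is_m = batch.classify()
        assert not observed_b.any()
        assert not is_m.any()
        sen = batch.gen_sen
        assert (sen[~batch.truncated] >= 0).all()
        # onset happened at a length where the law is positive
        onsets = batch.shortest_at_sen_onset
        from telosen.arrest import LawParams as LP
        from telosen import eval_arrest_law

        for l in onsets[onsets >= 0]:
            assert eval_arrest_law(params.a_sen_A, params.b_sen_A,
                                   params.l_min_A, int(l)) > 0

    def test_immortal_parameters_truncate_at_cap(self, bank, dist):
        params = LawParams(
            b_nta=0.0, b_sen_A=0.0, b_sen_B=0.0, l_min_A=0.0, l_min_B=0.0,
            p_accident=0.0, h=0,
        )
        rec = simulate_lineage(params, dist, bank, RngHub(6), max_generations=50)
        assert rec.truncated
        assert rec.n_cycles == 51
        assert rec.gen_death is None

    def test_replay_is_deterministic(self, bank, dist, params):
        a = simulate_lineages(50, params, dist, bank, RngHub(7))
        b = simulate_lineages(50, params, dist, bank, RngHub(7))
        np.testing.assert_array_equal(a.cycle_types, b.cycle_types)
        np.testing.assert_array_equal(a.durations, b.durations)
        np.testing.assert_array_equal(a.shortest, b.shortest)

    def test_shortest_telomere_non_increasing_along_lineage(self, bank, dist, params):
        """Every telomere is non-increasing down a lineage, so the
        per-cell minimum is too (and never negative)."""
        batch = simulate_lineages(100, params, dist, bank, RngHub(8))
        for i in range(100):
            n = int((batch.cycle_types[i] >= 0).sum())
            mins = batch.shortest[i, :n]
            assert (np.diff(mins) <= 0).all()
            assert mins.min() >= 0

    def test_first_nta_precedes_type_a_senescence(self, bank, dist, params):
        batch = simulate_lineages(500, params, dist, bank, RngHub(9))
        observed_b, _ = batch.classify()
        nta = batch.gen_first_nta
        sen = batch.gen_sen
        med_nta = np.median(nta[nta >= 0])
        med_sen_a = np.median(sen[(sen >= 0) & ~observed_b])
        assert med_nta < med_sen_a


class TestClassification:
    def test_long_then_normal_is_type_b(self):
        rec = record_from_durations([90, 95, 250, 92, 300, 310])
        assert classify_lineage(rec, 180.0)[0] == "B"

    def test_terminal_only_arrests_are_type_a(self):
        rec = record_from_durations([90, 93, 95, 200, 250])
        assert classify_lineage(rec, 180.0)[0] == "A"

    def test_hidden_type_b_flagged_as_m(self):
        """A true-B record whose nta sequence runs straight into
        senescence and death shows only terminal long cycles."""
        rec = record_from_durations(
            [90, 95, 250, 300, 310],
            cycle_types=[0, 0, CYCLE_NTA, CYCLE_SEN, CYCLE_SEN],
        )
        observed, is_m = classify_lineage(rec, 180.0)
        assert observed == "A"
        assert is_m

    def test_batch_and_scalar_classification_agree(self, bank, dist, params):
        batch = simulate_lineages(200, params, dist, bank, RngHub(10))
        observed_b, is_m = batch.classify()
        for rec, ob, m in zip(batch.records(), observed_b, is_m):
            s_obs, s_m = classify_lineage(rec, params.D)
            assert (s_obs == "B") == bool(ob)
            assert s_m == bool(m)
            assert rec.observed_type == s_obs


class TestCurves:
    def test_sen_curve_is_sorted(self, bank, dist, params):
        batch = simulate_lineages(100, params, dist, bank, RngHub(11))
        curves = arrest_generation_curves(batch)
        for arr in curves.values():
            assert (np.diff(arr) >= 0).all()

    def test_sen_curve_is_union_of_typed_curves(self, bank, dist, params):
        batch = simulate_lineages(400, params, dist, bank, RngHub(12))
        curves = arrest_generation_curves(batch)
        merged = np.sort(np.concatenate([curves["sen_A"], curves["sen_B"]]))
        np.testing.assert_array_equal(merged, curves["sen"])

    def test_fatal_arrest_sequences_are_hidden_type_b(self, bank):
        """Lineages whose only arrest sequence ends in death (never a
        recovery) are observationally type A with the M flag set, and
        contribute nothing to the observed-B senescence curve."""
        params = LawParams(
            p_accident=0.2, p_repair=0.0, b_nta=1.0, a_nta=0.0,
            b_sen_A=0.0, l_min_A=0.0, h=0,
        )
        # every surviving generation-1 daughter enters nta and can never
        # repair, so each arrest sequence runs until accidental death
        batch = simulate_lineages(50, params, point_dist(300), bank, RngHub(13))
        observed_b, is_m = batch.classify()
        had_nta = (batch.cycle_types == CYCLE_NTA).any(axis=1)
        assert not observed_b.any()
        assert had_nta.any()
        np.testing.assert_array_equal(is_m, had_nta)
        curves = arrest_generation_curves(batch)
        assert curves["sen_B"].size == 0
        assert curves["sen_A"].size == curves["sen"].size

    def test_three_known_sen_generations(self, bank):
        params = LawParams(p_accident=0.0, p_death=1.0, b_nta=0.0)
        batch = simulate_lineages(3, params, point_dist(27), bank, RngHub(14))
        curves = arrest_generation_curves(batch)
        np.testing.assert_array_equal(curves["sen"], [1, 1, 1])


class TestProportion:
    def test_observed_b_proportion_in_published_band(self, bank, dist, params):
        batch = simulate_lineages(1000, params, dist, bank, RngHub(15))
        assert 0.5 < observed_type_b_proportion(batch) < 0.95
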