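"""Telomere matrix division rule and initial-distribution transform."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from telosen import InitialDistribution, divide_telomeres, transform_distribution
from telosen.telomeres import (
    MATRIX_SHAPE,
    N_CHROMOSOMES,
    TelomereError,
    divide_batch,
    divide_with_coupling,
)


def matrix_of(value):
    return np.full(MATRIX_SHAPE, value, dtype=np.int64)


class TestDivision:
    def test_forced_coupling_shortens_complementary_ends(self):
        parent = matrix_of(0)
        parent[0, 0], parent[1, 0] = 100, 200
        b = np.zeros(N_CHROMOSOMES, dtype=int)
        b[0] = 1
        d1, d2 = divide_with_coupling(parent, 7, b)
        assert (d1[0, 0], d1[1, 0]) == (93, 200)
        assert (d2[0, 0], d2[1, 0]) == (100, 193)

    def test_zero_overhang_is_identity(self, rng):
        parent = rng.integers(0, 400, size=MATRIX_SHAPE)
        d1, d2 = divide_telomeres(parent, 0, rng)
        np.testing.assert_array_equal(d1, parent)
        np.testing.assert_array_equal(d2, parent)

    def test_conservation_by_enumeration(self):
        """Sum over both daughters loses exactly 2h per chromosome,
        for every possible coupling value (brute-force over B in {0,1})."""
        h = 7
        parent = matrix_of(0)
        parent[0, :], parent[1, :] = 100, 200
        for bval in (0, 1):
            b = np.full(N_CHROMOSOMES, bval)
            d1, d2 = divide_with_coupling(parent, h, b)
            per_chrom = d1.sum(axis=0) + d2.sum(axis=0)
            expected = parent.sum(axis=0) * 2 - 2 * h
            np.testing.assert_array_equal(per_chrom, expected)

    def test_clamping_at_zero(self):
        parent = matrix_of(0)
        parent[0, 0], parent[1, 0] = 3, 200
        b = np.ones(N_CHROMOSOMES, dtype=int)
        d1, _ = divide_with_coupling(parent, 7, b)
        assert d1[0, 0] == 0
        assert d1[1, 0] == 200

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(TelomereError):
            divide_telomeres(np.zeros((3, 16), dtype=int), 7, rng)
        with pytest.raises(TelomereError):
            divide_telomeres(matrix_of(100), -1, rng)
        with pytest.raises(TelomereError):
            divide_telomeres(matrix_of(-5), 7, rng)

    @settings(derandomize=True, max_examples=50)
    @given(
        seed=st.integers(0, 10_000),
        h=st.integers(0, 15),
    )
    def test_coupling_identity_property(self, seed, h):
        """The end shortened in daughter 1 is exactly the end left intact
        in daughter 2 (pre-clamping), for random parents and overhangs."""
        rng = np.random.default_rng(seed)
        parent = rng.integers(h, 500, size=MATRIX_SHAPE)
        d1, d2 = divide_telomeres(parent, h, rng)
        np.testing.assert_array_equal((parent - d1) + (parent - d2),
                                      np.full(MATRIX_SHAPE, h))

    def test_monotone_along_lineage(self, rng):
        lengths = matrix_of(300)
        for _ in range(40):
            d1, d2 = divide_telomeres(lengths, 7, rng)
            child = d1 if rng.random() < 0.5 else d2
            assert (child <= lengths).all()
            lengths = child

    def test_expected_shortening_is_half_overhang(self, rng):
        """A fixed telomere loses h/2 per division on average."""
        h, n = 7, 20_000
        parents = np.full((n, 2, 16), 300, dtype=np.int64)
        coupling = rng.integers(0, 2, size=(n, 16))
        d1, _ = divide_batch(parents, h, coupling)
        loss = 300 - d1[:, 0, 0]
        se = np.sqrt(0.25 / n) * h
        assert abs(loss.mean() - h / 2) < 3 * se


class TestInitialDistribution:
    def test_identity_transform(self):
        dist = InitialDistribution(l_inf=100, l_mode=300, l_sup=500,
                                   l_0=0, l_1=200, l_trans=0)
        x = np.array([100, 215, 300, 417, 500])
        np.testing.assert_array_equal(dist.transform(x), x)

    def test_mode_is_fixed_point_up_to_translation(self):
        for l_trans in (-30, 0, 12):
            dist = InitialDistribution(l_trans=l_trans)
            assert dist.transform(300) == 300 + l_trans

    def test_endpoint_mapping_with_best_fit_dilations(self):
        dist = InitialDistribution(l_inf=100, l_mode=300, l_sup=500,
                                   l_0=40, l_1=58, l_trans=0)
        assert dist.transform(100) == 140
        assert dist.transform(500) == 358

    def test_left_flank_collapse_rejected(self):
        with pytest.raises(TelomereError):
            InitialDistribution(l_0=250)

    def test_out_of_support_rejected(self, dist):
        with pytest.raises(TelomereError):
            dist.transform(600)

    def test_degenerate_distribution_is_constant(self, rng):
        dist_point = InitialDistribution(l_inf=300, l_mode=300, l_sup=300,
                                         l_0=0, l_1=1)
        m = dist_point.sample_matrix(rng)
        assert (m == 300).all()

    def test_translation_commutes_with_sampling(self):
        a = InitialDistribution(l_trans=0).sample_lengths(
            500, np.random.default_rng(3)
        )
        b = InitialDistribution(l_trans=-20).sample_lengths(
            500, np.random.default_rng(3)
        )
        np.testing.assert_array_equal(a - 20, b)

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(100, 500), st.floats(100, 500))
    def test_transform_preserves_order(self, x, y):
        dist = InitialDistribution()
        fx, fy = dist.transform(x), dist.transform(y)
        if x <= y:
            assert fx <= fy

    def test_sampled_cdf_matches_direct_inverse_cdf(self):
        """Matrix-path samples and direct transformed draws agree
        (two-sample KS not rejected at the 1% level)."""
        dist = InitialDistribution()
        rng1 = np.random.default_rng(11)
        pooled = np.concatenate(
            [dist.sample_matrix(rng1).ravel() for _ in range(1000)]
        )
        rng2 = np.random.default_rng(12)
        direct = dist.sample_lengths(32_000, rng2)
        assert stats.ks_2samp(pooled, direct).pvalue > 0.01

    def test_loaded_sample_replaces_base(self, tmp_path):
        path = tmp_path / "lengths.txt"
        path.write_text("\n".join(["250"] * 50 + ["350"] * 30))
        from telosen import load_length_sample

        dist = InitialDistribution(base_sample=load_length_sample(path),
                                   l_0=0, l_1=100)
        draws = dist.sample_lengths(200, np.random.default_rng(0))
        assert set(np.unique(draws)) <= {250, 350}

    def test_functional_alias(self, dist, rng):
        m = InitialDistribution().sample_matrix(rng)
        assert m.shape == MATRIX_SHAPE
        assert transform_distribution(300, dist) == 300
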