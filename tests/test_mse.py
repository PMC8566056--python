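"""Coarse-graining and sample-entropy core: oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mselat import (
    MseParams,
    ParameterError,
    coarse_grain,
    entropy_matrix,
    entropy_table,
    mse_value,
    sample_entropy,
    sample_entropy_counts,
)
from mselat.synthetic import RoiTimeSeriesDataset

from _oracles import brute_force_sampen_counts


class TestCoarseGrain:
    @pytest.mark.parametrize(
        "x, tau, expected",
        [
            ([1, 2, 3, 4, 5, 6], 2, [1.5, 3.5, 5.5]),
            ([1, 2, 3, 4, 5, 6], 3, [2.0, 5.0]),
            ([1, 2, 3, 4, 5, 6, 7], 3, [2.0, 5.0]),  # remainder discarded
        ],
    )
    def test_window_averages(self, x, tau, expected):
        np.testing.assert_allclose(coarse_grain(x, tau), expected)

    def test_tau_one_is_identity(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_length_is_floor(self, rng):
        assert coarse_grain(rng.standard_normal(246), 3).size == 82

    def test_mean_conserved_over_truncated_window(self, rng):
        # mean of the coarse series equals the mean of the first
        # tau*floor(N/tau) samples exactly (window sums are regrouped sums)
        x = rng.standard_normal(101)
        for tau in (2, 3, 4, 7):
            y = coarse_grain(x, tau)
            np.testing.assert_allclose(
                y.mean(), x[: tau * (101 // tau)].mean(), rtol=1e-12
            )

    @pytest.mark.parametrize("tau", [0, -1, 7])
    def test_invalid_tau_raises(self, tau):
        with pytest.raises(ParameterError):
            coarse_grain([1.0, 2.0, 3.0], tau)


class TestSampleEntropy:
    def test_constant_series_has_zero_entropy(self):
        y = np.full(50, 3.7)
        for m in (1, 2):
            assert sample_entropy(y, m, 0.1) == 0.0

    def test_small_series_against_enumerator(self):
        y = np.array([1, 2, 3, 4, 5, 6, 7, 8], float)
        # r below the unit spacing: no off-diagonal matches, undefined
        assert brute_force_sampen_counts(y, 1, 0.5) == (0, 0)
        assert sample_entropy_counts(y, 1, 0.5) == (0, 0)
        assert math.isnan(sample_entropy(y, 1, 0.5))
        # r at the spacing: adjacent templates match, entropy defined
        a, b = brute_force_sampen_counts(y, 1, 1.0)
        assert sample_entropy_counts(y, 1, 1.0) == (a, b)
        assert sample_entropy(y, 1, 1.0) == pytest.approx(-math.log(a / b))

    @pytest.mark.parametrize("m", [1, 2, 3])
    @pytest.mark.parametrize("dist", ["normal", "uniform", "walk", "ties"])
    def test_counts_match_brute_force(self, m, dist, rng):
        for trial in range(6):
            length = int(rng.integers(m + 5, 60))
            if dist == "normal":
                y = rng.standard_normal(length)
            elif dist == "uniform":
                y = rng.uniform(-1, 1, length)
            elif dist == "walk":
                y = np.cumsum(rng.standard_normal(length))
            else:
                y = rng.integers(0, 4, length).astype(float)  # heavy ties
            r_abs = float(rng.uniform(0.05, 1.0))
            expected = brute_force_sampen_counts(y, m, r_abs)
            assert sample_entropy_counts(y, m, r_abs) == expected

    def test_chunked_path_matches_direct(self, rng):
        # force the memory-bounded path and compare against the direct one
        from mselat import mse

        y = rng.standard_normal(300)
        direct = sample_entropy_counts(y, 2, 0.4)
        old = mse._CHUNK_THRESHOLD
        mse._CHUNK_THRESHOLD = 10
        try:
            assert sample_entropy_counts(y, 2, 0.4) == direct
        finally:
            mse._CHUNK_THRESHOLD = old

    def test_undefined_when_no_matches(self):
        y = np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0])
        assert math.isnan(sample_entropy(y, 1, 0.5))

    def test_entropy_nonnegative_and_a_le_b(self, rng):
        for _ in range(30):
            y = rng.standard_normal(int(rng.integers(20, 120)))
            a, b = sample_entropy_counts(y, 2, float(rng.uniform(0.1, 1.5)))
            assert 0 <= a <= b
            if a > 0:
                assert -math.log(a / b) >= 0

    def test_monotone_in_tolerance(self, rng):
        y = rng.standard_normal(150)
        rs = np.linspace(0.1, 1.5, 12)
        counts = [sample_entropy_counts(y, 1, r) for r in rs]
        a_vals = [c[0] for c in counts]
        b_vals = [c[1] for c in counts]
        assert a_vals == sorted(a_vals)
        assert b_vals == sorted(b_vals)
        ent = [sample_entropy(y, 1, r) for r in rs]
        defined = [e for e in ent if not math.isnan(e)]
        assert defined == sorted(defined, reverse=True)

    def test_iid_normal_analytic_limit(self):
        # for long iid N(0,1) series with m=1, A/B -> P(|X-Y| <= r) and
        # the entropy approaches -ln erf(r / (2*sqrt(1/2)*sqrt(2)))
        rng = np.random.default_rng(7)
        vals = [sample_entropy(rng.standard_normal(10_000), 1, 0.56) for _ in range(3)]
        expected = -math.log(math.erf(0.28))
        assert abs(np.mean(vals) - expected) < 0.1

    def test_too_short_series_raises(self):
        with pytest.raises(ParameterError):
            sample_entropy_counts(np.array([1.0, 2.0]), 2, 0.5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=8, max_size=40),
        st.integers(1, 2),
        st.floats(0.05, 2.0),
    )
    def test_counts_property_vs_enumerator(self, values, m, r_abs):
        y = np.asarray(values)
        expected = brute_force_sampen_counts(y, m, r_abs)
        assert sample_entropy_counts(y, m, r_abs) == expected


class TestMseValue:
    def test_constant_series_zero(self):
        assert mse_value(np.full(100, 2.0), MseParams(1, 0.56, 3)) == 0.0

    def test_tau_one_on_unit_sd_series_equals_sampen(self, rng):
        x = rng.standard_normal(200)
        x = (x - x.mean()) / x.std()
        got = mse_value(x, MseParams(m=1, r=0.56, tau=1))
        ref = sample_entropy(x, 1, 0.56 * x.std())
        assert got == pytest.approx(ref, rel=1e-12)

    def test_composition_of_oracles(self, rng):
        # mse = sampen(coarse_grain(x, tau), m, r * sd(x)) with sd taken
        # on the original series
        x = rng.standard_normal(120)
        params = MseParams(m=1, r=0.56, tau=3)
        y = coarse_grain(x, 3)
        a, b = brute_force_sampen_counts(y, 1, 0.56 * np.std(x))
        assert mse_value(x, params) == pytest.approx(-math.log(a / b))

    def test_white_noise_entropy_decays_with_scale(self):
        # classic multiscale result: for iid noise the coarse-grained
        # series is closer to its tolerance band, entropy falls with tau
        rng = np.random.default_rng(21)
        diff = []
        for _ in range(50):
            x = rng.standard_normal(246)
            e1 = mse_value(x, MseParams(1, 0.56, 1))
            e3 = mse_value(x, MseParams(1, 0.56, 3))
            diff.append(e3 - e1)
        assert np.mean(diff) < 0

    def test_params_invalid_for_length(self):
        with pytest.raises(ParameterError):
            mse_value(np.arange(100, dtype=float), MseParams(m=2, r=0.5, tau=50))


class TestEntropyMatrix:
    def test_shape_and_loop_equivalence(self, small_dataset):
        params = MseParams(1, 0.56, 3)
        mat = entropy_matrix(small_dataset, params)
        assert mat.values.shape == (small_dataset.n_subjects, small_dataset.n_regions)
        for s in (0, 3):
            for g in (0, 7):
                assert mat.values[s, g] == mse_value(small_dataset.data[s, g], params)

    def test_constant_dataset_all_zero(self):
        ds = RoiTimeSeriesDataset(
            data=np.ones((4, 3, 60)),
            labels=np.array([1, 1, 0, 0]),
            region_names=["a", "b", "c"],
        )
        mat = entropy_matrix(ds, MseParams(1, 0.3, 2))
        assert np.all(mat.values == 0.0)
        assert mat.n_undefined == 0


class TestEntropyTable:
    def test_matches_entropy_matrix_bitwise(self, small_dataset):
        m_values, r_values, tau_values = [1, 2], [0.3, 0.44, 0.56], [1, 3]
        table = entropy_table(small_dataset, m_values, r_values, tau_values)
        assert table.shape == (2, 2, 3, small_dataset.n_subjects, small_dataset.n_regions)
        for mi, m in enumerate(m_values):
            for ti, tau in enumerate(tau_values):
                for ri, r in enumerate(r_values):
                    mat = entropy_matrix(small_dataset, MseParams(m, r, tau))
                    np.testing.assert_array_equal(table[mi, ti, ri], mat.values)

    def test_unsorted_r_rejected(self, small_dataset):
        with pytest.raises(ParameterError):
            entropy_table(small_dataset, [1], [0.5, 0.3], [1])
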