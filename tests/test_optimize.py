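"""Parameter-selection stages: statistics oracles and selection contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mselat import (
    MseParams,
    ParamGrid,
    RoiTimeSeriesDataset,
    SyntheticConfig,
    auc,
    entropy_matrix,
    generate_dataset,
    optimize_all,
    region_pvalues,
    roc_curve,
    select_m,
    select_r,
    select_tau,
    significance_count,
)
from _oracles import mann_whitney_auc_oracle, pooled_ttest_oracle


class TestRegionPvalues:
    def test_matches_textbook_formula(self, rng):
        values = rng.standard_normal((20, 6))
        labels = np.array([1] * 10 + [0] * 10)
        pv = region_pvalues(values, labels)
        for g in range(6):
            expected = pooled_ttest_oracle(
                list(values[:10, g]), list(values[10:, g])
            )
            assert pv[g] == pytest.approx(expected, rel=1e-10)

    def test_identical_distributions_p_one(self):
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 2)
        labels = np.array([1] * 5 + [0] * 5)
        pv = region_pvalues(col[:, None], labels)
        assert pv[0] == pytest.approx(1.0)

    def test_extreme_separation_tiny_p(self, rng):
        col = np.concatenate([np.zeros(5), np.ones(5)]) + rng.normal(0, 1e-6, 10)
        labels = np.array([1] * 5 + [0] * 5)
        assert region_pvalues(col[:, None], labels)[0] < 1e-6

    def test_masked_values_dropped(self):
        col = np.array([1.0, 1.1, 0.9, np.nan, 1.05, 2.0, 2.1, 1.9, 2.05, np.nan])
        labels = np.array([1] * 5 + [0] * 5)
        pv = region_pvalues(col[:, None], labels)
        expected = pooled_ttest_oracle([1.0, 1.1, 0.9, 1.05], [2.0, 2.1, 1.9, 2.05])
        assert pv[0] == pytest.approx(expected, rel=1e-10)

    def test_all_masked_class_gives_nan(self):
        col = np.array([np.nan] * 5 + [1.0, 2.0, 3.0, 4.0, 5.0])
        labels = np.array([1] * 5 + [0] * 5)
        assert np.isnan(region_pvalues(col[:, None], labels)[0])

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            region_pvalues(np.ones((4, 2)), np.ones(4))


class TestSignificanceCount:
    def test_strict_inequality(self):
        assert significance_count(np.array([0.01, 0.04, 0.05, 0.9]), 0.05) == 2

    def test_undefined_excluded(self):
        assert significance_count(np.array([np.nan, np.nan]), 0.05) == 0
        assert significance_count(np.array([0.01, np.nan]), 0.05) == 1

    def test_uniform_null_rate(self, rng):
        # 90 uniform p-values -> expected count alpha*90 = 4.5
        counts = [
            significance_count(rng.uniform(size=90), 0.05) for _ in range(300)
        ]
        assert np.mean(counts) == pytest.approx(4.5, abs=0.6)


class TestAuc:
    @pytest.mark.parametrize(
        "values, labels, expected",
        [
            ([3, 4, 1, 2], [1, 1, 0, 0], 1.0),
            ([1, 2, 1, 2], [1, 1, 0, 0], 0.5),
            ([1, 3, 5, 2, 4], [1, 1, 1, 0, 0], 0.5),  # 3 of 6 winning pairs
        ],
    )
    def test_known_values(self, values, labels, expected):
        assert auc(values, labels) == pytest.approx(expected)

    def test_exhaustive_pair_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 20))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            if labels.sum() in (0, n):
                continue
            values = rng.integers(0, 6, n).astype(float)  # many ties
            assert auc(values, labels) == mann_whitney_auc_oracle(values, labels)

    def test_label_flip_symmetry(self, rng):
        values = rng.standard_normal(14)
        labels = np.array([1] * 7 + [0] * 7)
        assert auc(values, labels) == pytest.approx(1 - auc(values, 1 - labels))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 8), min_size=4, max_size=16),
        st.data(),
    )
    def test_auc_property_vs_oracle(self, values, data):
        n = len(values)
        n_pos = data.draw(st.integers(1, n - 1))
        labels = [1] * n_pos + [0] * (n - n_pos)
        got = auc(np.array(values, float), np.array(labels))
        assert got == mann_whitney_auc_oracle(values, labels)
        assert 0.0 <= got <= 1.0


class TestRocCurve:
    def test_perfect_separation_passes_through_corner(self):
        curve = roc_curve([5.0, 6.0, 1.0, 2.0], [1, 1, 0, 0])
        assert (0.0, 1.0) in {tuple(p) for p in curve}

    def test_endpoints(self, rng):
        curve = roc_curve(rng.standard_normal(10), [1] * 5 + [0] * 5)
        assert tuple(curve[0]) == (0.0, 0.0)
        assert tuple(curve[-1]) == (1.0, 1.0)

    def test_identical_values_diagonal(self):
        curve = roc_curve(np.ones(8), [1] * 4 + [0] * 4)
        assert [tuple(p) for p in curve] == [(0.0, 0.0), (1.0, 1.0)]

    def test_trapezoidal_area_equals_auc(self, rng):
        for _ in range(25):
            values = rng.integers(0, 5, 12).astype(float)
            labels = np.array([1] * 6 + [0] * 6)
            curve = roc_curve(values, labels)
            area = np.trapezoid(curve[:, 1], curve[:, 0])
            assert abs(area - auc(values, labels)) < 1e-12

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [1, 1])


def _dataset_from_array(data, labels):
    return RoiTimeSeriesDataset(
        data=data,
        labels=np.asarray(labels),
        region_names=[f"R{g}" for g in range(data.shape[1])],
    )


class TestSelectionStages:
    def test_select_m_membership_and_counts_shape(self, small_dataset):
        grid = ParamGrid(r_values=(0.4, 0.56), tau_values=(1, 3))
        m_star, counts = select_m(small_dataset, grid)
        assert m_star in grid.m_values
        assert counts.shape == (2, 2, 2)
        assert counts.min() >= 0
        assert counts.max() <= small_dataset.n_regions

    def test_select_r_single_candidate(self, small_dataset):
        r_star, table = select_r(small_dataset, 1, [3], [0.56], top_k=2)
        assert r_star == 0.56
        assert table.shape == (small_dataset.n_regions, 1)

    def test_select_tau_single_candidate(self, small_dataset):
        tau_star, table = select_tau(small_dataset, 1, 0.56, [3], top_k=2)
        assert tau_star == 3
        assert table.shape == (small_dataset.n_regions, 1)

    def test_auc_tables_in_unit_interval(self, small_dataset):
        _, table = select_r(small_dataset, 1, [1, 3], [0.4, 0.56], top_k=2)
        assert np.all((table >= 0) & (table <= 1))

    def test_fast_dynamics_difference_selects_tau_one(self):
        # groups differing only in fast (within-TR) structure: group 1
        # has anti-correlated MA(1) noise, group 0 white noise.  The
        # difference vanishes under averaging, so scale 1 wins.
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            n, t = 12, 246
            data = np.empty((n, 20, t))
            for s in range(n):
                for g in range(20):
                    e = rng.standard_normal(t + 1)
                    x = e[1:] - 0.9 * e[:-1] if s < 6 else rng.standard_normal(t)
                    data[s, g] = (x - x.mean()) / x.std()
            ds = _dataset_from_array(data, [1] * 6 + [0] * 6)
            tau_star, _ = select_tau(ds, 1, 0.56, [1, 2, 3, 4, 5], top_k=2)
            hits += tau_star == 1
        assert hits >= 4

    def test_optimize_all_contract_and_determinism(self, small_dataset):
        grid = ParamGrid(r_values=(0.4, 0.5, 0.56), tau_values=(1, 2, 3))
        res1 = optimize_all(small_dataset, grid)
        res2 = optimize_all(small_dataset, grid)
        assert res1.selected.m in grid.m_values
        assert res1.selected.r in grid.r_values
        assert res1.selected.tau in grid.tau_values
        assert res1.selected == res2.selected
        np.testing.assert_array_equal(res1.sig_counts, res2.sig_counts)
        np.testing.assert_array_equal(res1.auc_table_r, res2.auc_table_r)
        assert len(res1.audit) >= 3
        assert len(res1.tau_candidates) == grid.n_tau_candidates

    def test_optimize_all_recovers_coarse_scale(self):
        # on a planted dataset the selected scale should exceed 1
        ds = generate_dataset(SyntheticConfig(seed=17))
        grid = ParamGrid(r_values=(0.4, 0.56), tau_values=(1, 2, 3))
        res = optimize_all(ds, grid)
        assert res.selected.tau > 1

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            ParamGrid(r_values=())
        with pytest.raises(ValueError):
            ParamGrid(tau_values=(3, 1))
        with pytest.raises(ValueError):
            ParamGrid(alpha_screen=1.5)
        with pytest.raises(ValueError):
            ParamGrid(top_k=0)
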