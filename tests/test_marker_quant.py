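"""Counting estimator: Otsu threshold vs. exhaustive oracle, slice
sampling, positive calls, per-stack estimates, and the pooled t-test."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from planeye import marker_quant as mq, synthetic_data as sd
from planeye.io_formats import CountingSettings
from planeye.segmentation import NucleusROI, SegParams


def otsu_oracle(values):
    """Brute-force Otsu: try every midpoint cut, maximize between-class
    variance with an explicit loop."""
    values = np.sort(np.asarray(values, dtype=float))
    uniq = np.unique(values)
    best_t, best_var = None, -1.0
    n = len(values)
    for i in range(len(uniq) - 1):
        t = (uniq[i] + uniq[i + 1]) / 2
        lo, hi = values[values <= t], values[values > t]
        var = (len(lo) / n) * (len(hi) / n) * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def pooled_t_oracle(a, b):
    """Independent implementation: scipy's equal-variance two-sample test."""
    return stats.ttest_ind(a, b, equal_var=True)


class TestOtsu:
    def test_two_point_masses_split_between_them(self):
        values = np.array([10.0] * 50 + [200.0] * 50)
        t = mq.otsu_threshold(values)
        assert 10 < t < 200
        assert t == pytest.approx(otsu_oracle(values))

    def test_constant_input_is_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            mq.otsu_threshold(np.full(100, 7.0))

    def test_invariant_under_sample_duplication(self):
        rng = np.random.default_rng(0)
        values = rng.normal(50, 10, 200)
        assert mq.otsu_threshold(values) == mq.otsu_threshold(np.tile(values, 3))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_exhaustive_oracle_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        values = np.round(rng.uniform(0, 100, n), 1)
        if len(np.unique(values)) < 2:
            values = np.concatenate([values, values + 5.0])
        assert mq.otsu_threshold(values) == pytest.approx(otsu_oracle(values))


class TestThresholdSlices:
    def test_selected_slices_contain_the_cells(self, clean_stack_config):
        """Cells occupy a known z-band; selected slices must fall inside it."""
        cfg = dataclasses.replace(clean_stack_config, noise_sd=1.0, background=2.0)
        stack, truth = sd.generate_stack(cfg)
        lo = min(c.z_um - c.radius_um for c in truth)
        hi = max(c.z_um + c.radius_um for c in truth)
        indices = mq.select_threshold_slices(stack)
        assert indices
        for i in indices:
            assert lo - cfg.z_spacing_um <= i * cfg.z_spacing_um <= hi + cfg.z_spacing_um

    def test_zero_signal_stack_is_an_error(self):
        from planeye.io_formats import ImageStack

        stack = ImageStack(
            nuclear=np.zeros((5, 16, 16)), marker=np.zeros((5, 16, 16)),
            z_spacing_um=0.5, pixel_size_um=0.5,
        )
        with pytest.raises(ValueError, match="manual threshold"):
            mq.select_threshold_slices(stack)

    def test_rule_all_returns_every_slice(self, clean_stack):
        stack, _ = clean_stack
        assert mq.select_threshold_slices(stack, rule="all") == list(range(stack.n_slices))


def _roi(pixels):
    return NucleusROI(0, 1, np.array(pixels), (0.0, 0.0), (0, 0, 1, 1))


class TestCalls:
    def test_median_odd_and_even_cardinality(self):
        img = np.zeros((4, 4))
        img[0, :4] = [1, 2, 3, 4]
        roi3 = _roi([(0, 0), (0, 1), (0, 2)])
        roi4 = _roi([(0, 0), (0, 1), (0, 2), (0, 3)])
        assert mq.median_intensity(roi3, img) == 2.0
        assert mq.median_intensity(roi4, img) == 2.5

    def test_out_of_bounds_roi_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            mq.median_intensity(_roi([(9, 9)]), np.zeros((4, 4)))

    def test_positive_call_is_strictly_greater(self):
        img = np.full((2, 2), 100.0)
        roi = _roi([(0, 0), (0, 1)])
        assert mq.call_positive([roi], img, 99.0).calls.tolist() == [True]
        assert mq.call_positive([roi], img, 100.0).calls.tolist() == [False]
        assert mq.call_positive([roi], img, 1e9).n_positive == 0

    def test_noise_free_positive_cell_median_equals_assigned_intensity(
        self, clean_stack, clean_stack_config
    ):
        stack, truth = clean_stack
        cfg = clean_stack_config
        cell = next(c for c in truth if c.marker_positive)
        z = round(cell.z_um / cfg.z_spacing_um)
        col = int(cell.x_um / cfg.pixel_size_um)
        row = int(cell.y_um / cfg.pixel_size_um)
        roi = _roi([(row, col), (row, col + 1), (row + 1, col)])
        assert mq.median_intensity(roi, stack.marker[z]) == cell.marker_intensity


class TestSampleSlices:
    @pytest.mark.parametrize(
        "n,spacing,interval,expected",
        [
            (100, 0.5, 5.0, list(range(0, 100, 10))),
            (100, 0.3, 5.0, [0, 17, 33, 50, 67, 83]),
            (10, 0.5, 0.5, list(range(10))),
        ],
    )
    def test_stated_sampling_grids(self, n, spacing, interval, expected):
        assert mq.sample_slices(n, spacing, interval) == expected

    def test_interval_below_spacing_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            mq.sample_slices(10, 1.0, 0.5)

    def test_indices_strictly_increasing_and_in_range(self):
        idx = mq.sample_slices(37, 0.3, 2.5)
        assert idx == sorted(set(idx))
        assert all(0 <= i < 37 for i in idx)


class TestEstimateCounts:
    SEG = SegParams(smoothing_sigma_px=1.0, min_separation_px=4,
                    min_area_px=10, max_area_px=2000, border_policy="keep")

    def test_zero_marker_signal_gives_zero_total(self, clean_stack):
        stack, _ = clean_stack
        zeroed = dataclasses.replace(stack, marker=np.zeros_like(stack.marker))
        est = mq.estimate_counts(zeroed, seg_params=self.SEG, interval_um=5.0,
                                 threshold=50.0)
        assert est.total == 0

    def test_counts_match_geometric_occupancy_oracle(self, clean_stack,
                                                     clean_stack_config):
        """Noise-free stack: each sampled slice's positive count is bracketed
        by geometric occupancy of the true positive cells — every cell whose
        sphere comfortably intersects the plane (in-plane disc above the
        resolution limit) is counted, and nothing outside occupancy is."""
        stack, truth = clean_stack
        cfg = clean_stack_config
        est = mq.estimate_counts(stack, seg_params=self.SEG, interval_um=5.0,
                                 threshold=100.0)
        for idx, count in zip(est.slice_indices, est.per_slice_counts):
            z = idx * cfg.z_spacing_um
            comfortable = sum(
                1 for c in truth
                if c.marker_positive and abs(c.z_um - z) < 0.8 * c.radius_um
            )
            any_overlap = sum(
                1 for c in truth
                if c.marker_positive and abs(c.z_um - z) < c.radius_um
            )
            assert comfortable <= count <= any_overlap
        assert est.total == sum(est.per_slice_counts)

    def test_joint_scaling_of_intensity_and_threshold_is_invariant(self, clean_stack):
        stack, _ = clean_stack
        doubled = dataclasses.replace(stack, marker=stack.marker * 2.0)
        e1 = mq.estimate_counts(stack, seg_params=self.SEG, threshold=100.0)
        e2 = mq.estimate_counts(doubled, seg_params=self.SEG, threshold=200.0)
        assert e1.per_slice_counts == e2.per_slice_counts

    def test_threshold_monotonicity(self, clean_stack):
        stack, _ = clean_stack
        totals = [
            mq.estimate_counts(stack, seg_params=self.SEG, threshold=t).total
            for t in [10.0, 50.0, 100.0, 179.0, 250.0]
        ]
        assert totals == sorted(totals, reverse=True)


class TestCombineSides:
    def _est(self, sample="a1", side="left", total=30, interval=5.0):
        return mq.CountEstimate(
            sample_id=sample, side=side, slice_indices=[0, 10],
            per_slice_counts=[total - 10, 10],
            params={"threshold": 100.0, "interval_um": interval,
                    "backend": "classical", "seg_params": "p"},
        )

    def test_sums_totals(self):
        assert mq.combine_sides(self._est(total=30), self._est(side="right", total=25)) == 55

    def test_parameter_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mq.combine_sides(self._est(), self._est(side="right", interval=2.5))

    def test_missing_side_named(self):
        with pytest.raises(ValueError, match="right"):
            mq.combine_sides(self._est(), None)

    def test_different_animals_rejected(self):
        with pytest.raises(ValueError, match="different animals"):
            mq.combine_sides(self._est("a1"), self._est("a2", side="right"))


class TestCompareGroups:
    def test_identical_groups_give_t0_p1(self):
        res = mq.compare_groups([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0

    def test_zero_variance_unequal_means_is_an_error(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            mq.compare_groups([0, 0, 0, 0], [1, 1, 1, 1])

    def test_zero_variance_equal_means_is_null(self):
        res = mq.compare_groups([2, 2], [2, 2])
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_scipy_oracle_on_fixed_vectors(self):
        res = mq.compare_groups([2, 4, 6], [5, 7, 9])
        oracle = pooled_t_oracle([2, 4, 6], [5, 7, 9])
        assert res.t == pytest.approx(oracle.statistic)
        assert res.p == pytest.approx(oracle.pvalue)
        assert res.df == 4

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_scipy_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(10, 3, int(rng.integers(2, 12)))
        b = rng.normal(12, 2, int(rng.integers(2, 12)))
        res = mq.compare_groups(a, b)
        oracle = pooled_t_oracle(a, b)
        assert res.t == pytest.approx(oracle.statistic)
        assert res.p == pytest.approx(oracle.pvalue)


class TestRobustnessSweep:
    def test_single_cell_grid_equals_plain_estimate(self, clean_stack):
        stack, _ = clean_stack
        other, _ = sd.generate_stack(
            sd.StackSimConfig(width_px=64, height_px=64, n_slices=20,
                              z_spacing_um=0.5, pixel_size_um=0.5, n_cells=5,
                              fraction_positive=0.4, background=0.0,
                              noise_sd=0.0, min_distance_um=7.0, seed=12,
                              sample_id="other"),
        )
        from planeye.io_formats import SweepSettings

        table = mq.robustness_sweep(
            {"a": [stack], "b": [other]},
            seg_params=SegParams(border_policy="keep", min_area_px=10),
            sweep=SweepSettings(threshold_multipliers=(1.0,), intervals_um=(5.0,)),
        )
        assert len(table.rows) == 1
        row = table.rows[0]
        base = mq.marker_threshold([stack])
        direct = mq.estimate_counts(
            stack, seg_params=SegParams(border_policy="keep", min_area_px=10),
            interval_um=5.0, threshold=base,
        )
        assert row["totals_a"] == [direct.total]

    def test_totals_non_increasing_in_multiplier(self, clean_stack):
        stack, _ = clean_stack
        from planeye.io_formats import SweepSettings

        table = mq.robustness_sweep(
            {"a": [stack], "b": [stack]},
            seg_params=SegParams(border_policy="keep", min_area_px=10),
            sweep=SweepSettings(threshold_multipliers=(0.9, 1.0, 1.1),
                                intervals_um=(5.0,)),
        )
        by_mult = {row["multiplier"]: row["totals_a"][0] for row in table.rows}
        assert by_mult[0.9] >= by_mult[1.0] >= by_mult[1.1]

    def test_grid_covers_configuration_exactly(self, clean_stack):
        stack, _ = clean_stack
        from planeye.io_formats import SweepSettings

        sweep_cfg = SweepSettings(threshold_multipliers=(0.9, 1.1),
                                  intervals_um=(2.5, 5.0))
        table = mq.robustness_sweep(
            {"a": [stack], "b": [stack]},
            seg_params=SegParams(border_policy="keep", min_area_px=10),
            sweep=sweep_cfg,
        )
        cells = {(r["multiplier"], r["interval_um"]) for r in table.rows}
        assert cells == {(0.9, 2.5), (0.9, 5.0), (1.1, 2.5), (1.1, 5.0)}
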