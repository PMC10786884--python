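"""Stratified sampling, accuracy statistics, unbiased area estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from bogmap import validation as val
from bogmap.reference import load_reference_confusion_matrix
from bogmap.synthetic import ClassMap

from conftest import PROPORTIONS, degrade_map


class TestAllocation:
    def test_equal_areas_split_equally(self):
        alloc = val.allocate_stratified_sample({1: 10.0, 2: 10.0, 3: 10.0}, 99, 0)
        assert list(alloc.counts) == [33, 33, 33]

    def test_floor_pins_small_stratum_then_splits_proportionally(self):
        alloc = val.allocate_stratified_sample({1: 80.0, 2: 15.0, 3: 5.0}, 100, 10)
        assert alloc.as_dict() == {1: 76, 2: 14, 3: 10}

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        areas=st.lists(st.floats(1, 1e6), min_size=2, max_size=7),
        total=st.integers(50, 2000),
    )
    def test_counts_always_sum_to_total(self, areas, total):
        mapped = {c + 1: a for c, a in enumerate(areas)}
        floor = min(5, total // len(areas))
        alloc = val.allocate_stratified_sample(mapped, total, floor)
        assert alloc.total == total
        assert (alloc.counts >= floor).all()

    def test_infeasible_floor_rejected(self):
        with pytest.raises(ValueError):
            val.allocate_stratified_sample({1: 1.0, 2: 1.0}, 10, 50)


class TestDrawPoints:
    @pytest.fixture(scope="class")
    @staticmethod
    def class_map(truth_map):
        return truth_map

    def test_one_point_per_class(self, class_map):
        alloc = val.SampleAllocation(list(range(1, 8)), [1] * 7, 1)
        points = val.draw_validation_points(class_map, alloc, seed=0)
        assert len(points) == 7
        assert sorted(code for _, code in points) == list(range(1, 8))

    def test_point_stratum_matches_map_class(self, class_map):
        alloc = val.SampleAllocation(list(range(1, 8)), [5] * 7, 5)
        for (r, c), code in val.draw_validation_points(class_map, alloc, seed=1):
            assert class_map.grid[r, c] == code

    def test_same_seed_identical_points(self, class_map):
        alloc = val.SampleAllocation(list(range(1, 8)), [5] * 7, 5)
        a = val.draw_validation_points(class_map, alloc, seed=2)
        b = val.draw_validation_points(class_map, alloc, seed=2)
        assert a == b

    def test_oversized_allocation_rejected(self, class_map):
        n_water = int((class_map.grid == 6).sum())
        alloc = val.SampleAllocation([6], [n_water + 1], 0)
        with pytest.raises(ValueError, match="water"):
            val.draw_validation_points(class_map, alloc, seed=0)


class TestConfusionMatrix:
    def test_identical_labels_give_diagonal_matrix(self):
        labels = [1, 1, 2, 3, 3, 3]
        cm = val.build_confusion_matrix(labels, labels)
        assert (cm.counts == np.diag([2, 1, 3])).all()

    def test_reference_matrix_totals(self):
        cm = load_reference_confusion_matrix()
        assert cm.row_totals.tolist() == [197, 130, 50, 252, 660, 121, 50]
        assert cm.col_totals.tolist() == [169, 108, 37, 281, 665, 147, 53]
        assert cm.n == 1460

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            val.build_confusion_matrix([], [])

    def test_unknown_class_code_rejected(self):
        with pytest.raises(ValueError):
            val.build_confusion_matrix([1, 99], [1, 1])


class TestAccuracyReport:
    def test_reference_matrix_statistics(self):
        cm = load_reference_confusion_matrix()
        rep = val.accuracy_report(cm)
        assert rep.oa == pytest.approx(100 * 1303 / 1460)
        disp = rep.display()
        assert disp["oa"] == 89
        assert disp["ua"]["cutover"] == 70
        assert disp["pa"]["cutaway"] == 97

    def test_truncation_not_rounding_for_display(self):
        cm = load_reference_confusion_matrix()
        disp = val.accuracy_report(cm).display()
        # 244/252 = 96.8 -> 96 and 244/281 = 86.8 -> 86 under truncation
        assert disp["ua"]["forestry"] == 96
        assert disp["pa"]["forestry"] == 86

    def test_zero_column_total_is_undefined_not_zero(self):
        cm = val.ConfusionMatrix(np.array([[2, 1], [0, 0]]), [1, 2])
        rep = val.accuracy_report(cm)
        assert np.isnan(rep.ua[1])
        assert rep.display()["ua"]["cutover"] is None


def two_class_worked_case():
    """2-stratum example: W = (0.8, 0.2), rows (45,5)/50 and (10,40)/50."""
    return val.ConfusionMatrix(
        np.array([[45, 5], [10, 40]]), [1, 2], np.array([800.0, 200.0])
    )


class TestAreaEstimators:
    def test_diagonal_matrix_gives_weights_on_diagonal(self):
        cm = val.ConfusionMatrix(
            np.diag([30, 20]), [1, 2], np.array([600.0, 400.0])
        )
        p = val.area_error_matrix(cm)
        np.testing.assert_allclose(p, np.diag([0.6, 0.4]))

    def test_worked_two_class_proportions(self):
        p = val.area_error_matrix(two_class_worked_case())
        np.testing.assert_allclose(p, [[0.72, 0.08], [0.04, 0.16]])
        assert p.sum() == pytest.approx(1.0)

    def test_diagonal_matrix_recovers_mapped_areas_with_zero_se(self):
        cm = val.ConfusionMatrix(
            np.diag([30, 20]), [1, 2], np.array([600.0, 400.0])
        )
        est = val.unbiased_area_estimates(cm)
        np.testing.assert_allclose(est.areas_ha, [600.0, 400.0])
        np.testing.assert_allclose(est.se_ha, [0.0, 0.0])

    def test_worked_two_class_area_and_se(self):
        est = val.unbiased_area_estimates(two_class_worked_case())
        assert est.areas_ha[0] == pytest.approx(760.0)
        expected_se = np.sqrt((0.64 * 0.09 + 0.04 * 0.16) / 49)
        assert est.se_proportions[0] == pytest.approx(expected_se)
        assert est.se_ha[0] == pytest.approx(1000 * expected_se)
        assert est.ci_low_ha[0] < est.areas_ha[0] < est.ci_high_ha[0]

    def test_proportions_sum_to_one(self):
        est = val.unbiased_area_estimates(two_class_worked_case())
        assert est.proportions.sum() == pytest.approx(1.0)
        assert est.stratum_weights.sum() == pytest.approx(1.0)

    def test_small_stratum_se_undefined(self):
        cm = val.ConfusionMatrix(
            np.array([[1, 0], [5, 45]]), [1, 2], np.array([100.0, 900.0])
        )
        with pytest.raises(ValueError, match="stratum size < 2"):
            val.unbiased_area_estimates(cm)

    def test_missing_areas_rejected(self):
        cm = val.ConfusionMatrix(np.diag([5, 5]), [1, 2])
        with pytest.raises(ValueError, match="mapped areas"):
            val.area_error_matrix(cm)

    def test_count_and_area_oa_differ_under_unequal_sampling(self):
        """Oversampling an accurate small stratum inflates count OA only."""
        cm = val.ConfusionMatrix(
            np.array([[80, 20], [0, 100]]), [1, 2], np.array([900.0, 100.0])
        )
        count_oa = val.accuracy_report(cm).oa
        area_oa = val.area_based_overall_accuracy(cm)
        assert count_oa == pytest.approx(90.0)
        assert area_oa == pytest.approx(100 * (0.9 * 0.8 + 0.1 * 1.0))
        assert count_oa != area_oa


class TestZonalTabulation:
    def test_whole_map_region_equals_global_areas(self, truth_map):
        h, w = truth_map.shape
        table = val.zonal_tabulate(truth_map, [("all", box(0, 0, w, h))])
        global_areas = truth_map.class_areas_ha()
        for code, area in global_areas.items():
            name = val.class_name(code)
            assert table.loc["all", name] == pytest.approx(area)
        assert table.loc["all", "total"] == pytest.approx(
            h * w * truth_map.pixel_size_ha
        )

    def test_two_region_split_matches_hand_count(self, truth_map):
        h, w = truth_map.shape
        half = w // 2
        table = val.zonal_tabulate(
            truth_map,
            [("west", box(0, 0, half, h)), ("east", box(half, 0, w, h))],
        )
        left = truth_map.grid[:, :half]
        for code in range(1, 8):
            want = (left == code).sum() * truth_map.pixel_size_ha
            assert table.loc["west", val.class_name(code)] == pytest.approx(want)
        # disjoint regions partition the map: rows sum to the global areas
        totals = table.drop(columns="total").sum()
        for code, area in truth_map.class_areas_ha().items():
            assert totals[val.class_name(code)] == pytest.approx(area)

    def test_empty_region_warns_and_returns_zero_row(self, truth_map):
        with pytest.warns(UserWarning, match="nowhere"):
            table = val.zonal_tabulate(
                truth_map, [("nowhere", box(-50, -50, -10, -10))]
            )
        assert table.loc["nowhere", "total"] == 0


class TestMonteCarloCalibration:
    """The stratified estimator is unbiased and its 95% CIs are calibrated.

    Fixed truth map, fixed imperfect map (10% of pixels flipped), 500
    independently seeded stratified samples.
    """

    @pytest.fixture(scope="class")
    @staticmethod
    def mc_results():
        import bogmap.synthetic as syn

        truth = syn.generate_class_map(200, 200, PROPORTIONS, patch_scale=15, seed=0)
        pred = degrade_map(truth, 0.10, seed=1)
        mapped = pred.class_areas_ha()
        alloc = val.allocate_stratified_sample(mapped, 700, 50)
        codes = sorted(mapped)
        true_areas = np.array([truth.class_areas_ha()[c] for c in codes])
        estimates, covered = [], np.zeros(len(codes))
        for rep in range(500):
            pts = val.draw_validation_points(pred, alloc, seed=100 + rep)
            ref = val.simulate_reference_labels(truth, pts, 0.0, seed=0)
            cm = val.build_confusion_matrix(
                [c for _, c in pts], ref, mapped, codes
            )
            est = val.unbiased_area_estimates(cm)
            estimates.append(est.areas_ha)
            covered += (est.ci_low_ha <= true_areas) & (true_areas <= est.ci_high_ha)
        return np.array(estimates), covered / 500, true_areas

    def test_estimator_is_unbiased_within_monte_carlo_error(self, mc_results):
        estimates, _, true_areas = mc_results
        mc_se = estimates.std(axis=0, ddof=1) / np.sqrt(len(estimates))
        assert (np.abs(estimates.mean(axis=0) - true_areas) <= 2 * mc_se).all()

    def test_ci_coverage_near_nominal(self, mc_results):
        _, coverage, _ = mc_results
        assert ((coverage >= 0.90) & (coverage <= 0.99)).all()
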