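"""Grid overlay, prediction sampling, confusion-matrix metrics and RMSE."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hydromorph.classes import CATEGORY_OF, PRED_CATEGORIES, TRUTH_ORDER, FeatureClass
from hydromorph.examples import example_survey_confusion
from hydromorph.geo import GeoTransform
from hydromorph.imagery_io import ControlPointPair
from hydromorph.rasters import ClassifiedMap
from hydromorph.validation import (ConfusionMatrix, OutOfExtentError, confusion,
                                   coregistration_rmse, metrics, overlay_grid,
                                   sample_predictions)


class TestOverlayGrid:
    def test_lattice_count_inclusive_edges(self):
        pts = overlay_grid((0.0, 0.0, 10.0, 10.0), spacing=2.0)
        assert len(pts) == 36

    def test_spacing_larger_than_extent_keeps_anchor(self):
        pts = overlay_grid((5.0, 5.0, 6.0, 6.0), spacing=10.0)
        assert len(pts) == 1
        np.testing.assert_allclose(pts[0], (5.0, 5.0))

    def test_circular_boundary_matches_per_point_test(self):
        t = GeoTransform(0.0, 20.0, 1.0)
        rows, cols = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        xs, ys = t.world_of(rows, cols)
        mask = (xs - 10.0) ** 2 + (ys - 10.0) ** 2 <= 36.0
        pts = overlay_grid((0.0, 0.0, 20.0, 20.0), spacing=1.0, boundary=(mask, t))
        # oracle: test each lattice point independently
        count = 0
        for x in np.arange(0.0, 20.0 + 1e-9, 1.0):
            for y in np.arange(0.0, 20.0 + 1e-9, 1.0):
                r, c = t.pixel_of(x, y)
                r, c = min(max(int(r), 0), 19), min(max(int(c), 0), 19)
                if mask[r, c]:
                    count += 1
        assert len(pts) == count

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            overlay_grid((0, 0, 1, 1), spacing=0.0)


class TestSamplePredictions:
    def _map(self):
        labels = np.array([[int(FeatureClass.RIFFLE), int(FeatureClass.GRASS)],
                           [int(FeatureClass.TREE), 0]], dtype=np.int32)
        return ClassifiedMap(labels=labels, transform=GeoTransform(0.0, 2.0, 1.0),
                             valid_mask=labels != 0)

    def test_pixel_centre_returns_that_category(self):
        cmap = self._map()
        assert sample_predictions(cmap, np.array([[0.5, 1.5]])) == ["RI"]
        assert sample_predictions(cmap, np.array([[1.5, 1.5]])) == ["VG"]  # grass->VG
        assert sample_predictions(cmap, np.array([[0.5, 0.5]])) == ["TE"]

    def test_boundary_point_rounds_half_down(self):
        cmap = self._map()
        # x=1.0 is the seam between columns 0 and 1 -> column 0
        assert sample_predictions(cmap, np.array([[1.0, 1.5]])) == ["RI"]

    def test_vegetation_relabel_invisible_after_merge(self):
        cmap = self._map()
        relabelled = ClassifiedMap(
            labels=np.where(cmap.labels == int(FeatureClass.GRASS),
                            int(FeatureClass.VEGETATED_BANK), cmap.labels),
            transform=cmap.transform, valid_mask=cmap.valid_mask)
        pts = np.array([[1.5, 1.5]])
        assert sample_predictions(cmap, pts) == sample_predictions(relabelled, pts)

    def test_out_of_extent_reported_with_indices(self):
        cmap = self._map()
        with pytest.raises(OutOfExtentError) as err:
            sample_predictions(cmap, np.array([[0.5, 1.5], [99.0, 99.0]]))
        assert err.value.indices == [1]

    def test_ge_mask_overrides_category(self):
        cmap = self._map()
        ge = np.zeros((2, 2), dtype=bool)
        ge[0, 0] = True
        assert sample_predictions(cmap, np.array([[0.5, 1.5]]), ge_mask=ge) == ["GE"]


def _brute_force_metrics(truth, pred):
    """Per-point tally oracle: independent of the matrix implementation."""
    n = len(truth)
    out = {}
    for cls in TRUTH_ORDER:
        own = CATEGORY_OF[cls]
        tp = sum(1 for t, p in zip(truth, pred)
                 if t == cls and (p == own or (cls == FeatureClass.TREE and p == "VG")))
        tp_own = sum(1 for t, p in zip(truth, pred) if t == cls and p == own)
        fn = sum(1 for t in truth if t == cls) - tp
        fp = sum(1 for t, p in zip(truth, pred) if p == own) - tp_own
        tn = n - tp - fn - fp
        out[cls] = (tp, fn, fp, tn)
    return out


class TestConfusionAndMetrics:
    def test_perfect_agreement_is_diagonal(self):
        truth = [FeatureClass.RIFFLE] * 6 + [FeatureClass.GRASS] * 4
        pred = ["RI"] * 6 + ["VG"] * 4
        cm = confusion(truth, pred)
        rep = metrics(cm)
        assert rep.ac == 1.0
        assert rep.per_class[FeatureClass.RIFFLE].tpr == 1.0

    def test_empty_inputs_all_zero_matrix(self):
        cm = confusion([], [])
        assert cm.grand_total == 0
        assert (cm.counts == 0).all()

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([FeatureClass.RIFFLE], [])

    def test_survey_matrix_row_and_grand_totals(self):
        cm = example_survey_confusion()
        expected_rows = [1334, 287, 3339, 2082, 2573, 1755, 299, 313, 468, 71, 344, 220]
        np.testing.assert_array_equal(cm.row_totals(), expected_rows)
        assert cm.grand_total == 13085

    def test_metrics_match_brute_force_tally_on_random_lists(self, rng):
        classes = list(TRUTH_ORDER)
        cats = list(PRED_CATEGORIES)
        for trial in range(5):
            truth = [classes[i] for i in rng.integers(0, len(classes), 200)]
            pred = [cats[i] for i in rng.integers(0, len(cats), 200)]
            rep = metrics(confusion(truth, pred))
            oracle = _brute_force_metrics(truth, pred)
            for cls, (tp, fn, fp, tn) in oracle.items():
                m = rep.per_class[cls]
                assert (m.tp, m.fn, m.fp, m.tn) == (tp, fn, fp, tn)

    @given(st.lists(st.tuples(st.sampled_from(list(TRUTH_ORDER)),
                              st.sampled_from(list(PRED_CATEGORIES))),
                    min_size=1, max_size=120))
    def test_ratio_complements_sum_to_one(self, pairs):
        truth = [t for t, _ in pairs]
        pred = [p for _, p in pairs]
        rep = metrics(confusion(truth, pred))
        for m in rep.per_class.values():
            if m.tpr is not None:
                assert m.tpr + m.fnr == pytest.approx(1.0)
            if m.tnr is not None:
                assert m.tnr + m.fpr == pytest.approx(1.0)

    def test_absent_class_ratios_undefined_not_zero(self):
        rep = metrics(confusion([FeatureClass.RIFFLE], ["RI"]))
        m = rep.per_class[FeatureClass.GRASS]
        assert m.tpr is None and m.fnr is None
        assert m.tnr is not None  # negatives exist for an absent class

    def test_tree_canopy_vegetation_convention_switchable(self):
        cm = example_survey_confusion()
        with_vg = metrics(cm, tree_vg_as_tp=True)
        without = metrics(cm, tree_vg_as_tp=False)
        assert with_vg.per_class[FeatureClass.TREE].tpr == pytest.approx(
            (496 + 1013) / 1755)
        assert without.per_class[FeatureClass.TREE].tpr == pytest.approx(496 / 1755)


class TestCoregistrationRmse:
    def _pairs(self, offsets, role="GCP"):
        return [ControlPointPair(f"P{i}", role, 0.0, 0.0, dx, dy)
                for i, (dx, dy) in enumerate(offsets)]

    def test_identical_pairs_zero(self):
        rep = coregistration_rmse(self._pairs([(0.0, 0.0)] * 5))
        assert rep.rmse == 0.0

    def test_two_pairs_mixed_axes(self):
        rep = coregistration_rmse(self._pairs([(0.01, 0.0), (0.0, 0.01)]))
        assert rep.rmse == pytest.approx(0.01)

    def test_three_four_five_triangle(self):
        rep = coregistration_rmse(self._pairs([(0.03, 0.04)] * 7))
        assert rep.rmse == pytest.approx(0.05)
        assert rep.mae_x == pytest.approx(0.03)
        assert rep.mae_y == pytest.approx(0.04)

    def test_role_filter_and_empty_error(self):
        pairs = self._pairs([(0.1, 0.0)], role="GCP")
        assert coregistration_rmse(pairs, "GCP").n == 1
        with pytest.raises(ValueError, match="no control points"):
            coregistration_rmse(pairs, "XP")

    @given(st.floats(-100, 100), st.floats(-100, 100))
    def test_translation_invariance(self, tx, ty):
        base = [(0.02, -0.01), (-0.03, 0.04), (0.0, 0.05)]
        p1 = [ControlPointPair(f"{i}", "GCP", 0.0, 0.0, dx, dy)
              for i, (dx, dy) in enumerate(base)]
        p2 = [ControlPointPair(f"{i}", "GCP", tx, ty, tx + dx, ty + dy)
              for i, (dx, dy) in enumerate(base)]
        assert coregistration_rmse(p1).rmse == pytest.approx(
            coregistration_rmse(p2).rmse, rel=1e-9, abs=1e-12)

    def test_uniform_scaling_of_offsets(self):
        base = [(0.02, -0.01), (-0.03, 0.04)]
        r1 = coregistration_rmse(self._pairs(base)).rmse
        r3 = coregistration_rmse(self._pairs([(3 * a, 3 * b) for a, b in base])).rmse
        assert r3 == pytest.approx(3 * r1)
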