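import numpy as np
import pytest

import _oracles as oracle
from wormalign import annotation as an


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(23)


@pytest.fixture()
def catalog():
    return an.LabelCatalog.generic(
        6, counts={"N001": 130, "N002": 65, "N003": 260, "N004": 130, "N005": 130}
    )


def _two_roi_volume():
    rois = np.zeros((6, 6, 6), dtype=int)
    rois[1:4, 1:4, 1:4] = 1
    rois[4:6, 4:6, 4:6] = 2
    return rois


class TestBuildWeightVolume:
    def test_background_weight_is_one(self, catalog):
        rois = _two_roi_volume()
        w = an.build_weight_volume({1: ("N001", 5), 2: ("N002", 2)}, rois, catalog)
        assert w[0, 0, 0] == 1.0

    def test_confidence_and_rarity_weighting(self, catalog):
        rois = _two_roi_volume()
        w = an.build_weight_volume({1: ("N001", 5), 2: ("N002", 2)}, rois, catalog)
        assert w[2, 2, 2] == pytest.approx(1000.0)  # (130/130) * f(5)
        assert w[5, 5, 5] == pytest.approx(100.0)  # (130/65) * f(2)

    def test_unlabeled_roi_gets_near_zero_weight(self, catalog):
        rois = _two_roi_volume()
        w = an.build_weight_volume({1: ("N001", 3)}, rois, catalog)
        assert w[5, 5, 5] == pytest.approx(an.UNLABELED_WEIGHT)

    def test_homogeneity_in_corpus_counts(self, catalog):
        rois = _two_roi_volume()
        doubled = an.LabelCatalog.generic(
            6, counts={k: 2 * v for k, v in catalog.counts.items()}
        )
        w1 = an.build_weight_volume({1: ("N001", 4)}, rois, catalog)
        w2 = an.build_weight_volume({1: ("N001", 4)}, rois, doubled)
        assert np.allclose(w2[rois == 1], w1[rois == 1] / 2.0)

    def test_invalid_confidence_rejected(self, catalog):
        with pytest.raises(ValueError):
            an.build_weight_volume({1: ("N001", 1)}, _two_roi_volume(), catalog)

    def test_missing_corpus_count_rejected(self, catalog):
        with pytest.raises(ValueError):
            an.build_weight_volume({1: ("N999", 5)}, _two_roi_volume(), catalog)


class TestWeightedCrossEntropy:
    def test_confident_correct_prediction_near_zero(self, catalog):
        rois = _two_roi_volume()
        target = an.one_hot_labels({1: "N001", 2: "N002"}, rois, catalog)
        logits = 50.0 * target
        w = np.ones(rois.shape)
        assert an.weighted_cross_entropy(logits, target, w) < 1e-6

    def test_uniform_logits_closed_form(self, catalog):
        rois = _two_roi_volume()
        target = an.one_hot_labels({1: "N001"}, rois, catalog)
        w = np.ones(rois.shape)
        k = catalog.k
        val = an.weighted_cross_entropy(np.zeros((k,) + rois.shape), target, w)
        assert val == pytest.approx(np.log(k) / k)

    def test_matches_loop_oracle(self, rng):
        k, dims = 4, (5, 4, 3)
        logits = rng.normal(size=(k,) + dims)
        labels = rng.integers(0, k, size=dims)
        target = np.zeros((k,) + dims)
        np.put_along_axis(target, labels[None], 1.0, axis=0)
        weights = rng.uniform(0.1, 5.0, size=dims)
        assert an.weighted_cross_entropy(logits, target, weights) == pytest.approx(
            oracle.weighted_cross_entropy_loops(logits, target, weights), abs=1e-6
        )

    def test_loss_decreases_toward_true_label(self, rng):
        k, dims = 5, (4, 4, 2)
        labels = rng.integers(0, k, size=dims)
        target = np.zeros((k,) + dims)
        np.put_along_axis(target, labels[None], 1.0, axis=0)
        weights = rng.uniform(0.5, 2.0, size=dims)
        noise = rng.normal(size=(k,) + dims)
        vals = [
            an.weighted_cross_entropy(noise + alpha * target, target, weights)
            for alpha in (0.0, 1.0, 2.0, 4.0)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestWeightedMeanIou:
    def test_perfect_prediction_scores_one(self, rng):
        k, dims = 3, (4, 4, 4)
        labels = rng.integers(0, k, size=dims)
        target = np.zeros((k,) + dims)
        np.put_along_axis(target, labels[None], 1.0, axis=0)
        assert an.weighted_mean_iou(target, target, np.ones(dims)) == 1.0

    def test_half_overlap_channel(self):
        # 4 voxels, one foreground channel: prediction covers the true voxel
        # plus one false voxel -> intersection 1, union 2
        k, dims = 2, (4, 1, 1)
        target = np.zeros((k,) + dims)
        target[1, 0] = 1.0
        target[0, 1:] = 1.0
        pred = np.zeros((k,) + dims)
        pred[1, :2] = 1.0
        pred[0, 2:] = 1.0
        w = np.ones(dims)
        iou_fg = 1.0 / 2.0
        iou_bg = 2.0 / 3.0
        assert an.weighted_mean_iou(pred, target, w) == pytest.approx(
            (iou_fg + iou_bg) / 2
        )

    def test_matches_loop_oracle(self, rng):
        k, dims = 4, (4, 3, 3)
        p = rng.random((k,) + dims)
        labels = rng.integers(0, k, size=dims)
        target = np.zeros((k,) + dims)
        np.put_along_axis(target, labels[None], 1.0, axis=0)
        weights = rng.uniform(0.1, 3.0, size=dims)
        assert an.weighted_mean_iou(p, target, weights) == pytest.approx(
            oracle.weighted_mean_iou_loops(p, target, weights), abs=1e-6
        )

    def test_disjoint_channels_score_zero(self):
        k, dims = 2, (2, 1, 1)
        target = np.zeros((k,) + dims)
        target[1, 0] = 1.0
        target[0, 1] = 1.0
        pred = np.zeros((k,) + dims)
        pred[0, 0] = 1.0
        pred[1, 1] = 1.0
        assert an.weighted_mean_iou(pred, target, np.ones(dims)) == 0.0


class TestExtractRoiLabels:
    def test_one_hot_map_gives_one_hot_row(self):
        rois = np.zeros((4, 4, 4), int)
        rois[1:3, 1:3, 1:3] = 7
        p = np.zeros((3, 4, 4, 4))
        p[2] = 1.0
        pred = an.extract_roi_labels(p, rois)
        assert pred.roi_indices.tolist() == [7]
        assert pred.label_index(0) == 2
        assert pred.confidence(0) == pytest.approx(1.0)

    def test_rows_sum_to_one(self, rng):
        rois = _two_roi_volume()
        logits = rng.normal(size=(5, 6, 6, 6))
        p = an.softmax_probabilities(logits)
        pred = an.extract_roi_labels(p, rois)
        assert np.allclose(pred.d.sum(axis=1), 1.0, atol=1e-9)

    def test_interior_outweighs_boundary(self):
        # 3-voxel line ROI: the end voxels touch background, the middle one
        # is interior (weight 1 vs 0.01) and decides the label
        rois = np.zeros((5, 1, 1), int)
        rois[1:4, 0, 0] = 1
        p = np.zeros((3, 5, 1, 1))
        p[1] = 1.0
        p[:, 2, 0, 0] = [0.0, 0.0, 1.0]
        pred = an.extract_roi_labels(p, rois)
        assert pred.label_index(0) == 2

    def test_invariant_to_roi_relabeling(self, rng):
        rois = _two_roi_volume()
        p = an.softmax_probabilities(rng.normal(size=(4, 6, 6, 6)))
        a = an.extract_roi_labels(p, rois)
        relabeled = np.where(rois == 1, 40, rois)
        relabeled = np.where(relabeled == 2, 9, relabeled)
        b = an.extract_roi_labels(p, relabeled)
        assert np.allclose(np.sort(a.d, axis=0), np.sort(b.d, axis=0))


class TestPostprocessLabels:
    def _pred(self, rows, indices):
        return an.PredictionMatrix(np.asarray(rows, dtype=float), np.asarray(indices))

    def test_oversegmented_duplicates_share_label(self, catalog):
        rois = np.zeros((8, 4, 4), int)
        rois[1, 1, 1] = 1
        rois[2, 1, 1] = 2
        rows = np.zeros((2, catalog.k))
        rows[0, 1] = 0.95
        rows[0, 0] = 0.05
        rows[1, 1] = 0.90
        rows[1, 0] = 0.10
        out = an.postprocess_labels(self._pred(rows, [1, 2]), rois, catalog)
        assert out[1][0] == "N001" and out[2][0] == "N001"

    def test_distant_duplicate_loses_lower_confidence_label(self, catalog):
        rois = np.zeros((40, 4, 4), int)
        rois[1, 1, 1] = 1
        rois[35, 1, 1] = 2
        rows = np.zeros((2, catalog.k))
        rows[0, 1] = 0.95
        rows[1, 1] = 0.90
        out = an.postprocess_labels(self._pred(rows, [1, 2]), rois, catalog)
        assert 1 in out and 2 not in out

    def test_deleted_classes_removed(self):
        catalog = an.LabelCatalog(["background", "granule", "RIM"], {})
        rois = np.zeros((6, 4, 4), int)
        rois[1, 1, 1] = 1
        rows = np.zeros((1, 3))
        rows[0, 1] = 0.99
        out = an.postprocess_labels(self._pred(rows, [1]), rois, catalog)
        assert out == {}

    def test_confidence_floor(self, catalog):
        rois = np.zeros((6, 4, 4), int)
        rois[1, 1, 1] = 1
        rows = np.zeros((1, catalog.k))
        rows[0, 1] = 0.6
        rows[0, 2] = 0.4
        out = an.postprocess_labels(self._pred(rows, [1]), rois, catalog)
        assert out == {}

    def test_lr_ambiguity_emits_class_label(self):
        catalog = an.LabelCatalog(["background", "AVAL", "AVAR"], {})
        rois = np.zeros((6, 4, 4), int)
        rois[1, 1, 1] = 1
        rows = np.array([[0.0, 0.55, 0.45]])
        out = an.postprocess_labels(self._pred(rows, [1]), rois, catalog)
        assert out[1][0] == "AVA"
        assert out[1][1] == pytest.approx(1.0)

    def test_undersegmentation_deletes_label(self, catalog):
        rois = np.zeros((8, 4, 4), int)
        rois[1:4, 1:3, 1:3] = 1  # 12 voxels
        p = np.zeros((catalog.k, 8, 4, 4))
        p[1] = 0.9
        # a strong foreign class on >= 20% of the ROI's voxels
        p[2, 3, 1:3, 1:3] = 0.9
        p[1, 3, 1:3, 1:3] = 0.05
        rows = np.zeros((1, catalog.k))
        rows[0, 1] = 0.85
        out = an.postprocess_labels(
            self._pred(rows, [1]), rois, catalog, probabilities=p
        )
        assert out == {}

    def test_background_argmax_leaves_roi_unlabeled(self, catalog):
        rois = np.zeros((6, 4, 4), int)
        rois[1, 1, 1] = 1
        rows = np.zeros((1, catalog.k))
        rows[0, 0] = 0.99
        out = an.postprocess_labels(self._pred(rows, [1]), rois, catalog)
        assert out == {}
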