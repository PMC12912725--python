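import itertools
from collections import Counter

import numpy as np
import pytest

from wormalign import synthetic, tracking


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(17)


class TestSimilarityEntry:
    def test_unregistered_pair_scores_zero(self):
        f = tracking.RoiPairFeatures(registered=False)
        assert tracking.similarity_entry(f) == 0.0

    def test_perfect_features_score_one(self):
        f = tracking.RoiPairFeatures()
        assert tracking.similarity_entry(f) == pytest.approx(1.0)

    def test_printed_formula_hand_value(self):
        f = tracking.RoiPairFeatures(
            displacement=0.5, quality=0.9, overlap=0.8,
            brightness=0.1, centroid_distance=1.0, nonrigid=0.02,
        )
        expected = 0.5 * 0.9**25 * 0.8 * np.exp(-(3 * 0.1 + 1 * 1.0 + 1 * 0.02))
        assert tracking.similarity_entry(f) == pytest.approx(expected)

    def test_negative_quality_clamped_to_zero(self):
        f = tracking.RoiPairFeatures(quality=-0.3)
        assert tracking.similarity_entry(f) == 0.0

    @pytest.mark.parametrize(
        "field,increasing",
        [
            ("displacement", False),
            ("quality", True),
            ("overlap", True),
            ("brightness", False),
            ("centroid_distance", False),
            ("nonrigid", False),
        ],
    )
    def test_monotonicity(self, field, increasing):
        values = np.linspace(0.05, 0.95, 7)
        scores = []
        for v in values:
            f = tracking.RoiPairFeatures(
                displacement=0.2, quality=0.9, overlap=0.8,
                brightness=0.1, centroid_distance=0.5, nonrigid=0.05,
            )
            setattr(f, field, float(v))
            scores.append(tracking.similarity_entry(f))
        diffs = np.diff(scores)
        assert np.all(diffs > 0) if increasing else np.all(diffs < 0)


class TestColor:
    def test_equal_channels_unit_vector(self):
        vol = np.ones((4, 4, 2, 4))
        mask = np.zeros((4, 4, 2), bool)
        mask[1, 1, 1] = True
        assert np.allclose(tracking.color_vector(mask, vol), 1.0)

    def test_hand_computed_vector_and_distance(self):
        vol = np.zeros((2, 1, 1, 4))
        vol[0, 0, 0] = [2, 2, 4, 8]
        mask = np.zeros((2, 1, 1), bool)
        mask[0, 0, 0] = True
        vec = tracking.color_vector(mask, vol)
        assert np.allclose(vec, [0.5, 0.5, 1.0, 2.0])
        assert tracking.color_distance(np.ones(4), vec) == pytest.approx(2.0)
        assert tracking.color_distance(vec, np.ones(4)) == pytest.approx(2.0)

    def test_brightness_scale_invariance(self):
        vol = np.zeros((2, 1, 1, 4))
        vol[0, 0, 0] = [1, 2, 3, 4]
        mask = np.zeros((2, 1, 1), bool)
        mask[0, 0, 0] = True
        a = tracking.color_vector(mask, vol)
        b = tracking.color_vector(mask, vol * 10.0)
        assert np.allclose(a, b)


class TestClustering:
    def _block_matrix(self):
        # two perfect 3-ROI blocks across 3 timepoints
        roi_ids = [(t, k) for t in range(3) for k in (1, 2)]
        n = len(roi_ids)
        mat = np.zeros((n, n))
        for i, (ti, ki) in enumerate(roi_ids):
            for j, (tj, kj) in enumerate(roi_ids):
                if ki == kj and ti != tj:
                    mat[i, j] = 0.9
        from scipy import sparse

        return tracking.SimilarityMatrix(sparse.csr_matrix(mat), roi_ids)

    def test_two_perfect_blocks_give_two_clusters(self):
        sim = self._block_matrix()
        assignment = tracking.cluster_rois(sim, w7=1e-4, w8=0.05)
        assert len(assignment.clusters) == 2
        for members in assignment.clusters:
            ks = {k for _, k in members}
            assert len(ks) == 1 and len(members) == 3

    def test_floor_above_entries_yields_singletons(self):
        sim = self._block_matrix()
        assignment = tracking.cluster_rois(sim, w7=0.95, w8=0.05)
        assert len(assignment.clusters) == 6

    def test_collision_cap_blocks_same_timepoint_merges(self):
        from scipy import sparse

        roi_ids = [(0, 1), (0, 2)]
        mat = np.array([[0, 0.9], [0.9, 0]])
        sim = tracking.SimilarityMatrix(sparse.csr_matrix(mat), roi_ids)
        assignment = tracking.cluster_rois(sim, w7=1e-4, w8=0.0)
        assert len(assignment.clusters) == 2

    def test_cluster_count_nonincreasing_in_floor(self, rng):
        from scipy import sparse

        n = 12
        mat = rng.random((n, n)) * 0.5
        mat = np.triu(mat, 1)
        mat = mat + mat.T
        roi_ids = [(t, k) for t in range(4) for k in range(3)]
        counts = []
        for w7 in (0.45, 0.3, 0.15, 0.05, 0.01):
            sim = tracking.SimilarityMatrix(sparse.csr_matrix(mat), list(roi_ids))
            counts.append(len(tracking.cluster_rois(sim, w7=w7, w8=1.0).clusters))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


@pytest.fixture(scope="module")
def tracked():
    ph = synthetic.make_phantom(
        synthetic.PhantomSpec(dims=(64, 32, 16), n_cells=20, seed=3)
    )
    series = synthetic.make_timeseries(ph, n_frames=6, seed=3)
    rois = {t: f.rois for t, f in enumerate(series.frames)}
    reds = {t: f.red for t, f in enumerate(series.frames)}
    greens = {t: f.green for t, f in enumerate(series.frames)}
    regs = [
        tracking.Registration(moving=i, fixed=j, ddf=series.true_ddf(j, i))
        for i, j in itertools.combinations(range(6), 2)
    ]
    sim = tracking.build_similarity_matrix(regs, rois, reds)
    assignment = tracking.cluster_rois(sim, 1e-4, 0.05)
    return series, rois, reds, greens, sim, assignment


class TestPipeline:
    def test_matrix_is_symmetric(self, tracked):
        sim = tracked[4]
        assert (sim.matrix != sim.matrix.T).nnz == 0

    def test_identity_links_recovered(self, tracked):
        _, _, _, _, _, assignment = tracked
        correct = total = 0
        for members in assignment.clusters:
            ids = [k for _, k in members]
            correct += Counter(ids).most_common(1)[0][1]
            total += len(ids)
        assert correct / total > 0.99

    def test_traces_flat_for_constant_ratio_cells(self, tracked):
        series, rois, reds, greens, _, assignment = tracked
        traces = tracking.extract_traces(assignment, greens, reds, rois)
        # each cluster's trace should stay near its planted green/red ratio
        spread = traces.max() - traces.min()
        assert float(spread.max()) < 0.5

    def test_planted_activity_step_recovered(self):
        ph = synthetic.make_phantom(
            synthetic.PhantomSpec(dims=(64, 32, 16), n_cells=15, seed=4)
        )
        series = synthetic.make_timeseries(
            ph, n_frames=8, n_activity_steps=2, seed=4
        )
        rois = {t: f.rois for t, f in enumerate(series.frames)}
        greens = {t: f.green for t, f in enumerate(series.frames)}
        reds = {t: f.red for t, f in enumerate(series.frames)}
        clusters = [[(t, k + 1) for t in range(8)] for k in range(15)]
        traces = tracking.extract_traces(
            tracking.ClusterAssignment(clusters), greens, reds, rois
        )
        for step in series.steps:
            trace = traces[step.cell].to_numpy()
            before = trace[: step.t_start].mean()
            after = trace[step.t_start :].mean()
            # the green ratio doubles at the planted frame
            assert after / before == pytest.approx(2.0, rel=0.15)
            jumps = np.abs(np.diff(trace))
            assert int(np.argmax(jumps)) == step.t_start - 1

    def test_absent_cluster_yields_gap_not_zero(self):
        rois = {0: np.zeros((4, 4, 2), int), 1: np.zeros((4, 4, 2), int)}
        rois[0][1, 1, 0] = 1
        green = {t: np.full((4, 4, 2), 4.0) for t in (0, 1)}
        red = {t: np.full((4, 4, 2), 2.0) for t in (0, 1)}
        assignment = tracking.ClusterAssignment([[(0, 1)]])
        traces = tracking.extract_traces(assignment, green, red, rois)
        assert traces.loc[0, 0] == pytest.approx(2.0)
        assert np.isnan(traces.loc[1, 0])

    def test_unregistered_pairs_contribute_nothing(self):
        rois = {0: np.zeros((6, 6, 2), int), 1: np.zeros((6, 6, 2), int)}
        rois[0][1:3, 1:3, :] = 1
        rois[1][1:3, 1:3, :] = 1
        vols = {t: (rois[t] > 0).astype(float) + 0.1 * np.random.default_rng(t).random((6, 6, 2)) for t in (0, 1)}
        sim = tracking.build_similarity_matrix([], rois, vols)
        assert sim.matrix.nnz == 0


class TestClusterLabelAccuracy:
    def test_hand_example(self):
        assignment = tracking.ClusterAssignment(
            [[(0, 1), (1, 1), (2, 1)], [(0, 2), (1, 2), (2, 2)]]
        )
        labels = {
            (0, 1): "A", (1, 1): "A", (2, 1): "A",
            (0, 2): "B", (1, 2): "B", (2, 2): "C",
        }
        assert tracking.cluster_label_accuracy(assignment, labels) == pytest.approx(5 / 6)

    def test_pure_clusters_are_perfect(self):
        assignment = tracking.ClusterAssignment([[(t, 1) for t in range(4)]])
        labels = {(t, 1): "X" for t in range(4)}
        assert tracking.cluster_label_accuracy(assignment, labels) == 1.0

    def test_small_clusters_excluded(self):
        assignment = tracking.ClusterAssignment(
            [[(0, 1), (1, 1)], [(0, 2), (1, 2), (2, 2)]]
        )
        labels = {
            (0, 1): "A", (1, 1): "B",
            (0, 2): "C", (1, 2): "C", (2, 2): "C",
        }
        # the 2-label cluster is excluded from both sums
        assert tracking.cluster_label_accuracy(assignment, labels) == 1.0

    def test_no_qualifying_cluster_flagged(self):
        assignment = tracking.ClusterAssignment([[(0, 1)]])
        with pytest.raises(ValueError):
            tracking.cluster_label_accuracy(assignment, {(0, 1): "A"})

    def test_lr_suffix_ignored_when_requested(self):
        assignment = tracking.ClusterAssignment([[(0, 1), (1, 1), (2, 1)]])
        labels = {(0, 1): "AVAL", (1, 1): "AVAR", (2, 1): "AVAL"}
        assert tracking.cluster_label_accuracy(assignment, labels, ignore_lr=True) == 1.0
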