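"""Dense-array SBM: stage-by-stage contracts plus a 1-D watershed oracle."""

import numpy as np
import pytest

from sbmclust import (
    CellBudgetError,
    ClusterSpec,
    DegenerateFeatureError,
    SBMParams,
    ParameterError,
    generate_mixture,
    minmax_normalise,
    sbm_fit,
)
from sbmclust.sbm import (
    chunkify_array,
    dechunkify,
    expand_array,
    find_centroids_array,
)


class TestMinmaxNormalise:
    def test_linear_map_endpoints_and_midpoint(self):
        out = minmax_normalise([[0.0], [5.0], [10.0]], 25)
        np.testing.assert_allclose(out, [[0.0], [12.5], [25.0]])

    def test_identity_when_already_in_range(self):
        X = np.array([[0.0, 0.0], [2.5, 1.0], [5.0, 5.0]])
        np.testing.assert_allclose(minmax_normalise(X, 5), X)

    def test_two_point_range_maps_to_endpoints(self):
        out = minmax_normalise([[1.0, 10.0], [3.0, 30.0]], 4)
        np.testing.assert_allclose(out, [[0.0, 0.0], [4.0, 4.0]])

    def test_constant_feature_names_column(self):
        X = np.array([[1.0, 2.0], [3.0, 2.0]])
        with pytest.raises(DegenerateFeatureError, match="column 1"):
            minmax_normalise(X, 10)

    def test_single_point_is_degenerate(self):
        with pytest.raises(DegenerateFeatureError):
            minmax_normalise([[1.0, 2.0]], 10)


class TestChunkify:
    def test_hand_floored_example(self):
        Xn = np.array([[0.1, 0.1], [1.5, 1.5], [1.6, 1.4]])
        counts = chunkify_array(Xn, 2)
        expected = np.zeros((2, 2), dtype=int)
        expected[0, 0] = 1
        expected[1, 1] = 2
        np.testing.assert_array_equal(counts, expected)

    def test_total_cells_is_pn_to_the_n(self):
        Xn = np.full((4, 3), 1.0)
        assert chunkify_array(Xn, 5).size == 125

    def test_point_at_upper_bound_clamps_into_last_chunk(self):
        counts = chunkify_array(np.array([[2.0, 2.0]]), 2)
        assert counts[1, 1] == 1

    def test_count_conservation(self, rng):
        Xn = rng.uniform(0, 7, size=(500, 2))
        assert chunkify_array(Xn, 7).sum() == 500

    def test_out_of_range_rejected(self):
        with pytest.raises(Exception, match="range"):
            chunkify_array(np.array([[-0.5, 1.0]]), 2)

    def test_cell_budget_refusal(self):
        Xn = np.full((3, 8), 0.5)
        with pytest.raises(CellBudgetError):
            chunkify_array(Xn, 25, cell_budget=10**6)


class TestFindCentroids:
    def test_unique_interior_maximum(self):
        assert find_centroids_array(np.array([1, 5, 2]), threshold=2) == [(1,)]

    def test_threshold_excludes_all(self):
        assert find_centroids_array(np.array([1, 5, 2]), threshold=6) == []

    def test_two_peaks_sorted_by_descending_count(self):
        counts = np.zeros((7, 7), dtype=int)
        counts[1, 1] = 9
        counts[5, 5] = 7
        assert find_centroids_array(counts, threshold=0) == [(1, 1), (5, 5)]

    def test_count_ties_break_lexicographically(self):
        counts = np.zeros((7, 7), dtype=int)
        counts[5, 1] = 4
        counts[1, 5] = 4
        assert find_centroids_array(counts, threshold=0) == [(1, 5), (5, 1)]

    def test_plateau_produces_no_candidate(self):
        # equal-count neighbours fail the strict-dominance rule
        assert find_centroids_array(np.array([3, 3]), threshold=0) == []


class TestExpand:
    def test_monotone_descent_from_single_peak(self):
        counts = np.array([1, 5, 2])
        labels = expand_array(counts, [(1,)])
        assert labels.tolist() == [1, 1, 1]

    def test_contested_chunk_joins_first_processed_centroid(self):
        counts = np.array([4, 1, 5])
        centroids = find_centroids_array(counts, threshold=0)
        assert centroids == [(2,), (0,)]
        labels = expand_array(counts, centroids)
        # chunk 1 is reachable from both peaks; the 5-peak expands first
        assert labels.tolist() == [2, 1, 1]

    def test_single_occupied_chunk(self):
        counts = np.array([[0, 0], [0, 3]])
        labels = expand_array(counts, [(1, 1)])
        assert labels[1, 1] == 1
        assert labels.sum() == 1

    def test_candidate_absorbed_by_larger_neighbour_is_merged(self):
        # 5 and 4 are adjacent local maxima of their own ends; the 4-chunk
        # satisfies descent from 5 and must not seed a second cluster
        counts = np.array([5, 4, 1])
        centroids = find_centroids_array(counts, threshold=0)
        assert centroids == [(0,)]  # 4 is not a candidate (5 dominates it)
        counts = np.array([5, 5, 1])
        assert find_centroids_array(counts, threshold=0) == []

    def test_rising_count_blocks_expansion(self):
        # descent rule: a higher-count neighbour never joins the frontier
        counts = np.array([2, 1, 9, 0, 4])
        labels = expand_array(counts, [(2,), (4,), (0,)])
        assert labels.tolist() == [3, 1, 1, 0, 2]


def watershed_1d_oracle(counts, threshold):
    """Independent 1-D reimplementation of the centroid+expansion rules.

    Enumerates candidates by direct neighbour comparison, then grows each
    in processing order with an explicit frontier list, checking descent.
    """
    n = len(counts)
    cands = [
        i
        for i in range(n)
        if counts[i] > threshold
        and all(counts[i] > counts[j] for j in (i - 1, i + 1) if 0 <= j < n)
    ]
    cands.sort(key=lambda i: (-counts[i], i))
    labels = [0] * n
    pending = set(cands)
    label = 0
    for c in cands:
        if c not in pending:
            continue
        pending.discard(c)
        label += 1
        frontier = [c]
        labels[c] = label
        while frontier:
            nxt = []
            for i in frontier:
                for j in (i - 1, i + 1):
                    if (
                        0 <= j < n
                        and labels[j] == 0
                        and 0 < counts[j] <= counts[i]
                    ):
                        labels[j] = label
                        pending.discard(j)
                        nxt.append(j)
            frontier = nxt
    return labels


@pytest.mark.parametrize("trial", range(50))
def test_1d_clusters_match_watershed_oracle(trial):
    rng = np.random.default_rng(1000 + trial)
    counts = rng.integers(0, 10, size=rng.integers(3, 15))
    threshold = int(rng.integers(0, 4))
    centroids = find_centroids_array(counts, threshold)
    labels = expand_array(counts, centroids)
    assert labels.tolist() == watershed_1d_oracle(counts.tolist(), threshold)


class TestDechunkify:
    def test_composition_of_chunkify_and_labels(self):
        Xn = np.array([[0.1, 0.1], [1.5, 1.5], [1.6, 1.4]])
        chunk_labels = np.full((2, 2), 0)
        chunk_labels[0, 0] = 1
        chunk_labels[1, 1] = 1
        assert dechunkify(chunk_labels, Xn).tolist() == [1, 1, 1]

    def test_point_in_unlabelled_chunk_is_noise(self):
        chunk_labels = np.zeros((3, 3), dtype=int)
        assert dechunkify(chunk_labels, np.array([[1.5, 1.5]])).tolist() == [0]


class TestSbmFit:
    def test_separated_mixture_fully_recovered(self):
        specs = [
            ClusterSpec.make([0.0, 0.0], 100, 1.0),
            ClusterSpec.make([20.0, 0.0], 100, 1.0),
        ]
        cloud = generate_mixture(specs, seed=4)
        res = sbm_fit(cloud.points, SBMParams(pn=10, threshold=1))
        assert res.n_clusters == 2
        assert res.noise_label == 0
        # labels must be a pure relabelling of the generating labels
        for lab in (1, 2):
            assert len(np.unique(cloud.labels[res.labels == lab])) == 1

    def test_single_point_dataset_is_degenerate(self):
        with pytest.raises(DegenerateFeatureError):
            sbm_fit([[1.0, 2.0]], SBMParams(pn=5))

    def test_deterministic(self, rng):
        X = rng.normal(size=(300, 2))
        a = sbm_fit(X, SBMParams(pn=8, threshold=2))
        b = sbm_fit(X, SBMParams(pn=8, threshold=2))
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_every_point_labelled_and_stats_consistent(self, rng):
        X = rng.normal(size=(400, 2))
        res = sbm_fit(X, SBMParams(pn=12, threshold=3))
        assert res.labels.shape == (400,)
        assert res.n_noise == int(np.sum(res.labels == 0))
        assert res.chunk_stats["total_cells"] == 12**2

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            SBMParams(pn=1)
        with pytest.raises(ParameterError):
            SBMParams(pn=10, threshold=-1)
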