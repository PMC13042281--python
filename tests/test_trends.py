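"""Segment assignment, trend matrices, clustering and heatmap ordering."""

import numpy as np
import pandas as pd
import pytest

import velostream as vs
from velostream.errors import EmptyNeighborhoodError, ParameterError
from velostream.trends import UNASSIGNED


def straight_path(n_points=10, start=(0.0, 0.0, 0.0), stop=(9.0, 0.0, 0.0)):
    pts = np.linspace(start, stop, n_points)
    return vs.Trajectory(pts, np.asarray(start), "completed", vs.IntegrationConfig())


@pytest.fixture
def path():
    return straight_path()


class TestAssignSegments:
    def test_cell_on_first_point_gets_segment_zero(self, path):
        ds = vs.CellEmbedding(["a"], np.array([[0.0, 0.0, 0.0]]))
        a = vs.assign_segments(path, ds, n_segments=5, radius=0.5)
        assert a.segment_of[0] == 0

    def test_cell_nearest_last_point_clips_to_last_segment(self, path):
        ds = vs.CellEmbedding(["a"], np.array([[9.0, 0.1, 0.0]]))
        a = vs.assign_segments(path, ds, n_segments=5, radius=0.5)
        # nearest point index 9 of 10 -> floor(9*5/10) = 4 = n_segments - 1
        assert a.segment_of[0] == 4

    def test_far_cells_stay_unassigned(self, path):
        ds = vs.CellEmbedding(["a", "b"], np.array([[0.0, 5.0, 0.0], [4.0, 0.2, 0.0]]))
        a = vs.assign_segments(path, ds, n_segments=3, radius=1.0)
        assert a.segment_of[0] == UNASSIGNED
        assert a.segment_of[1] != UNASSIGNED

    def test_matches_brute_force_nearest_point_oracle(self, path, rng):
        coords = rng.uniform([-1, -2, -2], [10, 2, 2], (300, 3))
        ds = vs.CellEmbedding([f"c{i}" for i in range(300)], coords)
        n_seg, radius = 4, 1.5
        a = vs.assign_segments(path, ds, n_segments=n_seg, radius=radius)
        for i in range(300):
            d = np.linalg.norm(path.points - coords[i], axis=1)
            j = int(np.argmin(d))
            if d[j] > radius:
                assert a.segment_of[i] == UNASSIGNED
            else:
                expect = min(j * n_seg // path.n_points, n_seg - 1)
                assert a.segment_of[i] == expect

    def test_count_conservation(self, path, rng):
        coords = rng.uniform([-1, -2, -2], [10, 2, 2], (200, 3))
        ds = vs.CellEmbedding([f"c{i}" for i in range(200)], coords)
        a = vs.assign_segments(path, ds, n_segments=6, radius=1.0)
        assert a.segment_cell_counts().sum() == a.n_assigned

    def test_nonpositive_radius_rejected(self, path):
        ds = vs.CellEmbedding(["a"], np.zeros((1, 3)))
        with pytest.raises(ParameterError):
            vs.assign_segments(path, ds, n_segments=3, radius=0.0)


def _one_cell_per_segment(path, values_per_segment):
    """Dataset with exactly one cell on a path point of each segment."""
    n_seg = len(values_per_segment)
    # 10-point path, n_seg segments: put a cell at point floor(s*10/n_seg)
    idx = [s * path.n_points // n_seg for s in range(n_seg)]
    coords = path.points[idx]
    ds = vs.CellEmbedding([f"c{s}" for s in range(n_seg)], coords)
    mod = vs.ModalityMatrix(["f"], np.asarray(values_per_segment, float)[:, None], "RNA")
    return ds.with_modality(mod)


class TestSegmentMeans:
    def test_one_cell_per_segment_raw_means(self, path):
        vals = [3.0, 1.0, 4.0, 1.0, 5.0]
        ds = _one_cell_per_segment(path, vals)
        a = vs.assign_segments(path, ds, n_segments=5, radius=0.01)
        tm = vs.segment_means(a, ds.modalities["RNA"], "raw")
        np.testing.assert_allclose(tm.means[0], vals)

    def test_constant_feature_zscore_row_is_zero(self, path):
        ds = _one_cell_per_segment(path, [2.0, 2.0, 2.0, 2.0, 2.0])
        a = vs.assign_segments(path, ds, n_segments=5, radius=0.01)
        tm = vs.segment_means(a, ds.modalities["RNA"], "zscore")
        np.testing.assert_array_equal(tm.means[0], 0.0)

    def test_zscore_rows_have_zero_mean_unit_variance(self, path, rng):
        coords = rng.uniform([0, -1, -1], [9, 1, 1], (120, 3))
        ds = vs.CellEmbedding([f"c{i}" for i in range(120)], coords)
        ds = ds.with_modality(
            vs.ModalityMatrix([f"g{j}" for j in range(5)], rng.normal(size=(120, 5)), "RNA")
        )
        a = vs.assign_segments(path, ds, n_segments=4, radius=3.0)
        tm = vs.segment_means(a, ds.modalities["RNA"], "zscore")
        np.testing.assert_allclose(tm.means.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(tm.means.var(axis=1), 1.0, atol=1e-9)

    def test_relative_rows_start_at_zero(self, path):
        ds = _one_cell_per_segment(path, [3.0, 5.0, 2.0, 8.0, 3.0])
        a = vs.assign_segments(path, ds, n_segments=5, radius=0.01)
        tm = vs.segment_means(a, ds.modalities["RNA"], "relative")
        assert tm.means[0][0] == 0.0
        np.testing.assert_allclose(tm.means[0], np.array([3, 5, 2, 8, 3.0]) - 3.0)

    def test_matches_brute_force_groupby_oracle(self, path, rng):
        coords = rng.uniform([0, -1, -1], [9, 1, 1], (400, 3))
        ds = vs.CellEmbedding([f"c{i}" for i in range(400)], coords)
        vals = rng.normal(size=(400, 8))
        ds = ds.with_modality(
            vs.ModalityMatrix([f"g{j}" for j in range(8)], vals, "RNA")
        )
        a = vs.assign_segments(path, ds, n_segments=5, radius=2.0)
        tm = vs.segment_means(a, ds.modalities["RNA"], "raw")
        df = pd.DataFrame(vals)
        df["seg"] = a.segment_of
        expect = df[df["seg"] != UNASSIGNED].groupby("seg").mean()
        for s in expect.index:
            np.testing.assert_allclose(tm.means[:, s], expect.loc[s].to_numpy(),
                                       atol=1e-12)

    def test_empty_middle_segment_linearly_filled(self, path):
        # cells only in segments 0, 1, 3, 4 of 5: segment 2 interpolates 1 and 3
        vals = [1.0, 2.0, 7.0, 4.0]
        idx = [0, 2, 7, 9]  # point indices -> segments 0, 1, 3, 4
        coords = path.points[idx]
        ds = vs.CellEmbedding([f"c{i}" for i in range(4)], coords)
        ds = ds.with_modality(vs.ModalityMatrix(["f"], np.array(vals)[:, None], "RNA"))
        a = vs.assign_segments(path, ds, n_segments=5, radius=0.01)
        assert a.segment_cell_counts()[2] == 0
        tm = vs.segment_means(a, ds.modalities["RNA"], "raw")
        np.testing.assert_allclose(tm.means[0], [1.0, 2.0, 4.5, 7.0, 4.0])

    def test_no_assigned_cells_raises_with_hint(self, path):
        ds = vs.CellEmbedding(["a"], np.array([[0.0, 50.0, 0.0]]))
        ds = ds.with_modality(vs.ModalityMatrix(["f"], np.ones((1, 1)), "RNA"))
        a = vs.assign_segments(path, ds, n_segments=3, radius=0.5)
        with pytest.raises(EmptyNeighborhoodError, match="radius"):
            vs.segment_means(a, ds.modalities["RNA"], "raw")


def planted_trend_matrix(n_up=6, n_down=6, n_segments=8, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n_segments)
    rows, ids = [], []
    for i in range(n_up):
        rows.append(t + noise * rng.normal(size=n_segments))
        ids.append(f"up_{i}")
    for i in range(n_down):
        rows.append(1 - t + noise * rng.normal(size=n_segments))
        ids.append(f"down_{i}")
    means = np.array(rows)
    return vs.TrendMatrix(ids, means, "raw", np.ones(n_segments, dtype=int))


class TestClusterTrends:
    def test_k1_centroid_is_column_mean(self):
        tm = planted_trend_matrix()
        c = vs.cluster_trends(tm, k=1, seed=0)
        assert set(c.labels) == {0}
        np.testing.assert_allclose(c.centroids[0], tm.means.mean(axis=0), atol=1e-12)

    def test_planted_up_down_families_recovered_exactly(self):
        tm = planted_trend_matrix(noise=0.01)
        c = vs.cluster_trends(tm, k=2, seed=1)
        up_labels = set(c.labels[:6])
        down_labels = set(c.labels[6:])
        assert len(up_labels) == 1 and len(down_labels) == 1
        assert up_labels != down_labels

    def test_same_seed_reproduces_labels(self):
        tm = planted_trend_matrix(noise=0.1, seed=3)
        a = vs.cluster_trends(tm, k=3, seed=11)
        b = vs.cluster_trends(tm, k=3, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_top_n_selection_by_variance(self):
        tm = planted_trend_matrix(n_up=4, n_down=4)
        flat = vs.TrendMatrix(
            tm.feature_ids + ["flat"],
            np.vstack([tm.means, np.full((1, tm.n_segments), 0.5)]),
            "raw", tm.segment_cell_counts,
        )
        c = vs.cluster_trends(flat, k=2, seed=0, top_n=8, selection="variance")
        assert "flat" not in c.feature_ids
        assert len(c.feature_ids) == 8

    def test_k_above_feature_count_rejected(self):
        tm = planted_trend_matrix(n_up=2, n_down=2)
        with pytest.raises(ParameterError):
            vs.cluster_trends(tm, k=5, seed=0)


class TestOrderClusters:
    def test_rising_before_falling(self):
        tm = planted_trend_matrix(noise=0.0)
        c = vs.order_clusters(vs.cluster_trends(tm, k=2, seed=0))
        first = c.centroids[c.cluster_order[0]]
        second = c.centroids[c.cluster_order[1]]
        assert first[-1] - first[0] >= 0
        assert second[-1] - second[0] < 0

    def test_up_clusters_ordered_by_peak_position(self):
        centroids = np.array([
            [0.0, 0.1, 0.2, 0.3, 0.2, 1.0],   # up, max at 5
            [0.0, 0.2, 1.0, 0.6, 0.5, 0.4],   # up, max at 2
        ])
        c = vs.TrendClustering(2, np.array([0, 1]), centroids, np.arange(2), 0,
                               ["a", "b"])
        ordered = vs.order_clusters(c)
        np.testing.assert_array_equal(ordered.cluster_order, [1, 0])

    def test_random_centroids_match_tuple_sort_oracle(self, rng):
        k = 6
        centroids = rng.normal(size=(k, 7))
        c = vs.TrendClustering(k, rng.integers(0, k, 30), centroids, np.arange(k), 0,
                               [f"f{i}" for i in range(30)])
        ordered = vs.order_clusters(c)
        keys = []
        for i in range(k):
            up = centroids[i, -1] - centroids[i, 0] >= 0
            extremum = np.argmax(centroids[i]) if up else np.argmin(centroids[i])
            keys.append((0 if up else 1, int(extremum), i))
        expect = [i for _, _, i in sorted(keys)]
        np.testing.assert_array_equal(ordered.cluster_order, expect)


class TestHeatmapTable:
    def test_single_feature_single_row(self):
        tm = planted_trend_matrix(n_up=1, n_down=0)
        c = vs.order_clusters(vs.cluster_trends(tm, k=1, seed=0))
        table = vs.heatmap_table(tm, c)
        assert len(table) == 1
        assert table["feature_id"].iloc[0] == "up_0"

    def test_row_count_equals_retained_features(self):
        tm = planted_trend_matrix()
        c = vs.order_clusters(vs.cluster_trends(tm, k=2, seed=0))
        assert len(vs.heatmap_table(tm, c)) == len(tm.feature_ids)

    def test_csv_round_trip_preserves_means(self, tmp_path):
        tm = planted_trend_matrix(noise=0.05)
        c = vs.order_clusters(vs.cluster_trends(tm, k=2, seed=0))
        table = vs.heatmap_table(tm, c)
        p = tmp_path / "heat.csv"
        # 17 significant digits round-trips float64 exactly
        table.to_csv(p, index=False, float_format="%.17g")
        back = pd.read_csv(p, float_precision="round_trip")
        seg_cols = [col for col in table.columns if col.startswith("segment_")]
        np.testing.assert_array_equal(back[seg_cols].to_numpy(),
                                      table[seg_cols].to_numpy())

    def test_feature_permutation_permutes_rows_only(self, rng):
        tm = planted_trend_matrix(noise=0.02, seed=5)
        perm = rng.permutation(len(tm.feature_ids))
        tm2 = vs.TrendMatrix(
            [tm.feature_ids[i] for i in perm], tm.means[perm], tm.normalization,
            tm.segment_cell_counts,
        )
        c1 = vs.order_clusters(vs.cluster_trends(tm, k=2, seed=0))
        c2 = vs.order_clusters(vs.cluster_trends(tm2, k=2, seed=0))
        t1 = vs.heatmap_table(tm, c1).set_index("feature_id")
        t2 = vs.heatmap_table(tm2, c2).set_index("feature_id")
        seg_cols = [col for col in t1.columns if col.startswith("segment_")]
        np.testing.assert_allclose(
            t1.loc[sorted(t1.index), seg_cols].to_numpy(),
            t2.loc[sorted(t2.index), seg_cols].to_numpy(),
        )
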