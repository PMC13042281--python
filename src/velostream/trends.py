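"""Feature-activity trends along a trajectory.

Cells within a radius of an integrated trajectory are assigned to one of
a user-chosen number of consecutive segments (by nearest trajectory
point, so segments partition the path's steps equally).  Per-segment
mean activities form a features x segments trend matrix, which is
normalized, clustered with k-means, and ordered for heatmap display:
up-regulated cluster profiles first (by the position of their maximum),
then down-regulated ones (by the position of their minimum).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .datasets import CellEmbedding, ModalityMatrix
from .errors import EmptyNeighborhoodError, ParameterError
from .integrate import Trajectory

NORMALIZATIONS = ("raw", "zscore", "relative")

UNASSIGNED = -1


@dataclass
class SegmentAssignment:
    """Which trajectory segment, if any, each cell belongs to.

    ``segment_of`` holds one entry per cell: a segment index in
    ``[0, n_segments)`` for cells within `radius` of the trajectory,
    :data:`UNASSIGNED` otherwise.
    """

    trajectory: Trajectory
    n_segments: int
    radius: float
    segment_of: np.ndarray  # (n_cells,), int

    @property
    def cell_to_segment(self) -> dict[int, int]:
        return {
            int(i): int(s) for i, s in enumerate(self.segment_of) if s != UNASSIGNED
        }

    @property
    def n_assigned(self) -> int:
        return int((self.segment_of != UNASSIGNED).sum())

    def segment_cell_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_segments, dtype=int)
        assigned = self.segment_of[self.segment_of != UNASSIGNED]
        np.add.at(counts, assigned, 1)
        return counts


@dataclass
class TrendMatrix:
    """Per-segment mean feature activities, optionally normalized per row."""

    feature_ids: list[str]
    means: np.ndarray  # (n_features, n_segments)
    normalization: str
    segment_cell_counts: np.ndarray

    @property
    def n_segments(self) -> int:
        return self.means.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.means,
            index=pd.Index(self.feature_ids, name="feature_id"),
            columns=[f"segment_{s}" for s in range(self.n_segments)],
        )
        return df


@dataclass
class TrendClustering:
    """k-means clusters of trend profiles plus their display order."""

    k: int
    labels: np.ndarray            # (n_retained,)
    centroids: np.ndarray         # (k, n_segments)
    cluster_order: np.ndarray     # permutation of [0, k)
    seed: int
    feature_ids: list[str]        # retained features, aligned with labels

    def __post_init__(self) -> None:
        order = np.asarray(self.cluster_order, dtype=int)
        if sorted(order.tolist()) != list(range(self.k)):
            raise ParameterError(f"cluster_order must be a permutation of 0..{self.k - 1}")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.k:
            raise ParameterError("labels reference nonexistent clusters")
        self.cluster_order = order


def assign_segments(
    trajectory: Trajectory,
    dataset: CellEmbedding,
    n_segments: int,
    radius: float,
) -> SegmentAssignment:
    """Assign cells near the trajectory to equal-step segments.

    A cell within `radius` (Euclidean, to the nearest trajectory point)
    gets segment ``floor(nearest_point_index * n_segments / n_points)``,
    clipped to the last segment; farther cells stay unassigned.
    """
    if radius <= 0:
        raise ParameterError(f"radius must be positive, got {radius}")
    if n_segments < 1:
        raise ParameterError(f"n_segments must be >= 1, got {n_segments}")
    if trajectory.n_points < 2:
        raise ParameterError(
            f"trajectory must have at least 2 points, got {trajectory.n_points}"
        )
    tree = cKDTree(trajectory.points)
    dist, nearest = tree.query(dataset.coords)
    seg = np.floor(nearest * n_segments / trajectory.n_points).astype(int)
    seg = np.minimum(seg, n_segments - 1)
    seg[dist > radius] = UNASSIGNED
    return SegmentAssignment(
        trajectory=trajectory, n_segments=n_segments, radius=radius, segment_of=seg
    )


def _fill_empty_segments(row: np.ndarray, empty: np.ndarray) -> np.ndarray:
    """Linear interpolation over empty segments; ends take the nearest value."""
    filled = np.flatnonzero(~empty)
    return np.interp(np.arange(len(row)), filled, row[filled])


def _normalize_rows(means: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "raw":
        return means
    if normalization == "zscore":
        mu = means.mean(axis=1, keepdims=True)
        sd = means.std(axis=1, keepdims=True)  # population std: unit variance rows
        out = np.zeros_like(means)
        ok = sd[:, 0] > 1e-12
        out[ok] = (means[ok] - mu[ok]) / sd[ok]
        return out
    if normalization == "relative":
        return means - means[:, [0]]
    raise ParameterError(f"normalization must be one of {NORMALIZATIONS}, got {normalization!r}")


def segment_means(
    assignment: SegmentAssignment,
    modality: ModalityMatrix,
    normalization: str = "raw",
) -> TrendMatrix:
    """Mean activity of every feature over the cells of each segment.

    Empty segments are filled by linear interpolation between the nearest
    flanking non-empty segments (ends: nearest non-empty value), then the
    requested row-wise normalization is applied: ``zscore`` centers and
    scales each feature across segments (constant rows become all-zero);
    ``relative`` subtracts the first segment's mean.
    """
    if normalization not in NORMALIZATIONS:
        raise ParameterError(
            f"normalization must be one of {NORMALIZATIONS}, got {normalization!r}"
        )
    counts = assignment.segment_cell_counts()
    if counts.sum() == 0:
        raise EmptyNeighborhoodError(
            f"no cells within radius {assignment.radius} of the trajectory; "
            "try a larger radius"
        )
    n_seg = assignment.n_segments
    sums = np.zeros((n_seg, modality.n_features))
    assigned_mask = assignment.segment_of != UNASSIGNED
    np.add.at(sums, assignment.segment_of[assigned_mask], modality.values[assigned_mask])
    means = np.full((n_seg, modality.n_features), np.nan)
    occ = counts > 0
    means[occ] = sums[occ] / counts[occ, None]
    means = means.T  # features x segments
    empty = ~occ
    if empty.any():
        for f in range(means.shape[0]):
            means[f] = _fill_empty_segments(means[f], empty)
    return TrendMatrix(
        feature_ids=list(modality.feature_ids),
        means=_normalize_rows(means, normalization),
        normalization=normalization,
        segment_cell_counts=counts,
    )


def cluster_trends(
    trends: TrendMatrix,
    k: int,
    seed: int = 0,
    top_n: Optional[int] = None,
    selection: str = "variance",
) -> TrendClustering:
    """k-means clustering of trend profiles.

    When `top_n` is given, features are first shortlisted by the selection
    statistic across segments (``variance`` or ``range``).  k-means runs on
    the trend rows as stored (cluster on a normalized TrendMatrix for
    scale-free grouping) with seeded initialization and 10 restarts; the
    initial cluster order is the identity — see :func:`order_clusters`.
    """
    rows = trends.means
    feature_ids = list(trends.feature_ids)
    if top_n is not None and top_n < rows.shape[0]:
        stat = rows.var(axis=1) if selection == "variance" else np.ptp(rows, axis=1)
        if selection not in ("variance", "range"):
            raise ParameterError(f"selection must be 'variance' or 'range', got {selection!r}")
        keep = np.sort(np.argsort(stat)[::-1][:top_n])
        rows = rows[keep]
        feature_ids = [feature_ids[i] for i in keep]
    if not (1 <= k <= rows.shape[0]):
        raise ParameterError(
            f"k must be in [1, {rows.shape[0]}] (number of retained features), got {k}"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(rows)
    return TrendClustering(
        k=k,
        labels=labels,
        centroids=km.cluster_centers_,
        cluster_order=np.arange(k),
        seed=seed,
        feature_ids=feature_ids,
    )


def centroid_is_up(centroid: np.ndarray) -> bool:
    """Up-regulated iff last-segment value minus first-segment value >= 0."""
    return bool(centroid[-1] - centroid[0] >= 0)


def order_clusters(clustering: TrendClustering) -> TrendClustering:
    """Order clusters for display: up-regulated profiles first.

    Within the up-regulated group clusters are sorted by the segment index
    of their centroid maximum (earlier peaks first); down-regulated
    clusters follow, sorted by the segment index of their centroid minimum.
    Ties break by cluster index.
    """
    keys = []
    for c in range(clustering.k):
        centroid = clustering.centroids[c]
        if centroid_is_up(centroid):
            keys.append((0, int(np.argmax(centroid)), c))
        else:
            keys.append((1, int(np.argmin(centroid)), c))
    order = np.array([c for _, _, c in sorted(keys)], dtype=int)
    return replace(clustering, cluster_order=order)


def heatmap_table(trends: TrendMatrix, clustering: TrendClustering) -> pd.DataFrame:
    """Trend rows ordered for heatmap display.

    Rows sort by (position of their cluster in the display order, the
    feature's own extremum position — maximum for up-regulated clusters,
    minimum for down-regulated — then feature id).  Columns carry the
    feature id, cluster id and per-segment values, ready for CSV export.
    """
    id_to_row = {fid: i for i, fid in enumerate(trends.feature_ids)}
    missing = [f for f in clustering.feature_ids if f not in id_to_row]
    if missing:
        raise ParameterError(f"clustering references unknown features: {missing[:5]}")
    order_pos = {int(c): pos for pos, c in enumerate(clustering.cluster_order)}
    records = []
    for fi, fid in enumerate(clustering.feature_ids):
        label = int(clustering.labels[fi])
        row = trends.means[id_to_row[fid]]
        up = centroid_is_up(clustering.centroids[label])
        extremum = int(np.argmax(row)) if up else int(np.argmin(row))
        records.append((order_pos[label], extremum, fid, label, row))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    data = {
        "feature_id": [r[2] for r in records],
        "cluster": [r[3] for r in records],
    }
    for s in range(trends.n_segments):
        data[f"segment_{s}"] = [r[4][s] for r in records]
    return pd.DataFrame(data)
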