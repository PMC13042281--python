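"""Regular-grid velocity fields over a 3D embedding.

Per-cell velocity vectors are averaged onto a regularly spaced grid
(either by nearest-node binning or with a Gaussian kernel), and the
resulting :class:`GridVectorField` supports continuous trilinear
evaluation for streamline integration plus cone-glyph extraction for
rendering.  Grids use 0-based node indices; a voxel is the half-open
box ``[node, node + spacing)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .datasets import CellEmbedding
from .errors import MissingVelocityError, ParameterError

log = logging.getLogger(__name__)


@dataclass
class GridSpec:
    """Geometry of a regular 3D grid.

    `origin` is the position of node (0,0,0); node (i,j,k) sits at
    ``origin + spacing * (i,j,k)``.  `scale` is a scalar multiplier applied
    to stored vectors whenever the field is sampled or rendered — it
    stretches integration step displacement and glyph length without
    moving node positions.
    """

    origin: np.ndarray
    spacing: np.ndarray
    shape: tuple[int, int, int]
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.shape = tuple(int(s) for s in self.shape)
        if np.any(self.spacing <= 0):
            raise ParameterError(f"grid spacing must be positive, got {self.spacing}")
        if any(s < 2 for s in self.shape):
            raise ParameterError(f"grid shape components must be >= 2, got {self.shape}")
        if self.scale <= 0:
            raise ParameterError(f"grid scale must be positive, got {self.scale}")

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def upper(self) -> np.ndarray:
        """Position of the last node along each axis."""
        return self.origin + self.spacing * (np.array(self.shape) - 1)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )

    def node_positions(self) -> np.ndarray:
        """(n_nodes, 3) array of node positions in ijk-raveled (C) order."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def contains(self, points: np.ndarray, atol: float = 1e-12) -> np.ndarray:
        """Boolean mask: which points lie inside the grid bounding box."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = self.origin - atol
        hi = self.upper + atol
        return np.all((pts >= lo) & (pts <= hi), axis=1)


@dataclass
class GridVectorField:
    """Averaged velocity vectors on a regular grid.

    `vectors` has shape ``grid.shape + (3,)``; `occupancy` has shape
    ``grid.shape`` and counts the cells that contributed to each node.
    Nodes no cell contributed to hold the zero vector.
    """

    grid: GridSpec
    vectors: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=int)
        if self.vectors.shape != self.grid.shape + (3,):
            raise ParameterError(
                f"vectors shape {self.vectors.shape} != grid shape {self.grid.shape} + (3,)"
            )
        if self.occupancy.shape != self.grid.shape:
            raise ParameterError(
                f"occupancy shape {self.occupancy.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ParameterError("field vectors contain non-finite values")

    def to_dataframe(self) -> pd.DataFrame:
        """Flat table of (node index, position, vector, occupancy)."""
        idx = np.indices(self.grid.shape).reshape(3, -1).T
        pos = self.grid.origin + idx * self.grid.spacing
        vec = self.vectors.reshape(-1, 3)
        return pd.DataFrame(
            {
                "i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2],
                "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
                "vx": vec[:, 0], "vy": vec[:, 1], "vz": vec[:, 2],
                "occupancy": self.occupancy.ravel(),
            }
        )


def build_grid(
    coords: np.ndarray,
    resolution: int,
    padding_fraction: float = 0.05,
    scale: float = 1.0,
) -> GridSpec:
    """Build a regular grid covering the (padded) bounding box of `coords`.

    `resolution` counts nodes along the longest axis; shorter axes get
    proportionally fewer nodes, ``ceil((resolution - 1) * extent_ratio) + 1``
    with a floor of 2, which keeps voxels near-cubic.  A degenerate
    (zero-extent) axis gets 2 nodes of unit spacing centered on the data.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] < 1 or coords.shape[1] != 3:
        raise ParameterError(f"coords must be (n, 3), got {coords.shape}")
    if resolution < 2:
        raise ParameterError(f"resolution must be >= 2, got {resolution}")
    if not (0 <= padding_fraction < 1):
        raise ParameterError(f"padding_fraction must be in [0, 1), got {padding_fraction}")

    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    extent = hi - lo
    pad = padding_fraction * extent
    lo = lo - pad
    hi = hi + pad
    extent = hi - lo

    longest = float(extent.max())
    shape = np.empty(3, dtype=int)
    spacing = np.empty(3)
    origin = lo.copy()
    for a in range(3):
        if extent[a] <= 0:
            shape[a] = 2
            spacing[a] = 1.0
            origin[a] = lo[a] - 0.5
            log.info("axis %d has zero extent; using 2 nodes with unit spacing", a)
        else:
            n = max(2, math.ceil((resolution - 1) * extent[a] / longest) + 1)
            shape[a] = n
            spacing[a] = extent[a] / (n - 1)
    return GridSpec(origin=origin, spacing=spacing, shape=tuple(shape), scale=scale)


def nearest_node_indices(grid: GridSpec, coords: np.ndarray) -> np.ndarray:
    """(n, 3) integer indices of the grid node nearest each coordinate."""
    u = (np.atleast_2d(coords) - grid.origin) / grid.spacing
    idx = np.rint(u).astype(int)
    return np.clip(idx, 0, np.array(grid.shape) - 1)


def average_velocities(
    dataset: CellEmbedding,
    grid: GridSpec,
    method: str = "bin-mean",
    bandwidth: Optional[float] = None,
) -> GridVectorField:
    """Average per-cell velocities onto grid nodes.

    ``bin-mean``: each node holds the arithmetic mean of the velocities of
    the cells whose nearest node it is; occupancy is the cell count.

    ``gaussian-kernel``: each node holds the kernel-weighted mean over all
    cells with weight ``exp(-d^2 / (2 sigma^2))``, ``sigma = bandwidth``
    (default: half the largest voxel edge); occupancy counts cells within
    3 sigma of the node.
    """
    if not dataset.has_velocities:
        raise MissingVelocityError(
            "dataset has no velocity vectors; field averaging requires them"
        )
    vel = dataset.velocities
    coords = dataset.coords
    vectors = np.zeros(grid.shape + (3,))
    occupancy = np.zeros(grid.shape, dtype=int)

    if method == "bin-mean":
        idx = nearest_node_indices(grid, coords)
        flat = np.ravel_multi_index(tuple(idx.T), grid.shape)
        sums = np.zeros((grid.n_nodes, 3))
        counts = np.zeros(grid.n_nodes, dtype=int)
        np.add.at(sums, flat, vel)
        np.add.at(counts, flat, 1)
        occ = counts > 0
        sums[occ] /= counts[occ, None]
        vectors = sums.reshape(grid.shape + (3,))
        occupancy = counts.reshape(grid.shape)
    elif method == "gaussian-kernel":
        sigma = bandwidth if bandwidth is not None else float(grid.spacing.max()) / 2.0
        if sigma <= 0:
            raise ParameterError(f"bandwidth must be positive, got {sigma}")
        nodes = grid.node_positions()
        # chunk over nodes to bound the distance-matrix footprint
        chunk = max(1, int(2e6 // max(1, len(coords))))
        vec_flat = np.zeros((grid.n_nodes, 3))
        occ_flat = np.zeros(grid.n_nodes, dtype=int)
        for s in range(0, grid.n_nodes, chunk):
            block = nodes[s:s + chunk]
            d2 = ((block[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
            w = np.exp(-d2 / (2.0 * sigma**2))
            tot = w.sum(axis=1)
            ok = tot > 0
            vec_flat[s:s + chunk][ok] = (w[ok] @ vel) / tot[ok, None]
            occ_flat[s:s + chunk] = (d2 <= (3.0 * sigma) ** 2).sum(axis=1)
        vectors = vec_flat.reshape(grid.shape + (3,))
        occupancy = occ_flat.reshape(grid.shape)
        vectors[occupancy == 0] = 0.0
    else:
        raise ParameterError(f"unknown averaging method {method!r}")
    return GridVectorField(grid=grid, vectors=vectors, occupancy=occupancy)


def sample_field(
    field: GridVectorField, point: np.ndarray, with_flag: bool = False
):
    """Trilinearly interpolate the field at `point`, scaled by ``grid.scale``.

    Points outside the grid bounding box yield the zero vector; pass
    ``with_flag=True`` to additionally receive the in-domain flag.
    """
    vec, inside = sample_field_many(field, np.asarray(point, dtype=float).reshape(1, 3))
    if with_flag:
        return vec[0], bool(inside[0])
    return vec[0]


def sample_field_many(
    field: GridVectorField, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized trilinear sampling; returns (vectors, inside_mask)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    grid = field.grid
    inside = grid.contains(pts)
    out = np.zeros((len(pts), 3))
    if not inside.any():
        return out, inside
    u = (pts[inside] - grid.origin) / grid.spacing
    hi = np.array(grid.shape) - 1
    u = np.clip(u, 0.0, hi)  # guard the atol band at the boundary
    i0 = np.minimum(np.floor(u).astype(int), hi - 1)
    f = u - i0
    acc = np.zeros((len(u), 3))
    for dx in (0, 1):
        wx = f[:, 0] if dx else 1.0 - f[:, 0]
        for dy in (0, 1):
            wy = f[:, 1] if dy else 1.0 - f[:, 1]
            for dz in (0, 1):
                wz = f[:, 2] if dz else 1.0 - f[:, 2]
                w = (wx * wy * wz)[:, None]
                acc += w * field.vectors[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    out[inside] = acc * grid.scale
    return out, inside


def field_from_function(grid: GridSpec, fn) -> GridVectorField:
    """Evaluate an analytic vector field ``fn(points) -> (n, 3)`` at every node.

    All nodes are marked occupied (occupancy 1).  Intended for analytic
    test fields and synthetic benchmarks.
    """
    nodes = grid.node_positions()
    vals = np.asarray(fn(nodes), dtype=float).reshape(len(nodes), 3)
    return GridVectorField(
        grid=grid,
        vectors=vals.reshape(grid.shape + (3,)),
        occupancy=np.ones(grid.shape, dtype=int),
    )


def cone_glyphs(
    field: GridVectorField, min_occupancy: int = 1
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (anchor, direction) glyph per sufficiently occupied, non-zero node.

    Directions are node vectors scaled by ``grid.scale``.  Nodes whose
    vector is exactly zero are excluded even at ``min_occupancy == 0`` —
    they carry no direction to draw.
    """
    occ = field.occupancy.ravel()
    vec = field.vectors.reshape(-1, 3)
    pos = field.grid.node_positions()
    keep = (occ >= min_occupancy) & (np.linalg.norm(vec, axis=1) > 0)
    return [
        (pos[i].copy(), vec[i] * field.grid.scale) for i in np.flatnonzero(keep)
    ]


def glyphs_to_dataframe(glyphs: list[tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    if not glyphs:
        return pd.DataFrame(columns=["x", "y", "z", "ux", "uy", "uz"])
    anchors = np.array([g[0] for g in glyphs])
    dirs = np.array([g[1] for g in glyphs])
    return pd.DataFrame(
        {
            "x": anchors[:, 0], "y": anchors[:, 1], "z": anchors[:, 2],
            "ux": dirs[:, 0], "uy": dirs[:, 1], "uz": dirs[:, 2],
        }
    )
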