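"""Synthetic datasets with known ground truth.

Every analysis module is testable without downloads: cells are sampled
around analytic vector fields (uniform flow, linear sink, bifurcation),
feature matrices carry planted monotone or transient trends along a
known reference path, and clone tables come with their ground-truth
membership.  All generators are deterministic under their seed; an
identical :class:`FixtureSpec` always reproduces the identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from .datasets import NO_CLONE, CellEmbedding, ModalityMatrix
from .errors import ParameterError
from .integrate import Trajectory

FIELD_KINDS = ("uniform", "linear-sink", "bifurcation")
PROFILE_SHAPES = ("monotone-up", "monotone-down", "transient-peak")

#: Default sampling box for synthetic embeddings, in embedding units.
DEFAULT_BOX = ((0.0, 0.0, 0.0), (10.0, 10.0, 10.0))


@dataclass
class FixtureSpec:
    """Everything a synthetic dataset depends on, seed included."""

    n_cells: int = 500
    field_kind: str = "linear-sink"
    field_params: dict = dc_field(default_factory=dict)
    noise_sd: float = 0.0
    n_features: int = 0
    n_clones: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.field_kind not in FIELD_KINDS:
            raise ParameterError(
                f"field_kind must be one of {FIELD_KINDS}, got {self.field_kind!r}"
            )
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")


def analytic_field(kind: str, params: dict):
    """The velocity function v(points) of a named analytic field.

    ``uniform``: constant ``v0`` (default (1, 0, 0)).
    ``linear-sink``: ``v(x) = -(x - c)`` toward center ``c`` (default box
    center) — the flow every trajectory should converge into.
    ``bifurcation``: unit flow along +x that, past ``branch_x``, diverges
    in ±z away from the midplane ``z0`` at rate ``branch_rate`` —
    emulating a fate decision.
    """
    box = np.asarray(params.get("box", DEFAULT_BOX), dtype=float)
    if kind == "uniform":
        v0 = np.asarray(params.get("v0", (1.0, 0.0, 0.0)), dtype=float)

        def fn(pts):
            return np.broadcast_to(v0, (len(pts), 3)).copy()
    elif kind == "linear-sink":
        c = np.asarray(params.get("center", box.mean(axis=0)), dtype=float)

        def fn(pts):
            return c - np.atleast_2d(pts)
    elif kind == "bifurcation":
        branch_x = float(params.get("branch_x", box[:, 0].mean()))
        z0 = float(params.get("z0", box.mean(axis=0)[2]))
        rate = float(params.get("branch_rate", 1.0))

        def fn(pts):
            pts = np.atleast_2d(pts)
            v = np.zeros_like(pts)
            v[:, 0] = 1.0
            past = pts[:, 0] > branch_x
            v[past, 2] = rate * np.sign(pts[past, 2] - z0)
            return v
    else:
        raise ParameterError(f"unknown field kind {kind!r}")
    return fn


def make_field_dataset(spec: FixtureSpec) -> CellEmbedding:
    """Cells uniform in a box, velocities from an analytic field plus noise.

    Adds a categorical ``region`` annotation (octant of the box) so loader
    and export paths exercise categorical columns.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.field_params.get("box", DEFAULT_BOX), dtype=float)
    coords = rng.uniform(box[0], box[1], size=(spec.n_cells, 3))
    fn = analytic_field(spec.field_kind, spec.field_params)
    velocities = fn(coords)
    if spec.noise_sd > 0:
        velocities = velocities + rng.normal(0.0, spec.noise_sd, size=velocities.shape)
    mid = box.mean(axis=0)
    octant = (
        (coords[:, 0] > mid[0]).astype(int) * 4
        + (coords[:, 1] > mid[1]).astype(int) * 2
        + (coords[:, 2] > mid[2]).astype(int)
    )
    return CellEmbedding(
        cell_ids=[f"cell_{i}" for i in range(spec.n_cells)],
        coords=coords,
        velocities=velocities,
        annotations={"region": np.array([f"octant_{o}" for o in octant], dtype=object)},
    )


def profile_value(shape: str, t: np.ndarray) -> np.ndarray:
    """A planted trend profile over path progress t in [0, 1]."""
    t = np.asarray(t, dtype=float)
    if shape == "monotone-up":
        return t
    if shape == "monotone-down":
        return 1.0 - t
    if shape == "transient-peak":
        return np.exp(-((t - 0.5) ** 2) / (2 * 0.15**2))
    raise ParameterError(f"unknown profile shape {shape!r}")


def make_trend_features(
    dataset: CellEmbedding,
    reference_path: Trajectory,
    profiles: list[str],
    noise_sd: float = 0.0,
    seed: int = 0,
    modality_name: str = "RNA",
) -> CellEmbedding:
    """Append a modality whose features follow planted trends along a path.

    Each cell's progress is the index of its nearest path point divided by
    (n_points - 1); each feature is its profile at that progress plus
    Gaussian noise.  Features are named ``{shape}_{i}``.
    """
    if reference_path.n_points < 2:
        raise ParameterError("reference path needs at least 2 points")
    rng = np.random.default_rng(seed)
    from scipy.spatial import cKDTree

    _, nearest = cKDTree(reference_path.points).query(dataset.coords)
    t = nearest / (reference_path.n_points - 1)
    values = np.column_stack([profile_value(shape, t) for shape in profiles])
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    feature_ids = [f"{shape}_{i}" for i, shape in enumerate(profiles)]
    return dataset.with_modality(
        ModalityMatrix(feature_ids=feature_ids, values=values, modality_name=modality_name)
    )


def add_clone_labels(
    dataset: CellEmbedding,
    n_clones: int,
    sentinel_fraction: float = 0.1,
    seed: int = 0,
) -> CellEmbedding:
    """Label an existing dataset's cells by nearest of random clone centers.

    Gives spatially coherent clones on any coordinate set without moving
    cells; a `sentinel_fraction` of cells is left unbarcoded.
    """
    if n_clones < 1:
        raise ParameterError(f"n_clones must be >= 1, got {n_clones}")
    rng = np.random.default_rng(seed)
    lo, hi = dataset.bounding_box()
    centers = rng.uniform(lo, hi, size=(n_clones, 3))
    nearest = np.argmin(
        ((dataset.coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    labels = np.array([f"clone_{c}" for c in nearest], dtype=object)
    labels[rng.random(dataset.n_cells) < sentinel_fraction] = NO_CLONE
    return dataset.with_clones(labels)


def make_clonal_dataset(
    spec: FixtureSpec,
    sentinel_fraction: float = 0.1,
    dispersed_fraction: float = 0.2,
    clone_sd: float = 0.6,
) -> tuple[CellEmbedding, pd.DataFrame]:
    """A clonally barcoded dataset plus its ground-truth membership table.

    Each clone's cells concentrate in a Gaussian blob around a random
    center (the "contiguous region") with a dispersed minority scattered
    uniformly; a `sentinel_fraction` of all cells carries no barcode.
    Returns ``(dataset, table)`` where the table has one row per cell with
    columns ``cell_id`` and ``clone_id`` (sentinel rows included), so the
    generator's own assignment can serve as the oracle for clone queries.
    """
    if spec.n_clones < 1:
        raise ParameterError(f"n_clones must be >= 1, got {spec.n_clones}")
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.field_params.get("box", DEFAULT_BOX), dtype=float)
    n = spec.n_cells
    labels = np.array([f"clone_{rng.integers(spec.n_clones)}" for _ in range(n)], dtype=object)
    centers = rng.uniform(box[0], box[1], size=(spec.n_clones, 3))
    coords = np.empty((n, 3))
    for i in range(n):
        c = centers[int(labels[i].split("_")[1])]
        if rng.random() < dispersed_fraction:
            coords[i] = rng.uniform(box[0], box[1])
        else:
            coords[i] = np.clip(rng.normal(c, clone_sd), box[0], box[1])
    unlabeled = rng.random(n) < sentinel_fraction
    labels[unlabeled] = NO_CLONE
    dataset = CellEmbedding(
        cell_ids=[f"cell_{i}" for i in range(n)],
        coords=coords,
        clones=labels.copy(),
    )
    table = pd.DataFrame({"cell_id": dataset.cell_ids, "clone_id": [str(c) for c in labels]})
    return dataset, table
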