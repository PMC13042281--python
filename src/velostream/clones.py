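"""Clonal-lineage queries on barcoded scRNA-seq data.

A user's "single click" is modeled as a sphere in embedding space: the
cells inside it are the query set, and the selection expands to every
cell sharing a clone barcode with a query cell.  Query cells and their
clonal relatives are reported separately; unbarcoded cells (the missing-
label sentinel) never relate cells to each other.  A clonal-enrichment
volume renders the expanded selection as a smooth scalar field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .datasets import NO_CLONE, CellEmbedding, ModalityMatrix
from .errors import EmptySelectionError, MissingCloneError, ParameterError
from .volume import RBFConfig, VolumeScalarField, volume_from_feature


@dataclass
class CloneQueryResult:
    """Query cells, their clonal relatives, and the clones they represent."""

    query_cells: set[int]
    related_cells: set[int]
    clone_ids: set[str]
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        if self.query_cells & self.related_cells:
            raise ParameterError("query and related cell sets must be disjoint")

    @property
    def all_cells(self) -> set[int]:
        return self.query_cells | self.related_cells

    def to_dataframe(self, dataset: CellEmbedding) -> pd.DataFrame:
        """Per-cell classification table; background cells are retained so
        downstream plots keep global context."""
        cls = np.full(dataset.n_cells, "background", dtype=object)
        for i in self.query_cells:
            cls[i] = "query"
        for i in self.related_cells:
            cls[i] = "related"
        clone = (
            [str(c) for c in dataset.clones]
            if dataset.clones is not None
            else [""] * dataset.n_cells
        )
        return pd.DataFrame(
            {"cell_id": dataset.cell_ids, "class": cls, "clone_id": clone}
        )


def select_sphere(
    dataset: CellEmbedding, center: np.ndarray, radius: float
) -> set[int]:
    """Indices of all cells within Euclidean distance `radius` of `center`."""
    if radius <= 0:
        raise ParameterError(f"radius must be positive, got {radius}")
    center = np.asarray(center, dtype=float).reshape(3)
    d = np.linalg.norm(dataset.coords - center, axis=1)
    return set(np.flatnonzero(d <= radius).tolist())


def expand_clones(
    dataset: CellEmbedding,
    query: set[int],
    center: Optional[np.ndarray] = None,
    radius: float = 1.0,
) -> CloneQueryResult:
    """Expand a query cell set to all clonally related cells.

    ``clone_ids`` are the barcodes carried by query cells (the missing-label
    sentinel excluded); ``related_cells`` are all non-query cells carrying
    any of those barcodes.
    """
    if not dataset.has_clones:
        raise MissingCloneError("dataset carries no clone labels")
    clones = dataset.clones
    query = {int(i) for i in query}
    clone_ids = {str(clones[i]) for i in query} - {NO_CLONE}
    related = {
        int(i)
        for i in np.flatnonzero(np.isin(clones.astype(str), sorted(clone_ids)))
        if int(i) not in query
    } if clone_ids else set()
    return CloneQueryResult(
        query_cells=query,
        related_cells=related,
        clone_ids=clone_ids,
        center=np.zeros(3) if center is None else np.asarray(center, dtype=float),
        radius=radius,
    )


def query_sphere_clones(
    dataset: CellEmbedding, center: np.ndarray, radius: float
) -> CloneQueryResult:
    """Convenience: sphere selection followed by clonal expansion."""
    query = select_sphere(dataset, center, radius)
    return expand_clones(dataset, query, center=center, radius=radius)


def clone_density_volume(
    dataset: CellEmbedding,
    result: CloneQueryResult,
    resolution: int = 10,
    config: Optional[RBFConfig] = None,
    seed: int = 0,
) -> VolumeScalarField:
    """Smooth clonal-enrichment volume of an expanded selection.

    Builds a 0/1 indicator over cells (1 for query and related cells) and
    interpolates it like any other feature, yielding a continuous picture
    of clone-associated regions that is easier to read than sparse point
    overlays when relatives are rare or dispersed.
    """
    selected = result.all_cells
    if not selected:
        raise EmptySelectionError("clone query selected no cells; nothing to render")
    indicator = np.zeros(dataset.n_cells)
    indicator[sorted(selected)] = 1.0
    tmp = dataset.with_modality(
        ModalityMatrix(
            feature_ids=["clone_indicator"],
            values=indicator[:, None],
            modality_name="_clones",
        )
    )
    return volume_from_feature(
        tmp, "_clones", "clone_indicator", resolution=resolution, config=config, seed=seed
    )
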