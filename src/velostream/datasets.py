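"""In-memory representation of a 3D-embedded single-cell dataset.

A :class:`CellEmbedding` bundles everything downstream analyses need:
3D embedding coordinates per cell, optional 3D velocity vectors projected
into the same embedding, categorical/continuous annotations, one feature
matrix per modality (RNA expression, ADT epitope levels, ...) and optional
clone-barcode labels for lineage-traced data.  Loaders for h5ad, h5mu and
delimited text all produce this one type, so the analysis modules are
format-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import VelostreamError

#: Sentinel clone label meaning "this cell carries no barcode".
NO_CLONE = ""


@dataclass
class ModalityMatrix:
    """A dense cells x features activity matrix for one modality."""

    feature_ids: list[str]
    values: np.ndarray  # (n_cells, n_features), float64
    modality_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise VelostreamError(
                f"modality {self.modality_name!r}: values must be 2-D, got shape {self.values.shape}"
            )
        if self.values.shape[1] != len(self.feature_ids):
            raise VelostreamError(
                f"modality {self.modality_name!r}: {len(self.feature_ids)} feature ids "
                f"but {self.values.shape[1]} value columns"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise VelostreamError(f"modality {self.modality_name!r}: duplicate feature ids")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(feature_id) from None

    def feature_values(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_index(feature_id)]


@dataclass
class CellEmbedding:
    """A validated, format-agnostic single-cell dataset in a 3D embedding.

    Parameters
    ----------
    cell_ids
        Unique per-cell identifiers.
    coords
        (n_cells, 3) embedding coordinates; must be finite.
    velocities
        Optional (n_cells, 3) velocity vectors in embedding units per unit
        pseudo-time, already projected into the embedding upstream.
    annotations
        Mapping annotation-name -> length-n_cells vector (categorical as
        object/str arrays, continuous as floats).
    modalities
        Mapping modality-name -> :class:`ModalityMatrix`.
    clones
        Optional length-n_cells clone labels; :data:`NO_CLONE` marks
        unbarcoded cells.
    """

    cell_ids: list[str]
    coords: np.ndarray
    velocities: Optional[np.ndarray] = None
    annotations: dict[str, np.ndarray] = field(default_factory=dict)
    modalities: dict[str, ModalityMatrix] = field(default_factory=dict)
    clones: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        n = len(self.cell_ids)
        if n < 1:
            raise VelostreamError("dataset must contain at least one cell")
        if len(set(self.cell_ids)) != n:
            raise VelostreamError("cell ids are not unique")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 3):
            raise VelostreamError(
                f"coords must have shape ({n}, 3), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise VelostreamError("coords contain non-finite values")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != (n, 3):
                raise VelostreamError(
                    f"velocities must have shape ({n}, 3), got {self.velocities.shape}"
                )
            if not np.all(np.isfinite(self.velocities)):
                raise VelostreamError("velocities contain non-finite values")
        for name, vec in self.annotations.items():
            arr = np.asarray(vec)
            if arr.shape[0] != n:
                raise VelostreamError(
                    f"annotation {name!r} has length {arr.shape[0]}, expected {n}"
                )
            self.annotations[name] = arr
        for name, mod in self.modalities.items():
            if mod.values.shape[0] != n:
                raise VelostreamError(
                    f"modality {name!r} has {mod.values.shape[0]} rows, expected {n}"
                )
        if self.clones is not None:
            arr = np.asarray(self.clones, dtype=object)
            if arr.shape[0] != n:
                raise VelostreamError(
                    f"clone labels have length {arr.shape[0]}, expected {n}"
                )
            self.clones = np.array([NO_CLONE if c is None else str(c) for c in arr], dtype=object)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def has_velocities(self) -> bool:
        return self.velocities is not None

    @property
    def has_clones(self) -> bool:
        return self.clones is not None

    def cell_index(self, cell_id: str) -> int:
        try:
            return self.cell_ids.index(cell_id)
        except ValueError:
            raise KeyError(cell_id) from None

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corners of the coordinate bounding box."""
        return self.coords.min(axis=0), self.coords.max(axis=0)

    def with_modality(self, modality: ModalityMatrix) -> "CellEmbedding":
        """Return a copy with `modality` added (or replaced) — non-mutating."""
        mods = dict(self.modalities)
        mods[modality.modality_name] = modality
        return replace(self, modalities=mods)

    def with_clones(self, clones: np.ndarray) -> "CellEmbedding":
        return replace(self, clones=clones)
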