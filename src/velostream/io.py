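"""Readers and writers for h5ad, h5mu and delimited text datasets.

All loaders return a :class:`~velostream.datasets.CellEmbedding`.  Only the
first three columns of an embedding array are used (the analyses are 3D
throughout); wider arrays are accepted with a logged notice.  Matrices are
densified on load — datasets at the scale these analyses target fit in
memory comfortably.
"""

from __future__ import annotations

import logging
from typing import Optional

import anndata as ad
import h5py
import numpy as np
import pandas as pd
from anndata.io import read_elem, write_elem

from .datasets import NO_CLONE, CellEmbedding, ModalityMatrix
from .errors import (
    AlignmentError,
    DimensionalityError,
    KeyLookupError,
    TableParseError,
)

log = logging.getLogger(__name__)

COORD_ROLES = ("x", "y", "z")
VELOCITY_ROLES = ("vx", "vy", "vz")


def _dense(x) -> np.ndarray:
    """Densify a possibly-sparse matrix to a float ndarray."""
    if hasattr(x, "toarray"):
        x = x.toarray()
    return np.asarray(x, dtype=float)


def _first3(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise DimensionalityError(
            f"array {name!r} has shape {arr.shape}; need at least 3 columns"
        )
    if arr.shape[1] > 3:
        log.info("array %r has %d columns; using the first 3", name, arr.shape[1])
    return arr[:, :3].copy()


def _annotations_from_obs(obs: pd.DataFrame) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for col in obs.columns:
        s = obs[col]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
            out[col] = s.to_numpy(dtype=float)
        else:
            out[col] = s.astype(str).to_numpy(dtype=object)
    return out


def _clones_from_annotations(
    annotations: dict[str, np.ndarray], clone_key: Optional[str], sentinel: str
) -> Optional[np.ndarray]:
    if clone_key is None:
        return None
    if clone_key not in annotations:
        raise KeyLookupError(clone_key, annotations.keys(), what="clone annotation")
    raw = annotations[clone_key]
    out = np.array(
        [NO_CLONE if (str(v) == sentinel or str(v) == "") else str(v) for v in raw],
        dtype=object,
    )
    return out


def _embedding_from_anndata(
    adata: ad.AnnData,
    coords_key: str,
    velocity_key: Optional[str],
    modality_name: str = "RNA",
    clone_key: Optional[str] = None,
    clone_sentinel: str = "nan",
) -> CellEmbedding:
    if coords_key not in adata.obsm:
        raise KeyLookupError(coords_key, adata.obsm.keys(), what="obsm key")
    coords = _first3(coords_key, np.asarray(adata.obsm[coords_key]))
    velocities = None
    if velocity_key is not None:
        if velocity_key not in adata.obsm:
            raise KeyLookupError(velocity_key, adata.obsm.keys(), what="obsm key")
        velocities = _first3(velocity_key, np.asarray(adata.obsm[velocity_key]))
    annotations = _annotations_from_obs(adata.obs)
    modality = ModalityMatrix(
        feature_ids=list(map(str, adata.var_names)),
        values=_dense(adata.X) if adata.X is not None else np.zeros((adata.n_obs, 0)),
        modality_name=modality_name,
    )
    return CellEmbedding(
        cell_ids=list(map(str, adata.obs_names)),
        coords=coords,
        velocities=velocities,
        annotations=annotations,
        modalities={modality_name: modality},
        clones=_clones_from_annotations(annotations, clone_key, clone_sentinel),
    )


def load_h5ad(
    path,
    coords_key: str,
    velocity_key: Optional[str] = None,
    clone_key: Optional[str] = None,
    clone_sentinel: str = "nan",
) -> CellEmbedding:
    """Load a single-modality AnnData (.h5ad) file.

    The expression matrix becomes a modality named ``"RNA"``; the first
    three columns of ``obsm[coords_key]`` (and of ``obsm[velocity_key]``
    when given) become coordinates and velocities.
    """
    adata = ad.read_h5ad(path)
    return _embedding_from_anndata(
        adata, coords_key, velocity_key, clone_key=clone_key, clone_sentinel=clone_sentinel
    )


def load_h5mu(
    path,
    coords_key: str,
    velocity_key: Optional[str] = None,
    coords_modality: str = "rna",
    clone_key: Optional[str] = None,
    clone_sentinel: str = "nan",
) -> CellEmbedding:
    """Load a multimodal (.h5mu, MuData on-disk layout) file.

    One :class:`ModalityMatrix` is produced per group under ``mod/``; all
    modalities must share the same cell set in the same order.  Coordinates
    and velocities are taken from ``coords_modality``'s obsm slots.
    """
    with h5py.File(path, "r") as f:
        if "mod" not in f:
            raise KeyLookupError("mod", f.keys(), what="h5mu group")
        mod_names = sorted(f["mod"].keys())
        adatas = {name: read_elem(f["mod"][name]) for name in mod_names}
    if coords_modality not in adatas:
        raise KeyLookupError(coords_modality, mod_names, what="modality")
    ref = adatas[coords_modality]
    ref_ids = list(map(str, ref.obs_names))
    for name, adata in adatas.items():
        ids = list(map(str, adata.obs_names))
        if ids != ref_ids:
            raise AlignmentError(
                f"modality {name!r} has {len(ids)} cells but modality "
                f"{coords_modality!r} has {len(ref_ids)}; cell sets must match"
            )
    emb = _embedding_from_anndata(
        ref,
        coords_key,
        velocity_key,
        modality_name=coords_modality,
        clone_key=clone_key,
        clone_sentinel=clone_sentinel,
    )
    for name, adata in adatas.items():
        if name == coords_modality:
            continue
        emb = emb.with_modality(
            ModalityMatrix(
                feature_ids=list(map(str, adata.var_names)),
                values=_dense(adata.X) if adata.X is not None else np.zeros((adata.n_obs, 0)),
                modality_name=name,
            )
        )
    return emb


def load_table(
    path,
    column_map: dict[str, str],
    delimiter: str = ",",
    modality_name: Optional[str] = "RNA",
    clone_sentinel: str = "nan",
) -> CellEmbedding:
    """Load a delimited text table (CSV/TSV with a header row).

    ``column_map`` assigns roles to column names: ``x``, ``y``, ``z``
    (required), ``vx``, ``vy``, ``vz`` (optional, all three or none),
    ``id`` (optional cell-id column), ``clone`` (optional clone label
    column) and ``annotations`` (optional list of annotation columns).
    Remaining numeric columns become a single modality named
    ``modality_name`` (pass None to discard them).  Row order is preserved;
    when no id column is mapped, ids ``cell_0..cell_{n-1}`` are synthesized.
    """
    df = pd.read_csv(path, sep=delimiter)
    for role in COORD_ROLES:
        if role not in column_map:
            raise KeyLookupError(role, column_map.keys(), what="column role")
    used_roles = [r for r in COORD_ROLES + VELOCITY_ROLES if r in column_map]
    for role in used_roles:
        col = column_map[role]
        if col not in df.columns:
            raise KeyLookupError(col, df.columns, what="column")
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} at data row {row}"
            )
        df[col] = parsed
    coords = df[[column_map[r] for r in COORD_ROLES]].to_numpy(dtype=float)
    velocities = None
    if any(r in column_map for r in VELOCITY_ROLES):
        if not all(r in column_map for r in VELOCITY_ROLES):
            raise KeyLookupError(
                "vx/vy/vz", column_map.keys(), what="complete velocity role set"
            )
        velocities = df[[column_map[r] for r in VELOCITY_ROLES]].to_numpy(dtype=float)

    if "id" in column_map:
        cell_ids = df[column_map["id"]].astype(str).tolist()
    else:
        cell_ids = [f"cell_{i}" for i in range(len(df))]

    annotations: dict[str, np.ndarray] = {}
    for col in column_map.get("annotations", []):
        if col not in df.columns:
            raise KeyLookupError(col, df.columns, what="column")
        annotations.update(_annotations_from_obs(df[[col]]))

    clones = None
    if "clone" in column_map:
        col = column_map["clone"]
        if col not in df.columns:
            raise KeyLookupError(col, df.columns, what="column")
        raw = df[col].astype(str).to_numpy(dtype=object)
        clones = np.array(
            [NO_CLONE if v in (clone_sentinel, "", "nan") else v for v in raw], dtype=object
        )

    reserved = {column_map[r] for r in used_roles}
    reserved |= {column_map[r] for r in ("id", "clone") if r in column_map}
    reserved |= set(column_map.get("annotations", []))
    modalities = {}
    if modality_name is not None:
        feat_cols = [
            c for c in df.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(df[c])
        ]
        if feat_cols:
            modalities[modality_name] = ModalityMatrix(
                feature_ids=feat_cols,
                values=df[feat_cols].to_numpy(dtype=float),
                modality_name=modality_name,
            )
    return CellEmbedding(
        cell_ids=cell_ids,
        coords=coords,
        velocities=velocities,
        annotations=annotations,
        modalities=modalities,
        clones=clones,
    )


# ---------------------------------------------------------------------------
# Writers (round-trip partners of the loaders)

def _to_anndata(dataset: CellEmbedding, modality: ModalityMatrix,
                coords_key: str, velocity_key: str) -> ad.AnnData:
    obs = pd.DataFrame(index=pd.Index(dataset.cell_ids, name="cell_id"))
    for name, vec in dataset.annotations.items():
        obs[name] = vec
    if dataset.clones is not None:
        obs["clone"] = [str(c) for c in dataset.clones]
    adata = ad.AnnData(
        X=modality.values.copy(),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(modality.feature_ids, name="feature_id")),
    )
    adata.obsm[coords_key] = dataset.coords.copy()
    if dataset.velocities is not None:
        adata.obsm[velocity_key] = dataset.velocities.copy()
    return adata


def write_h5ad(
    dataset: CellEmbedding,
    path,
    modality: str = "RNA",
    coords_key: str = "X_umap",
    velocity_key: str = "velocity_umap",
) -> None:
    """Write one modality of a dataset as an .h5ad file."""
    if modality in dataset.modalities:
        mod = dataset.modalities[modality]
    else:
        mod = ModalityMatrix([], np.zeros((dataset.n_cells, 0)), modality)
    _to_anndata(dataset, mod, coords_key, velocity_key).write_h5ad(path)


def write_h5mu(
    dataset: CellEmbedding,
    path,
    coords_modality: Optional[str] = None,
    coords_key: str = "X_umap",
    velocity_key: str = "velocity_umap",
) -> None:
    """Write all modalities of a dataset in the MuData on-disk layout."""
    if not dataset.modalities:
        raise KeyLookupError("(any)", [], what="modality")
    if coords_modality is None:
        coords_modality = sorted(dataset.modalities)[0]
    with h5py.File(path, "w") as f:
        f.attrs["encoding-type"] = "MuData"
        f.attrs["encoding-version"] = "0.1.0"
        mod_group = f.create_group("mod")
        for name, mod in dataset.modalities.items():
            if name == coords_modality:
                adata = _to_anndata(dataset, mod, coords_key, velocity_key)
            else:
                adata = ad.AnnData(
                    X=mod.values.copy(),
                    obs=pd.DataFrame(index=pd.Index(dataset.cell_ids, name="cell_id")),
                    var=pd.DataFrame(index=pd.Index(mod.feature_ids, name="feature_id")),
                )
            write_elem(mod_group, name, adata)


def write_table(
    dataset: CellEmbedding,
    path,
    delimiter: str = ",",
    modality: Optional[str] = "RNA",
) -> None:
    """Write a dataset as a delimited text table (loaders' round-trip partner)."""
    df = pd.DataFrame({"cell_id": dataset.cell_ids})
    df[["x", "y", "z"]] = dataset.coords
    if dataset.velocities is not None:
        df[["vx", "vy", "vz"]] = dataset.velocities
    for name, vec in dataset.annotations.items():
        df[name] = vec
    if dataset.clones is not None:
        df["clone"] = [str(c) if c != NO_CLONE else "" for c in dataset.clones]
    if modality is not None and modality in dataset.modalities:
        mod = dataset.modalities[modality]
        for j, fid in enumerate(mod.feature_ids):
            df[fid] = mod.values[:, j]
    df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Validation report

def validate_for_field(dataset: CellEmbedding) -> dict:
    """Report-only diagnostic of what a dataset can be used for.

    Returns a plain dict (JSON-serializable) with cell counts, bounding
    box, non-finite counts, and usability flags: a dataset without
    velocities cannot drive field averaging or integration but remains
    usable for volume interpolation and clonal queries.
    """
    lo, hi = dataset.bounding_box()
    flags = []
    if not dataset.has_velocities:
        flags.append("no-velocity")
    if not dataset.modalities:
        flags.append("no-modalities")
    if not dataset.has_clones:
        flags.append("no-clones")
    return {
        "n_cells": dataset.n_cells,
        "has_velocities": dataset.has_velocities,
        "nonfinite_coords": int((~np.isfinite(dataset.coords)).sum()),
        "nonfinite_velocities": (
            int((~np.isfinite(dataset.velocities)).sum()) if dataset.has_velocities else 0
        ),
        "bounding_box": {"min": lo.tolist(), "max": hi.tolist()},
        "modalities": {m: mod.n_features for m, mod in dataset.modalities.items()},
        "flags": flags,
        "usable_for_field": dataset.has_velocities,
        "usable_for_volume": bool(dataset.modalities),
        "usable_for_clones": dataset.has_clones,
    }
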