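"""Radial-basis-function interpolation of per-cell features onto dense grids.

A scattered per-cell feature (gene expression, epitope level, clone
indicator) is interpolated onto a regular grid of independently chosen
resolution, producing an isosurface-ready scalar volume.  The interpolant
solves the standard augmented RBF system with a degree-1 polynomial tail,

    | Phi + lambda I   P |  | c |   | y |
    |      P^T         0 |  | d | = | 0 | ,    s(x) = Phi(x) c + p(x) d

with P = [1, x, y, z] and kernel phi(r) one of gaussian
``exp(-(eps r)^2)``, linear ``r``, quadratic (thin-plate family)
``r^2 log r`` with ``phi(0) = 0``, or multiquadric
``sqrt(1 + (eps r)^2)``.  The polynomial tail is what makes the linear
and thin-plate kernels (which are only conditionally positive definite)
well posed, and it lets every kernel reproduce constant and affine
features exactly.  The smoothing weight lambda trades training-point
fidelity for smoothness (lambda -> infinity approaches the ordinary
least-squares plane).  Duplicate coordinates are averaged before fitting
so the system stays non-singular at zero smoothing; datasets larger than
``max_points`` are subsampled (seeded) to keep the dense solve
conditioned and fast.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import cdist

from .datasets import CellEmbedding
from .errors import KeyLookupError, ParameterError
from .field import GridSpec, build_grid

log = logging.getLogger(__name__)

KERNELS = ("gaussian", "linear", "quadratic", "multiquadric")


@dataclass
class RBFConfig:
    """Kernel choice and conditioning knobs for volume interpolation.

    epsilon is the kernel shape parameter (inverse embedding-length units);
    smoothing is the ridge weight lambda added to the system diagonal;
    value_range, when set, clamps evaluated node values for display.
    """

    kernel: str = "gaussian"
    epsilon: float = 1.0
    smoothing: float = 0.0
    max_points: int = 2000
    value_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ParameterError(
                f"kernel must be one of {KERNELS}, got {self.kernel!r}"
            )
        if self.epsilon <= 0:
            raise ParameterError(f"epsilon must be positive, got {self.epsilon}")
        if self.smoothing < 0:
            raise ParameterError(f"smoothing must be >= 0, got {self.smoothing}")
        if self.max_points < 4:
            raise ParameterError(f"max_points must be >= 4, got {self.max_points}")
        if self.value_range is not None:
            lo, hi = self.value_range
            if not lo < hi:
                raise ParameterError(f"value_range must satisfy lo < hi, got {self.value_range}")


def kernel_matrix(r: np.ndarray, kernel: str, epsilon: float) -> np.ndarray:
    """Apply the radial kernel phi elementwise to a distance array."""
    if kernel == "gaussian":
        return np.exp(-((epsilon * r) ** 2))
    if kernel == "linear":
        return r
    if kernel == "quadratic":
        out = np.zeros_like(r)
        pos = r > 0
        out[pos] = r[pos] ** 2 * np.log(r[pos])
        return out
    if kernel == "multiquadric":
        return np.sqrt(1.0 + (epsilon * r) ** 2)
    raise ParameterError(f"unknown kernel {kernel!r}")


def _poly_basis(points: np.ndarray) -> np.ndarray:
    """Degree-1 polynomial basis [1, x, y, z] evaluated at each point."""
    pts = np.atleast_2d(points)
    return np.column_stack([np.ones(len(pts)), pts])


@dataclass
class RBFInterpolant:
    """A fitted RBF interpolant, callable on (m, 3) query points."""

    centers: np.ndarray
    coefficients: np.ndarray      # kernel weights, one per center
    poly_coefficients: np.ndarray  # [constant, x, y, z] tail
    config: RBFConfig

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        phi = kernel_matrix(
            cdist(pts, self.centers), self.config.kernel, self.config.epsilon
        )
        return phi @ self.coefficients + _poly_basis(pts) @ self.poly_coefficients


def _average_duplicates(coords: np.ndarray, values: np.ndarray):
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return coords, values
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inverse, values)
    np.add.at(counts, inverse, 1.0)
    log.info("averaged %d duplicate coordinates before RBF fit", len(coords) - len(uniq))
    return uniq, sums / counts


def fit_rbf(
    coords: np.ndarray,
    values: np.ndarray,
    config: RBFConfig,
    seed: int = 0,
) -> RBFInterpolant:
    """Fit an RBF interpolant to scattered (coords, values).

    Rows with non-finite coordinates or values are dropped; at least 4
    finite points must remain.  When more than ``config.max_points`` points
    survive, a seeded uniform subsample of that size is fitted instead.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    values = np.asarray(values, dtype=float).ravel()
    if coords.shape[0] != values.shape[0]:
        raise ParameterError(
            f"{coords.shape[0]} coordinates but {values.shape[0]} values"
        )
    finite = np.all(np.isfinite(coords), axis=1) & np.isfinite(values)
    coords, values = coords[finite], values[finite]
    if len(values) < 4:
        raise ParameterError(
            f"need at least 4 finite points to fit an RBF, got {len(values)}"
        )
    if len(values) > config.max_points:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(values), size=config.max_points, replace=False))
        coords, values = coords[keep], values[keep]
    coords, values = _average_duplicates(coords, values)

    n = len(values)
    phi = kernel_matrix(cdist(coords, coords), config.kernel, config.epsilon)
    phi[np.diag_indices_from(phi)] += config.smoothing
    p = _poly_basis(coords)
    a = np.zeros((n + 4, n + 4))
    a[:n, :n] = phi
    a[:n, n:] = p
    a[n:, :n] = p.T
    rhs = np.concatenate([values, np.zeros(4)])
    try:
        sol = scipy.linalg.solve(a, rhs)
    except scipy.linalg.LinAlgError as e:
        raise ParameterError(
            f"RBF system is singular ({e}); increase smoothing or epsilon"
        ) from e
    return RBFInterpolant(
        centers=coords, coefficients=sol[:n], poly_coefficients=sol[n:], config=config
    )


@dataclass
class VolumeScalarField:
    """A dense scalar volume: one interpolated feature value per grid node."""

    grid: GridSpec
    values: np.ndarray  # shape grid.shape
    config: RBFConfig
    feature_id: str = ""
    modality_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ParameterError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("volume values contain non-finite entries")

    def to_dataframe(self) -> pd.DataFrame:
        idx = np.indices(self.grid.shape).reshape(3, -1).T
        pos = self.grid.origin + idx * self.grid.spacing
        return pd.DataFrame(
            {
                "i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2],
                "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
                "value": self.values.ravel(),
            }
        )


def evaluate_volume(
    interpolant: RBFInterpolant,
    grid: GridSpec,
    feature_id: str = "",
    modality_name: str = "",
) -> VolumeScalarField:
    """Evaluate an interpolant at every node of `grid`.

    Values outside the interpolant's ``value_range`` (when set) are clamped
    to the range bounds — clamping is display-range only and happens after
    evaluation.
    """
    vals = interpolant(grid.node_positions()).reshape(grid.shape)
    rng = interpolant.config.value_range
    if rng is not None:
        vals = np.clip(vals, rng[0], rng[1])
    return VolumeScalarField(
        grid=grid, values=vals, config=interpolant.config,
        feature_id=feature_id, modality_name=modality_name,
    )


def volume_from_feature(
    dataset: CellEmbedding,
    modality: str,
    feature_id: str,
    resolution: int = 10,
    config: Optional[RBFConfig] = None,
    padding_fraction: float = 0.05,
    seed: int = 0,
) -> VolumeScalarField:
    """Interpolate one feature of one modality onto its own dense grid.

    The volume grid's resolution is independent of any vector-field grid.
    Unknown feature ids raise a lookup error listing near matches.
    """
    config = config or RBFConfig()
    if modality not in dataset.modalities:
        raise KeyLookupError(modality, dataset.modalities.keys(), what="modality")
    mod = dataset.modalities[modality]
    if feature_id not in mod.feature_ids:
        near = difflib.get_close_matches(feature_id, mod.feature_ids, n=5)
        raise KeyLookupError(feature_id, near or ["(no near matches)"], what="feature")
    grid = build_grid(dataset.coords, resolution, padding_fraction)
    interp = fit_rbf(dataset.coords, mod.feature_values(feature_id), config, seed=seed)
    return evaluate_volume(interp, grid, feature_id=feature_id, modality_name=modality)
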