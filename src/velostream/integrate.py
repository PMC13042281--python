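"""Field-line integration through a grid vector field.

Trajectories are integrated with fixed-step Euler or classical
fourth-order Runge-Kutta.  Integration stops after the configured number
of steps, when a step displaces less than the difference threshold
(stationary flow), or when the next point would leave the grid bounding
box — the last in-domain point is kept and the trajectory is flagged.
RK4 intermediate evaluations that fall outside the box use the sampler's
zero-vector convention rather than aborting the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .datasets import CellEmbedding
from .errors import KeyLookupError, ParameterError
from .field import GridVectorField, sample_field

TERMINATION_COMPLETED = "completed"
TERMINATION_BELOW_THRESHOLD = "below-threshold"
TERMINATION_OUT_OF_DOMAIN = "out-of-domain"


@dataclass
class IntegrationConfig:
    """Fixed-step integration settings.

    step_size is in pseudo-time units (a step displaces by roughly
    ``step_size * |v|``); diff_threshold is in embedding units and stops
    integration early once a step's Euclidean displacement falls below it.
    """

    method: str = "rk4"
    step_size: float = 0.1
    n_steps: int = 100
    diff_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if self.method not in ("euler", "rk4"):
            raise ParameterError(f"method must be 'euler' or 'rk4', got {self.method!r}")
        if self.step_size == 0:
            raise ParameterError("step_size must be non-zero")
        if self.n_steps < 1:
            raise ParameterError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.diff_threshold < 0:
            raise ParameterError(f"diff_threshold must be >= 0, got {self.diff_threshold}")


@dataclass
class Trajectory:
    """An integrated field line: ordered points, seed, and why it stopped."""

    points: np.ndarray  # (n_points, 3)
    seed: np.ndarray
    termination: str
    config: IntegrationConfig

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.seed = np.asarray(self.seed, dtype=float).reshape(3)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def endpoint(self) -> np.ndarray:
        return self.points[-1]


@dataclass
class StreamlineSet:
    """A bundle of trajectories from a common seeding strategy."""

    trajectories: list[Trajectory]
    seeding: str = "grid-nodes"
    streamlet_steps: Optional[int] = None

    def __len__(self) -> int:
        return len(self.trajectories)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t_id, traj in enumerate(self.trajectories):
            for step, p in enumerate(traj.points):
                rows.append((t_id, step, p[0], p[1], p[2], traj.termination))
        return pd.DataFrame(
            rows, columns=["trajectory_id", "step", "x", "y", "z", "termination"]
        )


def euler_step(field: GridVectorField, point: np.ndarray, h: float) -> np.ndarray:
    """One forward-Euler step: ``point + h * v(point)``."""
    return np.asarray(point, dtype=float) + h * sample_field(field, point)


def rk4_step(field: GridVectorField, point: np.ndarray, h: float) -> np.ndarray:
    """One classical fourth-order Runge-Kutta step."""
    p = np.asarray(point, dtype=float)
    k1 = sample_field(field, p)
    k2 = sample_field(field, p + 0.5 * h * k1)
    k3 = sample_field(field, p + 0.5 * h * k2)
    k4 = sample_field(field, p + h * k3)
    return p + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


_STEPPERS: dict[str, Callable] = {"euler": euler_step, "rk4": rk4_step}


def integrate(
    field: GridVectorField, seed: np.ndarray, config: IntegrationConfig
) -> Trajectory:
    """Integrate a field line from `seed` under `config`.

    A seed outside the grid bounding box yields a single-point trajectory
    flagged out-of-domain.  A tentative next point outside the box is
    discarded (last in-domain point kept).  Zero-displacement steps always
    stop the trajectory, so consecutive duplicate points never occur.
    """
    seed = np.asarray(seed, dtype=float).reshape(3)
    stepper = _STEPPERS[config.method]
    if not field.grid.contains(seed[None, :])[0]:
        return Trajectory([seed], seed, TERMINATION_OUT_OF_DOMAIN, config)
    points = [seed]
    p = seed
    termination = TERMINATION_COMPLETED
    for _ in range(config.n_steps):
        nxt = stepper(field, p, config.step_size)
        if not field.grid.contains(nxt[None, :])[0]:
            termination = TERMINATION_OUT_OF_DOMAIN
            break
        disp = float(np.linalg.norm(nxt - p))
        if disp < config.diff_threshold or disp == 0.0:
            termination = TERMINATION_BELOW_THRESHOLD
            break
        points.append(nxt)
        p = nxt
    return Trajectory(np.array(points), seed, termination, config)


def seed_from_cell(dataset: CellEmbedding, cell_id: str) -> np.ndarray:
    """The embedding coordinates of a named cell, as an integration seed."""
    try:
        i = dataset.cell_index(cell_id)
    except KeyError:
        raise KeyLookupError(cell_id, dataset.cell_ids[:20], what="cell id") from None
    return dataset.coords[i].copy()


def generate_streamlines(
    field: GridVectorField,
    config: IntegrationConfig,
    density: float = 1.0,
    min_occupancy: int = 1,
    seed: int = 0,
) -> StreamlineSet:
    """Integrate streamlines from a random subset of occupied grid nodes.

    Candidate seeds are all nodes with occupancy >= `min_occupancy`;
    ``floor(density * n_candidates)`` of them are drawn uniformly without
    replacement (deterministic under `seed`) and integrated.  Trajectories
    shorter than 2 points are dropped.
    """
    if not (0 < density <= 1):
        raise ParameterError(f"density must be in (0, 1], got {density}")
    occ = field.occupancy.ravel()
    candidates = np.flatnonzero(occ >= min_occupancy)
    n_take = int(np.floor(density * len(candidates)))
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(candidates, size=n_take, replace=False)) if n_take else []
    positions = field.grid.node_positions()
    trajectories = [
        t for i in chosen
        if (t := integrate(field, positions[i], config)).n_points >= 2
    ]
    return StreamlineSet(trajectories=trajectories, seeding="grid-nodes")


def make_streamlets(lines: StreamlineSet, streamlet_steps: int) -> StreamlineSet:
    """Truncate each streamline to its first ``streamlet_steps + 1`` points.

    Streamlets are forward-time prefixes, preserving the flow direction a
    color gradient along the line conveys.
    """
    if streamlet_steps < 1:
        raise ParameterError(f"streamlet_steps must be >= 1, got {streamlet_steps}")
    out = []
    for traj in lines.trajectories:
        pts = traj.points[: streamlet_steps + 1]
        out.append(Trajectory(pts, traj.seed, traj.termination, traj.config))
    return StreamlineSet(
        trajectories=out, seeding=lines.seeding, streamlet_steps=streamlet_steps
    )


def trajectory_to_dataframe(traj: Trajectory, trajectory_id: int = 0) -> pd.DataFrame:
    return StreamlineSet([traj]).to_dataframe().assign(trajectory_id=trajectory_id)
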