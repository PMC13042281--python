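"""End-to-end analysis pipeline with a reproducible run record.

A :class:`RunConfig` fully determines a run: input (file or synthetic
fixture), grid/field settings, integration, and the optional analysis
stages (streamlines, single-cell trajectory, feature volume, trajectory
trends, clonal query).  ``run_pipeline`` executes the stages in workflow
order, exports CSV/JSON tables plus an HTML scene, and returns a
manifest listing every artifact with its content checksum — rerunning
the same config regenerates byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .clones import query_sphere_clones
from .datasets import CellEmbedding
from .errors import VelostreamError
from .export import SceneComponent, export_scene, sha256_of
from .field import build_grid, average_velocities, cone_glyphs, glyphs_to_dataframe
from .integrate import (
    IntegrationConfig,
    StreamlineSet,
    Trajectory,
    generate_streamlines,
    integrate,
    make_streamlets,
    seed_from_cell,
    trajectory_to_dataframe,
)
from .synthetic import FixtureSpec, add_clone_labels, make_field_dataset, make_trend_features
from .trends import assign_segments, cluster_trends, heatmap_table, order_clusters, segment_means
from .volume import RBFConfig, volume_from_feature

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, serializable description of one pipeline run.

    Dotted config-file keys mirror the attribute sections below; CLI
    flags override file values.  The global `seed` drives streamline
    subsampling, RBF subsampling, k-means initialization and fixture
    generation, so a serialized RunConfig reproduces a run bit-for-bit
    given the same input files.
    """

    # input
    input_path: Optional[str] = None
    input_format: str = "fixture"          # fixture | h5ad | h5mu | csv
    coords_key: str = "X_umap"
    velocity_key: Optional[str] = "velocity_umap"
    coords_modality: str = "rna"
    column_map: dict = dc_field(default_factory=lambda: {
        "x": "x", "y": "y", "z": "z", "vx": "vx", "vy": "vy", "vz": "vz", "id": "cell_id",
    })
    # fixture (used when input_format == "fixture")
    fixture_kind: str = "linear-sink"
    fixture_n_cells: int = 500
    fixture_noise_sd: float = 0.05
    fixture_n_features: int = 12
    fixture_n_clones: int = 5
    # grid / field
    grid_resolution: int = 15
    grid_padding: float = 0.05
    grid_scale: float = 1.0
    field_method: str = "bin-mean"
    field_bandwidth: Optional[float] = None
    # integration
    method: str = "rk4"
    step_size: float = 0.1
    n_steps: int = 60
    diff_threshold: float = 1e-6
    # streamlines
    streamlines: bool = True
    density: float = 0.25
    min_occupancy: int = 1
    streamlet_steps: Optional[int] = None
    # single-cell trajectory
    seed_cell: Optional[str] = None
    trajectory_file: Optional[str] = None
    # volume
    volume: bool = False
    volume_modality: str = "RNA"
    volume_feature: Optional[str] = None
    volume_resolution: int = 8
    volume_kernel: str = "gaussian"
    volume_epsilon: float = 1.0
    volume_smoothing: float = 0.0
    volume_range: Optional[tuple[float, float]] = None
    # trends
    trends: bool = False
    trends_modality: str = "RNA"
    n_segments: int = 8
    trend_radius: float = 2.0
    k_clusters: int = 4
    normalization: str = "zscore"
    top_n: Optional[int] = None
    # clones
    clones: bool = False
    clone_center: Optional[tuple[float, float, float]] = None
    clone_radius: float = 1.0
    # run-level
    out_dir: str = "velostream_out"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise VelostreamError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("volume_range", "clone_center"):
            v = getattr(cfg, name)
            if v is not None:
                setattr(cfg, name, tuple(v))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def integration_config(self) -> IntegrationConfig:
        return IntegrationConfig(
            method=self.method,
            step_size=self.step_size,
            n_steps=self.n_steps,
            diff_threshold=self.diff_threshold,
        )

    def rbf_config(self) -> RBFConfig:
        return RBFConfig(
            kernel=self.volume_kernel,
            epsilon=self.volume_epsilon,
            smoothing=self.volume_smoothing,
            value_range=self.volume_range,
        )


def _load_dataset(config: RunConfig) -> CellEmbedding:
    fmt = config.input_format
    if fmt == "fixture":
        spec = FixtureSpec(
            n_cells=config.fixture_n_cells,
            field_kind=config.fixture_kind,
            noise_sd=config.fixture_noise_sd,
            seed=config.seed,
        )
        ds = make_field_dataset(spec)
        if config.fixture_n_features > 0:
            lo, hi = ds.bounding_box()
            path = Trajectory(
                np.linspace(lo, hi, 20), lo, "completed",
                IntegrationConfig(),
            )
            shapes = ["monotone-up", "monotone-down", "transient-peak"]
            profiles = [shapes[i % 3] for i in range(config.fixture_n_features)]
            ds = make_trend_features(ds, path, profiles, noise_sd=config.fixture_noise_sd,
                                     seed=config.seed)
        if config.fixture_n_clones > 0:
            ds = add_clone_labels(ds, config.fixture_n_clones, seed=config.seed)
        return ds
    if fmt == "h5ad":
        return vio.load_h5ad(config.input_path, config.coords_key, config.velocity_key)
    if fmt == "h5mu":
        return vio.load_h5mu(
            config.input_path, config.coords_key, config.velocity_key,
            coords_modality=config.coords_modality,
        )
    if fmt == "csv":
        return vio.load_table(config.input_path, config.column_map)
    raise VelostreamError(f"unknown input format {fmt!r}")


def trajectory_from_csv(path) -> Trajectory:
    """Read back a trajectory exported by this package (first trajectory_id)."""
    df = pd.read_csv(path)
    df = df[df["trajectory_id"] == df["trajectory_id"].iloc[0]].sort_values("step")
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    term = str(df["termination"].iloc[-1])
    return Trajectory(pts, pts[0], term, IntegrationConfig())


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    Workflow order: load -> validate -> grid/field -> streamlines /
    trajectory -> volume / trends / clones -> scene export.  A stage whose
    prerequisites are missing (e.g. field averaging without velocities) is
    skipped with a notice recorded in the manifest; a stage that raises
    aborts the run with a stage-named error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "artifacts": []}
    scene: list[SceneComponent] = []

    def record(name: str, path: Path) -> None:
        manifest["artifacts"].append(
            {"name": name, "path": str(path), "sha256": sha256_of(path)}
        )

    def stage(name: str):
        def wrap(fn):
            try:
                result = fn()
            except VelostreamError as e:
                manifest["stages"][name] = {"status": "error", "message": str(e)}
                raise VelostreamError(f"stage {name!r} failed: {e}") from e
            manifest["stages"][name] = {"status": "ok", **(result or {})}
        return wrap

    # --- load + validate -------------------------------------------------
    holder: dict = {}

    @stage("load")
    def _():
        holder["dataset"] = _load_dataset(config)
        return {"n_cells": holder["dataset"].n_cells}

    dataset: CellEmbedding = holder["dataset"]

    @stage("validate")
    def _():
        report = vio.validate_for_field(dataset)
        p = out / "validation.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True))
        record("validation", p)
        return {"flags": report["flags"]}

    # --- grid / field ----------------------------------------------------
    field = None
    if dataset.has_velocities:
        @stage("field")
        def _():
            grid = build_grid(
                dataset.coords, config.grid_resolution, config.grid_padding,
                scale=config.grid_scale,
            )
            holder["field"] = average_velocities(
                dataset, grid, method=config.field_method, bandwidth=config.field_bandwidth
            )
            p = out / "field.csv"
            holder["field"].to_dataframe().to_csv(p, index=False)
            record("field", p)
            glyphs = glyphs_to_dataframe(cone_glyphs(holder["field"]))
            scene.append(SceneComponent("cones", glyphs))
            return {"grid_shape": list(grid.shape), "occupied_nodes": int((holder["field"].occupancy > 0).sum())}
        field = holder["field"]
    else:
        manifest["stages"]["field"] = {
            "status": "skipped", "message": "dataset has no velocities",
        }
        log.info("field stage skipped: dataset has no velocities")

    scatter = pd.DataFrame(dataset.coords, columns=["x", "y", "z"])
    scatter.insert(0, "cell_id", dataset.cell_ids)
    scene.append(SceneComponent("scatter", scatter))

    # --- streamlines -----------------------------------------------------
    if config.streamlines and field is not None:
        @stage("streamlines")
        def _():
            lines = generate_streamlines(
                field, config.integration_config(),
                density=config.density, min_occupancy=config.min_occupancy,
                seed=config.seed,
            )
            if config.streamlet_steps is not None:
                lines = make_streamlets(lines, config.streamlet_steps)
            holder["streamlines"] = lines
            p = out / "streamlines.csv"
            lines.to_dataframe().to_csv(p, index=False)
            record("streamlines", p)
            scene.append(SceneComponent("streamlines", lines.to_dataframe()))
            return {"n_streamlines": len(lines)}

    # --- single-cell trajectory -----------------------------------------
    trajectory = None
    if config.trajectory_file is not None:
        trajectory = trajectory_from_csv(config.trajectory_file)
        manifest["stages"]["trajectory"] = {"status": "ok", "source": "file"}
    elif config.seed_cell is not None and field is not None:
        @stage("trajectory")
        def _():
            seed_pt = seed_from_cell(dataset, config.seed_cell)
            holder["trajectory"] = integrate(field, seed_pt, config.integration_config())
            p = out / "trajectory.csv"
            trajectory_to_dataframe(holder["trajectory"]).to_csv(p, index=False)
            record("trajectory", p)
            scene.append(SceneComponent("trajectory", trajectory_to_dataframe(holder["trajectory"])))
            return {"n_points": holder["trajectory"].n_points,
                    "termination": holder["trajectory"].termination}
        trajectory = holder["trajectory"]

    # --- volume ----------------------------------------------------------
    if config.volume and config.volume_feature is not None:
        @stage("volume")
        def _():
            vol = volume_from_feature(
                dataset, config.volume_modality, config.volume_feature,
                resolution=config.volume_resolution, config=config.rbf_config(),
                seed=config.seed,
            )
            p = out / "volume.csv"
            vol.to_dataframe().to_csv(p, index=False)
            record("volume", p)
            scene.append(SceneComponent("volume", vol.to_dataframe()))
            return {"feature": config.volume_feature}

    # --- trends ----------------------------------------------------------
    if config.trends and trajectory is not None and config.trends_modality in dataset.modalities:
        @stage("trends")
        def _():
            assignment = assign_segments(
                trajectory, dataset, config.n_segments, config.trend_radius
            )
            trend = segment_means(
                assignment, dataset.modalities[config.trends_modality],
                normalization=config.normalization,
            )
            clustering = order_clusters(
                cluster_trends(trend, config.k_clusters, seed=config.seed, top_n=config.top_n)
            )
            table = heatmap_table(trend, clustering)
            p = out / "trend_heatmap.csv"
            table.to_csv(p, index=False)
            record("trend_heatmap", p)
            return {"n_assigned": assignment.n_assigned, "k": clustering.k}

    # --- clones ----------------------------------------------------------
    if config.clones and dataset.has_clones and config.clone_center is not None:
        @stage("clones")
        def _():
            result = query_sphere_clones(
                dataset, np.asarray(config.clone_center), config.clone_radius
            )
            p = out / "clones.csv"
            result.to_dataframe(dataset).to_csv(p, index=False)
            record("clones", p)
            return {"n_query": len(result.query_cells), "n_related": len(result.related_cells)}

    # --- scene -----------------------------------------------------------
    @stage("scene")
    def _():
        p = out / "scene.html"
        export_scene(scene, p, format="html")
        record("scene", p)
        return {"n_components": len(scene)}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
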