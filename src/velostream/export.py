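"""Scene and table export.

CSV/JSON tables are the canonical, byte-reproducible outputs; the HTML
scene is a self-contained document embedding the component tables as
JSON for interactive viewing, and static raster/vector export goes
through matplotlib (excluded from byte-exact guarantees).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ParameterError

SCENE_KINDS = ("scatter", "cones", "streamlines", "volume", "trajectory")
SCENE_FORMATS = ("html", "png", "svg", "csv-bundle")

PALETTES = {
    "default": ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd"],
    # Okabe-Ito, safe for the common color-vision deficiencies
    "colorblind": ["#0072B2", "#E69F00", "#009E73", "#D55E00", "#CC79A7"],
}


@dataclass
class SceneComponent:
    """One layer of a 3D scene: a kind tag plus its underlying table."""

    kind: str
    table: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in SCENE_KINDS:
            raise ParameterError(f"kind must be one of {SCENE_KINDS}, got {self.kind!r}")
        if not self.name:
            self.name = self.kind


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _scene_html(components: list[SceneComponent], palette: str) -> str:
    payload = {
        "components": [
            {
                "kind": c.kind,
                "name": c.name,
                "columns": list(c.table.columns),
                "rows": c.table.to_numpy().tolist(),
            }
            for c in components
        ]
    }
    style = {"palette": palette, "colors": PALETTES[palette]}
    summary = "".join(
        f"<li><b>{c.name}</b> ({c.kind}): {len(c.table)} rows</li>" for c in components
    )
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>velostream scene</title></head><body>\n"
        "<h1>velostream 3D scene</h1>\n"
        f"<ul>{summary}</ul>\n"
        f"<script id='scene-style' type='application/json'>{json.dumps(style)}</script>\n"
        "<script id='scene-data' type='application/json'>"
        f"{json.dumps(payload)}</script>\n"
        "</body></html>\n"
    )


def export_scene(
    components: list[SceneComponent],
    path,
    format: str = "html",
    palette: str = "default",
) -> Path:
    """Write a layered scene to `path` in the requested format.

    ``html`` embeds every component's data table; ``csv-bundle`` writes one
    CSV per component into the directory `path`; ``png``/``svg`` render a
    static 3D view via matplotlib.  The palette option affects style
    metadata only, never the data tables.
    """
    if not components:
        raise ParameterError("scene needs at least one component")
    if format not in SCENE_FORMATS:
        raise ParameterError(f"format must be one of {SCENE_FORMATS}, got {format!r}")
    if palette not in PALETTES:
        raise ParameterError(f"palette must be one of {sorted(PALETTES)}, got {palette!r}")
    path = Path(path)
    if format == "html":
        path.write_text(_scene_html(components, palette))
        return path
    if format == "csv-bundle":
        path.mkdir(parents=True, exist_ok=True)
        for i, c in enumerate(components):
            c.table.to_csv(path / f"{i:02d}_{c.name}.csv", index=False)
        return path
    # static raster/vector render
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    colors = PALETTES[palette]
    for i, c in enumerate(components):
        color = colors[i % len(colors)]
        t = c.table
        if c.kind in ("scatter", "cones", "volume") and {"x", "y", "z"} <= set(t.columns):
            ax.scatter(t["x"], t["y"], t["z"], s=4, color=color, label=c.name, alpha=0.6)
        elif c.kind in ("streamlines", "trajectory") and "trajectory_id" in t.columns:
            for _, grp in t.groupby("trajectory_id"):
                ax.plot(grp["x"], grp["y"], grp["z"], color=color, lw=0.8)
    ax.legend(loc="upper right", fontsize=7)
    fig.savefig(path, format=format)
    plt.close(fig)
    return path
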