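# velostream

Headless analysis of single-cell differentiation dynamics in a **3D
embedding**: grid-averaged RNA-velocity vector fields, Euler / fourth-order
Runge–Kutta field-line integration (streamlines, streamlets, cone glyphs),
radial-basis-function volumetric interpolation of per-cell features,
trajectory-neighborhood feature-trend heatmap tables, and clonal-lineage
queries on barcoded scRNA-seq data.

It is written for single-cell researchers who already have a 3-component
embedding (for example a 3D UMAP) with per-cell velocity vectors projected
into it by an upstream package (scVelo, UnitVelo, ...), and who want to
compute — scripted, reproducibly, without a GUI — the geometric objects
that make those dynamics interpretable.

## The computations at the core

**Vector field.** Per-cell velocities $v_i \in \mathbb{R}^3$ are averaged
onto a regular grid: either the arithmetic mean over the cells nearest
each node (bin mean) or a Gaussian-kernel weighted mean with weight
$\exp(-d^2/2\sigma^2)$. Between nodes the field is evaluated by trilinear
interpolation, scaled by a user `scale` factor; outside the grid the field
is zero and trajectories terminate.

**Integration.** Field lines solve $\dot{x} = v(x)$ with fixed-step Euler
($x_{n+1} = x_n + h\,v(x_n)$) or classical RK4
($x_{n+1} = x_n + \tfrac{h}{6}(k_1 + 2k_2 + 2k_3 + k_4)$). Integration
stops after `n_steps`, when a step displaces less than the difference
threshold, or at the grid boundary.

**Volumes.** A scattered feature $y_i$ at positions $x_i$ is interpolated
with the standard augmented RBF system
$s(x) = \sum_j c_j\,\varphi(\lVert x - x_j\rVert) + d_0 + d^\top x$, with
kernels Gaussian $e^{-(\varepsilon r)^2}$, linear $r$, quadratic (thin-plate
family) $r^2 \log r$, or multiquadric $\sqrt{1 + (\varepsilon r)^2}$, and a
ridge weight $\lambda$ on the kernel diagonal for smoothing.

**Trends.** Cells within a radius of a trajectory are assigned to equal
step-index segments; per-segment mean activities form a features × segments
matrix, normalized (z-score or relative-to-first-segment), clustered with
seeded k-means, and ordered for display: up-regulated profiles first by
the position of their maximum, down-regulated after by the position of
their minimum.

**Clones.** A spherical selection is expanded to every cell sharing a
clone barcode with a selected cell; query cells, clonal relatives and
background are reported separately, and the expanded set can be rendered
as a smooth clonal-enrichment volume.

## Worked example

```python
import numpy as np
import velostream as vs

ds = vs.make_field_dataset(
    vs.FixtureSpec(n_cells=2000, field_kind="linear-sink", noise_sd=0.1, seed=0)
)
grid = vs.build_grid(ds.coords, resolution=10)
field = vs.average_velocities(ds, grid, method="gaussian-kernel")
cfg = vs.IntegrationConfig(method="rk4", step_size=0.05, n_steps=200)
lines = vs.generate_streamlines(field, cfg, density=0.2, seed=0)

center = np.array([5.0, 5.0, 5.0])
seed_d = np.mean([np.linalg.norm(t.seed - center) for t in lines.trajectories])
end_d = np.mean([np.linalg.norm(t.endpoint - center) for t in lines.trajectories])
print(len(lines), round(seed_d, 2), "->", round(end_d, 2))
```

prints

```
199 5.99 -> 0.06
```

199 streamlines were seeded across the grid; their seeds start on average
5.99 embedding units from the planted attractor and their endpoints finish
0.06 units from it — the averaged field preserves the sink the synthetic
velocities encode, and RK4 integration follows it in. The scripts in
`examples/` walk through each capability the same way (field + streamlines,
convergence orders, volumes, trend heatmaps, clonal queries) and print what
the numbers mean.

A thin CLI mirrors the library (`velostream fixtures | field | streamlines |
trajectory | volume | trends | clones | run`); `velostream run --config
cfg.yaml` executes the full pipeline and writes CSV/JSON tables, an HTML
scene and a manifest of artifact checksums.

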