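# Methods

This note documents the models and numerical choices behind velostream:
what each computation assumes, which parameters matter, and what the
synthetic data used in the tests does and does not establish about real
single-cell datasets.

## Scope and assumptions

velostream operates strictly downstream of velocity estimation. Cells
arrive with 3D embedding coordinates and (optionally) 3-component velocity
vectors already projected into that embedding; the package never touches
spliced/unspliced counts, transition-probability matrices, normalization or
dimensionality reduction. Embeddings with more than three components are
truncated to their first three columns with a logged notice — every
analysis here is inherently 3D. All matrices are densified on load;
datasets at the scale these analyses target (10^4–10^6 cells, a few
thousand retained features) fit comfortably in memory. Indexing is 0-based
throughout and voxels are half-open intervals `[node, node + spacing)`.

## Grid and vector field

`build_grid(coords, resolution, padding_fraction)` covers the (padded)
data bounding box with a regular grid. `resolution` counts nodes along the
longest axis; a shorter axis of extent ratio ρ gets
`ceil((resolution−1)·ρ) + 1` nodes (floor 2), which keeps voxels close to
cubic so integration behaves isotropically. A zero-extent axis gets two
nodes of unit spacing centered on the data. Defaults: resolution 15,
padding 5% per side.

Two averaging estimators are provided because the averaging rule is a
genuine design freedom:

- **bin-mean** (default): each node takes the arithmetic mean over the
  cells whose nearest node it is. Unbiased within a voxel, but leaves
  zero vectors at unoccupied nodes — on grids much finer than the cell
  density, trilinear sampling then mixes in zeros and weakens the field.
- **gaussian-kernel**: kernel-weighted mean over all cells,
  σ = `bandwidth` (default half the largest voxel edge); occupancy counts
  cells within 3σ. Smoother and hole-free near data, at the cost of
  spatial resolution.

Grid vectors are not smoothed after averaging. The `scale` parameter
multiplies sampled vectors (hence step displacements and glyph lengths)
without moving node positions.

Field evaluation between nodes is trilinear over the 8 surrounding nodes —
exact for affine fields, convexity-preserving, cheap. Outside the grid
bounding box the sampler returns the zero vector with an out-of-domain
flag rather than extrapolating, so trajectories terminate cleanly at the
hull. Nearest-node lookup would be the obvious cheaper fallback; it was
not added because trilinear already dominates no part of the runtime.

## Integration

Fixed-step Euler and classical RK4, forward time only (a negative
`step_size` is accepted for exploration). Termination is
threefold: the configured step count; a step whose Euclidean displacement
falls below `diff_threshold` (a zero-displacement step always stops, so
trajectories never contain consecutive duplicates); or a tentative next
point outside the grid box, in which case the last in-domain point is
kept and the trajectory is flagged. RK4's intermediate evaluations may
probe outside the box; they use the sampler's zero-vector convention
rather than aborting, matching the sampler's contract. `diff_threshold`
compares a single step's displacement — the simplest monotone stopping
rule consistent with the parameter's name.

Streamline seeding draws `floor(density · n_candidates)` occupied nodes
uniformly without replacement from a seeded generator, so a run is
reproducible bit-for-bit. Streamlets are forward prefixes (first
`streamlet_steps + 1` points) rather than centered windows: prefixes
preserve the flow direction that color gradients along the line convey.

On the analytic linear sink v(x) = −(x−c), whose flow is
x(t) = c + (x₀−c)e^{−t}, the test suite verifies the textbook behavior:
endpoint error ratios ≈ 2 (Euler) and ≈ 16 (RK4) under step halving, and
a 100-step RK4 trajectory at h = 0.05 within 1e−6 of the closed form.

## RBF volumes

Feature volumes solve the standard augmented RBF system with a degree-1
polynomial tail and moment conditions:

    | Φ + λI   P | | c |   | y |
    | Pᵀ       0 | | d | = | 0 |,   s(x) = Φ(x)c + d₀ + d·x

with kernels gaussian `exp(−(εr)²)`, linear `r`, quadratic (thin-plate
family) `r² log r` with φ(0) = 0, multiquadric `sqrt(1+(εr)²)`. The
polynomial tail is not optional decoration: the linear and thin-plate
kernels are only *conditionally* positive definite, and the tail is what
makes their systems well posed. It also buys exact reproduction of
constant and affine features for every kernel — without it, a planted
linear feature shows O(0.1) errors at sparsely supported grid corners.
"Quadratic" follows the standard quadratic-order RBF reading (r² log r);
the paper-facing alternative of a pure r² kernel is rank-3 degenerate and
was rejected. λ (`smoothing`, default 0) is added to the kernel diagonal
only; as λ → ∞ the fit approaches the ordinary least-squares plane, and
the training residual is non-decreasing in λ (verified empirically on
fixed instances).

Conditioning: duplicate coordinates are averaged before fitting (a plain
duplicate makes the system exactly singular at λ = 0); datasets larger
than `max_points` (default 2000) are subsampled with a seeded uniform
draw, keeping the dense solve O(max_points³) and reproducible. ε defaults
to 1.0 and should be set near the inverse data scale for the gaussian
kernel — very flat gaussians are the one configuration that approaches
the conditioning limit. Volume values are never renormalized;
`value_range` clamping is display-only and applied after evaluation. The
volume grid's resolution is independent of the vector-field grid by
construction (they are separate `GridSpec` objects).

## Trajectory trends

Cells within `radius` of a trajectory (point distance, not distance to
interpolated line segments — robust and cheap, and segments of the drawn
path are what users see) are assigned segment
`floor(nearest_point_index · n_segments / n_points)`, clipped to the last
segment: an equal partition of steps rather than arclength, which is
robust to uneven step displacements near sinks. Per-segment means of each
feature form the trend matrix; an empty segment takes the linear
interpolation of its nearest flanking non-empty segments (ends copy the
nearest non-empty value). Normalizations: `zscore` centers/scales each
feature across segments with population variance (constant rows become
all-zero rather than NaN); `relative` subtracts the first segment's mean.

Clustering runs scikit-learn k-means with seeded initialization and 10
restarts on the trend rows as stored — cluster a z-scored matrix for
scale-free grouping. Defaults: k = 6, optional shortlist of the top 200
features by across-segment variance (range is the alternative statistic).
Display order: a centroid is up-regulated iff its last-minus-first value
is ≥ 0 (a slope fit would weight interior segments; last-minus-first
matches the "where does it end up" reading of a trend); up-regulated
clusters sort by the segment index of their maximum, down-regulated by
the index of their minimum, ties by cluster index. Heatmap rows sort by
cluster display position, then the feature's own extremum position, then
feature id.

## Clonal queries

The GUI gesture of clicking a region is modeled as a sphere (center +
radius; default radius one voxel edge of the default grid). Expansion is
pure set algebra over one-label-per-cell barcodes: clone ids are the
labels carried by query cells minus the missing-label sentinel (empty
string); related cells are all non-query cells carrying any of those
labels. Sentinel-labeled cells never relate cells to each other.
Expansion is idempotent and the shared-label relation symmetric — both
are tested. The clonal-enrichment volume interpolates the 0/1 indicator
of the expanded set with the same RBF machinery; a `value_range` of
(0, 1) is advisable since indicator extrapolation can overshoot at grid
corners.

## Synthetic data: what it emulates and what it does not

The generators produce cells uniform in a 10×10×10 box (embedding units)
with velocities from three analytic fields — uniform flow, the linear
sink v(x) = −(x−c), and a bifurcation (unit +x flow diverging ±z past a
branch point, a minimal fate decision) — plus isotropic Gaussian noise
(default SD 0.05 in the pipeline fixture, i.e. 5% of unit speed).
Trend features follow planted profiles (linear up, linear down, Gaussian
transient peaking at mid-path with width 0.15 of the path) evaluated at
each cell's progress along a reference path. Clonal datasets place each
clone's cells in a Gaussian blob (SD 0.6) around a random center with a
20% dispersed minority and 10% unbarcoded cells, emulating barcode
lineage data where clones concentrate in related states but straggle.

These fixtures give exact ground truth for oracles, which is their
purpose. They do not reproduce real embeddings' curved manifolds,
density gradients spanning orders of magnitude, dropout-driven feature
sparsity, or velocity estimation noise that is correlated across
neighboring cells. Passing tests therefore establishes that the
numerics are correct (averaging, interpolation, integration, statistics,
set algebra are exactly what they claim), not that velocity-derived
trajectories on a particular biological dataset are faithful — that
depends on the upstream velocity estimates and embedding quality.

## Problem sizes and reproducibility

Oracle comparisons run at 10³ cells (×50 features for trends), grids of
resolution 8–10, and 200-point RBF systems — sizes at which brute-force
oracles are exact and instantaneous while still exercising every code
path; the pipeline reproducibility check runs the full fixture pipeline
twice at 400 cells. One integer seed drives every random draw (fixture
sampling, streamline subsampling, RBF subsampling, k-means restarts), and
CSV/JSON tables are the canonical outputs: two runs of one configuration
are byte-identical, which the suite asserts via content checksums. HTML
scenes embed the same tables as JSON; static raster/vector export goes
through matplotlib and is excluded from byte-exactness guarantees.

## Known limitations

- No adaptive step-size control; step count and size are fixed per run.
- No backward-time streamlines by default (sign the step size to explore).
- Trend analysis offers no differential statistics between alternative
  trajectory branches.
- Clone labels are one per cell; delimiter-joined multi-labels are parsed
  only if split upstream.
- The h5mu writer/reader covers the modality groups this package uses
  (X, obs, var, obsm per modality); it is not a full MuData
  implementation.
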