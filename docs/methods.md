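# Methods

This note records the models, the parameters that matter, the numerical
choices, and what the synthetic benchmark does and does not establish.

## Imaging model

A DIC micrograph is treated as

g(x, y) = c + s · D_θ f(x, y) + b(x, y) + ε(x, y),

where *f* is the specimen's optical density (≈ thickness), D_θ the
directional derivative along the shear axis θ, *b* a smooth illumination
bias, and ε sensor noise. D_θ is discretized with forward differences,
`D_θ f = cos θ (f[i, j+1] − f[i, j]) + sin θ (f[i+1, j] − f[i, j])`, with
Neumann (replicated) boundaries; rows grow downward and θ is measured from
the column axis. The same stencil is used by the synthetic renderer and the
reconstruction, so the forward and inverse models are consistent by
construction. θ defaults to 45°, a conventional shear orientation; it is a
configuration parameter because real instruments vary.

## Illumination correction

Subtractive high-pass: the background estimate is a Gaussian blur with
σ = `sigma_frac` · min(rows, cols), `sigma_frac` = 0.125 by default —
large enough that cell-scale relief (tens of µm) passes untouched, small
enough to capture scene-scale shading. Subtractive rather than divisive:
the DIC signal rides additively on mid-gray, so dividing would modulate
relief amplitude with the bias. The residual is re-stretched to [0, 1].
High-pass filtering is only approximately idempotent (the blur of the
residual is small but not zero); a second application changes the image by
less than a few percent, which is the property the tests assert.

## Bespoke seeding (10×, 20×)

The gradient support separates relief-bearing cells from flat background.
Plain per-pixel Sobel magnitude is heavy-tailed under noise and Otsu's
threshold on it is unstable, so the magnitude is first pooled with a small
Gaussian (σ = 1 px) into a local gradient energy. The support cut is
`max(0.7 · t_otsu, median + 4 · MAD_left)`: the Otsu threshold lands well
inside the relief tail and would clip the faint rim of every cell, so 70%
of it is used; the left-sided-MAD noise floor (robust to the cell tail)
takes over on sparse or empty frames, where Otsu would otherwise split the
noise distribution itself and declare half the frame foreground. The
support is closed (3×3) and hole-filled.

Seeds are bright blobs — brightness above its own Otsu threshold — inside
the support, opened (3×3) to suppress speckle, closed (radius-3 disk) to
re-join lobe fragments, re-intersected with the support, and filtered by a
small per-magnification area floor (20/50/100 px) so noise specks never
seed. One bright lobe per cell is the expected DIC appearance: a cell's
relief is bright on the up-shear side and dark on the down-shear side.

## Feineigle reconstruction (40×)

E(f) = ‖D_θ f − g‖² + λ‖∇f‖² is minimized by raster-order pointwise
Gauss–Seidel on the normal equations (each pixel set to its closed-form
minimizer with neighbors fixed), implemented as a compiled CSR sweep. The
energy trace is non-increasing (coordinate descent on a convex quadratic)
and is asserted at every sweep. Components of *f* constant along θ are
unobservable; λ > 0 pins them and the output is re-centered to zero mean.

Defaults: λ = 0.01, `max_sweeps` = 4000, `tol` = 1e-4 (relative energy
decrease per sweep). λ was chosen by measuring the exact minimizer against
the true synthetic height map: at λ = 0.1 the regularizer over-smooths
(correlation ceiling ≈ 0.90), at λ = 0.01 the ceiling is ≈ 0.95 and the
achieved correlation after a few thousand sweeps is 0.93. Gauss–Seidel
attenuates low-frequency error slowly, hence thousands of sweeps; on a
224×224 frame a reconstruction takes a few seconds. Reconstruction quality
depends on the cell layout relative to the integration direction, so
reported fidelity is for a fixed reference scene.

Seeds: the reconstruction is split into three classes by two-threshold
Otsu. Reconstructed background ripple straddles the lower threshold, so the
watershed support is cut at the midpoint between the two thresholds
(essentially ripple-free) and dilated 8 px to recover the attenuated cell
rim; seeds are 8-connected components of `{d > h_frac · max d}` of the
Euclidean distance transform of the top class, `h_frac` = 0.5 — deep
enough to split touching cells whose distance basins overlap by less than
half their depth. Polarity is configurable (`invert`) for specimens whose
optical density runs the other way.

## Watershed and post-processing

The flooding surface is the Sobel magnitude of the corrected image; markers
are the seeds plus a 5-px border ring marked background. Flooding is
restricted to the foreground support (Bespoke support at 10×/20×, the
non-background reconstruction class at 40×). The restriction is essential
to the DIC geometry: cell edges parallel to the shear axis produce no
gradient ridge, so an unrestricted flood leaks background into cells
through those silent edges and, conversely, balloons cell basins into flat
background. Region invariants (disjoint, 8-connected, consecutive ids) are
re-established after every stage.

Under-segmentation repair: regions larger than `split_factor` (= 2) times
the median region area are re-thresholded locally with Otsu; if that
reveals ≥ 2 components of at least `min_split_component_px` (= 64) px,
those components seed a repartition of the whole parent region (watershed
within the parent). Repartitioning, rather than keeping only the bright
components, is what makes the split pieces cell-sized; the bright lobe of
a DIC cell is roughly a third of its footprint and would otherwise always
fall below the area filter. A region whose local threshold yields a single
component passes through unchanged. Finally the magnification-specific
area filter removes regions below 700/1900/3000 px (10×/20×/40×),
boundary inclusive; it runs after splitting so that split products are
judged on their own areas.

## Morphometry

All lengths are reported in units of 100 µm and areas in (100 µm)²,
using the manifest's µm-per-pixel calibration; placeholders (1.0/0.5/0.25
µm/px for 10×/20×/40×) are used, with a log warning, when no calibration is
given. Per region:

* **log_area** — natural log of pixel count × (µm/px / 100)². Natural log:
  any base is an affine rescale absorbed by the downstream z-scoring.
* **major/minor axis** — 4·√(eigenvalues) of the coordinate covariance,
  the ellipse with the region's second central moments; a 1/12 per-pixel
  variance correction accounts for pixels being unit squares and keeps
  1-px-wide regions away from a zero minor axis.
* **eccentricity** — √(1 − λ₂/λ₁). Note it is ill-conditioned near
  circularity: a 24 vs 23 px ellipse has true eccentricity 0.28 yet
  rasterization moves the estimate by ~0.1 while both axes are within 2%.
  The accuracy benchmark therefore samples axis ratios ≥ 1.1, where the
  5% accuracy statement is meaningful.
* **perimeter** — Moore-traced boundary chain, steps weighted 1 (axis) and
  √2 (diagonal). The estimator overshoots smooth contours by up to ~8% at
  shallow edge angles and undershoots very small regions; tests carry that
  slack explicitly.
* **solidity** — area over the area of the rasterized convex hull of the
  pixel centers. Rasterizing the hull (rather than using the polygon area)
  makes solidity exactly 1 for convex digitized shapes and bounds it by 1
  for every region.

## Population analysis

k-means (k = 3, Lloyd's algorithm, k-means++ initialization, best of 10
seeded restarts, empty clusters re-seeded from the farthest point) on
per-column z-scored features — the six features mix logs, lengths and
ratios, and unscaled Euclidean distance would be dominated by perimeter.
The per-iteration inertia is asserted non-increasing, and on tiny instances
the fit equals exhaustive partition search. Semantics for k = 3: the
smallest cluster is **green** (conglomerates/artifacts); of the remaining
two, the higher mean eccentricity is **red** (fiber-like), the other
**blue** (convex); ties break on mean major axis. Shares are rounded
half-up to two decimals. The isomap check (k-NN graph, geodesic distances,
classical MDS, 10 neighbors, 2 components) is the standard verification
that blue/red form compact clouds while green scatters. Timelines report
average regions per image per culture day, with image counts taken from
the manifest so empty images count in the denominator.

The k = 3 partition of a two-phenotype culture is only meaningful when
some under-segmented conglomerates are present to anchor the third
cluster; on a perfectly segmented two-population sample the third centroid
must split a real population and the semantic rule degrades. This mirrors
the role the conglomerate cluster plays in real cultures. The share
recovery study is correspondingly defined over a fixed scene series; its
result is invariant to the clustering seed.

## Synthetic cultures

`make_scene`/`render_dic` emulate the study conditions: mid-gray frames
with smooth polynomial illumination bias (amplitude 0.1), Gaussian noise
(σ = 0.02), and cells rendered as the directional derivative of
cosine-tapered height bumps scaled to ±0.3 — visible but not dominant, the
DIC look. Bump amplitude is proportional to the cell's semi-minor axis
(optical path scales with thickness ≈ width); without this, thin fibers
would dominate the global contrast normalization with unrealistically
steep slopes and convex cells would fall below every threshold. The
cosine taper makes each cell's support compact and exactly equal to its
ground-truth mask, so IoU scoring is unambiguous.

Phenotypes: convex cells default to 30–44 µm equivalent diameter
(spread keratinocytes; the type ranges 10–50 µm) with axis ratio ≤ 1.3,
fibers to 90–140 µm × 10–15 µm (axis ratio ≥ 3). Placement is
rejection-sampled with disjoint, margin-separated footprints. Mixed-culture
scenes add a clump of small (14–20 µm) convex cells with adjacent
footprints: ground truth keeps them separate, but their merged bright
lobes under-segment into a single conglomerate region — the mechanism
behind the green cluster.

What passing tests show — and what they do not: the benchmark establishes
that the pipeline inverts its own imaging model (segmentation recall ≥ 0.9
at IoU 0.5 on non-touching scenes, composition recovery within ±10
percentage points, reconstruction fidelity r > 0.9). Real DIC adds optics
the renderer omits (Nomarski prism point-spread, polarization artifacts,
internal cell texture, overlapping and motile cells, debris), so absolute
performance on real micrographs will differ; the synthetic results bound
the method's behavior only under the stated model. Fibers lying along the
shear axis produce almost no relief and are legitimately missed — the same
blindness real DIC has.

## Degenerate inputs and tie-breaking

Constant images, single-bin histograms, empty seed maps and empty
labelings all return well-defined empty results with warnings rather than
failing. Otsu ties resolve to the smallest threshold (pair:
lexicographically smallest); k-means determinism comes from fixed seeds
(default 17); all label rasters keep consecutive ids with a stable order.
The distance transform treats everything outside the raster as background.

## Problem sizes

Default test and acceptance studies use 512×512 10× frames (~16–24 cells),
224×224 40× frames (3 cells), 20-image series, 1000-histogram Otsu
sweeps and 50-ellipse accuracy runs — sizes chosen so the full suite and
the acceptance script each complete in about a minute on one CPU while
keeping every estimate's sampling error well inside the asserted margins.
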