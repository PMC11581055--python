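# Methods

`stiptrack` segments and tracks cells in 2D time-lapse microscopy. This
note describes the models and algorithms it implements, the parameters that
matter, the design choices made where the design was genuinely open, what
the synthetic generator does and does not emulate, and known limitations.

## Processing model

Every frame is processed jointly with its two temporal neighbors as a
3-slab volume `L(τ, y, x)`, `τ ∈ {t−1, t, t+1}` (boundary frames replicate
the missing neighbor). The pipeline per frame is:

1. nonlinear spatio-temporal scale space (anisotropic diffusion),
2. automatic scale selection from multi-scale interest-point counts,
3. watershed superpixels seeded by interest points and edge-map minima,
4. cell/non-cell classification of superpixels by a small dense network,
5. level-set boundary refinement and adherent-cluster separation,
6. motion-compensated max-likelihood linking into an acyclic oriented
   lineage graph with mitosis detection.

## Spatio-temporal anisotropic diffusion

The scale space solves the Perona–Malik equation on the 3-slab volume,

    ∂L/∂s = div( g(|∇L|) ∇L ),

with an explicit 6-neighbor scheme (2 spatial + 1 temporal axis),
reflecting boundaries, and edge-stopping function
`g(x) = exp(−(x/k)²)`. The exponential form favors preservation of
high-contrast edges over wide smooth ramps, which suits sharp cell
boundaries. The temporal axis uses the same grid spacing as the spatial
axes; a spacing ratio would be a single extra constant but there is no
principled value for it at typical frame intervals, so it is fixed at 1.

Parameters (config section `scale_space`):

| name | default | meaning |
|---|---|---|
| `n_scales` | 8 | scale levels; level 0 is the input |
| `step` | 0.15 | explicit time step; must be ≤ 1/6 for stability |
| `steps_per_scale` | 1 | explicit iterations per scale increment |
| `conductance_k` | data-driven | 90th percentile of the triplet's \|∇L\| |
| `conductance_form` | `exponential` | also `rational`, `constant` |

With `g ≡ 1` the scheme reduces to the heat equation and matches Gaussian
convolution of variance `2·s·step` (verified to < 1 % RMS), which anchors
the nonlinear solver against a closed form. The explicit scheme obeys the
maximum principle and conserves total intensity under reflecting
boundaries; both are asserted in tests.

## Interest-point detectors

Three detector responses are evaluated on the central slab:

* **moments** — 3D Harris: structure tensor `M` of Gaussian-smoothed
  first-derivative products (integration scales `σᵢ = 2`, `τᵢ = 1`),
  scored `S = det M − κ·(tr M)³` with `κ = 0.005`. The trace is cubed, so
  `κ` must be far smaller than the classic 2D value 0.04.
* **hessian_st** — `S = |det H|` of the 3×3 space-time Hessian evaluated at
  differentiation scales `(σ, τ)` (Gaussian pre-smoothing, then exact
  second differences). This is the pipeline default.
* **hessian_temporal** — `S = |det|` of the 2×2 spatial Hessian of the
  central temporal difference `L_t`; it responds only to moving structure.

Derivatives are central finite differences on the diffused maps.
First-derivative products scale as intensity⁶ (moments), second-derivative
determinants as intensity³ (3×3) and intensity² (2×2); these exact power
laws and agreement with brute-force cofactor oracles are test-asserted.

Interest points are regional maxima of `S` above a *relative* threshold
(`10⁻⁴ × max S` per frame), so thresholding survives frame-to-frame
contrast changes. A plateau contributes a single locus (its centroid,
snapped to the nearest plateau pixel).

**Two roles, two scales.** The detector serves two distinct purposes and
these want different differentiation scales:

* *Scale selection* counts noise features, which only the bare response
  (`σ = τ = 0`, derivatives straight on the diffused maps) tracks —
  pre-smoothing the response decouples the count curve from image noise
  and destroys the noise-monotonicity of the selected scale.
* *Point localization* wants the response to peak at cell centers. Cells
  are flat-topped rather than Gaussian, and moderately elongated
  (semi-major axis a ≈ 1.15 r for the default eccentricity), so the
  matched determinant-of-Hessian scale is `σ = a/√2 ≈ 0.8·r` with
  `r = detection.expected_radius` (default 6 px), and `τ = 1.5` frames.
  At smaller σ the response of an elongated cell has twin peaks ±3 px off
  center; at σ ≳ r cells fragment into several superpixels downstream.

The pipeline therefore selects the scale from the bare-response count
profile and extracts the reported interest points from the blob-matched
response at that scale. `hessian_temporal` is available by config but is
not the default: its response is odd-symmetric around a moving blob's
center, placing maxima off-center, which hurts both seeding and the
cell-center criterion.

## Automatic scale selection

For each frame the number of interest points is counted at every scale
with identical detector settings. Noise features collapse over the first
one or two diffusion increments while cell features persist, so the
normalized count curve `c(s)/c(0)` drops steeply and then flattens. The
selected scale is the elbow: the smallest interior scale maximizing the
discrete second difference of the normalized curve, ties broken toward the
smaller scale (preserving detail). A degenerate profile (all counts equal,
e.g. constant frames) falls back to scale 1 with a warning.

Selection is per frame, so frames with different noise/contrast levels in
one sequence are handled independently — the property the method exists
for. On synthetic data the mean selected scale increases with the injected
noise level, and ≥ 90 % of planted cell centers keep an interest point
within 3 px at the selected scale (both test-asserted).

## Watershed superpixels

Interest-point loci are converted into a Parzen density (exact sum of
unit-peak Gaussian kernels, bandwidth `0.5 × expected_radius`). The
watershed relief fuses two min-max-normalized terms with equal weight:
the spatial gradient magnitude of the selected-scale map, and the inverted
density — low inside cells, high on boundaries. Equal weights are the
least-informative choice given no stated weighting.

Markers fuse interest-point seeds (dilated by 1 px) with the regional
minima of the *edge map* (gradient magnitude of the diffused map). The
edge map — not the fused relief — supplies the minima: its flat plateaus
inside cells and across the background guarantee that background basins
own markers, otherwise cell markers flood into the background and
superpixels straddle the cell/background boundary. Overlapping seeds merge
into one marker. Marker-controlled watershed (4-connectivity) partitions
every pixel; fragments under 5 px merge into the neighbor across the
lowest ridge.

## Cell detection

Each superpixel is summarized by 9 features: mean and variance of
(1) selected-scale intensity, (2) detector response, (3) motion
displacement magnitude, (4) spatio-temporal intensity-gradient magnitude,
plus (5) the area in pixels — the unique (mean, variance) pairing of the
four descriptor categories that yields a 9-node input layer.

Training labels come from reference masks: a superpixel is a cell sample
when ≥ 50 % of its pixels lie in reference cell regions. Background
superpixels vastly outnumber cell superpixels, so before training the
descriptor cloud is clustered with DBSCAN under the Mahalanobis metric
(ridge-regularized covariance; `min_pts = 10`; `eps` = the 15th percentile
of pairwise distances on a 500-sample seeded subsample, which adapts to
feature scaling) and the most populous cluster is undersampled, without
replacement and seeded, to the size of the second most populous one.
Only multiplicities change; feature vectors are never altered. DBSCAN runs
jointly on the full training set.

The classifier is a fully connected 9→12→6→2 network, ReLU after the two
hidden layers, softmax cross-entropy output — 212 parameters (192 weights,
20 biases). It is implemented directly in NumPy with manual
backpropagation: plain SGD with momentum 0.9, learning rate 10⁻², batch
64, 200 epochs, He initialization from a seeded generator; features are
z-scored with training-set statistics stored in the model. Training is
bitwise-deterministic given the seed. Models serialize to a single JSON
file (layer shapes, weights, standardization constants, seed metadata).

## Boundary refinement and cluster separation

The binary cell mask is refined by a region-based level set with a local
two-phase clustering data term: within a Gaussian window (σ = window/2,
window = 7 px) around each pixel, intensities are modeled by an inside and
an outside mean; the contour moves down the windowed misclassification
energy with a length penalty ν = 0.2·window². The level-set function is
re-canonicalized as a signed distance after every accepted step — with a
drifting |∇φ| the discretized energy is not a reliable acceptance
criterion — making the energy a pure function of the interface; steps that
would raise it are rejected with a halved (later regrown) time step, so
the energy trace is non-increasing. On a blurred disk initialized 3 px too
wide, the refined boundary lands within 1 px (mean) of the analytic
half-height contour. A hard causal bound confines the front to the initial
mask dilated by one pixel per iteration.

Adherent clusters are then separated in three stages:

1. **Screening.** A region is flagged when its solidity (area / convex
   hull area) falls below 0.85 *or* its area exceeds `1.7·π·r²`. The area
   screen is necessary: the grid-exact solidity of two overlapping disks
   is ≈ 0.89 — even tangent disks only reach ≈ 0.88 — so side-by-side
   pairs are near-convex and pass any solidity threshold that single
   elongated cells also pass.
2. **Splitting.** Flagged regions are split by marker-controlled watershed
   of the interior distance transform, seeded at its h-maxima (depth
   1 px).
3. **Gating.** A split line is kept only if it sits in an intensity valley
   of the diffused map: the mean intensity on the piece interface must dip
   ≥ 20 % below the mean interior intensity of the adjoining pieces. True
   cell-cell necks are dark (the blurred inter-cell gap); watershed lines
   crossing a single cell are not — on the benchmark fixture the two
   populations are separated by an order of magnitude (dips ≥ 0.22 vs
   ≤ 0.02). Finally, slivers under `0.15·π·r²` px merge into their
   largest-contact neighbor.

## Motion estimation and tracking

Dense flow between consecutive frames is combined local/global optical
flow: the brightness-constancy gradient's structure tensor integrated over
a ρ = 2 px Gaussian neighborhood (local term) with Horn–Schunck smoothness
of weight α = (0.05 × intensity range)² (global term), solved by
Jacobi-style fixed-point iteration (≤ 200 iterations, stop when the mean
update < 10⁻⁴ px). An outer warping loop (3 iterations) re-linearizes
brightness constancy, so integer displacements up to 4 px are recovered
with median endpoint error < 0.5 px on one pyramid level — adequate
because cell displacements are small relative to frame size. Labels are
transported by nearest-neighbor scatter along the field (labels are
categorical; interpolation is meaningless); pixels leaving the frame are
dropped, and no label can be invented.

Linking is bi-frame maximum-likelihood matching: the prior frame's label
map is warped by the flow, and the likelihood that current cell i
continues warped prior cell j is their intersection-over-union — the
natural proximity between indicator functions. Each current cell takes the
argmax prior cell; a maximum below `reject_threshold = 0.1` signals
appearance. When all overlaps are zero but a warped prior centroid lies
within `2·r`, a Gaussian centroid-distance likelihood (σ = r) stands in,
tolerating low temporal resolution. A prior cell claimed by two current
cells encodes a division; claims are capped at 2 (binary fission), excess
claimants in likelihood order become appearances.

Tracks are built by traversing the per-frame links backward from every
chain end; chains sharing a common ancestor prefix are split recursively
into a mother track and daughter tracks (the shared prefix is the mother;
this handles nested divisions). Every segmented cell belongs to exactly
one track. The lineage graph has one vertex per cell state, migration
edges within tracks, and division edges from a mother's last state to each
daughter's first; acyclicity, in-degree ≤ 1, and division arity ≤ 2 are
verified. Cells reappearing after full disappearance start new tracks.
Masks are re-labeled with track ids and the track set serializes to the
4-column `L B E P` text form.

## Evaluation measures

* **Jaccard / DSC** on pixel sets, with the identity `DSC = 2J/(1+J)`.
* **SEG**: for each reference cell, find the result region covering more
  than half of it (at most one exists); score their Jaccard, else 0;
  average over all reference cells.
* **DET / TRA**: normalized acyclic-oriented-graph matching costs,
  `1 − min(AOGM, AOGM₀)/AOGM₀`, clamped to [0, 1], where AOGM counts
  weighted edit operations turning the computed graph into the reference:
  node splits (weight 5), false negatives (10), false positives (1) for
  DET; additionally edge deletions (1), additions (1.5) and semantic
  corrections (1) for TRA. AOGM₀ is the cost of building the reference
  from scratch. Node matching reuses the SEG detection test (> 0.5
  reference overlap) for internal consistency. The weights are the
  standard published values and are configurable.

## Synthetic data generator

The generator emulates the stated challenges of real time-lapse data:
elliptical cells (radius ~ N(6, 1) px, axis ratio 1.4, random orientation)
with Brownian steps (σ = 1 px/frame), scheduled divisions (mother replaced
by two half-area daughters displaced ± 0.8·a along the elongation axis),
rendering as background 0.2 + contrast 0.5 × indicator blurred σ = 1 px,
additive Gaussian noise (σ = 0.03) plus signal-dependent noise
(0.02·√I·N(0,1)) so the contrast-to-noise ratio varies with intensity.
Masks, lineage table, and per-pixel ground-truth motion are exactly
consistent with the rendered cells, and everything is bitwise-deterministic
per seed. Cells repel with a hard core (≈ 1 px minimum gap): they may touch
— exercising cluster separation — but never interpenetrate, as physical
nuclei do not; interpenetrating ellipses form convex blobs that no
observable cue can split.

The default benchmark is a pair of 128×128, 20-frame sequences ("01",
"02") with 8 initial cells and 2 divisions each, at the noise levels
above; a noise-free variant switches both noise terms off. Problem sizes
were chosen so the full train-on-01 / test-on-02 protocol and the test
suite execute in minutes on one core.

What the generator does *not* emulate: optics (PSF tails, vignetting,
photobleaching), texture inside cells, shape dynamics beyond rigid motion,
cells entering/leaving the field of view, and dense colonies. Passing
tests therefore demonstrate the machinery is correct and self-consistent
on blob-like, moderately dense data; they do not certify performance on
any real microscopy modality.

## Numerical choices and degenerate inputs

* Diffusion step fixed at 0.15 ≤ 1/6: the explicit-scheme stability bound
  in 3 dimensions; violating it raises immediately.
* Relative interest-point threshold; a response map that is globally
  constant yields no points (a full-frame plateau is not a feature).
* Empty interest-point sets give an all-zero density with a warning;
  segmentation then runs on edge-map minima alone.
* DBSCAN covariance is ridge-regularized (`λ = 10⁻⁶·tr C/d`) so
  constant features cannot make the Mahalanobis metric singular.
* Scale-selection ties break toward the smaller scale within a 10⁻¹²
  tolerance (float-noise ties would otherwise be broken arbitrarily).
* Tracking with an empty frame simply terminates all tracks; an empty
  sequence of matchings is rejected.

## Known limitations

* Cells much smaller than `expected_radius` (≳ 2 SD below the mean, ~25 px
  area) sit at the edge of the σ-matched detector's range and are
  occasionally missed or split late around their division events; the
  radius prior is a single global scalar.
* Matching is greedy per cell over consecutive frame pairs; there is no
  whole-sequence association optimization, so a one-frame segmentation
  error can surface as a spurious appearance or division.
* The level-set data term assumes locally two-phase intensity; textured
  interiors or halos (phase contrast) would need a different criterion.
* One pyramid level limits flow recovery to displacements of a few pixels
  per frame.
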