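# Methods

`corrbridge` implements the quantitative core of a correlative multimodal
imaging (CMI) workflow for neural tissue: the same stained, resin-embedded
block is imaged by in vivo 2-photon microscopy, laboratory micro-CT (LXRT),
synchrotron X-ray tomography with propagation-based phase contrast (SXRT),
and serial block-face electron microscopy (SBEM). The package covers the
analysis layer of that workflow — coordinate bridging, tracing evaluation,
resolution estimation, spine statistics, and a minimal reconstruction
chain — together with seeded generators that emulate the statistical
structure of each input, so every procedure is testable without any imaging
data.

## Coordinate bridging (warp)

Each dataset lives in its own coordinate system. Point annotations move
between systems through transforms fitted to manually placed landmark
pairs:

* **scale-offset** — per-axis `y = s·x + o`, fitted by least squares; used
  between aligned pyramids of the same acquisition;
* **affine** — full 3×4 least-squares fit; requires ≥ 4 non-coplanar pairs;
* **thin-plate spline (TPS)** — affine part plus radial kernel terms
  `Σ wᵢ·U(|x − cᵢ|)` with the 3D biharmonic kernel `U(r) = r` (not the 2D
  `r² log r`: all spaces here are volumetric). At zero regularisation the
  TPS interpolates its defining landmarks exactly (residuals are at
  numerical precision, far below 1 nm).

Transforms are directed edges of a dataset graph. Scale-offset and affine
edges register exact inverses automatically; the TPS inverse is a second
TPS fitted to the swapped landmark pairs and is therefore *approximate* —
round-trip error on interior points is measured in tests at well below
0.5 % of the bounding-box diagonal for smooth deformations. Routing
between two spaces uses the path with fewest edges (lexicographic
tie-break on space ids); path quality weighting was considered and
rejected as out of scope, since in practice these graphs are small and
hand-curated. All coordinates are nm (float64) throughout the package.

## Traceable length (trace_eval)

A test tracing (e.g. a dendrite followed in SXRT) is compared against a
reference tracing (an EM consensus warped into the same space). Both
root-to-tip paths are fitted with a cubic spline (cumulative chord-length
parameterisation, natural boundary conditions) and resampled at a constant
arc step, default 320 nm. Arc length along the spline is computed by
adaptive quadrature of the spline speed and inverted on a dense grid; the
endpoint is always emitted so tips are never truncated. Paths of ≤ 3
distinct points fall back to piecewise-linear interpolation, where a cubic
fit is under-determined.

For each test point the Euclidean distance to the nearest reference
*point* is computed (point-to-point, not point-to-segment: at 320 nm
sampling the segment-projection correction is negligible relative to the
thresholds). The tracing is **lost** at the first sample whose distance
exceeds the lost threshold — 12 µm for olfactory-bulb mitral cells, 6 µm
for hippocampal CA1, both parameters of `EvalParams` — and the arc
position of that sample is the **traceable length**. An optional
`min_run_length` debounce exists but defaults to 1 (a single sample above
threshold marks loss, the literal definition). Tracings correctly followed
for at least the 35 µm linkage threshold are **linked**; the four-way
status (`linked_kept`, `linked_lost`, `lost_at_linkage`, `too_short`)
separates dendrite-level tracing performance from failures in the short
soma-to-dendrite linkage region. Cohort summaries report per-tracer means,
the cross-tracer mean ± SEM, and pooled box statistics with whiskers at
the most extreme points within 1.5× the interquartile range.

A geometric consequence worth stating explicitly: a wrong turn at arc
position `d` can only be *detected* once the divergent path has moved
threshold-far from the reference, so measured loss positions trail the
underlying departure by roughly the lost threshold. The synthetic cohort
generator therefore places linkage-zone departures uniformly in the first
20 µm, which puts the detected losses in ≈ [12, 32] µm — concentrated in
the first 40 µm of dendrite and below the 35 µm linkage criterion — so the
generative failure labels and the four-way classification correspond
one-to-one. Late departures are placed beyond 40 µm and register as
`linked_lost`.

## Resolution estimation (fsc)

Two half-volumes sharing signal but carrying independent noise (odd/even
projection-angle half-tomograms for X-ray data; odd/even slices with 2×2
in-plane pooling for serial-section EM) are compared per frequency shell:

    FSC(r) = Re(Σ_shell F_a F_b*) / √(Σ_shell |F_a|² · Σ_shell |F_b|²)

Shells are one frequency voxel wide, binned by rounded radius (the
community default; floor-binning is the obvious alternative and changes
results by less than a shell). Non-cubic volumes are handled by
normalising frequencies per axis before binning, so radii are cycles per
voxel. Four criteria are implemented: the 1-bit and ½-bit information
thresholds, the 3σ noise-significance threshold `3/(√(nᵢ/2)+1)` (the
`+1`-free variant is available behind a flag, since the two are not
distinguishable from a threshold value alone), and the fixed 1/7 level.
The crossing is the first shell below threshold, refined by linear
interpolation; resolution = voxel size / crossing frequency, with a
beyond-Nyquist sentinel when no crossing exists.

Lab micro-CT reconstructions can carry an artifactual correlation floor at
frequencies where true signal is absent. `normalise_high_freq` estimates
that floor as the mean of the *averaged* curve in the band
[1/(3 px), 1/(2 px)] and maps every curve through `(FSC − m)/(1 − m)`,
which pins FSC = 1 and sends the band mean to zero; a subtract-only mode
is available. ROI defaults are 500-voxel cubes (100 for LXRT).

The synthetic pair generator builds a band-limited Gaussian random field
(hard Fourier cutoff) plus independent white noise scaled so the in-band
per-shell SNR is exactly `s`; the expected FSC is then `s/(s+1)` below the
cutoff and 0 above, with sampling scatter ~1/√nᵢ — the closed forms the
tests assert at 3/√nᵢ tolerance.

## Spine statistics (spines)

CA1 pyramidal somata are fitted with a layer line in the x,y plane (z is
ignored because apical dendrites run parallel to the imaging plane). The
default fit is total least squares (first principal axis through the
centroid): the measured quantity is a *perpendicular* distance, and TLS
makes it invariant to the coordinate-axis choice; an ordinary y-on-x mode
exists for strict replication. The deep side is set by an explicit
orientation hint vector, since no algorithmic rule determines which side
of the layer is "deep"; deeper cells get positive depths.

Spine and spine-apparatus densities are counts divided by shaft length,
pooled across all branchlets of one dendrite type within a cell. Branched
(two-headed) spines count once, including when both heads contain a
spine apparatus. Inter-spine distances are successive gaps of sorted
attachment arcs within one branchlet, never spanning branchlets;
branchlets with fewer than two spines are excluded.

Under homogeneous Poisson spine placement the gaps are exponential,
`f(x) = λe^(−λx)` with rate λ (per µm). The rate is estimated by maximum
likelihood, `λ̂ = 1/mean(gap)`. Note a finite-window property of this
estimator: interior gaps exclude the two boundary intervals of each
branchlet, so with n spines on a branchlet the expected mean gap is
L/(n+1) rather than 1/λ, biasing λ̂ upward by a factor ≈ (n+1)/n (about
+2 % at the study's ~43 spines per branchlet). The count/length density
estimator is free of this bias; recovery tests use it for the rate and
check the gap MLE after the window correction. The one-sample Kolmogorov–Smirnov test
against the *fitted* exponential is biased conservative if the standard
null distribution is used (the rate was estimated from the same data), so
two calibrations are offered: `naive` (the standard distribution, matching
common practice) and `parametric_bootstrap` (Lilliefors-style: resample
exponential samples of the same size, refit the rate each time, compare
the observed statistic against that null; the default for validation).
Because the statistic is scale-free under refitting, the bootstrap is
fully vectorised. Inter-apparatus gaps are compared against the same
fitted exponential as the all-spines analysis (a refit option exists).

Density-versus-depth uses ordinary least squares with a two-sided t-test
on the slope (n − 2 df) and a pointwise 95 % confidence band for the mean
response. With spine rate λ and per-spine apparatus probability
`p(depth) = p₀ + β·depth`, the expected apparatus density is `λ·p(depth)`,
so the generative slope recovered by the regression is `λβ` — the value
the coverage tests check. Generator defaults mirror the study scale: 7
cells, ~2 mm of shaft in ~10 branchlets per cell, λ = 1.5 spines/µm
(≈ 3000 spines), apparatus base probability 0.14 (≈ 14 % of spines).

## Tomography core (tomo)

Projections are normalised as `(p − d)/(f − d)` with dark `d` and flat
`f`. Single-distance Paganin phase retrieval divides each projection's
Fourier transform by `1 + πλz(δ/β)(u² + v²)` (λ = hc/E; u, v in cycles
per nm) and takes `−ln` of the result; the filtered intensity itself is
also exposed, since either convention appears in pipelines. The filter's
DC gain is exactly 1 and every other frequency is attenuated. Defaults
follow the beamline settings used for SXRT of stained tissue: 22 keV,
52 mm propagation distance, 325 nm pixels, δ/β = 1; an absolute-(δ, β)
constructor covers settings quoted as separate refractive-index parts
(e.g. δ = 2×10⁻⁶, β = 6×10⁻⁷ → ratio 10/3).

Reconstruction is parallel-beam, slice-separable 2D filtered
back-projection: rows are zero-padded to √2× width (edge-replication
behind a flag), filtered with a Ram-Lak ramp, and back-projected with
bilinear interpolation, scaled by π/n_angles. The discrete ramp is derived
from the band-limited spatial kernel (h[0] = 1/4, h[odd] = −1/(πn)²)
rather than a bare |f| frequency ramp: the kernel's small positive DC term
is what keeps reconstruction amplitudes unbiased. The forward projector
(rotated bilinear sampling, unit pixel steps) exists as the oracle for
round-trip tests; an independent reference implementation is used as a
cross-check in the test suite, never as the implementation. Ring removal
and centre-finding are pass-through stubs by design — they belong to
beamline pipelines outside this package's scope.

## Synthetic data (synthetic)

All generators draw from independent substreams derived from a single seed
plus a CRC-32 of the generator name, so module tests cannot perturb each
other and every output is bit-reproducible. Conditions emulated:

* **Dendrite cohorts** — persistent random walks traversing ~200 µm nearly
  straight (mitral-cell apical dendrites crossing the external plexiform
  layer), 2 µm steps, per-tracer Gaussian node jitter σ = 100 nm, and
  wrong-turn departures: probability q in the linkage zone (first 20 µm,
  see above), probability q₂ beyond 40 µm. The true per-tracer error
  process of human tracers is unknown; this q/q₂/σ model is a stated
  assumption, not a claim about real data.
* **FSC pairs** — shared band-limited field plus independent noise with
  exact per-shell SNR (closed-form expectation available).
* **Spiny cells** — homogeneous Poisson spines, Bernoulli apparatus flags
  with depth-dependent probability, somata on a known layer line.
* **Landmarks** — known affine plus a smooth sinusoidal displacement field
  (quarter period across the box — the gentle bulk-deformation regime of
  fixed-tissue shrinkage, and the smoothness at which a few dozen
  landmarks determine the field), with an exact held-out grid.
* **Phantoms** — analytic disc, nested ellipses, seeded Gaussian blobs.

What passing these tests shows: the estimators and procedures are
implemented correctly and recover known ground truth under their stated
assumptions. What they do not show: performance on real multi-gigavoxel
data with staining gradients, reconstruction artefacts, anisotropic
resolution, or human tracer behaviour — none of which the generators
attempt to model.

## Numerical choices and problem sizes

* Resampling spacing 320 nm everywhere; spline arc inversion on a dense
  grid of ≥ 8 points per input knot, rescaled to the quadrature total.
* Nearest neighbours via a k-d tree, asserted exactly equal to brute force.
* Box-statistic whiskers use the 1.5×IQR rule; quartiles are numpy's
  linear-interpolation percentiles.
* FSC null scatter bounds use 3/√nᵢ (three standard deviations of the
  null correlation per shell).
* Bootstrap KS uses B = 999 resamples and the (1 + #{D* ≥ D})/(B + 1)
  p-value, so p is never exactly zero.
* Validation problem sizes — 200-cell cohorts, 64³ FSC volumes, 1000 KS
  null replicates, 500 regression replicates at 7 cells, 128² phantoms at
  720 angles — were chosen so each recovery check has enough power for its
  stated tolerance while the whole suite stays desk-scale.

## Known limitations

* The TPS inverse is approximate; per-edge round-trip error should be
  checked when accuracy matters.
* The KS naive mode reproduces common practice but is conservative with an
  estimated rate; use the bootstrap mode for calibrated inference.
* No image-space warping of voxel data (points and skeletons only), no
  masked/conical FSC, no iterative or cone-beam reconstruction.
* Automated consensus selection takes correctness flags as input; the
  curation that produces such flags is inherently manual.
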