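# Methods

## Geometry and conventions

A radial acquisition is 12 B-scans through the fovea, angles 0°–165° in 15°
steps, each nominally 9 mm wide. Image row 0 is the vitreous side; depth
grows with the row index; all indices are 0-based. A scan's angle is its
en-face orientation counter-clockwise from horizontal in [0°, 180°); the
left image half is the angle+180° half-line. Depth is posterior-positive
throughout.

Signed curvature is defined on the posterior-positive depth function f(x) of
the Bruch's membrane as κ = f″/(1+f′²)^{3/2}; κ > 0 means convex toward the
vitreous (an anterior bump), κ < 0 a posterior bowl. Under this convention a
normal posterior pole is uniformly slightly negative (−1/R of the globe), a
staphyloma floor strongly negative, and the staphyloma edge — an inflection
of the wall — crosses zero into positive values, which is exactly the
yellow-map / red-floor / green-ring reading of the color scale. Device
pixel calibrations (axial and lateral µm/px) are required inputs on every
scan; the software never assumes a vendor default.

## Segmentation

Per B-scan: a 3×3 median filter (speckle outliers), then two linear
responses on the denoised image —

* **layer (ridge) response**: negated axial second-derivative-of-Gaussian
  (σ_axial = 2 px, σ_lateral = 1 px), clipped at 0. The truncated derivative
  kernel's small DC leak is subtracted (via the separable smoothing response)
  so uniform regions give exactly zero; this keeps the scale-free threshold
  meaningful. The response is orientation-selective: maximal on bright
  horizontal bands, ~0 on vertical structure.
* **gradient response**: axial Sobel (3×3), positive where intensity grows
  with depth.

Per column, ridge peaks at or above `threshold_frac` (default 0.3) of the
image's ridge-response maximum are kept; the reference maximum is the 99.9th
percentile of the response rather than the literal maximum, so a handful of
bright speckle spikes cannot lift the threshold above the true band
response. The first supra-threshold peak from the vitreous seeds the ILM
(refined anteriorly to the nearest rising-gradient peak) and the
nerve-fiber-layer boundary (nearest falling-gradient peak posteriorly); the
last peak seeds the BM, refined posteriorly to the nearest falling-gradient
peak (the bright RPE/BM complex dropping into the darker choroid). Columns
with no supra-threshold peak, or excluded by a per-scan mask (e.g. mirror
inversion near the scan edges), stay invalid; detection is strictly
column-local, so it is left-right-flip equivariant.

The detected BM is smoothed by a 1-D open active contour: only the depth
coordinate moves, energy = α·Σ(Δd)² + β·Σ(Δ²d)² − Σ ridge(d) with α = 0.1,
β = 1.0, ≤ 200 gradient-descent iterations with backtracking line search
(energy non-increasing by construction), convergence when the maximal
displacement falls below 0.01 px. Manually corrected columns (CSV of
angle/column/depth re-plots) are pinned fixed points; invalid columns split
the contour into independent spans. The snake may re-centre the trace onto
the band ridge by a roughly constant 1–2 px depth offset; curvature is
invariant to depth translation, so this does not bias κ. The NFL boundary is
detected for completeness but feeds nothing downstream.

## Curvature

The BM trace is scaled to µm (position relative to the fovea column), then
linearly interpolated onto a 1-µm grid; gaps wider than 1000 µm are never
bridged. The three-point stencil with h = 500 µm — the protocol's A-scan
spacing — is evaluated at every 1-µm grid centre whose entire ±500-µm window
is valid; centres within 500 µm of the trace ends are discarded, leaving an
8-mm evaluation extent from a 9-mm scan. Evaluating the fixed 1000-µm window
at 1-µm steps (rather than only at the 19 A-scan nodes) is the dense limit
of the same definition and makes the metrics insensitive to grid phase;
`metric_sampling="ascan"` restores node-only pooling. Collinear samples give
exactly zero. Interpolation is deliberately linear and the snake is the only
smoother, so the stencil is the sole differentiator; on smooth analytic
traces the stencil error is O(h²) (≈1.6% of 1/R at R = 2 mm, <0.1% at 13 mm).

## Color map and en-face rendering

κ = 0 → yellow (255, 255, 0); linear per-channel gradients to green
(0, 192, 32) at +0.0005 1/µm and red (255, 0, 0) at −0.0005; clamped beyond
±1/2000; channels rounded half-up (so +0.00025 → (128, 224, 16) exactly).
Channel-linear interpolation is a choice the scale's description leaves
open; it is exposed in `ColorScale`.

The en-face raster (default 10 µm/px over the 9-mm field, fovea at the
centre pixel) interpolates κ — not RGB, which would wash out the
zero-crossing ring — linearly in angle between the two adjacent directed
half-lines at equal radius, then colors. If exactly one angular neighbour is
valid at that radius its value is used unweighted; a pixel is invalid only
when its *nearest* half-line is invalid, so a fully masked scan costs its
angular share (1/12) of the map. Rendering is rotation-equivariant (rotating
all profile angles rotates the raster). Coverage is the valid fraction of
the 8-mm analysis disk (9 mm minus the two 500-µm margins). Registration of
the map onto SLO or fundus photographs is out of scope.

## Metrics and classifier

Mean |κ| and the population variance of signed κ are pooled over all valid
samples of all profiles. Variance is of *signed* κ: that is what separates a
smooth deep bowl (low variance) from an undulated mosaic surface (high
variance). Dimensionally the variance is 1/µm². The staphyloma call is
mean |κ| ≥ 7.8×10⁻⁵ AND var κ ≥ 0.26×10⁻⁸, both inclusive. Cohort summaries
report per-label n, mean and sample SD (n−1); single-eye groups report SD 0
with an explicit `sd_defined=False` flag.

## Synthetic phantoms

The surface model is a base sphere (radius default 13 000 µm, a myopic
globe) contributing −sagitta(r) relative to the fovea, plus optional
Gaussian deformations that add posterior depth: a staphyloma bowl (default
800 µm deep, σ = 1500 µm — deep enough to flip the floor well past the
classifier thresholds while keeping the edge ring inside the 4-mm analysis
radius) and a focal choroidal excavation (default 150 µm, σ = 300 µm, the
narrow "red spot" lesion). B-scans are rendered at 7 µm axial × 20 µm
lateral px (451 columns = 9 mm), with a 300-µm retina between a
hyperreflective ILM band and the bright RPE/BM complex; band rows are the
rounded trace rows and are returned as ground truth, and the BM edge is
built so the axial Sobel extremum falls exactly on the true row — hence
noiseless detection is exact by construction. Speckle is multiplicative
log-normal, I·exp(σZ − σ²/2), default σ = 0.2 (moderate clinical quality;
0.3 is used as a stress level). Everything is seeded and byte-reproducible.

What the phantoms do *not* emulate: fan-beam/optical distortion of OCT
geometry (out of scope; local 1000-µm curvature is reported to be robust to
it), vessel shadows, motion artifacts, real mirror inversion (modelled only
as band-free columns or explicit masks), and pathology-distorted inner
retina. Passing phantom tests therefore validates the geometry and
statistics of the method, not segmentation robustness on poor-quality
clinical images — where manual re-plots remain the fallback, as in practice.

Metric-space cohorts for classifier studies draw (mean |κ|, var κ) pairs per
eye from moment-matched log-normal marginals with correlation 0.8 on the log
scale. Log-normality reflects that both metrics are positive and
right-skewed (the with-staphyloma variance has CV ≈ 0.73; a normal would put
~8% of its mass below zero), and the strong positive coupling reflects that
both rise together with staphyloma severity.

## Numerical choices and degenerate inputs

* Detection ties: peak plateaus resolve to the first (most anterior) index
  for the ILM's "first peak" and the last for the BM's "last peak".
* Traces shorter than the 1000-µm window yield an empty profile with a
  warning, not an error; an eye with zero valid κ samples raises.
* CSV floats are written at 17 significant digits and read back with
  round-trip parsing, so CSV I/O is bit-exact; 8- and 16-bit images are
  never rescaled.
* Snake divergence (energy increase beyond tolerance) raises; backtracking
  makes this unreachable in practice.
* A single-scan set loads with a warning; en-face rendering requires ≥ 2
  distinct angles.

## Problem sizes

Defaults are sized for desk-scale validation: 12 scans of 177–420 × 451 px
per phantom eye (~2–3 s per eye end-to-end), 1-µm curvature grids of ~9000
samples per line, and 100-eye-per-group metric-space cohorts.

## Known limitations

1-D curvature per scan line, not surface (2-D) differential geometry; no
vendor/DICOM readers (JSON + TIFF/PNG manifests only); no automatic
mirror-artifact detection; inferential cohort statistics (ANOVA etc.) are
out of scope — the cohort table is descriptive only.
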