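# Methods

This note documents the models, estimators and defaults behind the
package, the design choices that were genuinely open, and what the
synthetic-data path does and does not establish about real angiograms.

## Data model and geometry

An en-face angiogram is a square grayscale image, min–max normalized to
[0, 1] per image (export intensity units vary by scanner and are not
assumed). The default acquisition geometry is a 3 × 3 mm field at
304 × 304 pixels centered on the fovea, one image per plexus (SVC, IVC,
DVC) per eye; other square sizes are accepted and the physical pixel
size is always `fov_mm / width` (≈ 9.87 µm at the default). Coordinates
are (row, col), 0-based, row 0 at the superior edge; all physical
conversions go through the pixel size. Laterality (OD/OS) is carried
with every image because it decides which side of the macular grid is
temporal.

## Vessel segmentation

**Enhancement.** Oriented log-Gabor quadrature filters (6 orientations,
σ/f = 0.55, wavelengths {2, 3, 4, 6} px) yield an even/odd response
pair per scale and orientation. The vesselness measure is phase
symmetry: Σ max(even − |odd|, 0) over orientations, normalized by the
summed amplitude plus a floor equal to the image-mean amplitude. The
floor suppresses the near-zero-amplitude background, where filter
ringing would otherwise read as symmetric structure; because it scales
with the signal, the whole map is invariant to global intensity scaling
(measured: < 10⁻¹² relative RMS change under a 5× contrast change).
Scales are combined by maximum and the map rescaled to [0, 1].

**Active contour.** A two-region Chan–Vese-type level set evolves under
the sum of inside/outside mean-deviation energies on *both* the
intensity channel and the enhancement channel (weights 1.0 / 1.0), plus
a boundary-length (curvature) regularizer with a deliberately low
default weight (0.1). The published family of models this follows uses
an infinite-perimeter regularizer to favor fine vessels; that
construction is intentionally not reproduced here — a low-weight
standard regularizer serves the same practical role for feeding
morphometry, and the module boundary allows a faithful variant to be
swapped in. Initialization is the Otsu threshold of the enhancement
map, making the pipeline deterministic and seed-free. Evolution runs at
most 300 iterations (dt = 0.45, smoothed Dirac ε = 1.5, φ clipped to
±3) and stops when fewer than 10⁻⁴ of pixels change sign;
non-convergence returns the current mask with a warning, never an
exception.

**FAZ extraction.** The vessel mask is morphologically closed (disk of
radius 6 px) to bridge inter-capillary gaps; the avascular connected
component containing the image center — or the nearest component within
15 px — is the FAZ, hole-filled, with its marching-squares boundary
attached. A vessel-free mask yields the whole image flagged degenerate;
a region touching the border is flagged clipped.

## The twelve biomarkers

FAZ shape (whole image; the FAZ is central by definition):

| metric | definition | default estimator |
|---|---|---|
| FA | FAZ area | pixel count; reported in px, mm², and % of field (reporting unit configurable, default %) |
| FC | 4πA/P² | perimeter from the smoothed subpixel contour (below) |
| FAR | major/minor axis | second-central-moment ellipse of the region |
| FR | 4A/(π·major²) | avoids the perimeter, hence less sensitive to border irregularity |
| FS | A / convex area | convex hull of pixel *corners* (guarantees FS ≤ 1; a plus-sign polyomino measures exactly 5/7) |

**Perimeter estimator.** The raw marching-squares contour of a
digitized smooth shape is ~5% long (staircase bias), and chain-code or
Crofton estimates trade that bias between smooth and straight shapes.
The default here resamples the subpixel contour at 0.5 px and applies a
periodic Gaussian smooth of σ = 1 px before measuring length: a
rasterized disk of radius 50 then measures FC = 0.991, an axis-aligned
square π/4 within 2%, and a 2:1 ellipse within 1.1% of the
Ramanujan-perimeter value. Crofton and chain-code remain available in
config.

Vasculature (on a region of interest):

* **Orientation field** — structure tensor (Gaussian σ = 2 px) on the
  mask or intensity image; vessel direction is the minor eigenvector,
  coherence (λ₁−λ₂)/(λ₁+λ₂).
* **Direction ellipse** — vessel-pixel orientations binned over [0, π)
  (36 bins), mirrored to a polar rose of radius = bin count; the
  ellipse comes from the rose's second-moment matrix with semi-axes
  √(2λ) so an isotropic rose of radius r maps to a circle of radius r.
  `direction_area` = πab (rose units², so it scales with the square of
  the vessel-pixel count), `direction_ratio` = b/a ∈ (0, 1]. This is
  one concrete operationalization of an ambiguously specified quantity;
  it reproduces the qualitative behavior expected of it (lower density
  ⇒ smaller area; ratio ≈ 0.8 on realistic masks) and is isolated
  behind a single function so alternatives can be swapped.
* **Tortuosity** — per skeleton branch, arc/chord; image value is the
  arc-length-weighted mean (unweighted selectable). Branch arcs are
  measured on the resampled, σ = 1 px smoothed polyline, which removes
  the up-to-8% digital staircase bias: a straight branch measures
  exactly 1.0 and a rasterized semicircle π/2 within 2%. Closed loops
  (chord ≈ 0, e.g. the perifoveal arcade) are excluded and counted in a
  diagnostics field. The arc–chord form was chosen because its
  magnitudes (≈ 1.1–2.7 on synthetic maculae) match the 1.56–1.98 range
  reported for real capillary networks; curvature-integral variants
  would need their own calibration.
* **VAD / VLD** — 100 × |mask ∧ region| / |region| and
  100 × |skeleton ∧ region| / |region|. VLD deliberately uses the raw
  centerline pixel count (its definition), not a length estimate.
* **FD** — box counting on the binary mask (not the skeleton) with
  sizes {2, 4, 8, 16, 32, 64, 128}, grid anchored at the origin
  (4-offset averaging available); FD = −OLS slope of log N(s) vs log s.
  Validated on a line (1.00), a filled square (2.00) and a depth-5
  Sierpiński carpet (log 8/log 3 ± 0.003).
* **B-num** — skeleton pixels are classified by connectivity number
  (0→1 transitions around the 8-neighborhood ring — robust against
  thick-diagonal thinning artifacts, unlike a raw ≥ 3 neighbor count);
  candidates within 2 px merge into one node at their centroid, since
  thinning emits junction-pixel clusters at oblique crossings. A
  degree-4 crossing counts as one node: a 2-D projection cannot
  distinguish crossing from branching. Skeletonization is
  topology-preserving thinning (scikit-image); skeleton *length* (used
  only for ground-truth validation, not for VLD) applies
  Vossepoel–Smeulders weights (0.948 axial / 1.340 diagonal).

Branch extraction walks pixel chains between nodes (junction pixels and
their skeleton neighbors are blocked before labeling, since sibling
arms stay 8-connected past the junction pixel itself); terminal spurs
shorter than 5 px are pruned and nodes recomputed once.

## ETDRS grid

Central circle of diameter R = 0.75 mm around the grid center (the FAZ
centroid, falling back to the image center when the FAZ is degenerate),
internal ring to 2R, external ring to 3R, quadrants bounded by the ±45°
diagonals. Superior is up; temporal is image-left for OD and
image-right for OS. Pixels exactly on a diagonal go to the
superior/inferior sectors (closed intervals): this tie rule is
deterministic and makes the OD and OS partitions exact mirror images,
which a "clockwise-next" rule cannot be. The central circle is its own
region and is excluded from the eight sectors. Sector masks partition
their annuli exactly, so area-weighted sector densities reproduce
annulus densities to machine precision. Per-sector FD box-counts the
sector-restricted foreground on the sector's bounding box; per-sector
tortuosity averages branches whose midpoint falls in the sector; B-num
counts nodes by coordinate membership.

## Statistics

* **t-tests** — Welch by default (the compared groups' SDs differ
  visibly; the demographic worked example reproduces under both
  variants, so the choice is safe), pooled available; the
  summary-statistics form is the primary implementation and the
  raw-sample form reduces to it exactly (equivalence held to 1e-12 in
  tests). Degenerate zero-variance inputs return p = 1 (equal means) or
  a flagged p = 0. Demographic comparisons use eye-level n (50/44):
  the published age p-value (0.904) reproduces under eye-level n and
  not under subject-level n; subject-level remains a config option.
* **Logistic regression** — own Newton/IRLS maximum-likelihood fit
  (convergence |score| < 1e-8, 100 iterations), validated against
  statsmodels to 1e-6. Predictors are z-scored by default so odds
  ratios are per SD — unscaled predictors spanning ~10⁵ raw units
  otherwise produce the degenerate-looking OR = 1.000 (1.000–1.000).
  Perfect separation is flagged with a 0/∞ sentinel, never an
  exception; constant covariates (e.g. gender in an all-female cohort)
  are dropped with a warning.
* **Significance maps** — pure threshold function at p ≤ 0.001 /
  p ≤ 0.05 (closed boundaries). No multiple-testing correction by
  default, matching common practice in the source literature; an
  optional Benjamini–Hochberg flag never increases the significant
  count.

## Synthetic data

**What it emulates.** Trees grow from border roots by a discrete random
walk (step 3 px, heading jitter σ = 8°/step) with per-step bifurcation
probability 0.05 and mean split half-angle 35°, pulled gently toward
the image center (20% of the angular error per step) to emulate the
centripetal course of macular vessels. The FAZ is a noise-perturbed
ellipse (default 0.3 mm², a typical healthy value at this field size)
ringed by a terminal capillary arcade — a closed centerline loop just
outside the polygon, as in real maculae — which is what makes the
avascular zone recoverable by segmentation. Centerlines keep a
clearance of 2 × width + 3 px from each other so rasterized vessels
never fuse; masks are centerline dilations by a 2 px disk; images add
multiplicative Gaussian speckle (σ = 0.15) and a linear background ramp
(amplitude 0.1), the two dominant OCTA artifacts the segmentation must
tolerate. Every polyline, split event and branch arc/chord is recorded
during growth, so bifurcation counts, centerline length, FAZ area and
axial ratio have *exact* ground truth: bifurcation recovery is exact on
500/500 default trees, skeleton length within 5%, and FAZ area/axial
ratio within 10% through the full noisy segmentation path.
Split events whose arms fail to establish at least 10 px are rolled
back and not counted; junction sites keep ≥ 5 px mutual separation so
skeleton-based detection is unambiguous.

**What it does not emulate.** Capillary-texture realism, perfusion
variation, projection and motion artifacts, vessel-caliber
distributions, and inter-metric correlation structure. Cohort tables
draw each biomarker independently per eye from published group
means/SDs — marginals match the source populations, but joint structure
does not (the source tables disclose only marginals). Passing tests
therefore establish estimator correctness and pipeline calibration on
controlled geometry, not segmentation performance on real OCTA texture.

**Cohort presets** embed the published per-group mean (SD) of all 12
biomarkers × 3 plexuses for the patient-vs-control, optic-neuritis and
non-optic-neuritis contrasts, plus demographics (age, BMI, visual
acuity), at the published eye-level sample sizes (50/44/25/19). The
power of the simulated superficial-plexus vessel-density contrast at
α = 0.001 is 0.829 by the noncentral-t distribution (Welch df 85.7,
noncentrality 4.38); simulation reproduces this within binomial error,
and at α = 0.05 the power is 0.991.

## Numerical and degenerate-input choices

* Constant images normalize to all zeros and segment to empty masks.
* Empty vessel masks: VAD = VLD = B-num = 0; FD, tortuosity and the
  direction ellipse report NaN (recorded missing), never an exception
  on the assembly path.
* The direction ellipse of a single-orientation field is degenerate:
  area and ratio 0 with a flag.
* All generators are pure functions of (parameters, seed); identical
  seeds give byte-identical images and masks.
* Problem sizes in the test suite (500 trees for exact recovery, 20
  noisy fixtures for the segmentation path, 1000 replicate cohorts for
  coverage and power) were chosen to put Monte-Carlo error well below
  the tolerance being checked while keeping the default run in the
  low minutes.

## Known limitations

* The segmentation is a competent simplification, not a reproduction of
  the published infinite-active-contour model; its role here is to feed
  morphometry, and all downstream analysis accepts precomputed masks.
* FA's published scale (values near 3–4 for a region that is ~0.3 mm²
  and ~3% of the field) matches none of px/mm²/% exactly; FA is stored
  in all three units and reported in % by default. Similarly, published
  FR magnitudes (32–50) are inconsistent with any unit-free roundness
  definition; FR here is standard roundness (≤ 1) and no attempt is
  made to reproduce those magnitudes.
* 2-D projection makes crossings and bifurcations indistinguishable;
  B-num counts both as one node.
* Absolute biomarker values of the source cohorts cannot be reproduced
  without the patient images; only their statistical structure is
  emulated.
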