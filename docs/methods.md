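# Methods

This note records the modeling assumptions, parameter choices, and numerical
conventions behind `aerolus`, in the spirit of a package methods appendix.

## The measurement problem

Ultrasound cannot image an aerated lung directly: air reflects the beam at
the pleura, so the image below consists of reverberation artifacts.  The
package treats the clinical question — *how much air is in the superficial
lung?* — as a regression problem: artifact statistics extracted from the
cine clip predict the proportion of air measured independently on CT in the
lung region the beam interrogates.  Everything is exercised on synthetic
data with known ground truth, so the statistical machinery (not any one
rendering) is what the tests certify.

## Synthetic data generator

### What it emulates

* A pressure-titration experiment: per lung, air fraction follows a
  saturating logistic response of airway pressure, normalized to 0 at
  0 cmH₂O and to a lung-specific maximum at 50 cmH₂O.  Lung-level
  parameters are drawn per lung: maximum air fraction ~ N(0.64, 0.05)
  (clipped to [0.45, 0.80]) so lungs saturate well below full aeration,
  half-response pressure ~ N(27, 2) cmH₂O and logistic width ~ N(7, 0.8)
  cmH₂O, placing the first type-1 appearance near 20 cmH₂O and type-2 near
  35 cmH₂O.  Deflation follows the inflation curve raised to a power
  γ ~ N(0.4, 0.05) < 1, so at equal pressure the deflating lung always holds
  at least as much air (hysteresis holds *exactly* because air fractions are
  deterministic given lung parameters; observation noise enters only through
  image rendering).  Suction deflates to a small per-lung residual
  (uniform 1–9 %).
* Grade-dependent artifact morphology.  Air-fraction breakpoints
  (0, 0.15, 0.50, 0.85) bin observations into grades {0, 0.5, 1, 2, 3}:
  homogeneous dim tissue (0); discontinuous bright pleural segments at
  depths 0.3–2 cm (0.5); a continuous pleural echo over a confluent bright
  field (1); distinct vertical B-line streaks plus horizontal A-line bands
  (2); A-lines only (3).  Within types 1–2 the rendering varies continuously
  with air fraction: the white-out field dims and develops column structure
  as air rises; type-2 streaks widen and brighten while their count falls
  from `bline_count_max` to 1; A-line intensity grows with air.  A
  consequence worth noting: MPI *decreases* with air across types 1–2
  (discrete bright artifacts over a darkening background average dimmer than
  a white-out), while remaining strictly increasing over grades 0 → 0.5 → 1.
* A-line geometry: reverberation bands at depths m·d_pleura for m ≥ 2 with
  intensity I₀·decay^(m−1) (the m = 1 echo is the pleural line itself);
  decay defaults to 0.6.  The pleural depth defaults to 1.0 cm so the A-line
  fundamental (1/d = 1 cycle/cm) sits inside the default spectral band.
* Speckle: multiplicative log-normal noise, `exp(σZ − σ²/2)` (mean
  preserving, keeps 8-bit intensities non-negative), σ = 0.30 per frame.
* The inflation/deflation asymmetry: during deflation and suction, speckle
  dispersion and all clip-level rendering jitters (gain ±4 %, field/
  background brightness ±7 %, streak brightness ±7 %, A-line intensity
  ±12 %, B-line count ±0.8) are inflated by the deflation noise multiplier
  (default 1.5), so deflation-only fits are systematically weaker.
* CT phantoms: a slab lung with a 2-voxel exterior margin viewed along
  axis 0.  The superficial region holds an *exact* count of air voxels
  (`round(f·n)`), so the realized fraction is within 1/(2n) of the request;
  gray values are clipped around 0.05 m⁻¹ (air) and 0.40 m⁻¹ (tissue) so
  thresholding at 0.15 m⁻¹ is error-free, and a bright "vessel" block is
  buried 4 mm below the superficial region to verify the 1-cm restriction
  excludes deep structures.

### What it does not emulate

No acoustic wave propagation, beamforming, curvilinear geometry, motion, or
probe-dependent gain response; no atelectasis-versus-liquid ambiguity; rib
shadows are fixed lateral bands.  Passing tests therefore demonstrate that
the *analysis* recovers what the generator encodes — not that any specific
artifact statistic would attain the same accuracy on clinical images.

## Image statistics

* Population (ddof = 0) standard deviation in CoV.
* Spectra: per-line `|DFT|²/N`, lines along the stated axis, averaged over
  the orthogonal axis, trapezoid-integrated over the frequency grid points
  inside the band.  The band excludes DC, must stay at or below Nyquist and
  contain at least two grid points; no window by default (a Hann window is
  available behind a flag).  Offsets are invisible (DC excluded); intensity
  scaling by *a* scales AUCs by a².
* Band default 0.1–2.0 cycles/cm: brackets the A-line fundamental
  (1 cycle/cm at the default pleural depth) and the quasi-periodic B-line
  pitch (streaks are placed evenly with random offset and ±8 % jitter, so
  pitch ranges ≈ 0.7–3.5 cm⁻¹·…; at low counts the pitch frequency falls
  inside the band).
* Pooling: frames first within each ROI, then area-weighted across ROIs.
  With multiple depths supplied, MPI and spectral AUCs use the 4-cm ROIs,
  CoV the 2-cm ROIs; a single supplied depth is used for everything.
* Coordinates: 0-based pixel indices, row 0 at the transducer face.

## CT ground truth

Air = gray value strictly below the threshold (default 0.15 m⁻¹) inside the
lung mask.  The superficial region is built with an exact Euclidean distance
transform (anisotropic voxel sampling respected) from the *probe-facing*
boundary only: the background set is the non-lung voxels lying in front of
the first lung voxel of each transverse column, plus a virtual plane at the
volume face.  Lateral and deep lung boundaries do not generate distance, so
a 30-mm slab at 1-mm voxels yields exactly the first 10 layers at a 10-mm
depth.  The depth is measured from the lung boundary (the pleural surface),
not the skin.

## Grading

Consensus follows the two-rater-plus-tiebreaker protocol; the grade enters
regression models as a numeric covariate with 0.5 steps (a single
coefficient).  The rule-based auto-grader is a surrogate rater for
synthetic clips only: thresholds (echo level 100, pleural coverage 0.6,
A-line contrast 1.25, ≥ 2 B-line columns) are calibrated on the generator
and documented as such; it is not a clinical classifier.

## Regression stage

Ordinary pooled least squares via statsmodels (repeated lungs within lambs
are deliberately not modeled as random effects, matching the pooled
protocol the pipeline replicates).  Reported per model:

* r² (equals the squared sample correlation for the simple models);
* two-sided coefficient p-values from the t distribution;
* the 95 % prediction-interval half-width at the covariate mean,
  `t₀.₉₇₅,df · s · √(1 + 1/n)` (the leverage of the mean point is 1/n), plus
  the mean half-width over the training points as an alternative summary —
  the evaluation point of a single quoted "± x %" interval is otherwise
  ambiguous;
* full prediction intervals at arbitrary covariate points (leverage term
  included); displayed bounds are clamped to [0, 100] % with raw values
  retained.

Backward elimination removes the covariate with the largest p-value while
it exceeds α (default 0.05, the package-wide significance convention),
refitting each time; if everything is removed an intercept-only fit is
returned with a warning status.  AUC∥ enters the multivariate model on the
log₁₀ scale, consistent with its simple model.  Kruskal-Wallis uses
mid-ranks with the standard tie correction (H defined as 0 when every value
ties); the paired t-test uses sample-SD differences.

## Problem sizes and numerical checks

Cohort-level computations use the desk-scale geometry (208 × 160 px at
0.025 cm/px, 45 frames, 32³ CT at 1 mm) — small enough that a full 7-lamb,
14-step study simulates and analyzes in well under a minute, while keeping
every ROI ≥ 16 px in both transform directions.  Single-volume checks use
the full 64³ / 0.5-mm phantom.  Statistical operating characteristics are
checked by simulation: coefficient recovery over 100 replicates of n = 168,
prediction-interval coverage on 1,000 points from a model fitted to 1,000
training points (the training size keeps the conditional coverage of one
fitted model within the [93, 97] % acceptance window), and null-covariate
retention over 500 fits.  Oracle comparisons (direct pixel loops, naive
O(N²) DFT, per-voxel scans, exhaustive distances) run on 16×16 blocks and
small grids where brute force is exact and affordable.

## Known limitations

* The generator's artifact model is phenomenological; coefficients fitted on
  synthetic cohorts (e.g. multivariate r² ≈ 0.87 at the default noise
  settings) characterize the synthetic conditions, not clinical imaging.
* Suction is treated as deflation to a small residual air fraction; how
  airway re-flooding changes image texture beyond that is not modeled.
* CoV acquires a phase-dependent offset because the deflation multiplier
  inflates speckle dispersion, which is itself the CoV noise floor; pooled
  ("all data") fits for CoV are accordingly weaker than either subset.
* Type-3 images never arise under the default lung parameters (maximum air
  fraction < 0.85), so per-grade summaries report type 3 as N/A.
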