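# Methods

This note documents the models, defaults and numerical choices behind each
module, what the synthetic generators do and do not emulate, and the known
limitations.

## 77 K spectrum processing (`photophen.spectra`)

Processing order is fixed and recorded as provenance:
resample → smooth → baseline → normalize. The order matters — subtracting a
baseline from an already-normalized spectrum changes the statistic — so the
pipeline rejects out-of-order application rather than silently accepting it.

- **Resampling**: linear interpolation onto a uniform grid (default 0.5 nm)
  strictly inside the measured range; no extrapolation.
- **Smoothing**: centred running average over all points within ±2 nm
  (4 nm window, inclusive), truncated at the spectrum edges. The window is
  interpreted inclusively so that on a 1 nm grid a unit impulse spreads to
  exactly five points of 1/5 each; edge handling (truncated mean) is our
  choice, as common spreadsheet implementations leave it unspecified.
- **Baseline**: chlorophyll no longer emits at 800 nm, so the zero level is
  estimated there. We use the mean over 798–802 nm rather than the single
  800 nm sample for robustness to single-pixel noise. Negative values after
  subtraction are noise about zero and are kept, not clamped.
- **Normalization**: division by the maximum over the PSII window
  (680–690 nm). Peak-wavelength ties break toward the shorter wavelength for
  determinism. Normalization is idempotent and the PSI statistic is invariant
  under any positive rescaling of the raw spectrum.
- **PSI statistic**: the maximum of the processed spectrum over 710–730 nm,
  with its wavelength. A window *maximum* rather than a fixed wavelength is
  used because some taxa lack a distinct PSI peak; in that case the maximum
  sits on the window edge of a monotone tail and the result carries a
  no-local-peak flag instead of failing. A fixed-wavelength readout can be
  obtained by evaluating the processed spectrum directly.

**Dilution QC.** Self-absorption in concentrated powder samples distorts the
spectral shape (preferentially suppressing the strongly re-absorbed PSII
emission, which inflates the normalized PSI statistic). Samples measured as
a dilution series are screened by walking from most concentrated to most
dilute and selecting the most concentrated member whose PSI statistic agrees
with the next more dilute one within a relative tolerance (default 0.05,
configurable — agreement "in shape" is inherently a judgement call). If no
neighbouring pair agrees, the most dilute spectrum whose raw PSII signal
still exceeds a noise floor is selected and the series is flagged.

## PAM parameters (`photophen.pam`)

All parameter formulas are standard saturating-pulse definitions; F₀′ uses
the Oxborough–Baker estimate F₀′ = F₀/(F_V/F_M + F₀/F_M′), which reduces to
F₀ exactly in the dark limit F_M′ = F_M. The 0.42 rETR absorption factor is
a plant-derived estimate of the fraction of incident photons absorbed by
PSII; it is a named, configurable constant because it is not universal
across taxa.

**Pulse extraction.** The steady-state F is the mean over a pre-pulse window
(default 2 s, excluding in-pulse samples); F_M′ is estimated over a peak
window (default 1 s) from pulse onset. The default peak estimator is the
*mean* of the in-pulse samples: a saturating pulse holds fluorescence at a
plateau, and the sample maximum is biased upward by roughly half a noise SD,
which propagates into a systematic NPQ underestimate on noisy traces. The
maximum remains available (`peak_method="max"`) for windows that span a
rising transient. Pulses whose peak falls below the pre-pulse mean are
flagged and kept.

Negative NPQ and qL outside [0, 1] are reported raw with flags, never
clipped: they are quality-control signals (e.g. an imperfect dark reference).
Rapid light curves measured without dark acclimation need an explicit
`dark_reference=(F0, Fm)`; the group light curve is truncated before the
first PPFD step at which any replicate's rETR is non-positive, while
per-replicate curves are kept whole.

## Shape analysis (`photophen.shapes`)

Segmentation is a classical pipeline: percentile intensity normalization
(1st–99.9th), Gaussian smoothing (σ = 1 px), Otsu or fixed thresholding, and
optional splitting of touching blobs by watershed on the distance transform.
Watershed seeds are local maxima of a σ = 2 px smoothed distance map with a
minimum separation (default 10 px, of the order of the smallest expected
object radius); smoothing the distance map suppresses the spurious ridge
maxima that would otherwise oversplit elongated objects. Externally produced
label masks can be imported and re-measured through the same path, so the
measurement stage is independent of the segmenter.

**Perimeter.** Pixel-edge perimeters overestimate boundary length by up to
~27 % and would cap a true circle's circularity near 0.79, so the perimeter
is the length of a sub-pixel contour: the marching-squares 0.5-level contour
of the binary mask, regularised by a periodic cubic smoothing spline and
densely resampled. The spline's total squared-deviation budget is 0.05 px²
per contour vertex — a fixed sub-pixel allowance that removes the half-pixel
staircase wiggle at every object scale while leaving genuine curvature
intact. With this estimator the measured circularity of a rasterized circle
converges monotonically to 1 with radius (|error| ≈ 0.010 at r = 10 px,
0.0006 at r = 100 px), a rasterized 100 px square measures within 0.023 of
π/4, and ellipse fields are recovered to a mean |error| below 0.01.
Objects whose contour has fewer than 10 vertices fall back to the raw
polygon length; such objects are below any sensible minimum-area cut anyway.
Area is the pixel count times the pixel area. Circularity values slightly
above 1 can occur (estimator tolerance ~0.02) and are flagged, not clipped.

Border-touching objects are flagged and excluded from replicate summaries by
default, since their shape is truncated by the field of view. Replicate
summaries with fewer than 50 objects carry a low-count flag.

## Gated statistics (`photophen.stats`)

Per comparison family, at α = 0.05: Shapiro–Wilk per group and Levene across
groups; the parametric branch (Student's t for two groups, one-way ANOVA +
Tukey HSD for three or more) requires every check to pass, otherwise
Kruskal–Wallis + Dunn. Choices left open by common practice, made here:

- Levene runs with `center="median"` (the Brown–Forsythe form), matching the
  default of R's `car::leveneTest`; `center="mean"` is available.
- The two-group parametric test is the equal-variance Student form — the
  gate has already required variance homogeneity — with Welch as an option.
- Dunn's z-tests use the pooled-rank statistic with tie correction
  (T = Σ(t³−t)/(12(N−1))) and Holm adjustment by default (Bonferroni or
  none configurable). Dunn post-hoc implemented in-package.
- Groups smaller than 3 or constant-valued make normality testing undefined
  and force the non-parametric branch with an explanatory note. Data in
  which every pooled value is identical short-circuit to p = 1 (rank tests
  are undefined there, and no dataset could be less suggestive of a
  difference).

Under seeded Gaussian null simulations both omnibus branches reject within
the binomial 95 % interval around 0.05 (1000 replicates, 3 groups of 8; see
the test suite), and the empirical power of the full gated procedure for a
3 SD two-group effect at n = 4 exceeds 0.9 (`power_check`).

## Synthetic generators (`photophen.synth`)

The generators exist to make every pipeline stage recovery-testable; their
defaults define the standard test conditions used throughout the suite.

**Spectra.** A sum of Gaussian bands — PSII at 685 and 695 nm (σ = 6, 7 nm;
amplitudes 1000 and 550 counts) and PSI at 715 nm (σ = 10 nm; 450 counts) —
on a 50-count offset, over 650–800 nm at 0.5 nm. State 2 multiplies the PSI
amplitude by 2. Self-absorption is modelled as attenuation by
exp(−c·A(λ)), with A an idealized chlorophyll-like red-absorption profile
(Gaussian Qy band at 680 nm with a short-wavelength shoulder, normalized to
1; shipped as a packaged table and synthetic by construction). Because A is
~25× larger in the PSII window than at 710–730 nm, increasing c inflates
the normalized PSI statistic — the qualitative distortion the dilution QC
screens for. Real spectra have vibronic structure, wavelength-dependent
instrument response and correlated noise; none of these are emulated, so
passing recovery tests demonstrates correctness of the *processing*, not
robustness to every instrumental artefact.

**PAM traces.** Defined by inverting the analysis formulas: given NPQ(t) and
qL(t), F_M′ = F_M/(1+NPQ), F₀′ follows, and F is the unique root of the qL
definition, F = F_M′F₀′/(qL·(F_M′−F₀′)+F₀′). Defaults: F₀ = 400,
F_M = 2000 (F_V/F_M = 0.8), pulses every 30 s (1 s wide, sampled at 0.5 s),
a 120 s dark segment followed by 15 min red and 15 min far-red light. The
steady fluorescence is held piecewise-constant over each inter-pulse
interval at the value implied by the courses at the terminating pulse's
onset, so the analyser's pre-pulse-window mean recovers F exactly; this
makes the noise-free round trip an exact (≤ 1e−9) oracle rather than an
approximate one. No electron-transport or quencher kinetics are modelled —
the generator's purpose is formula-consistency, not mechanism.

**Images.** Non-overlapping ellipses (rejection-sampled placement with a
bounding-circle separation, default 3 px) with lognormal axis-ratio
distributions: ratio ~2 emulates ovoid free-living-algal chloroplasts,
~1.05 the near-spherical kleptoplasts observed in sea-slug cells. Defaults:
geometric-mean radius 2.5 µm at 0.2 µm/px (12.5 px), 10 % radius CV,
Gaussian noise (σ = 30 counts on a 3000-count signal), σ = 1 px blur.
Ground truth carries the analytic area πab and the Ramanujan-II perimeter
approximation (relative error < 1e−6 for axis ratios ≤ 5). Real micrographs
add out-of-focus light, intensity gradients within plastids and genuinely
touching organelles; the generator's separated, uniform-intensity objects
test the measurement chain, not segmentation under worst-case crowding.

## Problem sizes in the validation suite

The suite's simulation scales were chosen to give stable statistics while
keeping the full run fast on a laptop: 200 repetitions for the
state-transition null (5 spectra per group per repetition), 1000 null
replicates for type-I calibration (3 groups × 8), a 200-object scene at
1200×1200 px for shape recovery and 6 replicates per group (60-object
scenes at 800×800 px) for group separation. The whole suite runs in well
under a minute.

## Known limitations

- The dilution-selection tolerance (0.05 relative) operationalises a
  criterion that is visual in practice; borderline series should be
  inspected.
- The perimeter estimator is documented, not claimed identical to any
  particular imaging software's; absolute circularity values from different
  estimators should not be mixed in one analysis.
- The classical segmenter assumes bright convex-ish objects on a darker
  background; densely packed or strongly non-convex organelles are better
  segmented externally and imported as label masks.
- Statistical gating inflates neither branch's type-I error in our
  calibrations, but pre-testing is debated; the branch can be forced
  (`force_branch=`) when a fixed analysis plan is preferred.
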