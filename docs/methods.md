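# Methods

This note documents the models, numerical choices and limitations behind
`cochleametrics`.  It is written for someone who wants to trust (or doubt) the
numbers the pipeline produces.

## FCS forward model and estimation

**Model.** Indicator molecules diffuse in a periodic box; the confocal
detection profile is a 3-D Gaussian, `exp(−2(x²+y²)/w² − 2z²/(Sw)²)`, with
lateral 1/e² waist `w` (default 0.3 µm) and axial elongation `S` (default 5, a
typical confocal value; detection-volume calibrations vary by instrument and
are deliberately declared, not inferred).  Photon counts per bin are Poisson
with rate `background + Σ ε·profile(r_m)`, where `ε` is the per-molecule count
rate at the beam centre.  Anomalous transport (0 < α < 1) uses fractional
Brownian motion with Hurst exponent H = α/2 per axis, generated by
Davies–Harte circulant embedding (exact covariance; Cholesky fallback when the
embedding is numerically indefinite), so MSD(t) = 2Dt^α per axis by
construction.

**Box size.** The box must be large enough that the periodic images of the
detection profile do not distort the correlation decay.  An exact Fourier-mode
computation of G(t) for periodic-box diffusion shows that a box of 10× the
beam waist — where the axial profile extent `S·w` equals half the box —
biases the fitted τ_D by −7% structurally; at 15× the bias is −2.5%, below the
statistical scatter of a 60-s measurement.  The default box is therefore
4.5 µm with 606 molecules (N_eff ≈ 5).  All analytic ground truths
(mean rate, N_eff, apparent brightness) use box-truncated profile integrals.

**What the estimator recovers.** `G(0) = 1/N` counts molecules in the
effective volume `V_eff = (∫f)²/∫f²`, while the mean rate integrates the
flux-weighted volume `V_psf = ∫f`.  The brightness estimator
`(rate − background)/N` therefore recovers `ε·V_psf/V_eff` (γ·ε with
γ = 2^{−3/2} ≈ 0.354 in the wide-box limit), not the beam-centre ε.  The
simulator records this *apparent* brightness as the ground truth against
which recovery is judged.

**Correlator.** Both schemes evaluate the exact fluctuation estimator
`G(k) = [Σ δF_t δF_{t+k}/(n−k)] / mean²` via FFT; the multi-tau scheme is a
*lag grid* (16 lags per octave, bin-doubled spacing, capped at a quarter of
the trace), not the classic hardware coarse-graining, which carries a
triangular-averaging bias.  Consequence: multi-tau and direct estimates agree
to machine precision at shared lags.

**Finite-record bias and the repetition workflow.** Normalising a 10-s trace
by its own mean depresses G at long lags by O(τ_corr/T).
`fcs.fit_preparation` therefore (i) normalises every repetition by the mean
pooled over all repetitions at that location, shrinking the bias by the
number of repetitions; (ii) fits only lags up to 2% of one repetition
(longer lags are noise- and bias-dominated); (iii) fits the averaged curve
unweighted — pointwise inverse-variance weights estimated from ~6 repetitions
are noisy enough to bias τ_D measurably; and (iv) takes parameter CIs from
the scatter of per-repetition fits (t-based), because residuals of a
correlation curve are strongly correlated across lags and curvature-based CIs
from a single curve are overconfident.

**Fit.** Trust-region least squares with bounds N > 0, τ_D > 0,
α ∈ (0.05, 1], S fixed by default (fitting S jointly with α is
ill-conditioned; a flag records the choice).  Initialisation: N₀ = 1/G(first
lag), τ_D₀ = lag at half of G₀, α₀ = 1.  Tolerances 1e−12, max 10⁴
evaluations; non-convergence returns a flagged result, never a silent one.
A triplet factor `1 + T/(1−T)·e^(−t/τ_T)` is included only when it improves
AIC by ≥ 4 *and* the fitted τ_T is below τ_D/10 — both conditions guard
against the triplet term absorbing slow diffusion structure.

## Morphometry

Areas follow the pixel-count convention (pixels whose centres fall inside the
ROI × pixel_size²); the subpixel shoelace area is kept only as a test oracle.
The gap is the shortest Euclidean distance between the TM polygon boundary
(edges, not vertices) and the reticular-lamina polyline, computed in
continuous coordinates (shapely) and scaled by the pixel size; intersecting
geometry returns 0 rather than a penetration depth.  Width uses the explicit
measurement segment when present, falling back to the ROI extent along the
basilar-membrane direction.  Detachment is `gap > threshold` with threshold
0 µm by default (controls have no measurable gap).  Coordinates are 0-based
pixel indices, x = column, y = row.

## Kinematics

Phase-stamped pixel records are averaged into half-open phase bins
(default 16 bins covering [0, 2π)); any pixel/bin combination without samples
is an error that names the offending pixels.  Frames are optionally smoothed
with a spatial Gaussian (σ = 1 px default; the acquisition's filter
parameters are not fixed by the contract).  Motion is estimated per pixel
between the cycle-mean image and each phase frame with an iterative,
warping Lucas–Kanade scheme (skimage's ILK optical flow, radius 7, 10 warps)
— a documented equivalent of wavelet-based flow for this contract: per-pixel,
subpixel 2-D trajectories.  Displacements are reported relative to the cycle
mean, in nm.  Texture-free pixels are flagged via a structure-tensor score,
not given fabricated motion.  Trajectories are averaged over 5×5 regions
before deflection is computed as the bin-wise tip − base vector difference;
the normalised deflection divides its amplitude by the base amplitude by
default (recorded in the result, configurable) — the normalisation axis of
group comparisons is a declared choice.  The noise floor is the apparent
motion amplitude of a stimulus-free baseline image set (~30 nm at the default
SNR), and recovery is judged against max(30 nm, 15%).

## Evoked potentials

Band-pass filtering is zero-phase (4th-order Butterworth, forward–backward)
so CM phase is never biased; the 300–3000 Hz passband is the recording
convention.  All Fourier analysis trims to whole stimulus cycles and uses a
rectangular window, making amplitudes exact for periodic inputs.  SP is the
mean over whole cycles during the stimulus minus the pre-stimulus baseline
mean; its sign convention is positive = depolarising, and group comparisons
use |SP| because the SP's sign depends on level and frequency.  Thresholds:
the response criterion is configurable in µV (the audiometric default is 3×
the pre-stimulus noise SD); the threshold is the lowest level whose amplitude
reaches the criterion, linearly interpolated between bracketing levels, with
an explicit not-reached flag.  DPOAE extraction requires f2/f1 = 1.2 and a
window holding whole cycles of f1, f2 and 2f1−f2 (the common fundamental is
f1/5); the leakage check fails loudly with a usable window length.  ABR
latency is implemented as largest-|peak| latency after onset — a stated
convention, not wave labelling.

## Statistics

The brightness model is Gaussian GLS with compound-symmetric within-animal
correlation: V_i = σ²[(1−ρ)I + ρJ] per animal.  For fixed ρ, β̂ and σ̂² have
closed forms through the analytic CS inverse; the scalar profile over ρ is
optimised numerically (admissible range ρ ∈ (−1/(m−1), 1)).  Estimation is
REML by default with t(n−p) reference for CIs and p values; ML is available.
The default matters: under the study-shaped null (4 sites × 25 animals/group,
ρ = 0.5) the dose-term type-I error is 0.069 with REML + t versus 0.073 with
ML + normal, because the dose varies only between animals and the effective
sample size is the number of animals, not of observations.  This mirrors the
behaviour of the standard GLS tooling for such models.  statsmodels' MixedLM
(random intercept, an equivalent parameterisation for ρ ≥ 0) serves as an
independent oracle in the tests.

ANOVA + Tukey–Kramer uses the unequal-n studentised-range form throughout
(group sizes differ in every cohort).  The rank-sum test reports the first
sample's rank sum W and a Z statistic with midranks, tie-corrected variance
and continuity correction — the reporting format used for CM comparisons;
Kruskal–Wallis handles ≥ 3 groups.  The human threshold model is OLS of the
250-Hz threshold on age and gap, with added-variable data exposed for
partial-regression plots.  All tests are two-sided; no multiplicity
correction beyond Tukey–Kramer.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the estimators rely on:
Poisson photon statistics over diffusing emitters, compound-symmetric
brightness tables with a linear dose effect (dose coded 0/1/2 for
control/low/high; the concentration scale of a "dose unit" is a free
parameter), rectangular section phantoms whose gap/area/width are exact by
construction, analytic Gaussian-textured bundles translating rigidly with
phase, and sinusoid + DC + Gaussian-noise waveforms.  They do **not** emulate:
photobleaching, detector afterpulsing or saturation; indicator binding
kinetics (brightness maps to calcium only through the indicator's response);
irregular histological shapes, staining gradients or annotator variability;
non-rigid or axial (z) bundle motion; neural adaptation or realistic ABR
morphologies.  Passing tests therefore demonstrate correctness of the
estimators under their stated models, not robustness to every artefact of
real recordings.

Problem sizes in the test suite are chosen to make the statistical checks
sharp at desk scale: 50 simulated preparations × 6 ten-second repetitions for
FCS recovery, 200 replicate tables for dose-coefficient coverage, 1000
replicates for null calibrations, 100 random phantoms for morphometry, and 20
seeds for deflection recovery.

## Known limitations

* The periodic-box FCS model retains a ~2–3% structural τ_D bias at the
  default geometry; it is documented rather than corrected because it is
  small against measurement scatter.
* α and τ_D are strongly correlated near α = 1 with S fixed; α's upper bound
  at 1 means Brownian data pile estimates at the boundary (expected).
* The GLS assumes a common residual variance across sites and doses.
* Optical flow degrades for displacements beyond ~5 px per phase bin; the
  phantoms' pixel size (40 nm/px) keeps physiological motion well inside
  that range.
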