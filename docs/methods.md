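# Methods

`vasodyn` quantifies arteriolar function in longitudinal mouse imaging
studies of cerebral amyloid angiopathy along three axes — vessel-wall
dynamics from two-photon data, perfusion from pCASL MRI, and cohort
statistics — and ships a synthetic-data generator that produces every
input with known ground truth. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
tests do and do not show about real data.

## Vessel dynamics

**Spectral convention.** All spectral statistics use the one-sided
amplitude spectrum `2|X_k|/N` of the mean-normalized, mean-subtracted
diameter trace `d(t)/mean(d) − 1`, with no taper. With this
normalization a sinusoid of relative amplitude *a* completing an
integer number of cycles in the window contributes exactly *a* at its
bin; all downstream statistics are invariant to this fixed choice and
to rescaling the raw trace. No window function is applied: leakage
from out-of-band components is accepted and quantified in the tests
against a brute-force DFT oracle rather than suppressed.

**Vasomotion peak.** The maximum in-band amplitude over bins with
frequency in [0.04, 0.13] Hz (band edges inclusive), with the bin's
frequency reported. The trace must span at least one period of the
lower band edge (≥ 25 s; the standard acquisition is 300 s at 2 Hz,
giving a 3.3 mHz resolution). Up to 5 % missing frames are linearly
interpolated before the FFT; a trace missing more is rejected for that
session rather than patched. Vasomotion peaks of the 2–4 arteriolar
segments within one field of view are arithmetically averaged to one
FOV-session value to avoid pseudoreplication in the longitudinal
models.

**Diameter extraction.** Per frame, the intensity profile normal to
the vessel is averaged along the ROI segment, background-subtracted
(median of the outer 10 % of samples per side), optionally smoothed
with a Gaussian (µm units), and the diameter taken as the full width at
half maximum with crossings located by linear interpolation —
sub-pixel, and exact for the generator's plateau-convolved-Gaussian
cross-section. Frames with no crossing pair (vessel lost) are flagged
missing, never fabricated.

**Pulsatility.** Two statistics on high-rate traces: (i) the mean
absolute value of the linearly detrended normalized trace — the
time-normalized absolute AUC, equal to 2a/π for a pure cardiac
sinusoid of relative amplitude *a* and exactly invariant to repeating
a periodic trace; (ii) the spectral amplitude maximum over the cardiac
search band, fixed at 5–16.7 Hz (300–1000 bpm). The frequency of that
maximum times 60 is the spectral heart-rate estimate, and the
measurement is excluded when it differs from the animal's reference
heart rate (from RBC velocimetry) by strictly more than 50 % — a
mismatch of exactly 50 % is kept. Detrending is linear least squares;
a detrend does perturb a finite sinusoid at second order, which is why
the closed-form tests use long windows (the 2a/π identity is verified
to 1e−6 absolute on 20 s at 40 kHz; at 20 samples per cycle the
statistic is accurate to ~1 %).

**RBC velocimetry.** Line-scan kymographs (rows = scan lines, columns
= positions) show moving red blood cells as slanted streaks with slope
`velocity × line_period / pixel_pitch` px/line. Windows of ≥ 32 lines
are mean-subtracted and the streak slope estimated by maximizing the
variance of the Radon projection, parameterized by slope rather than
angle so the search grid is uniform in velocity: each line is sheared
by −slope × index (linear interpolation) and the aligned average's
variance is the figure of merit. For steep slopes a streak crosses the
scan line within a few lines, so the window is split into sub-blocks
short enough that at least half the columns keep full support, and
block variances are averaged. The search is a 40-point geometric grid
per sign over 0.05–20 px/line plus zero, refined by a 41-point local
grid (≈ 0.9 % resolution; the recovery requirement is 5 %). A window
whose best-aligned projection retains less than 40 % of the window's
total variance is flagged missing — alignment preserves streak
contrast but averages pure noise away (measured contrast ≈ 0.25 for
noise, ≥ 0.5 for streaks). The heart rate is the frequency of the
maximal spectral amplitude of the windowed velocity trace in the
cardiac band, ×60, reported only when the peak rises ≥ 3× above the
median in-band amplitude.

**Amyloid coverage.** Percent of vessel-wall pixels whose amyloid
channel meets a fixed threshold, on a user-supplied wall mask. The
mask and threshold are inputs; no segmentation is attempted.

## ASL quantification

CBF is computed per label/control pair from ΔM = control − label via
the single-compartment model

CBF = λ · ΔM · e^(PLD/T1b) / (2 · α · T1t · M0t · (1 − e^(−τ/T1t))).

With λ in mL/g and T1t in seconds the right-hand side is in mL/g/s; a
factor 6000 converts to mL/100 g/min. Defaults: λ = 0.9 mL/g,
T1b = 2430 ms (blood T1 at 9.4 T), α = 0.80. T1t, PLD and τ are
sequence-specific configuration with synthetic defaults T1t = 1900 ms,
PLD = 300 ms, τ = 3000 ms — typical mouse values at 9.4 T, chosen once
and carried through the sidecar metadata; they are configuration, not
claims. α is a constant, not estimated per animal. Voxels with
M0t at or below threshold are masked (NaN), never divided. The
label/control order is read from metadata; only when absent does the
code fall back to even-index = label, with a warning.

**Profile cleaning.** ROI time profiles (mean CBF over non-missing ROI
voxels per pair) are smoothed in two steps: a single, non-iterative
outlier pass marks points beyond 2 SD of the profile missing, with mean
and SD computed once from all points; then a centred three-point
moving average that shrinks to the available neighbours at edges and
across missing points. Removed points stay missing rather than being
interpolated — the moving average simply renormalizes — so a cleaned
profile is a fixed point of the operation. Note the moving average
smears a step (e.g. the hypercapnic onset) across one sample, so exact
round-trip identities are stated for the unsmoothed chain.

**CVR.** Time profiles are normalized to the mean CBF of the baseline
block; the block-averaged CVR is 100 × (stimulus mean / baseline mean
− 1). Blocks are half-open intervals: baseline "minute 1–5" =
[60 s, 300 s), stimulus "minute 6–10" = [300 s, 600 s). CVR is
invariant to any positive rescaling of the profile, and the whole chain
is invariant to a common gain on labels, controls and M0t.

## Cohort statistics

**Model ledger.** Longitudinal responses (per-FOV vasomotion peak,
pulsatility, diameter) are modelled with linear mixed effects using
lme4-style formulas: fixed effects from {amyloid coverage, age,
genotype, age × genotype}, random intercepts for mouse and FOV/vessel,
and optionally an uncorrelated random intercept + slope on age
(`(Age||FOV)`). Fits are maximum likelihood, not REML, so AIC/BIC are
comparable across different fixed-effect sets; the parameter count
k = n_fixed + n_variance_components + 1 (residual) is identical across
compared models, and AIC = −2·loglik + 2k, BIC = −2·loglik + k·log n
are recomputed from the reported log-likelihood. The best model has
the lowest AIC, ties broken by BIC; non-converged fits are retained
and flagged, never silently dropped. Fixed-effect inference is Wald-z
(estimates ± 1.96 SE); the reported total R² is the conditional R² —
(fixed-effect variance + summed random-effect variances) over the
total including residual, with slope components contributing
σ²_slope · mean(age²). Estimation is delegated to statsmodels MixedLM
with variance components for the non-primary grouping factors. A
Breusch–Pagan helper supports the decision to log-transform a
response; the transform itself is an explicit per-response flag.

**Secondary tests.** Mann–Whitney U reports the tie-corrected
normal-approximation Z in all cases and an exact two-sided p
(enumeration of all label assignments, P(|U − mn/2| ≥ |u − mn/2|))
when both groups have n ≤ 8, without continuity correction. Spearman's
ρ uses average ranks; p is exact by full permutation for n ≤ 9, else
the two-sided t-approximation. The two-way ANOVA uses Type-II sums of
squares with interaction; pre-selected cell pairs are tested with
Welch's t and Šídák-adjusted, p' = 1 − (1 − p)^m; with an empty cell
the interaction is not estimable and the additive model is reported
with a flag. ICC is the two-way random-effects, absolute-agreement,
single-measure coefficient from the mean-squares decomposition,
undefined only when the table carries no variance at all. Cohen's
kappa is unweighted, from the confusion matrix over the shared
category set; when both raters constantly assign the same category
(p_e = 1), κ is defined as 1 with a flag.

## Synthetic data

The generators are pure functions of their configuration including the
seed (identical config ⇒ bit-identical output, enforced by test).
They emulate the statistical structure the analyses assume, not the
instruments: diameter traces are baseline × (1 + vasomotion sinusoid +
cardiac sinusoid + linear drift + white Gaussian noise); vessel movies
render a plateau of the true diameter convolved with a Gaussian wall
profile (analytically, via the error function, so FWHM = true diameter
exactly); kymographs draw dark Gaussian streaks moving at the planted
velocity on a bright background with wrap-around to keep density
constant; ASL series invert the Buxton equation at the planted CBF —
scaled by (1 + CVR) after stimulus onset — so that noise-free
quantification round-trips to machine precision, with symmetric
outliers at a configurable rate; cohorts draw mouse and FOV random
intercepts and Gaussian residuals around fixed effects on the
log10(vasomotion) scale.

Defaults mirror the study conditions: 300 s traces at 2 Hz; cardiac
frequency 10 Hz (≈ 600 bpm mouse heart rate); line scans at 1 kHz with
0.5 µm pitch; ASL with 150 pairs at 4 s (baseline [60, 300) s,
hypercapnic block from 300 s); cohorts with 4 mice per genotype, 4
FOVs, sessions at 6/8/10/12 months (≈ 128 measurements), amyloid
coverage growing ~8 %/month after an 8-month onset in transgenics and
identically zero in wildtypes, and a planted age × genotype slope of
−0.097 log10-units per month. The frame and line rates are not pinned
by the study description and are configuration defaults only.

Not modelled: MRI physics (k-space, EPI ghosting), motion, anaesthesia
effects, photon noise beyond additive Gaussian, vessel curvature or
tracking. Passing tests therefore demonstrate the correctness of the
estimators on data satisfying their assumptions, and their noise
robustness at the configured levels — not robustness to instrument
artefacts absent from the simulation.

## Problem sizes and numerical choices

Recovery and selection properties are established at sizes where they
are sharp: vasomotion noise recovery over 100 seeds; velocimetry on
512-line kymographs (5 % tolerance against an estimator resolution of
~1 %); mixed-model interaction recovery and AIC selection over 100
replicate cohorts of 50 mice per genotype (1600 rows each), with the
null-selection rate bounded by the theoretical P(χ²₂ > 4) ≈ 0.135;
ANOVA type-I error over 1000 replicates of a balanced 2 × 3 layout.
The acceptance script reports the same quantities at 50 cohort
replicates. Degenerate inputs follow the rules above: reject
(Nyquist violations, unresolvable streak slopes, empty masks/windows,
< 2 mice per genotype), flag missing (lost vessel frames, flat
windows, masked voxels), or flag the result (non-convergence, tied
samples, constant raters). Ties in the AIC ranking are broken by BIC;
the exact-p tolerance in enumeration comparisons is 1e−12.

## Known limitations

FWHM diameter extraction assumes an axis-aligned straight vessel
within the ROI; the Radon velocimetry search is bounded to 0.05–20
px/line and saturates for faster flows; the LME layer supports random
slopes on age only (the notation the ledger uses), not arbitrary slope
terms; Wald inference can be anticonservative for very few grouping
levels (the study scale of 4 mice per genotype is reported as
estimates and information criteria, with inferential guarantees
established at 50 mice in simulation); and the pipeline performs no
image registration or motion correction — inputs are assumed aligned.
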