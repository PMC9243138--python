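# Methods

This note documents the models, conventions and numerical choices behind
`noxtact`.  It is the reference for what each metric means, which knobs
matter, and what the synthetic-data validation does and does not show.

## Stimuli and their analysis windows

**Heat.** The Peltier stimulus is modelled as a trapezoid: hold at the
baseline skin temperature (30 °C), linear ramp at `ramp_rate` (default
12 °C/s) to the plateau (50 °C), a short plateau dwell, a symmetric return
ramp, and a final hold.  Two windows are defined by thresholding the
rising phase of the trace:

* **S (noxious)** — from the rising 45 °C crossing to the end of the
  plateau.  The return ramp is excluded by convention, so S covers the
  onset of noxious drive, not its decay.
* **N (innocuous)** — the trailing 1.0 s of the rising 33–45 °C traversal.
* **steady-state N (alternative)** — the 1.0 s of baseline hold ending at
  ramp onset.

At the default ramp rate the 33→45 °C traversal takes exactly 1.000 s, and
the plateau dwell default (1/12 s) makes the S window exactly 0.500 s
(5/12 s of 45→50 °C rise + the dwell).  Window edges are recovered by
linear interpolation between samples; since the generated trace is
piecewise linear, the recovered durations are exact to float precision at
any sample rate.  Traces with several trials are scanned for every rising
45 °C crossing, so pooling over repeats needs no bookkeeping from the
caller.

**Tactile.** Deflection onsets must be ≥ 90 ms apart — this is enforced at
construction because the 30 ms post-onset S window and 60 ms pre-onset N
window would otherwise overlap neighbouring events and make the statistic
ill-defined.  Violating inputs are rejected, never silently clipped.

## The S/N statistic

S and N are pooled spike counts divided by pooled window durations
(rates), and the ratio is regularized:

    S/N = (r_S + ε) / (r_N + ε)

with ε = 0.1 Hz by default (config key `epsilon_hz`).  Rationale: the two
windows differ in duration, so raw-count ratios would be scale-dependent,
and silent-noise-window units would be infinite without regularization.
ε = 0.1 Hz is far below any response rate of interest, so ordering is
preserved; ratios for units near silence compress toward ε-dominated
values rather than exploding.  A spike exactly at a deflection onset
belongs to the S window (half-open window convention).

## Classification

A unit is *responsive* to a modality iff its S/N is strictly greater than
that modality's cutoff; ties sit on the non-responsive side (the median
unit of a population is deliberately not auto-classified as responding).
The four labels follow from the two responsiveness bits.  Study-level
cutoffs (1.46 noxH, 1.81 tactile) ship as named defaults
(`STUDY_CUTOFFS`); they are population medians from the original
recordings and cannot be recomputed from synthetic data, so
`compute_cutoffs` also supports recomputing medians from any cohort
(`cutoff_source: recompute` in the pipeline config).

## Thermal threshold

Per unit: pool spikes over heat trials aligned to ramp onset, bin at 10 ms,
smooth with a Gaussian (σ = 100 ms default, config key; σ = 0 disables),
find the peak within the ramp-onset→plateau-end epoch, and take the
earliest bin on the rising ramp whose smoothed rate reaches 80 % of the
peak.  The bin's left edge maps to temperature through the trace.  Only
the rising ramp is used, so hysteresis on the return ramp cannot
contaminate tuning.  Units with no spikes in the epoch get NaN (undefined)
and are excluded from dispersion comparisons — never coerced to zero.

Smoothing trades bias for variance: σ = 100 ms blurs ~1.2 °C of ramp, and
recovered thresholds for sigmoid-tuned units sit ~0.1–0.7 °C above the
closed-form 80 %-of-peak point at the default settings (validated in the
acceptance suite against the analytic inversion, tolerance ±1 °C).

## Onset latency

The study does not publish its latency algorithm; the estimator here is a
package convention, flagged as such.  From the deflection-pooled 1 ms
PSTH: compute 2-bin sliding-window means, threshold at baseline mean +
2 SD (baseline = the 60 ms pre-onset bins), find the first post-onset
window that is sustained above threshold, and report the first
individually suprathreshold bin within it.  The sustained-window
formulation keeps single noisy bins from triggering while still dating an
isolated sharp response from its own bin.  Undefined (NaN) if nothing
crosses within 60 ms.

## Suppression

A unit counts as suppressed when its noxious-heat S/N is strictly below 1.
Note what this measure is: among units whose true rate is unchanged by
heat the ratio straddles 1, so roughly half of them fall below 1 by
chance.  Observed suppressed fractions therefore mix genuinely suppressed
units with this chance level, exactly as in real recordings; the
synthetic cohorts show the same dilution.  Regional contrasts should be
read through the 2×2 chi-square, not as absolute percentages.

## Synthetic-data generator

Each unit is an inhomogeneous Poisson process with rate

    r(t) = supp(t) · [ b + g_t · Σ_i α((t − onset_i)/τ) ]
           + g_h · σ((T(t) − θ)/k)

where α(u) = u·e^(1−u) is the unit-peak alpha kernel (fast tactile
transient, τ = 5 ms default), σ is the logistic function (thermal tuning
with midpoint θ and scale k), and supp(t) equals the suppression factor
while T(t) > 45 °C, else 1.  Suppression is multiplicative and gated on
the noxious range — a modelling choice; the original observations report
only the S/N < 1 outcome, not a mechanism.  Spikes are drawn by
Lewis–Shedler thinning against a ceiling of 1.05× the analytic maximum of
r (baseline + heat gain + tactile gain × a kernel-superposition bound).

Default archetypes: nociceptive (b = 2 Hz, g_h = 20 Hz, θ = 46 °C,
k = 1 °C), tactile (b = 3 Hz, g_t = 30 Hz, τ = 5 ms), integrative (both
drives), non-reactive (b = 4 Hz).  A session runs 10 heat trials
back-to-back followed by 100 deflections at 200 ms (± 20 ms jitter)
intervals — a realistic repeat count that makes the 0.5 s S-window rate
estimable per unit.  Units draw from independent substreams keyed by
(seed, unit index), so adding units never perturbs existing ones, and
every generator is a pure function of (parameters, seed).

What the generator does *not* emulate: bursting and refractoriness
(Poisson spiking), adaptation across trials, correlated noise between
simultaneously recorded units, receptive-field structure across whiskers,
drift, and spike-sorting contamination.  Passing tests therefore validate
the *quantification chain* — windows, statistics, classification rules,
estimators — on data whose ground truth is known, not the biology of any
particular recording.

Imaging stacks are flat reflectance frames plus a Gaussian blob of
relative amplitude −1 % (intrinsic signals are reflectance decreases) and
i.i.d. pixel noise; behaviour traces are baseline + Gaussian escape bump +
noise; von Frey bending is a saturating exponential (or linear ramp) with
known analytic saturation point.

## Imaging conventions

dR/R uses the mean of the 20 frames immediately before stimulus onset as
the base image and averages a post-onset response window (default 2 s at
the frame rate).  The z-map normalizes by the mean and **population** SD
over all pixels of the same map (divide by N; sample SD would differ by a
factor irrelevant to region ranking, but the choice is fixed and tested).
Consequences: every valid z-map has pixel mean 0 and SD 1 to 1e−12 and is
exactly invariant under positive affine transforms of the input.
Activated-region extraction takes the largest connected component of
|z| ≥ threshold (default 2.0) with area ≥ 10 px and reports its
|z|-weighted centroid.  c-Fos counting: Sobel gradient magnitude → Otsu
threshold → morphological closing and hole fill → connected components
filtered to 20–400 px².  Overlapping somata merge into one component — a
known limitation of connected-components counting.  Stacks are assumed
pre-aligned; cross-day vessel-pattern registration is out of scope.

## Behaviour conventions

ROI motion energy is the mean absolute frame-to-frame pixel difference
inside the ROI (first sample 0).  Escape metrics z-score the trace against
the −5–0 s pre-stimulus baseline (population SD) and report the maximum z
and its time within the 0–5 s response horizon; all channels share this
machinery.  The von Frey bending onset is the derivative-collapse
saturation point: smooth (Gaussian, σ = 25 ms default), find the maximum
derivative of the rise, return the first later time the derivative falls
below 5 % of that maximum.  Smoothing shifts the detected point by O(σ)
(≈ 2.6 σ for an exponential rise), so clean traces should use σ = 0; the
default σ buys robustness on noisy camera traces at the cost of that
fixed offset.

## Statistics

Wilcoxon signed-rank (two-sided; zeros dropped; exact null for ≤ 25
nonzero untied differences, normal approximation otherwise), 2×2 Pearson
chi-square (no continuity correction by default; Yates by flag),
Kruskal–Wallis followed by Sidak-adjusted pairwise Mann–Whitney tests
(p′ = 1 − (1 − p)^m over all m pairs), and one-way ANOVA followed by
Tukey's HSD all delegate to scipy behind this package's result type.

The Ansari–Bradley dispersion test is implemented in-package: pooled
midranks are scored min(rank, N+1−rank); the statistic is the score sum of
the first sample; the two-sided p-value comes from exact enumeration of
all C(N, n) assignments for pooled N ≤ 20 (a permutation null, valid under
ties) and from a tie-robust normal approximation above.  The exact branch
is cross-checked against an independent implementation and against
Monte-Carlo permutation in the tests.  Crossover sizes (25 and 20) are
config-level constants chosen so the exact branches stay interactive.

Calibration: the test suite verifies a 5 % type-I rate for every test
under its null with 2000 seeded replicates (binomial 99 % bounds).  The
chi-square null is simulated at 500-per-group margins because the
uncorrected Pearson test is genuinely anti-conservative (~5.5 %) at small
counts — the calibration targets the regime the asymptotic test is built
for.  Post-hoc families are calibrated at the omnibus stage; Sidak-
adjusted all-pairs error on correlated comparisons is conservative by
construction and is not a pointwise-5 % quantity.

## Problem sizes and determinism

The shipped analyses use 400-unit sessions (50 per region × layer
stratum), 10 heat trials and 100 deflections per session, 25–30 simulated
units per threshold-recovery condition, and 2000 replicates per
calibration null — sizes at which every validated property is stable
seed-to-seed while the full suite stays interactive.  Every pipeline stage
derives its randomness from the single config seed; two runs of the same
config produce byte-identical output tables (CSV floats are written at
%.17g and read back with round-trip parsing), verified by sha256 digests
in the run manifest.

## Known limitations

* Poisson spiking understates the variance of real bursty units; S/N
  variability on real data will be somewhat larger than the synthetic
  calibration suggests.
* The latency estimator and the von Frey saturation rule are package
  conventions (flagged above); absolute values from them should not be
  compared against other studies' estimators without harmonization.
* Study-default cutoffs (1.46/1.81) are tied to the original recording
  population; for new datasets, recomputed medians are the comparable
  choice.
* MUA pooling across probe sites is left to the caller: each spike-train
  row is one analysis unit.
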