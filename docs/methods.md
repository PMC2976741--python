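# Methods

This note documents the models, conventions and numerical choices behind
`hypowatch`, in the package's own terms. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setup

The unit of data is a *record*: one ICU stay of minute-by-minute HR, SBP,
DBP and MAP trends on a uniform grid (missing minutes are explicit NaN),
plus patient age and timed doses of hemodynamically active medications. A
*labeled example* is a triple of consecutive intervals — observation window
(30 or 60 min), gap (60 or 120 min), 30-min target window. The target is
labeled hypotensive when MAP is in (10, 60) mmHg for **at least** 90% of
its minutes, control when MAP is in (10, 200) mmHg for **more than** 90%,
and excluded otherwise; inequality strictness follows that wording exactly
and is enforced by boundary tests (27/30 minutes sub-60 is hypotensive;
27/30 in-bound is not a control). Missing minutes count against every
fraction — the conservative reading. The observation window must hold
in-bound values in all four series for more than 95% of minutes.

Target tiles start at minute 0 of each record and stride 30. The tiling
phase is a free choice (nothing pins it down); minute-0 alignment is
reproducible, and labeling is checked against a brute-force counter at
every alignment phase. Only target windows are non-overlapping; observation
windows of consecutive examples may overlap when the observation length
exceeds 30 min.

## Features

Six series enter feature extraction: the four measured ones plus
PP = SBP − DBP and CO = HR × PP (the Windkessel estimate, proportional to
cardiac output up to arterial compliance). Per example:

* **48 statistical** (8 × 6): mean, median, SD, variance, IQR, skewness,
  kurtosis, least-squares slope vs. the minute index. Conventions:
  population (divide-by-n) variance/SD; skewness and kurtosis are the third
  and fourth standardized central moments, kurtosis non-excess, both defined
  as 0 for a constant series; IQR uses linear-interpolation quantiles.
  Statistics use the non-missing values only.
* **15 cross-correlation**: the zero-lag uncentered product moment
  `(1/n) Σ x_i y_i` over the minutes where both pair members are present.
  The raw (uncentered, unnormalized) form is deliberate; downstream
  standardization absorbs scale.
* **36 wavelet** (6 × 6): relative energies of a 5-level discrete Meyer
  decomposition, `Er = ‖coeffs‖² / E_T` with `E_T` the total over the six
  coefficient vectors, so each series' six energies sum to 1 by
  construction. Gaps are linearly interpolated (nearest value at the edges)
  first, since the transform needs a uniform grid; validity guarantees at
  most 5% of minutes are affected.
* **3 clinical**: age; summed raising-group dose; summed lowering-group
  dose, over events with minute index in the half-open observation window.
  The raising list is neosynephrine, norepinephrine, vasopressin, dopamine,
  dobutamine, epinephrine, milrinone, isuprel; the lowering list is
  nitroglycerine, nitroprusside, diltiazem, esmolol, labetalol, lasix.
  Both lists are closed; unknown drug names are rejected at parse time.

### The Meyer filter bank

No DWT library is available in the target environment, so `hypowatch._dwt`
builds the discrete Meyer filter pair itself: the lowpass response
`H(ω) = √2·φ̂(2ω)` (with `φ̂` the analytic Meyer scaling spectrum and its
raised-cosine roll-off polynomial ν(x) = x⁴(35 − 84x + 70x² − 20x³)) is
inverse-transformed with a half-sample linear-phase delay, truncated to 62
taps, and rescaled to exact DC gain √2; the highpass is the
quadrature-mirror partner. Tests verify DC gain, near-zero highpass sum,
shift-orthonormality (~1e-9 after truncation) and band placement, and the
pyramidal transform is validated against an independent naive
double-loop implementation.

The 62-tap filter is longer than the 30- or 60-sample windows it analyzes,
so every decomposition level is boundary-dominated; the transform uses
half-point symmetric extension with per-level output length
`floor((n + 61)/2)` (coefficient counts grow toward 60). Exact numerical
agreement with any particular toolbox is therefore not claimed — only the
energy normalization and qualitative band behavior (constant series →
approximation band; Nyquist alternation → first detail band), which are
asserted.

## Dimensionality reduction

Features are standardized with training-set means/SDs (a constant feature
keeps divisor 1 and triggers a warning — the two dose features are often
constant on medication-free cohorts) and projected onto the principal
components with the largest eigenvalues. "About 90% of variance" is
resolved deterministically: k is the smallest count whose cumulative
explained-variance ratio reaches the target (default 0.90). Loading signs
are fixed by making each column's largest-magnitude element positive. The
reducer is refit for every training-set variant — every fold and every
balanced sub-sample or regression subset — because test data must never
influence the projection; whether the original protocol refit per
sub-sample or once per fold is not determinable, and per-sub-sample refit
is the stricter choice.

## Networks

One topology serves both tasks: k inputs → 20 logistic/tanh hidden units →
1 output. The classifier (logistic output) emits a posterior probability;
its operating threshold maximizes sensitivity + specificity over candidate
thresholds at every distinct training score plus {0, 1}, ties broken toward
the smaller threshold (favoring sensitivity). The regressor (tanh hidden,
linear output) trains on standardized median-MAP targets and
de-standardizes at prediction.

Training is scikit-learn's Adam on mini-batches of 32 with initial learning
rate 5e-3, max 500 epochs, and early stopping on a seeded 20% validation
holdout with patience 10. Full-batch Adam at the library default rate was
observed to stall from some initializations (occasional chance-level runs);
mini-batches with the larger step are strictly an optimizer-quality fix and
are exposed as module constants. scikit-learn's early stopping monitors the
validation *score* (accuracy / R²) rather than the raw loss and restores
the best-validation weights; this is the one place the implementation
delegates the regularization criterion to the library. All randomness
(initialization and the validation split) is a pure function of the seed;
the threshold is selected per trained model.

## Evaluation protocol

Records — not examples — are randomly assigned to k near-equal folds
(default 5), so examples from one stay are exclusively train or test; the
disjointness is asserted programmatically inside every fold. For
classification, each fold's training set is balanced 10× (default) by
drawing a without-replacement sample of the control majority equal in size
to the hypotensive minority; test folds keep natural prevalence. For
regression, a 2,500-example training subset is redrawn instead (multiple
mode; single mode uses all training examples). Aggregates are mean ±
sample SD (ddof 1) over all fold × sub-sample runs; a run whose test fold
lacks a class is recorded as NaN with a warning and excluded. All
randomness derives from one experiment seed through a spawned seed tree.

AUC uses the rank (Mann–Whitney) statistic with midranks for ties, and is
tested equal to trapezoidal ROC integration to 1e-10. PPV/NPV are NaN for
degenerate confusion matrices. The percentage MAE is
`(1/N) Σ |ŷ−y|/y × 100`; the robust line (predicted on true) is iteratively
reweighted least squares with Tukey's biweight via statsmodels.

## Continuous monitoring

`continuous_predict` applies a trained reducer/classifier/regressor at
every minute t: the window [t−obs, t) is validity-checked, featurized and
scored, the outputs referring to the target window starting at t+gap.
Minutes failing validity (or inside the initial warm-up) carry a
no-prediction flag. By construction the trace equals scoring one-off
compiled examples (tested at 50 random minutes). For plotting, the MAP
prediction series is shifted forward by the gap so it overlays the true
MAP; probabilities stay unshifted to preserve their lead time. A fitted
pair from one cohort is used as-is; the caller is responsible for not
monitoring a record the models were trained on when leakage matters.

## Synthetic cohorts

The generator emulates the coarse structure of real trend data, not its
physiology:

* **Durations** lognormal, median 79.8 h with shape σ = 0.9 (matching a
  skewed IQR of ~100 h); fixtures use shorter (~30 h) records.
* **Baselines**: per-record resting levels (MAP 80 ± 7, PP 45 ± 6,
  HR 85 ± 9 between records) plus a clipped within-record random walk
  (SD 0.05 units/min) — the heterogeneity real regression targets have.
* **Noise**: AR(1) (coefficient 0.9) per series; innovation SDs 0.8 / 0.7 /
  1.0 mmHg/bpm for MAP/PP/HR. SBP and DBP derive from MAP and PP
  (SBP = MAP + 2PP/3), keeping the four pressures consistent and
  SBP ≥ DBP by construction.
* **Episodes**: Poisson count per record (default rate 3.6, calibrated once
  so multiple-compilation hypotensive-window prevalence sits near 2.6%,
  the imbalance regime of interest); each episode ramps MAP to a 50 mmHg
  plateau over 10 min, holds 60 min, and ramps back, guaranteeing at least
  one fully covered hypotensive target tile at any alignment. Mild
  compensatory tachycardia (+10 bpm) accompanies episodes.
* **Precursors** (the learnable signal): during the 90 min before onset —
  the obs+gap horizon, so the signal is visible to a 30/60 pipeline — a
  linear MAP drift (fixtures use −0.2 mmHg/min), progressive PP narrowing
  (fixtures 30%) and an innovation-SD multiplier (fixtures 2×) are imposed.
  Setting all three to zero yields the matched null cohort used as the
  no-signal control.
* **Corruptions**: whole-minute dropouts at `missing_rate`; out-of-bound
  spikes on HR or MAP at `artifact_rate` (confined to those two series so
  SBP ≥ DBP survives); optional pressor doses shortly after onsets.

What a green parameter-recovery test establishes: that the pipeline
recovers a precursor signature *of the injected kind* at the stated effect
sizes, and returns chance AUC when none exists. It does not establish
performance on real ICU data, whose artifacts, non-stationarity and
precursor physiology the generator does not model; the real-data headline
numbers are anchors, not reproduction targets.

## Known limitations

* No signal-quality index: the 10/200 bound is the only artifact filter.
* The record format is plain CSV/JSON; native waveform-database binaries
  are out of scope.
* The Meyer DWT on sub-filter-length windows is boundary-dominated (see
  above); band energies are comparable within this package but not across
  toolboxes.
* Regression's robust slope/intercept on synthetic cohorts depends
  strongly on the between-record baseline spread; with a narrow spread the
  bisquare fit flattens because the hypotensive tail is down-weighted as
  outlying.
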