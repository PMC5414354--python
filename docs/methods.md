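# Methods

This note documents the models the package implements, the assumptions they
make, the defaults and why, and what the synthetic-data generators do and
do not emulate.

## Single-enzyme corral kinetics

**Model.** A corral holds `Ras(0)` fluorescently loaded substrate molecules
at t = 0. A membrane-bound enzyme in catalytic state *i* exchanges
fluorescent nucleotide at a first-order rate in the remaining fluorescent
substrate, so the corral fluorescence in that state decays as
`F(t) ∝ exp(−k_i t)` and the molecular turnover of the state is
`TN_i = k_i · Ras(0)` (molecules/s, defined at the initial loading). An
enzyme visits a sequence of discrete states; on the log-intensity scale the
trace is piecewise linear, with slope changes at state switches.

**Correction.** The raw trace also decays by photobleaching and intrinsic
(enzyme-independent) nucleotide turnover. Both act identically on every
corral, so the pipeline divides each normalized trace by the average trace
of corrals without enzymatic activity. Inactive corrals are called by
endpoint decay within 3 robust standard deviations (1.4826·MAD) of the
array's median endpoint — the same outlier logic as the steady-state μ+3σ
threshold. This requires the dilute-loading regime (≲ 10–20 % active
corrals); at ≳ 50 % active the median endpoint no longer tracks the
inactive mode and an external (e.g. untransfected-control) reference must
be supplied. `normalize_trace` divides by the maximum of the first 10
frames rather than the literal first frame, to be robust to a single hot or
dropped acquisition frame.

**Change-point engine.** Both catalytic-state detection (piecewise linear
on log-intensity) and photobleaching step counting (piecewise constant on
intensity) use one engine (`corralkit.changepoint`). For a partition with
`k` breakpoints the criterion is

    n·log(RSS/n) + penalty · log(n) · (p·(k+1) + k)

with `p` free parameters per segment (2 linear, 1 constant) and each
breakpoint counting as a parameter; `penalty = 1` is plain BIC. The
partition minimizing RSS for each `k` is found by exact dynamic programming
over O(1) prefix-sum segment costs, so the reported segmentation is the
global optimum of the criterion up to `max_breakpoints` — not a greedy
binary-segmentation approximation. (An exhaustive-scan oracle in the test
suite verifies exact agreement on ≤300-frame traces with ≤2 breakpoints.)
Because the criterion is linear in `k`, raising the penalty can never
increase the selected number of breakpoints.

Numerical choices:
- RSS is floored at `64·ε·n·max|y|²` before taking the log — the
  cancellation level of the prefix-sum formulas — so that on (near-)
  noiseless data model selection is decided by the penalty term rather than
  floating-point crumbs.
- Non-positive intensities are floored at 10⁻⁶ of the initial value before
  the log transform (with a warning).
- `detect_states` defaults to `penalty = 2.0` rather than 1.0: the log
  transform amplifies additive camera noise in the deep tail of a decay,
  which under plain BIC seeds spurious breakpoints at late times. The
  stiffer penalty suppresses these; breakpoint localization is unaffected.
- `min_segment` defaults to 20 frames: states shorter than this are not
  resolvable above noise and merge into neighbours. Merged states average
  their rates, which leaves the pooled state-rate mean approximately
  unbiased because state dwell times are independent of state rates.
- Per-state rates are refit in intensity space (`A·exp(−k t)`, `k ≥ 0`
  bounded least squares, log-linear initialisation); a failed fit yields
  `k = NaN` and the state is excluded from pooled distributions.

## Steady-state exchange populations

Exchange per corral is `1 − (corrected endpoint)`, endpoint = mean of the
last 5 frames (noise suppression without biasing slow decays), clipped to
[−0.1, 1.1] to tolerate noise while flagging pathological corrals. The
major (weakly exchanging) population is fit by an iteratively trimmed
Gaussian — recompute (μ, σ) on values within 3σ, repeat to convergence of
the retained set (≤ 50 iterations), seeded by median/MAD — rather than a
mixture EM, because the high-exchange tail is broad and non-Gaussian and
only the major mode is modelled parametrically. The activation threshold is
the identity μ + 3σ (computed, never stored). Corrals above threshold but
≤ μ + 6σ are classed "nonspecific" (brief encounters by solution enzymes);
beyond μ + 6σ "processive". The 6σ cut is this package's operational
separation of the qualitative second population; it is configurable.

## Binding kinetics

Binding events are Poisson arrivals at rate proportional to solution
concentration. A track qualifies as a countable event when it dwells
≥ 2 frames (86 ms at the 43 ms single-molecule imaging resolution) —
one-frame detections are indistinguishable from noise. The cumulative
curve's OLS slope (free intercept, since the first moments after flow-in
may lag) is the per-field binding frequency; replicate fields at one
concentration pool as total events / total time; the molar binding rate is
the inverse-variance-weighted through-origin slope of frequency vs
concentration (zero enzyme ⇒ zero binding). Fold-inhibition is the ratio
of molar rates with first-order error propagation. Frequencies are
reported per field of view, with `field_area` carried for optional per-μm²
normalization.

## Diffusion mixtures

Step lengths over lag τ for a 2D Brownian species with coefficient D
follow `p(r) = (r/2Dτ)·exp(−r²/4Dτ)`; a fast/slow population is the
two-component mixture with fast fraction α. The primary fitter maximizes
the exact likelihood over raw (unbinned) steps — one-species D is the
closed form `Σr²/(4τn)`; the two-species fit optimizes
(log D₁, log D₂, logit α) by L-BFGS and orders the output D₁ ≥ D₂. A
histogram least-squares fit is retained as an independent cross-check,
matching how such distributions are conventionally fit from binned data.
Model selection uses BIC; with fewer than 500 steps the two-species fit is
not attempted. Comparisons between conditions bootstrap whole tracks (not
steps) to respect within-track correlation. The model contains no
localization-noise term; at small D·τ (step lengths comparable to the
localization precision) fitted D is biased upward accordingly.

## Calibration

- **Bleach steps:** piecewise-constant change-point fit (`penalty = 2`,
  `min_segment = 5` frames); downward level transitions are steps; traces
  with net upward drift or a final level above 25 % of the initial level
  are flagged and excluded from stoichiometry histograms.
- **FCS:** `G(τ) = (1/N)(1+τ/τ_D)⁻¹`, least squares over ≥ 10 lags;
  `D = w²/(4τ_D)` and density `= N/(πw²)` are exact identities of the fit
  object. The beam waist `w` is instrument-specific and required (default
  0.25 μm); the effective beam area convention is πw². No triplet or
  background terms are included in the model.
- **EGFP standard curve:** through-origin (blank-subtracted fluorescence),
  inverse prediction with a standard error; samples outside the standards'
  range are flagged as extrapolation.
- **Densitometry:** rolling-minimum baseline over 3× the band-window
  width; fractions over a full partition of a lane sum to 1.
- **Occupancy:** from an observed active fraction `f`,
  `λ = −ln(1−f)` and `P(exactly 1 | active) = λe^{−λ}/(1−e^{−λ})`. At
  f = 0.09 this gives 95.4 %, the quantitative basis for treating active
  corrals as single-enzyme measurements.

## Synthetic data: what it emulates and what it does not

The generators produce data with exactly the statistical structure the
analysis assumes, plus ground truth: per-state turnover drawn from a Gamma
distribution parameterized by (mean, sd) — positive support and right skew,
matching observed catalytic-rate histograms; state switching as a renewal
process with exponential dwells and i.i.d. rate redraws (the switching
timescale default, 0.01 s⁻¹, is a placeholder config value, not a measured
quantity); additive Gaussian intensity noise for camera traces and
multiplicative noise for FCS curves (shot noise vs correlator
normalization); homogeneous Poisson binding arrivals; per-track fixed
species identity with Gaussian per-axis displacements of variance 2Dτ.

Passing recovery tests therefore shows the pipeline is correct *under its
own model assumptions*. Real data depart in ways the generators do not
emulate: corral-to-corral loading heterogeneity, stage drift and flat-field
structure, fluorophore blinking (bleaching is single-exponential here),
localization error in tracks, multi-enzyme corrals beyond Poisson
statistics, and baseline drifts in lane profiles. Results on real data
depend on those departures being small or corrected upstream.

Default `frame_interval` is 0.043 s, the single-molecule imaging
resolution. Activity-assay simulations in the examples, tests and the
acceptance script use 2 s sampling — activity movies are time-lapse
acquisitions over ~10–20 minutes, where 43 ms sampling is neither realistic
nor informative (the kinetic content is in decays over hundreds of
seconds).

## Problem sizes used in the shipped checks

Recovery checks simulate 2000-corral arrays at 10 % active loading
(~200 active corrals per condition, ≥ 150 by construction), 600 s at 2 s
sampling; binding series use 0.5/1/2 nM × 600 s with 20 replicate fields;
diffusion mixtures use 10⁵ steps; FCS curves 50 log-spaced lags (10⁻⁴–10 s)
at 2 % noise; occupancy Monte-Carlo 10⁵ corrals. These sizes put Monte-
Carlo error well inside the stated tolerances (10 % for rate recovery,
15 % for fold ratios, 5 % for FCS) while completing in about a minute.

## Known limitations

- The state segmentation assumes homoscedastic Gaussian residuals on the
  log scale; for very deep decays the floor and the stiffer penalty are
  mitigations, not a heteroscedastic likelihood.
- The inactive-reference construction fails by design outside the dilute
  regime (error raised; supply an external control reference).
- No hidden-Markov alternative to change-point segmentation, no dwell-time
  survival analysis of binding, no anomalous-diffusion (MSD-vs-lag)
  analysis, and no pixel-level image rendering beyond uniform corral
  blocks; the change-point interface is pluggable for alternative engines.
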