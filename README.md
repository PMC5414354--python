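# corralkit

Analysis toolkit for single-molecule enzymology on supported-lipid-bilayer
**corral arrays** — micrometre-scale membrane patches bounded by metal
partitions, each holding fluorescently loaded, membrane-tethered substrate
(e.g. Ras carrying a fluorescent GTP analogue) and, at dilute loading, at
most one enzyme (e.g. the Ras exchange factor SOS). A single processive
enzyme depletes its corral's fluorescence; the decay kinetics of each corral
therefore report on one molecule at a time.

The package is written for experimentalists doing TIRF/epifluorescence
single-molecule assays on membrane microarrays, and covers the full
measurement stack:

- **`corralkit.activity`** — per-corral intensity traces → single-enzyme
  catalytic state paths. Each trace is normalized to its initial maximum,
  corrected for photobleaching and intrinsic nucleotide turnover by dividing
  with the average trace of inactive corrals, segmented into discrete
  catalytic states by penalized change-point detection on the
  log-intensity, and each state is fit to
  `F(t) = A·exp(−k_sos·t)`. The molecular turnover number is
  `TN = k_sos · Ras(0)`, with `Ras(0)` the fluorescent substrate count at
  t = 0 (given directly or as surface density × corral area).
- **`corralkit.steady`** — steady-state exchange under constant enzyme
  exposure: per-corral exchange `1 − corrected endpoint`, a robust Gaussian
  fit (μ, σ) of the weakly exchanging major population, the activation
  threshold **μ + 3σ**, and classification into major-inactive /
  nonspecific / processive corrals.
- **`corralkit.binding`** — membrane-binding kinetics: cumulative binding
  curves, their slopes (binding frequency, events·s⁻¹), the molar binding
  rate from a through-origin fit of frequency vs concentration
  (events·s⁻¹·nM⁻¹), fold-inhibition ratios between constructs, and
  relative binding under a titrated competitor.
- **`corralkit.diffusion`** — step-size distributions from single-particle
  tracks and maximum-likelihood fits of the two-species 2D Brownian mixture
  `p(r) = α·(r/2D₁τ)e^(−r²/4D₁τ) + (1−α)·(r/2D₂τ)e^(−r²/4D₂τ)`,
  with model selection between one and two species and track-bootstrap
  comparisons between membrane compositions.
- **`corralkit.calibration`** — photobleaching step counting for
  stoichiometry, EGFP standard-curve concentration estimation, FCS fitting
  of the 2D diffusion model `G(τ) = (1/N)(1 + τ/τ_D)⁻¹` for surface density
  and mobility, western-lane densitometry fractions, and Poisson
  single-enzyme occupancy statistics
  (`λ = −ln(1−f_active)`, `P(1 | active) = λe^(−λ)/(1−e^(−λ))`).
- **`corralkit.synthetic`** — generators for every input above with full
  ground truth, so each pipeline stage is verifiable by parameter recovery.
- **`corralkit.changepoint`** — the shared change-point engine: exact
  dynamic-programming optimization of a BIC-penalized piecewise-linear
  (catalytic states on log-intensity) or piecewise-constant (bleaching
  steps) Gaussian model.

## Worked example

Simulate a 400-corral array at 10% active loading with turnover drawn from
a Gamma distribution (mean 3.89, sd 1.98 molecules/s), then run the full
activity pipeline — normalize, build the inactive-average reference,
correct, segment, fit:

```python
import numpy as np
from corralkit import synthetic
from corralkit.activity import analyze_corral_array, rate_distribution
from corralkit.calibration import occupancy_stats

cfg = synthetic.ActivitySimConfig(
    n_corrals=400, frame_interval=2.0, duration=600.0, ras0=1000.0,
    state_rate_mean=3.89, state_rate_sd=1.98, state_switch_rate=0.01,
    photobleach_rate=0.0005, intrinsic_exchange_rate=0.0002,
    noise_sd=0.01, active_fraction=0.10, seed=11)
traces, truth = synthetic.simulate_corral_activity(cfg)

segs = analyze_corral_array(traces, ras0=1000.0)
summary = rate_distribution(segs)
true_mean = np.mean([tn for sp in truth.state_paths.values() for tn in sp.turnovers])
print(f"active corrals analysed: {len(segs)}")
print(f"catalytic states found:  {len(summary.rates)}")
print(f"mean turnover: {summary.mean:.2f} molecules/s (simulated truth {true_mean:.2f})")
print(f"sd of turnover: {summary.sd:.2f} molecules/s")
st = occupancy_stats(0.09)
print(f"single-enzyme fraction among active corrals: {100*st.single_given_active:.1f}%")
```

Output:

```
active corrals analysed: 36
catalytic states found:  91
mean turnover: 3.91 molecules/s (simulated truth 3.78)
sd of turnover: 1.83 molecules/s
single-enzyme fraction among active corrals: 95.4%
```

The pipeline finds the ~10% of corrals that hold an enzyme, splits each
trace into the discrete catalytic states the enzyme visits (here ~2.5
states per enzyme over 10 min), and recovers the population mean turnover
to within a few percent. The occupancy line is the Poisson argument for
why per-corral kinetics are single-molecule measurements: at 9% active
corrals, over 95% of active corrals contain exactly one enzyme.

The same stages are available from a shell via the `corralkit` entry point
(`corralkit simulate …`, `corralkit activity …`, `corralkit steady …`,
`corralkit binding …`, `corralkit diffusion …`, `corralkit bleach …`,
`corralkit fcs …`, `corralkit occupancy …`).

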