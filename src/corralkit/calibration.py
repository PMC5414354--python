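"""Calibration and validation quantifications.

Photobleaching step counting (fluorophore stoichiometry), EGFP
standard-curve concentration estimation, 2D-diffusion FCS fitting for
membrane density and mobility, western-lane densitometry fractions, and
Poisson single-enzyme occupancy statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .activity import IntensityTrace
from .changepoint import fit_piecewise


@dataclass
class StepCountResult:
    trace_id: str
    n_steps: int
    step_times: list[float]  # s
    step_heights: list[float]  # a.u., negative (downward)
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class FcsFit:
    """2D Gaussian-beam FCS fit: G(τ) = (1/N)(1 + τ/τ_D)^-1.

    N is the mean particle number in the beam area π·w²; derived quantities
    satisfy d = w²/(4 τ_D) and density = N/(π w²) exactly.
    """

    n_particles: float
    tau_d: float  # s
    beam_waist: float  # μm (input)

    @property
    def d(self) -> float:
        return self.beam_waist**2 / (4 * self.tau_d)

    @property
    def density(self) -> float:
        return self.n_particles / (np.pi * self.beam_waist**2)


@dataclass
class OccupancyStat:
    """Poisson corral-loading statistics at mean occupancy λ."""

    lam: float

    @property
    def active_fraction(self) -> float:
        return 1.0 - np.exp(-self.lam)

    @property
    def single_given_active(self) -> float:
        if self.lam == 0:
            return 1.0
        return self.lam * np.exp(-self.lam) / (1.0 - np.exp(-self.lam))


def count_bleach_steps(
    trace: IntensityTrace,
    penalty: float = 2.0,
    min_segment: int = 5,
    baseline_tolerance: float = 0.25,
) -> StepCountResult:
    """Count discrete photobleaching steps in an immobilized-molecule trace.

    Uses the shared change-point engine with a piecewise-constant model;
    downward level transitions are steps.  Traces whose final level is not
    near baseline (within ``baseline_tolerance`` of the initial level) or
    that show net upward drift are flagged and should be excluded from
    stoichiometry histograms.
    """
    if len(trace) < 20:
        raise ValueError("need >=20 frames to count bleaching steps")
    fit = fit_piecewise(
        trace.times, trace.values, model="constant",
        penalty=penalty, min_segment=min_segment,
    )
    levels = [float(np.mean(trace.values[a:b])) for a, b in fit.segment_bounds]
    times, heights = [], []
    for i, b in enumerate(fit.breakpoints):
        dh = levels[i + 1] - levels[i]
        if dh < 0:
            times.append(float(trace.times[b]))
            heights.append(dh)
    flagged, reason = False, ""
    if levels and levels[-1] > levels[0]:
        flagged, reason = True, "net upward drift"
    elif levels and abs(levels[-1]) > baseline_tolerance * max(abs(levels[0]), 1e-12):
        flagged, reason = True, "final level above baseline"
    return StepCountResult(
        trace_id=trace.corral_id, n_steps=len(times),
        step_times=times, step_heights=heights,
        flagged=flagged, flag_reason=reason,
    )


def step_histogram(results: list[StepCountResult], include_flagged: bool = False):
    """Counts and fractions by step number (flagged traces excluded by default)."""
    kept = [r for r in results if include_flagged or not r.flagged]
    if not kept:
        raise ValueError("no step-count results to histogram")
    ns = np.array([r.n_steps for r in kept])
    uniq, counts = np.unique(ns, return_counts=True)
    return {int(u): {"count": int(c), "fraction": float(c / len(ns))} for u, c in zip(uniq, counts)}


def egfp_concentration(
    sample_fluorescence: float,
    standards: list[tuple[float, float]],
) -> tuple[float, float, bool]:
    """Concentration (nM) from a through-origin EGFP standard curve.

    ``standards`` are (concentration_nM, fluorescence) pairs; blank
    subtraction justifies the zero intercept.  Returns
    ``(concentration, stderr, extrapolated)`` where the flag marks a sample
    outside the standards' fluorescence range.
    """
    if len(standards) < 3:
        raise ValueError("need >=3 standards")
    conc = np.array([s[0] for s in standards], dtype=float)
    fluo = np.array([s[1] for s in standards], dtype=float)
    sxx = np.sum(conc**2)
    slope = float(np.sum(conc * fluo) / sxx)
    resid = fluo - slope * conc
    dof = max(len(conc) - 1, 1)
    slope_se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    if slope <= 0:
        raise ValueError("standard curve slope must be positive")
    est = sample_fluorescence / slope
    est_se = est * slope_se / slope
    extrapolated = not (min(fluo.min(), 0.0) <= sample_fluorescence <= fluo.max())
    return float(est), float(est_se), bool(extrapolated)


def fit_fcs(lags: np.ndarray, g: np.ndarray, beam_waist: float) -> FcsFit:
    """Least-squares fit of the 2D-diffusion autocorrelation model.

    G(τ) = (1/N)(1 + τ/τ_D)^-1; diffusion coefficient and surface density
    follow from the FcsFit identities.  Requires ≥10 lag points.
    """
    lags = np.asarray(lags, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(lags) < 10:
        raise ValueError("need >=10 lag points")
    if beam_waist <= 0:
        raise ValueError("beam_waist must be positive")
    n0 = 1.0 / max(g[0], 1e-12)
    # crude τ_D start: lag where G falls to half its zero-lag value
    half = g[0] / 2
    below = np.flatnonzero(g <= half)
    tau0 = lags[below[0]] if len(below) else lags[len(lags) // 2]

    def model(tau, n, tau_d):
        return (1.0 / n) / (1.0 + tau / tau_d)

    popt, _ = curve_fit(
        model, lags, g, p0=[n0, max(tau0, lags[1])],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=5000,
    )
    n, tau_d = float(popt[0]), float(popt[1])
    if n <= 0 or tau_d <= 0:
        raise RuntimeError("FCS fit returned non-physical parameters")
    return FcsFit(n_particles=n, tau_d=tau_d, beam_waist=beam_waist)


def densitometry_fraction(
    profile: np.ndarray,
    window: tuple[int, int],
    baseline_window: int | None = None,
) -> float:
    """Fraction of background-subtracted lane intensity inside a band window.

    The baseline is a rolling minimum over ``baseline_window`` samples
    (default 3× the band-window width); intensities below baseline clip to
    zero.  ``window`` is a half-open index interval.
    """
    profile = np.asarray(profile, dtype=float)
    if np.any(profile < 0):
        raise ValueError("profile must be nonnegative")
    a, b = window
    if not (0 <= a < b <= len(profile)):
        raise ValueError("window must lie within the profile")
    if baseline_window is None:
        baseline_window = 3 * (b - a)
    half = max(baseline_window // 2, 1)
    base = np.array([
        profile[max(i - half, 0): i + half + 1].min() for i in range(len(profile))
    ])
    net = np.maximum(profile - base, 0.0)
    total = net.sum()
    if total <= 0:
        raise ValueError("zero total lane intensity after baseline subtraction")
    return float(net[a:b].sum() / total)


def occupancy_stats(active_fraction: float) -> OccupancyStat:
    """Poisson occupancy from the observed active-corral fraction.

    λ = −ln(1−f); the chance an active corral holds exactly one enzyme is
    λe^{−λ}/(1−e^{−λ}).  Dilute loading (f ≲ 0.1) makes multi-enzyme
    corrals rare, which is what licenses single-enzyme analysis.
    """
    if not (0 < active_fraction < 1):
        raise ValueError("active_fraction must be in (0, 1)")
    return OccupancyStat(lam=float(-np.log(1.0 - active_fraction)))
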