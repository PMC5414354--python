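"""Steady-state per-corral nucleotide exchange populations.

Under constant enzyme exposure, each corral's endpoint fluorescence (after
correction against an inactive control) measures how much substrate was
exchanged.  Across thousands of corrals the bulk forms a weakly-exchanging
Gaussian population; corrals driven dark by a stably recruited, processive
enzyme form a separate high-exchange tail.  The activation threshold is set
at μ+3σ of the major population, and corrals are classified as
major-inactive, nonspecific-above-threshold, or processive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity import CorrectedTrace, IntensityTrace, correct_trace, normalize_trace

EXCHANGE_CLIP = (-0.1, 1.1)


@dataclass
class ExchangeValue:
    corral_id: str
    exchange: float  # 1 - corrected endpoint fluorescence, clipped to [-0.1, 1.1]


@dataclass
class PopulationFit:
    mu: float
    sigma: float
    n_major: int
    n_above_threshold: int
    n_processive: int
    n_total: int
    n_iterations: int = 0

    @property
    def threshold(self) -> float:
        """Activation threshold μ + 3σ (an identity, never stored separately)."""
        return self.mu + 3 * self.sigma


def exchange_values(
    traces: list[IntensityTrace],
    reference: IntensityTrace,
    head_frames: int = 10,
    endpoint_frames: int = 5,
) -> list[ExchangeValue]:
    """Exchange fraction per corral: 1 − corrected endpoint.

    Both traces and reference are normalized to their initial maxima; the
    reference is the inactive-average from an untransfected-lysate control
    at matched total protein.  The endpoint is the mean of the last
    ``endpoint_frames`` frames for noise suppression.
    """
    ref_n = normalize_trace(reference, head_frames)
    if any(len(tr) > len(ref_n) for tr in traces):
        raise ValueError("reference shorter than traces")
    out = []
    for tr in traces:
        corr = correct_trace(normalize_trace(tr, head_frames), ref_n)
        end = float(np.mean(corr.values[-endpoint_frames:]))
        ex = float(np.clip(1.0 - end, *EXCHANGE_CLIP))
        out.append(ExchangeValue(tr.corral_id, ex))
    return out


def fit_major_population(
    values: list[ExchangeValue] | np.ndarray,
    max_iter: int = 50,
    trim_sd: float = 3.0,
) -> PopulationFit:
    """Robust Gaussian fit of the dominant low-exchange mode.

    Iteratively trims values beyond ``trim_sd`` standard deviations of the
    current (μ, σ) until the retained set stabilizes, so the processive
    tail does not inflate the estimates.  Starts from the median / scaled
    MAD.  Raises on non-convergence after ``max_iter`` iterations.
    """
    x = _as_array(values)
    if len(x) < 100:
        raise ValueError("need >=100 corrals for a population fit")
    mu = float(np.median(x))
    mad = float(np.median(np.abs(x - mu)))
    sigma = 1.4826 * mad if mad > 0 else float(np.std(x))
    prev_mask = None
    for it in range(1, max_iter + 1):
        if sigma == 0:
            mask = x == mu
        else:
            mask = np.abs(x - mu) <= trim_sd * sigma
        if not mask.any():
            raise RuntimeError("trimmed Gaussian fit lost all points")
        if prev_mask is not None and np.array_equal(mask, prev_mask):
            break
        mu = float(np.mean(x[mask]))
        sigma = float(np.std(x[mask]))
        prev_mask = mask
    else:
        raise RuntimeError(f"trimmed Gaussian fit did not converge in {max_iter} iterations")
    thr = mu + 3 * sigma
    return PopulationFit(
        mu=mu, sigma=sigma,
        n_major=int(np.sum(x <= thr)),
        n_above_threshold=int(np.sum(x > thr)),
        n_processive=0,  # filled by classify_corrals with a processive cut
        n_total=len(x), n_iterations=it,
    )


def classify_corrals(
    values: list[ExchangeValue] | np.ndarray,
    fit: PopulationFit,
    processive_cut: float | None = None,
) -> list[str]:
    """Label corrals by exchange depth relative to the population fit.

    ``major-inactive`` at or below μ+3σ; ``nonspecific`` above threshold but
    at or below the processive cut (default μ+6σ — brief encounters by
    solution enzymes, not sustained single-enzyme activity); ``processive``
    beyond that.
    """
    if processive_cut is None:
        processive_cut = fit.mu + 6 * fit.sigma
    x = _as_array(values)
    labels = []
    for v in x:
        if v <= fit.threshold:
            labels.append("major-inactive")
        elif v <= processive_cut:
            labels.append("nonspecific")
        else:
            labels.append("processive")
    return labels


def population_report(
    per_construct: dict[str, tuple[list[ExchangeValue], PopulationFit, list[str]]],
) -> pd.DataFrame:
    """Comparison table across constructs: n, μ, σ, threshold, % classes."""
    rows = []
    for construct, (values, fit, labels) in per_construct.items():
        n = len(labels)
        rows.append(
            {
                "construct": construct,
                "n": n,
                "mu": fit.mu,
                "sigma": fit.sigma,
                "threshold": fit.threshold,
                "pct_above_threshold": 100.0 * sum(l != "major-inactive" for l in labels) / n,
                "pct_processive": 100.0 * labels.count("processive") / n,
            }
        )
    return pd.DataFrame(rows)


def _as_array(values) -> np.ndarray:
    if isinstance(values, np.ndarray):
        return values.astype(float)
    return np.array([v.exchange for v in values], dtype=float)
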