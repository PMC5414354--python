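"""Step-size distributions and two-species Brownian mixture fits.

For a molecule diffusing in a membrane (2D) with coefficient D, the step
length r over a lag τ follows the Rayleigh-type density

    p(r) = (r / (2 D τ)) exp(-r² / (4 D τ)),

and a population containing a fast and a slow species is the mixture

    p(r) = α p(r; D₁) + (1 − α) p(r; D₂),   D₁ ≥ D₂, α ∈ [0, 1].

The primary fitter maximizes the exact likelihood over raw step lengths;
a histogram least-squares fit is provided as an independent cross-check,
matching how such distributions are commonly fit from binned data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize


@dataclass
class TrackSet:
    """Single-particle trajectories: per track, arrays of (frame, x, y)."""

    tracks: list[np.ndarray]  # each (n_i, 3): frame, x [μm], y [μm]
    frame_interval: float  # s
    construct: str = "unknown"
    membrane: str = "unknown"
    concentration: float = float("nan")
    duration: float | None = None

    def __post_init__(self) -> None:
        self.tracks = [np.asarray(t, dtype=float) for t in self.tracks]
        for t in self.tracks:
            if t.ndim != 2 or t.shape[1] != 3:
                raise ValueError("each track must be (n, 3): frame, x, y")
            if len(t) > 1 and np.any(np.diff(t[:, 0]) <= 0):
                raise ValueError("frames must be strictly increasing within a track")
            if not np.all(np.isfinite(t[:, 1:])):
                raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.tracks)

    def iter_frames_xy(self):
        for t in self.tracks:
            yield t


@dataclass
class StepSample:
    lag: float  # s
    step_lengths: np.ndarray  # μm

    def __post_init__(self) -> None:
        self.step_lengths = np.asarray(self.step_lengths, dtype=float)
        if np.any(self.step_lengths < 0):
            raise ValueError("step lengths must be nonnegative")


@dataclass
class DiffusionMixtureFit:
    d1: float  # μm² s^-1, fast
    d2: float  # μm² s^-1, slow (== d1 for 1-species)
    alpha: float  # fraction fast
    n_species: int
    log_likelihood: float
    lag: float
    n_steps: int
    residual_rms: float = float("nan")
    flag: str = ""


def step_sizes(tracks: TrackSet, lag_frames: int = 1) -> StepSample:
    """Euclidean displacements between positions ``lag_frames`` apart.

    Pairs separated by a frame gap other than exactly ``lag_frames`` are
    skipped; steps from all tracks are pooled.
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    steps = []
    for t in tracks.tracks:
        frames = t[:, 0].astype(int)
        pos = {f: i for i, f in enumerate(frames)}
        for f, i in pos.items():
            j = pos.get(f + lag_frames)
            if j is not None:
                steps.append(np.hypot(t[j, 1] - t[i, 1], t[j, 2] - t[i, 2]))
    if not steps:
        raise ValueError("no track long enough for the requested lag")
    return StepSample(lag=lag_frames * tracks.frame_interval, step_lengths=np.array(steps))


def _mixture_pdf(r: np.ndarray, d1: float, d2: float, alpha: float, tau: float) -> np.ndarray:
    p1 = r / (2 * d1 * tau) * np.exp(-(r**2) / (4 * d1 * tau))
    p2 = r / (2 * d2 * tau) * np.exp(-(r**2) / (4 * d2 * tau))
    return alpha * p1 + (1 - alpha) * p2


def mixture_cdf(r: np.ndarray, d1: float, d2: float, alpha: float, tau: float) -> np.ndarray:
    """Closed-form mixture CDF: α(1−e^{−r²/4D₁τ}) + (1−α)(1−e^{−r²/4D₂τ})."""
    r = np.asarray(r, dtype=float)
    return alpha * (1 - np.exp(-(r**2) / (4 * d1 * tau))) + (1 - alpha) * (
        1 - np.exp(-(r**2) / (4 * d2 * tau))
    )


def single_species_mle(sample: StepSample) -> float:
    """Closed-form maximum-likelihood D for one species: Σr² / (4 τ n)."""
    r = sample.step_lengths
    return float(np.sum(r**2) / (4 * sample.lag * len(r)))


def fit_step_mixture(sample: StepSample, n_species: int = 2) -> DiffusionMixtureFit:
    """Maximum-likelihood Brownian mixture fit of a step-length sample.

    The 1-species MLE is closed-form.  The 2-species fit optimizes
    (log D₁, log D₂, logit α) with L-BFGS from a moment-based start and
    returns components ordered ``d1 >= d2``.  Requires ≥500 steps for a
    2-species fit; on optimizer failure an error carrying the 1-species
    fallback is raised.
    """
    r = sample.step_lengths
    r = r[r > 0]
    tau = sample.lag
    n = len(r)
    if n == 0:
        raise ValueError("empty step sample")
    d_single = float(np.sum(r**2) / (4 * tau * n))
    ll_single = float(np.sum(np.log(_mixture_pdf(r, d_single, d_single, 1.0, tau))))
    if n_species == 1:
        return DiffusionMixtureFit(
            d1=d_single, d2=d_single, alpha=1.0, n_species=1,
            log_likelihood=ll_single, lag=tau, n_steps=n,
        )
    if n_species != 2:
        raise ValueError("n_species must be 1 or 2")
    if n < 500:
        raise ValueError("need >=500 steps for a 2-species fit")

    def nll(params):
        ld1, ld2, la = params
        d1, d2 = np.exp(ld1), np.exp(ld2)
        a = 1.0 / (1.0 + np.exp(-la))
        p = _mixture_pdf(r, d1, d2, a, tau)
        return -np.sum(np.log(np.maximum(p, 1e-300)))

    x0 = np.array([np.log(d_single * 2.0), np.log(d_single / 4.0), 0.0])
    res = minimize(nll, x0, method="L-BFGS-B")
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(
            f"2-species mixture fit failed; 1-species fallback D={d_single:.4g}"
        )
    d1, d2 = np.exp(res.x[0]), np.exp(res.x[1])
    a = 1.0 / (1.0 + np.exp(-res.x[2]))
    if d2 > d1:
        d1, d2, a = d2, d1, 1 - a
    return DiffusionMixtureFit(
        d1=float(d1), d2=float(d2), alpha=float(a), n_species=2,
        log_likelihood=float(-res.fun), lag=tau, n_steps=n,
    )


def fit_step_mixture_binned(
    sample: StepSample, n_species: int = 2, bins: int = 60
) -> DiffusionMixtureFit:
    """Least-squares fit of the mixture density to a normalized histogram.

    Cross-check oracle for :func:`fit_step_mixture`; fitting histograms is
    how these distributions are conventionally displayed and fit.
    """
    r = sample.step_lengths
    r = r[r > 0]
    tau = sample.lag
    dens, edges = np.histogram(r, bins=bins, density=True)
    mid = 0.5 * (edges[:-1] + edges[1:])
    d_single = float(np.sum(r**2) / (4 * tau * len(r)))
    if n_species == 1:
        def resid1(p):
            return _mixture_pdf(mid, np.exp(p[0]), np.exp(p[0]), 1.0, tau) - dens
        sol = least_squares(resid1, [np.log(d_single)])
        d = float(np.exp(sol.x[0]))
        return DiffusionMixtureFit(
            d1=d, d2=d, alpha=1.0, n_species=1, log_likelihood=float("nan"),
            lag=tau, n_steps=len(r), residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
        )

    def resid2(p):
        d1, d2 = np.exp(p[0]), np.exp(p[1])
        a = 1.0 / (1.0 + np.exp(-p[2]))
        return _mixture_pdf(mid, d1, d2, a, tau) - dens

    sol = least_squares(resid2, [np.log(d_single * 2), np.log(d_single / 4), 0.0])
    d1, d2 = float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))
    a = float(1.0 / (1.0 + np.exp(-sol.x[2])))
    if d2 > d1:
        d1, d2, a = d2, d1, 1 - a
    return DiffusionMixtureFit(
        d1=d1, d2=d2, alpha=a, n_species=2, log_likelihood=float("nan"),
        lag=tau, n_steps=len(r), residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
    )


def select_model(
    fit1: DiffusionMixtureFit, fit2: DiffusionMixtureFit | None, penalty: float = 1.0
) -> int:
    """Choose 1 or 2 species by a BIC-style penalized likelihood.

    The 2-species model (3 parameters vs 1) wins only when its penalized
    criterion improves on the single-species one; with <500 steps the
    2-species fit is unavailable and 1 is forced.
    """
    if fit2 is None or fit1.n_steps < 500:
        return 1
    n = fit1.n_steps
    bic1 = -2 * fit1.log_likelihood + penalty * 1 * np.log(n)
    bic2 = -2 * fit2.log_likelihood + penalty * 3 * np.log(n)
    return 2 if bic2 < bic1 else 1


def mobility_shift(
    tracks_a: TrackSet,
    tracks_b: TrackSet,
    lag_frames: int = 1,
    n_boot: int = 200,
    seed: int = 0,
    ci: float = 0.95,
) -> dict[str, tuple[float, tuple[float, float]]]:
    """Differences (b − a) in D₁, D₂, α with track-bootstrap intervals.

    Whole tracks are resampled (not individual steps) so within-track
    correlation is respected.  Requires equal frame intervals.
    """
    if not np.isclose(tracks_a.frame_interval, tracks_b.frame_interval):
        raise ValueError("track sets must share a frame interval (lag mismatch)")
    rng = np.random.default_rng(seed)

    def point_fit(ts: TrackSet) -> DiffusionMixtureFit:
        return fit_step_mixture(step_sizes(ts, lag_frames), n_species=2)

    fa, fb = point_fit(tracks_a), point_fit(tracks_b)
    deltas = {"d1": fb.d1 - fa.d1, "d2": fb.d2 - fa.d2, "alpha": fb.alpha - fa.alpha}

    boot = {k: [] for k in deltas}
    for _ in range(n_boot):
        res = []
        for ts in (tracks_a, tracks_b):
            idx = rng.integers(0, len(ts.tracks), size=len(ts.tracks))
            rs = TrackSet([ts.tracks[i] for i in idx], ts.frame_interval)
            res.append(fit_step_mixture(step_sizes(rs, lag_frames), n_species=2))
        boot["d1"].append(res[1].d1 - res[0].d1)
        boot["d2"].append(res[1].d2 - res[0].d2)
        boot["alpha"].append(res[1].alpha - res[0].alpha)
    lo, hi = 50 * (1 - ci), 50 * (1 + ci)
    return {
        k: (deltas[k], (float(np.percentile(boot[k], lo)), float(np.percentile(boot[k], hi))))
        for k in deltas
    }
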