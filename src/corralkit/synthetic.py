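"""Synthetic single-molecule measurements with full ground truth.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the analysis assumes: Markov-switching processive
enzymes depleting fluorescent substrate in corrals (with photobleaching and
intrinsic turnover), Poisson membrane-binding arrivals proportional to
solution concentration, two-species 2D Brownian tracks, stepped
photobleaching traces, 2D-diffusion FCS curves, and Poisson enzyme loading
of corral arrays.  All generators take an explicit seed and are bit-
reproducible; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity import IntensityTrace
from .binding import BindingEventStream
from .diffusion import TrackSet

DEFAULT_FRAME_INTERVAL = 0.043  # s, the single-molecule imaging time resolution


@dataclass
class ActivitySimConfig:
    """Conditions for the corral-activity simulator.

    An active corral holds one enzyme whose molecular turnover (molecules
    s^-1) is redrawn from a gamma distribution (mean ``state_rate_mean``,
    sd ``state_rate_sd``) at exponential switching times with rate
    ``state_switch_rate``; fluorescent substrate decays exponentially at
    ``k = TN / ras0`` per state, on top of global photobleaching and
    intrinsic nucleotide turnover.  ``noise_sd`` is the Gaussian noise
    level as a fraction of the initial intensity.
    """

    n_corrals: int = 100
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    duration: float = 600.0
    ras0: float = 1000.0  # fluorescently loaded substrate molecules at t=0
    state_rate_mean: float = 3.89  # molecules s^-1
    state_rate_sd: float = 1.98
    state_switch_rate: float = 0.01  # s^-1 (placeholder timescale; not measured here)
    photobleach_rate: float = 0.0005  # s^-1
    intrinsic_exchange_rate: float = 0.0002  # s^-1
    noise_sd: float = 0.01
    active_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "state_rate_mean", "state_rate_sd", "state_switch_rate",
            "photobleach_rate", "intrinsic_exchange_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ras0 <= 0:
            raise ValueError("ras0 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.active_fraction <= 1:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.duration / self.frame_interval < 10:
            raise ValueError("need at least 10 frames")


@dataclass
class StatePath:
    """True state path of one enzyme: switch times and per-state turnover."""

    breakpoint_times: list[float]  # strictly increasing, within (0, duration)
    turnovers: list[float]  # molecules s^-1, one per state

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.breakpoint_times, self.breakpoint_times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")


@dataclass
class GroundTruth:
    """Everything a recovery test needs about what was simulated."""

    enzyme_counts: list[int] = field(default_factory=list)  # per corral
    state_paths: dict[str, StatePath] = field(default_factory=dict)  # per active corral
    species_labels: list[str] = field(default_factory=list)  # per track: fast | slow
    arrival_rate: float | None = None  # events s^-1, per stream
    d: float | None = None
    density: float | None = None


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def simulate_corral_activity(config: ActivitySimConfig) -> tuple[list[IntensityTrace], GroundTruth]:
    """Fluorescence time series for a corral array with single-enzyme activity.

    Each active corral's fluorescent substrate count follows a piecewise
    exponential decay (rate ``TN_i / ras0`` during state i), multiplied by
    ``exp(-(photobleach + intrinsic) t)``; inactive corrals carry only the
    bleach/intrinsic channels.  Gaussian measurement noise is added on top.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration / config.frame_interval))
    times = np.arange(n_frames) * config.frame_interval
    bg_decay = np.exp(-(config.photobleach_rate + config.intrinsic_exchange_rate) * times)
    shape, scale = (
        _gamma_params(config.state_rate_mean, config.state_rate_sd)
        if config.state_rate_sd > 0
        else (None, None)
    )
    traces: list[IntensityTrace] = []
    truth = GroundTruth()
    for i in range(config.n_corrals):
        cid = f"corral{i:04d}"
        active = rng.random() < config.active_fraction
        truth.enzyme_counts.append(1 if active else 0)
        if active:
            # renewal process: exponential dwells, i.i.d. gamma rate redraws
            t_switch, bkps = 0.0, []
            while config.state_switch_rate > 0:
                dwell = rng.exponential(1.0 / config.state_switch_rate)
                t_switch += dwell
                if t_switch >= config.duration:
                    break
                bkps.append(t_switch)
            if shape is not None:
                tns = rng.gamma(shape, scale, size=len(bkps) + 1)
            else:
                tns = np.full(len(bkps) + 1, config.state_rate_mean)
            truth.state_paths[cid] = StatePath(list(bkps), [float(x) for x in tns])
            # integrated enzymatic decay exponent at each frame
            edges = np.array([0.0] + bkps + [config.duration])
            ks = tns / config.ras0
            cum_at_edges = np.concatenate([[0.0], np.cumsum(ks * np.diff(edges))])
            seg_idx = np.searchsorted(edges, times, side="right") - 1
            seg_idx = np.clip(seg_idx, 0, len(ks) - 1)
            exponent = cum_at_edges[seg_idx] + ks[seg_idx] * (times - edges[seg_idx])
            enzymatic = np.exp(-exponent)
        else:
            enzymatic = np.ones(n_frames)
        clean = config.ras0 * bg_decay * enzymatic
        noisy = clean + rng.normal(0.0, config.noise_sd * config.ras0, size=n_frames) \
            if config.noise_sd > 0 else clean
        traces.append(IntensityTrace(cid, times, noisy, config.frame_interval))
    return traces, truth


def simulate_steady_state(
    n_corrals: int,
    inactive_mu: float = 0.10,
    inactive_sigma: float = 0.03,
    processive_fraction: float = 0.02,
    processive_exchange_range: tuple[float, float] = (0.5, 1.0),
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Per-corral exchange values: Gaussian majority + uniform processive tail.

    Returns ``(values, labels)`` with labels ``major`` / ``processive``.
    """
    if not 0 <= processive_fraction <= 1:
        raise ValueError("processive_fraction must be in [0, 1]")
    if inactive_sigma < 0:
        raise ValueError("inactive_sigma must be >= 0")
    lo, hi = processive_exchange_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("processive_exchange_range must be within [0, 1]")
    rng = np.random.default_rng(seed)
    is_proc = rng.random(n_corrals) < processive_fraction
    values = rng.normal(inactive_mu, inactive_sigma, size=n_corrals) \
        if inactive_sigma > 0 else np.full(n_corrals, float(inactive_mu))
    values[is_proc] = rng.uniform(lo, hi, size=int(is_proc.sum()))
    labels = ["processive" if p else "major" for p in is_proc]
    return values, labels


def simulate_binding_events(
    molar_rate: float,
    concentration: float,
    duration: float,
    seed: int = 0,
    construct: str = "sim",
    membrane: str = "PS",
) -> BindingEventStream:
    """Homogeneous Poisson binding arrivals at rate ``molar_rate × concentration``."""
    if molar_rate < 0 or concentration < 0 or duration < 0:
        raise ValueError("molar_rate, concentration and duration must be >= 0")
    rng = np.random.default_rng(seed)
    rate = molar_rate * concentration
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    return BindingEventStream(
        construct=construct, membrane=membrane, concentration=concentration,
        duration=duration, event_times=times,
    )


def simulate_tracks(
    d_fast: float,
    d_slow: float,
    alpha: float,
    n_tracks: int,
    track_length: int,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    seed: int = 0,
) -> tuple[TrackSet, list[str]]:
    """Two-species 2D Brownian tracks; each track keeps one species for life.

    Per-axis displacements are Gaussian with variance ``2 D τ``.
    """
    if not d_fast >= d_slow > 0:
        raise ValueError("require d_fast >= d_slow > 0")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if track_length < 2:
        raise ValueError("track_length must be >= 2")
    rng = np.random.default_rng(seed)
    tracks, labels = [], []
    for _ in range(n_tracks):
        fast = rng.random() < alpha
        d = d_fast if fast else d_slow
        labels.append("fast" if fast else "slow")
        sd = np.sqrt(2 * d * frame_interval)
        steps = rng.normal(0.0, sd, size=(track_length - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        pos += rng.uniform(0, 50, size=2)  # random field position
        frames = np.arange(track_length, dtype=float)
        tracks.append(np.column_stack([frames, pos]))
    return TrackSet(tracks, frame_interval), labels


def simulate_bleach_trace(
    n_steps: int,
    unit_intensity: float = 1.0,
    noise_sd: float = 0.0,
    step_times: list[float] | None = None,
    duration: float = 30.0,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    seed: int = 0,
    trace_id: str = "bleach",
) -> IntensityTrace:
    """Stepped photobleaching staircase from ``n_steps × unit_intensity`` to 0.

    ``step_times`` default to sorted uniform draws inside (10%, 90%) of the
    duration; when given they must be strictly increasing, one per step.
    """
    rng = np.random.default_rng(seed)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if step_times is None:
        step_times = sorted(rng.uniform(0.1 * duration, 0.9 * duration, size=n_steps))
    step_times = list(step_times)
    if len(step_times) != n_steps:
        raise ValueError("one step time per bleaching step")
    if any(b <= a for a, b in zip(step_times, step_times[1:])):
        raise ValueError("step_times must be strictly increasing")
    if step_times and not (0 < step_times[0] and step_times[-1] < duration):
        raise ValueError("step_times must lie within (0, duration)")
    n_frames = int(round(duration / frame_interval))
    times = np.arange(n_frames) * frame_interval
    level = n_steps - np.searchsorted(step_times, times, side="right")
    values = level * unit_intensity + (
        rng.normal(0.0, noise_sd, size=n_frames) if noise_sd > 0 else 0.0
    )
    return IntensityTrace(trace_id, times, values, frame_interval)


def simulate_fcs_curve(
    d: float,
    surface_density: float,
    beam_waist: float,
    lags: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """2D-diffusion autocorrelation G(τ) = (1/N)(1+τ/τ_D)^-1 with
    multiplicative Gaussian noise.

    ``N = surface_density · π · beam_waist²`` and ``τ_D = beam_waist²/(4d)``.
    Returns ``(lags, G)``.
    """
    if d <= 0 or surface_density <= 0 or beam_waist <= 0:
        raise ValueError("d, surface_density and beam_waist must be positive")
    lags = np.asarray(lags, dtype=float)
    if len(lags) == 0:
        raise ValueError("lags must be nonempty")
    rng = np.random.default_rng(seed)
    n = surface_density * np.pi * beam_waist**2
    tau_d = beam_waist**2 / (4 * d)
    g = (1.0 / n) / (1.0 + lags / tau_d)
    if noise_sd > 0:
        g = g * (1.0 + rng.normal(0.0, noise_sd, size=len(lags)))
    return lags, g


def render_corral_stack(
    traces: list[IntensityTrace],
    n_rows: int,
    n_cols: int,
    corral_pixels: int = 10,
    border_pixels: int = 2,
) -> np.ndarray:
    """Render corral traces to a uniform-block image stack.

    Each corral is a ``corral_pixels``-square block of its trace value,
    separated by zero-intensity partition lines ``border_pixels`` wide —
    the minimal geometry needed to test trace extraction.  Returns a
    (frames, rows, cols) float array; corrals fill row-major order.
    """
    if len(traces) != n_rows * n_cols:
        raise ValueError("need exactly n_rows * n_cols traces")
    n_frames = len(traces[0])
    pitch = corral_pixels + border_pixels
    h = n_rows * pitch + border_pixels
    w = n_cols * pitch + border_pixels
    stack = np.zeros((n_frames, h, w))
    for idx, tr in enumerate(traces):
        r, c = divmod(idx, n_cols)
        y0 = border_pixels + r * pitch
        x0 = border_pixels + c * pitch
        stack[:, y0: y0 + corral_pixels, x0: x0 + corral_pixels] = tr.values[:, None, None]
    return stack


def simulate_poisson_loading(
    mean_enzymes_per_corral: float, n_corrals: int, seed: int = 0
) -> np.ndarray:
    """I.i.d. Poisson(λ) enzyme counts per corral."""
    if mean_enzymes_per_corral < 0:
        raise ValueError("mean occupancy must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.poisson(mean_enzymes_per_corral, size=n_corrals)
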