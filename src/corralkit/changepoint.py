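"""Penalized change-point detection for piecewise-linear and piecewise-constant signals.

A single engine serves two consumers: segmentation of log-intensity corral
traces into linear pieces (each linear piece on the log scale is one
exponential catalytic state) and counting of photobleaching steps
(piecewise-constant intensity levels).

The model is Gaussian residuals around a per-segment fit.  For a candidate
partition of an ``n``-point signal into ``k+1`` segments the criterion is

    n * log(RSS / n) + penalty * log(n) * (p * (k + 1) + k)

where ``RSS`` is the total residual sum of squares, ``p`` is the number of
free parameters per segment (2 for linear, 1 for constant) and each
breakpoint itself counts as one parameter.  ``penalty = 1`` is the BIC;
larger values yield fewer breakpoints (monotonically — the minimizer of a
criterion linear in ``k`` is non-increasing in the penalty weight).

The partition minimising RSS for each breakpoint count is found exactly by
dynamic programming over precomputed O(1) segment costs, so the result is
the global optimum of the penalized criterion up to ``max_breakpoints``,
not a greedy approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-300


def _prefix_sums(t: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    z = np.zeros(1)
    return {
        "t": np.concatenate([z, np.cumsum(t)]),
        "tt": np.concatenate([z, np.cumsum(t * t)]),
        "y": np.concatenate([z, np.cumsum(y)]),
        "yy": np.concatenate([z, np.cumsum(y * y)]),
        "ty": np.concatenate([z, np.cumsum(t * y)]),
    }


def segment_rss(ps: dict[str, np.ndarray], i, j, model: str):
    """Residual sum of squares of the best fit on the half-open window [i, j).

    ``i`` may be an array (vectorised over candidate left edges).
    """
    i = np.asarray(i)
    n = j - i
    sy = ps["y"][j] - ps["y"][i]
    syy = ps["yy"][j] - ps["yy"][i]
    rss_const = syy - sy * sy / n
    if model == "constant":
        return np.maximum(rss_const, 0.0)
    st = ps["t"][j] - ps["t"][i]
    stt = ps["tt"][j] - ps["tt"][i]
    sty = ps["ty"][j] - ps["ty"][i]
    sxx = stt - st * st / n
    sxy = sty - st * sy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = rss_const - np.where(sxx > 0, sxy * sxy / np.maximum(sxx, _EPS), 0.0)
    return np.maximum(rss, 0.0)


@dataclass
class PiecewiseFit:
    """Result of a penalized piecewise fit."""

    breakpoints: list[int]  # interior sample indices; segment s is [b[s-1], b[s])
    model: str
    rss: float
    criterion: float
    n_breakpoints_considered: int
    segment_bounds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.breakpoints) + 1


def _rss_floor(y: np.ndarray) -> float:
    # cancellation error of the prefix-sum RSS formulas is ~ eps * n * max|y|^2;
    # below this level RSS differences are numerical crumbs, not signal
    m = float(np.max(np.abs(y))) + 1e-30
    return 64.0 * np.finfo(float).eps * len(y) * m * m


def _criterion(n: int, rss: float, k: int, p: int, penalty: float, floor: float = _EPS) -> float:
    return n * np.log(max(rss, floor) / n) + penalty * np.log(n) * (p * (k + 1) + k)


def fit_piecewise(
    t: np.ndarray,
    y: np.ndarray,
    model: str = "linear",
    penalty: float = 1.0,
    min_segment: int = 20,
    max_breakpoints: int = 8,
) -> PiecewiseFit:
    """Optimal penalized segmentation of ``y(t)`` into linear or constant pieces.

    Parameters
    ----------
    t, y
        Sample coordinates; ``t`` strictly increasing.
    model
        ``"linear"`` (free slope + intercept per segment) or ``"constant"``.
    penalty
        Multiplier on the BIC parameter-count term; 1.0 is plain BIC.
    min_segment
        Minimum samples per segment.
    max_breakpoints
        Largest breakpoint count scanned by the dynamic program.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != len(t):
        raise ValueError("t and y must have equal length")
    if n < 2 * min_segment:
        raise ValueError(f"need at least {2 * min_segment} samples, got {n}")
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    p = 2 if model == "linear" else 1
    kmax = min(max_breakpoints, n // min_segment - 1)
    ps = _prefix_sums(t, y)

    # C[k][j]: minimal RSS of fitting y[0:j] with k+1 segments; B[k][j]: argmin split.
    inf = np.inf
    C = np.full((kmax + 1, n + 1), inf)
    B = np.zeros((kmax + 1, n + 1), dtype=int)
    idx = np.arange(n + 1)
    j0 = idx[idx >= min_segment]
    C[0, j0] = segment_rss(ps, 0, j0, model)
    for k in range(1, kmax + 1):
        jmin = (k + 1) * min_segment
        for j in range(jmin, n + 1):
            lo, hi = k * min_segment, j - min_segment
            cand = np.arange(lo, hi + 1)
            prev = C[k - 1, cand]
            ok = np.isfinite(prev)
            if not ok.any():
                continue
            costs = prev[ok] + segment_rss(ps, cand[ok], j, model)
            a = int(np.argmin(costs))
            C[k, j] = costs[a]
            B[k, j] = cand[ok][a]

    floor = _rss_floor(y)
    best_k, best_crit = 0, _criterion(n, C[0, n], 0, p, penalty, floor)
    for k in range(1, kmax + 1):
        if not np.isfinite(C[k, n]):
            continue
        crit = _criterion(n, C[k, n], k, p, penalty, floor)
        if crit < best_crit - 1e-12:
            best_k, best_crit = k, crit

    bkps: list[int] = []
    j = n
    for k in range(best_k, 0, -1):
        j = int(B[k, j])
        bkps.append(j)
    bkps.reverse()
    bounds = list(zip([0] + bkps, bkps + [n]))
    return PiecewiseFit(
        breakpoints=bkps,
        model=model,
        rss=float(C[best_k, n]),
        criterion=float(best_crit),
        n_breakpoints_considered=kmax,
        segment_bounds=bounds,
    )


def exhaustive_fit(
    t: np.ndarray,
    y: np.ndarray,
    model: str = "linear",
    penalty: float = 1.0,
    min_segment: int = 20,
    max_breakpoints: int = 2,
) -> PiecewiseFit:
    """Brute-force scan over every breakpoint placement (oracle; small inputs only).

    Evaluates the same penalized criterion as :func:`fit_piecewise` over all
    placements of up to ``max_breakpoints`` breakpoints and returns the global
    minimum.  Cost grows as ``n**max_breakpoints``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = 2 if model == "linear" else 1
    ps = _prefix_sums(t, y)
    floor = _rss_floor(y)

    best: tuple[float, list[int], float] | None = None

    def consider(bkps: list[int]) -> None:
        nonlocal best
        edges = [0] + bkps + [n]
        rss = float(sum(segment_rss(ps, a, b, model) for a, b in zip(edges, edges[1:])))
        crit = _criterion(n, rss, len(bkps), p, penalty, floor)
        if best is None or crit < best[0] - 1e-12:
            best = (crit, bkps, rss)

    consider([])
    if max_breakpoints >= 1:
        for b1 in range(min_segment, n - min_segment + 1):
            consider([b1])
    if max_breakpoints >= 2:
        for b1 in range(min_segment, n - 2 * min_segment + 1):
            j2 = np.arange(b1 + min_segment, n - min_segment + 1)
            if len(j2) == 0:
                continue
            rss1 = float(segment_rss(ps, 0, b1, model))
            rss2 = segment_rss(ps, np.full_like(j2, b1), j2, model)
            rss3 = segment_rss(ps, j2, n, model)
            tot = rss1 + rss2 + rss3
            a = int(np.argmin(tot))
            consider([b1, int(j2[a])])
    assert best is not None
    crit, bkps, rss = best
    bounds = list(zip([0] + bkps, bkps + [n]))
    return PiecewiseFit(
        breakpoints=bkps,
        model=model,
        rss=rss,
        criterion=crit,
        n_breakpoints_considered=max_breakpoints,
        segment_bounds=bounds,
    )
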