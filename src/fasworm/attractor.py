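"""Asymptotic classification of plane trajectories and the collapse amplitude.

A trajectory in the response plane is classified, after discarding a 5 s
transient, as either a *fixed point* — the trailing 5 s window is confined
to a disc of radius 0.01 (about three orders of magnitude below the healthy
cycle radius; genuinely tiny periodic orbits are deliberately classified as
fixed points) — or a *periodic orbit* — the trajectory escapes a
radius-0.01 disc around its own final point and re-enters it recurrently at
near-constant intervals.  The critical injury amplitude ``mu*`` at which the
limit cycle collapses into a stable fixed point is found by bisection on the
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .neural_modes import PlaneTrajectory

FIXED_POINT = "fixed_point"
PERIODIC = "periodic"


class AttractorUndetermined(RuntimeError):
    """Neither convergence criterion held within the simulation cap."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class AttractorResult:
    kind: str
    endpoint: np.ndarray | None = None       # fixed points only
    period: float | None = None              # s, periodic only
    frequency: float | None = None           # Hz, periodic only
    windows_checked: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (FIXED_POINT, PERIODIC):
            raise ValueError(f"unknown attractor kind {self.kind!r}")
        if (self.endpoint is None) == (self.period is None):
            raise ValueError("exactly one of endpoint/period must be populated")
        if self.period is not None and self.period <= 0:
            raise ValueError("period must be positive")


@dataclass
class MuProfile:
    """Collapse amplitude plus the sampling schedule below it."""

    mu_star: float
    endpoint: np.ndarray | None = None
    bracket: tuple[float, float] | None = None
    n_evals: int = 0
    mu_samples: np.ndarray | None = None
    results: dict[float, AttractorResult] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry helpers


def section_crossings(pt: PlaneTrajectory, center: np.ndarray) -> np.ndarray:
    """Times of same-direction crossings of a Poincare section.

    The section is the half-line ``{x > cx, y = cy}`` through ``center``;
    crossings are counted in the upward (+y) direction and located by linear
    interpolation between samples.
    """
    rel = pt.xy - np.asarray(center, dtype=float)
    x, y, t = rel[:, 0], rel[:, 1], pt.times
    up = (y[:-1] < 0) & (y[1:] >= 0) & (x[:-1] > 0) & (x[1:] > 0)
    idx = np.nonzero(up)[0]
    if idx.size == 0:
        return np.array([])
    frac = -y[idx] / (y[idx + 1] - y[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def estimate_period(pt: PlaneTrajectory) -> float:
    """Dominant oscillation period (s) via the unbiased autocorrelation.

    The centered x and y series are autocorrelated (FFT-based, unbiased
    normalization), summed, and the first peak after the first zero crossing
    is refined by parabolic interpolation.  Makes no assumption about orbit
    geometry (centroid-enclosing or not) and tolerates additive noise.
    """
    from scipy.fft import irfft, next_fast_len, rfft

    z = pt.xy - pt.xy.mean(axis=0)
    n = z.shape[0]
    if n < 8:
        raise AttractorUndetermined("too few samples to estimate a period")
    nfft = next_fast_len(2 * n)
    F = rfft(z, nfft, axis=0)
    acf = irfft((F * F.conj()).real, nfft, axis=0)[:n].sum(axis=1)
    if acf[0] <= 0:
        raise AttractorUndetermined("zero-variance trajectory; no period")
    biased = acf / acf[0]                          # tapered; stable peak picking
    r = acf / np.maximum(n - np.arange(n), 1)      # unbiased; accurate refinement
    r = r / r[0]
    half = n // 2
    neg = np.nonzero(biased[:half] < 0)[0]
    if neg.size == 0:
        raise AttractorUndetermined("autocorrelation never decays; trajectory not oscillatory")
    k0 = int(neg[0])
    k = k0 + int(np.argmax(biased[k0:half]))
    # the taper shifts the biased peak slightly; re-locate on the unbiased ACF
    w = max(3, k // 10)
    lo, hi = max(k0, k - w), min(half, k + w + 1)
    k = lo + int(np.argmax(r[lo:hi]))
    if k <= 0 or k >= half - 1 or r[k] <= 0:
        raise AttractorUndetermined("no autocorrelation peak; trajectory not periodic")
    denom = r[k - 1] - 2 * r[k] + r[k + 1]
    shift = 0.5 * (r[k - 1] - r[k + 1]) / denom if denom != 0 else 0.0
    return (k + float(np.clip(shift, -0.5, 0.5))) * pt.dt_sample


def cycle_frequency(pt: PlaneTrajectory, transient: float = 0.0) -> float:
    """Oscillation frequency (Hz) of a periodic plane trajectory."""
    tail = pt.after(pt.times[0] + transient)
    return 1.0 / estimate_period(tail)


def _reentry_times(tail_xy: np.ndarray, times: np.ndarray, ref: np.ndarray, radius: float) -> np.ndarray:
    """Times of successive visits of the path to the ``radius`` disc at ``ref``.

    Works on the polyline between samples (distance from ``ref`` to each
    segment), so a fast orbit cannot jump over the disc between samples.
    Each maximal run of segments dipping inside the disc counts as one
    visit, timed at its closest approach.
    """
    p = tail_xy[:-1]
    v = np.diff(tail_xy, axis=0)
    w = ref - p
    vv = (v**2).sum(axis=1)
    s = np.clip(np.divide((w * v).sum(axis=1), vv, out=np.zeros_like(vv), where=vv > 0), 0.0, 1.0)
    closest = p + s[:, None] * v
    d = np.linalg.norm(closest - ref, axis=1)
    inside = d <= radius
    if not inside.any():
        return np.array([])
    starts = np.nonzero(inside & ~np.concatenate([[False], inside[:-1]]))[0]
    ends = np.nonzero(inside & ~np.concatenate([inside[1:], [False]]))[0]
    visit_times = []
    for a, b in zip(starts, ends):
        k = a + int(np.argmin(d[a : b + 1]))
        visit_times.append(times[k] + s[k] * (times[k + 1] - times[k]))
    return np.asarray(visit_times)


def classify_attractor(
    pt: PlaneTrajectory,
    transient: float = 5.0,
    window: float = 5.0,
    radius: float = 0.01,
    center_mode: str = "mean",
    reentry_cv: float = 0.2,
    extend: Callable[[float], PlaneTrajectory] | None = None,
    max_time: float = 60.0,
) -> AttractorResult:
    """Classify a plane trajectory as a fixed point or a periodic orbit.

    The criteria are checked at the end of each successive ``window`` of
    simulated time after the transient:

    * fixed point — every point of the trailing window lies within
      ``radius`` of the window's reference center (its mean by default, its
      final point with ``center_mode='last'``); the endpoint is the trailing
      window mean;
    * periodic — the post-transient trajectory exits the ``radius`` disc
      around its final point (which lies on the orbit) and re-enters it at
      least twice, with the coefficient of variation of re-entry intervals
      below ``reentry_cv`` (guarding against slow oscillatory transients
      masquerading as cycles).

    ``extend(additional_seconds)`` is an optional continuation hook returning
    the prolonged trajectory; classification keeps extending until a
    criterion holds or ``max_time`` of simulated time is exceeded.
    """
    if pt.duration < transient + window:
        if extend is None:
            raise AttractorUndetermined(
                f"trajectory spans {pt.duration:.2f} s < transient+window"
            )
        pt = extend(transient + window - pt.duration)

    t0 = pt.times[0]
    checked = 0
    t_check = t0 + transient + window
    while True:
        while t_check <= pt.times[-1] + 1e-12:
            checked += 1
            win = pt.after(t_check - window)
            win = PlaneTrajectory(
                win.times[win.times <= t_check + 1e-12], win.xy[win.times <= t_check + 1e-12]
            )
            center = win.xy[-1] if center_mode == "last" else win.xy.mean(axis=0)
            dmax = float(np.linalg.norm(win.xy - center, axis=1).max())
            if dmax <= radius:
                return AttractorResult(
                    FIXED_POINT, endpoint=win.xy.mean(axis=0), windows_checked=checked
                )
            tail = pt.after(t0 + transient)
            tail = PlaneTrajectory(
                tail.times[tail.times <= t_check + 1e-12],
                tail.xy[tail.times <= t_check + 1e-12],
            )
            entries = _reentry_times(tail.xy, tail.times, tail.xy[-1], radius)
            if entries.size >= 3:
                intervals = np.diff(entries)
                mean_int = float(intervals.mean())
                # a decaying oscillatory transient re-enters at constant
                # intervals too while it shrinks through the disc scale; a
                # genuine orbit additionally keeps a steady extent
                h = tail.xy.shape[0] // 2
                ctr = tail.xy.mean(axis=0)
                rms1 = float(np.sqrt(((tail.xy[:h] - ctr) ** 2).sum(axis=1).mean()))
                rms2 = float(np.sqrt(((tail.xy[h:] - ctr) ** 2).sum(axis=1).mean()))
                steady = rms1 > 0 and rms2 >= 0.75 * rms1
                if mean_int > 0 and float(intervals.std()) / mean_int < reentry_cv and steady:
                    return AttractorResult(
                        PERIODIC,
                        period=mean_int,
                        frequency=1.0 / mean_int,
                        windows_checked=checked,
                    )
            t_check += window
        if extend is None or pt.duration >= max_time:
            raise AttractorUndetermined(
                "no convergence criterion held",
                diagnostics={
                    "duration": pt.duration,
                    "windows_checked": checked,
                    "last_window_extent": dmax if checked else None,
                },
            )
        pt = extend(min(window * 2, max_time - pt.duration))


# ---------------------------------------------------------------------------
# collapse amplitude


def find_mu_star(
    classify: Callable[[float], AttractorResult],
    rel_tol: float = 1e-3,
    mu_hi0: float = 1.0,
    mu_cap: float = 4096.0,
) -> MuProfile:
    """Bisection for the amplitude at which the cycle collapses.

    ``classify(mu)`` must return an :class:`AttractorResult`.  The healthy
    network (``mu = 0``) must classify periodic; the upper bound is found by
    doubling, then the bracket is bisected until its width falls below
    ``rel_tol`` times the upper end.  Returns the bracket midpoint, the
    bracket itself, and the endpoint observed on the fixed-point side.
    """
    base = classify(0.0)
    if base.kind != PERIODIC:
        raise ValueError("dynamics at mu=0 are not periodic; degenerate network")
    n_evals = 1
    lo, hi = 0.0, mu_hi0
    endpoint = None
    while True:
        res = classify(hi)
        n_evals += 1
        if res.kind == FIXED_POINT:
            endpoint = res.endpoint
            break
        lo = hi
        hi *= 2.0
        if hi > mu_cap:
            raise ValueError(f"no collapse found below mu = {mu_cap}")
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        res = classify(mid)
        n_evals += 1
        if res.kind == FIXED_POINT:
            hi = mid
            endpoint = res.endpoint
        else:
            lo = mid
    return MuProfile(
        mu_star=0.5 * (lo + hi),
        endpoint=endpoint,
        bracket=(lo, hi),
        n_evals=n_evals,
    )


def mu_schedule(mu_star: float) -> np.ndarray:
    """Sampling schedule below collapse: 5 interior points linearly spaced in
    (0, 0.9 mu*) plus 10 in (0.9 mu*, mu*), strictly increasing, endpoints
    excluded."""
    if mu_star <= 0:
        raise ValueError("mu_star must be positive")
    low = np.linspace(0.0, 0.9 * mu_star, 7)[1:-1]
    high = np.linspace(0.9 * mu_star, mu_star, 12)[1:-1]
    return np.concatenate([low, high])
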