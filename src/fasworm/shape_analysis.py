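"""Procrustes shape analysis of limit cycles.

The deformation of an injured limit cycle relative to the healthy one is
quantified by the Procrustes distance

    PD = min_{b, R, c} || S_B - (b S_A R + c) ||^2

over uniform scaling ``b > 0``, proper rotation ``R`` (reflections
excluded) and translation ``c`` — a dissimilarity that discounts where the
cycle sits, how large it is, and how it is oriented, leaving pure shape.
The value reported is the standardized (scale-normalized) form

    pd = 1 - tr(Sigma)^2 / (||A_c||^2 ||B_c||^2)

where ``Sigma`` holds the singular values of the centered cross-covariance;
this is symmetric in the two shapes and zero exactly for
similarity-equivalent shapes.  The raw minimized residual is also reported.

Cycles are compared as closed curves resampled to a common number of points
with a periodic cubic spline; the unknown phase offset between two cycles is
removed by exhaustive search over cyclic shifts (both traversal directions,
since reversing the direction of travel is not a rotation of the point set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .attractor import (
    PERIODIC,
    AttractorResult,
    AttractorUndetermined,
    estimate_period,
)
from .neural_modes import PlaneTrajectory


class ShapeError(ValueError):
    pass


@dataclass
class Shape:
    """One closed-cycle period as a uniformly resampled (N, 2) point matrix."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ShapeError("points must be (N, 2)")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class ProcrustesResult:
    pd: float                 # standardized dissimilarity, in [0, 1]
    b: float                  # scaling applied to S_A to match S_B
    R: np.ndarray             # 2x2 proper rotation
    c: np.ndarray             # translation
    raw: float                # minimized raw residual of the objective
    phase_shift: int = 0      # cyclic index offset used in alignment
    reversed: bool = False    # whether S_B traversal was reversed


# ---------------------------------------------------------------------------
# period extraction and resampling


def extract_period(
    pt: PlaneTrajectory,
    transient: float = 5.0,
    result: AttractorResult | None = None,
) -> np.ndarray:
    """Points of the last full cycle of a periodic plane trajectory.

    The period is estimated from the autocorrelation of the post-transient
    tail and the final whole period is sliced out.  ``result`` (from the
    attractor classifier) may be supplied to assert periodicity;
    non-periodic input is an error.
    """
    if result is not None and result.kind != PERIODIC:
        raise ShapeError("cannot extract a period from a non-periodic trajectory")
    tail = pt.after(pt.times[0] + transient)
    try:
        period = estimate_period(tail)
    except AttractorUndetermined as exc:
        raise ShapeError(str(exc)) from exc
    t_end = tail.times[-1]
    mask = (tail.times >= t_end - period) & (tail.times < t_end)
    pts = tail.xy[mask]
    if pts.shape[0] < 4:
        raise ShapeError("period contains fewer than 4 samples; increase sampling rate")
    return pts


def resample_closed_curve(points: np.ndarray, N: int = 200) -> Shape:
    """Resample a closed curve to N points via a periodic cubic spline.

    The curve is parameterized by normalized cumulative chord length and
    evaluated at uniform parameter spacing.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        raise ShapeError("need at least 4 points")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ShapeError("degenerate (zero-extent) curve")
    # drop zero-length segments to keep the parameterization strictly increasing
    keep = np.concatenate([[True], seg > 1e-12 * total])
    closed = closed[keep]
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)]) / seg.sum()
    spline = CubicSpline(u, closed, bc_type="periodic", axis=0)
    return Shape(spline(np.arange(N) / N))


# ---------------------------------------------------------------------------
# Procrustes


def procrustes(S_A: Shape, S_B: Shape) -> ProcrustesResult:
    """Optimal similarity alignment of ``S_A`` onto ``S_B``.

    Closed-form: center both shapes, take the SVD of the cross-covariance
    for the optimal proper rotation, then the optimal scaling.  The returned
    ``b`` is the factor by which ``S_A`` must be scaled to match ``S_B``
    (b < 1 when the second cycle has shrunk).
    """
    A, B = S_A.points, S_B.points
    if A.shape != B.shape:
        raise ShapeError(f"shapes must have equal N: {A.shape[0]} vs {B.shape[0]}")
    abar, bbar = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - abar, B - bbar
    na2 = float((Ac**2).sum())
    nb2 = float((Bc**2).sum())
    if na2 <= 0 or nb2 <= 0:
        raise ShapeError("zero-variance shape")
    M = Ac.T @ Bc
    U, sig, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt                      # applied as Ac @ R
    trace = float((sig * np.diag(D)).sum())
    b = trace / na2
    raw = nb2 - trace**2 / na2
    pd_val = 1.0 - trace**2 / (na2 * nb2)
    c = bbar - b * (abar @ R)
    return ProcrustesResult(pd=max(pd_val, 0.0), b=b, R=R, c=c, raw=max(raw, 0.0))


def phase_aligned_pd(S_A: Shape, S_B: Shape, try_reversal: bool = True) -> ProcrustesResult:
    """Minimum Procrustes distance over all cyclic phase shifts of ``S_B``.

    Both traversal directions of ``S_B`` are searched by default (direction
    reversal cannot be absorbed by a proper rotation of the plane).
    """
    best: ProcrustesResult | None = None
    variants = [(False, S_B.points)]
    if try_reversal:
        variants.append((True, S_B.points[::-1]))
    for rev, pts in variants:
        for shift in range(pts.shape[0]):
            res = procrustes(S_A, Shape(np.roll(pts, -shift, axis=0)))
            if best is None or res.pd < best.pd:
                res.phase_shift = shift
                res.reversed = rev
                best = res
    return best


# ---------------------------------------------------------------------------
# PD curves


@dataclass
class PDCurve:
    """Deficit profile of one injury: PD, scaling, translation versus mu."""

    mu_values: np.ndarray
    pd_values: np.ndarray
    scaling_values: np.ndarray
    translation_values: np.ndarray
    frequency_values: np.ndarray
    mu_star: float
    gaps: list[float] = field(default_factory=list)   # mu values that failed

    def __post_init__(self) -> None:
        for name in ("mu_values", "pd_values", "scaling_values", "translation_values", "frequency_values"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = self.mu_values.size
        if any(
            getattr(self, nm).size != k
            for nm in ("pd_values", "scaling_values", "translation_values", "frequency_values")
        ):
            raise ShapeError("PDCurve arrays must have equal length")
        if np.any(np.diff(self.mu_values) <= 0):
            raise ShapeError("mu values must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "mu": self.mu_values,
                "pd": self.pd_values,
                "scaling": self.scaling_values,
                "translation": self.translation_values,
                "frequency": self.frequency_values,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, mu_star: float) -> "PDCurve":
        df = pd.read_csv(path)
        return cls(
            df["mu"].to_numpy(), df["pd"].to_numpy(), df["scaling"].to_numpy(),
            df["translation"].to_numpy(), df["frequency"].to_numpy(), mu_star,
        )


def shape_from_trajectory(pt: PlaneTrajectory, transient: float = 5.0, N: int = 200) -> Shape:
    """Extract one period and resample it to a closed N-point shape."""
    return resample_closed_curve(extract_period(pt, transient=transient), N)


def pd_curve(
    plane_traj_at_mu: Callable[[float], PlaneTrajectory | None],
    schedule: np.ndarray,
    healthy_shape: Shape,
    mu_star: float,
    transient: float = 5.0,
    N: int = 200,
    healthy_frequency: float = np.nan,
) -> PDCurve:
    """PD/scaling/translation profile across the mu schedule.

    ``plane_traj_at_mu(mu)`` returns the (periodic) plane trajectory at that
    amplitude, or ``None`` when the dynamics did not classify periodic there.
    Per-mu failures are recorded as gaps, not raised.  The mu = 0 entry
    (healthy vs healthy: pd = 0, scaling 1, translation 0) is prepended.
    Translation is the displacement of the injured-cycle mean from the
    healthy-cycle mean.
    """
    healthy_centroid = healthy_shape.centroid
    mus = [0.0]
    pds = [0.0]
    scals = [1.0]
    trans = [0.0]
    freqs = [healthy_frequency]
    gaps: list[float] = []
    for mu in np.asarray(schedule, dtype=float):
        try:
            pt = plane_traj_at_mu(float(mu))
            if pt is None:
                gaps.append(float(mu))
                continue
            from .attractor import cycle_frequency

            shp = shape_from_trajectory(pt, transient=transient, N=N)
            res = phase_aligned_pd(healthy_shape, shp)
            mus.append(float(mu))
            pds.append(res.pd)
            scals.append(res.b)
            trans.append(float(np.linalg.norm(shp.centroid - healthy_centroid)))
            freqs.append(cycle_frequency(pt, transient=transient))
        except (ShapeError, AttractorUndetermined):
            gaps.append(float(mu))
    return PDCurve(
        np.array(mus), np.array(pds), np.array(scals), np.array(trans), np.array(freqs),
        mu_star=mu_star, gaps=gaps,
    )


def normalize_and_average(
    curves: list[PDCurve],
    which: str = "pd",
    grid_size: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average deficit curves on a common normalized-amplitude grid.

    Each curve's mu axis is rescaled to [0, 1] by its own mu*; PD values are
    additionally rescaled to a maximum of 1 (scaling and translation are
    averaged on their raw value scale, where the monotone trends are the
    object of interest).  Curves are spline-interpolated onto a common grid;
    the pointwise mean and standard deviation are returned as
    ``(grid, mean, std)``.
    """
    if not curves:
        raise ShapeError("empty curve list")
    key = {"pd": "pd_values", "scaling": "scaling_values", "translation": "translation_values"}
    if which not in key:
        raise ShapeError(f"unknown curve kind {which!r}")
    grid = np.linspace(0.0, 1.0, grid_size)
    rows = []
    for cv in curves:
        x = cv.mu_values / cv.mu_star
        y = getattr(cv, key[which]).astype(float).copy()
        if which == "pd":
            peak = np.abs(y).max()
            if peak > 0:
                y = y / peak
        if x.size >= 4:
            interp = CubicSpline(x, y)
        else:
            interp = lambda g, x=x, y=y: np.interp(g, x, y)
        rows.append(interp(np.clip(grid, x[0], x[-1])))
    stack = np.vstack(rows)
    return grid, stack.mean(axis=0), stack.std(axis=0)
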