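"""Artificial linear map from the neural plane onto body-shape coefficients.

Forward crawling appears as a closed orbit both in the motorneuron response
plane and in the phase plane of the worm's first two principal body-shape
("eigenworm") modes, where the healthy orbit is approximately a unit
circle.  We calibrate an affine map sending the healthy neural cycle as
close as possible to the unit circle at matched uniform phase, then apply
that fixed map to every injured trajectory — distorted orbits become
distorted posture-coefficient traces, and a collapsed fixed point becomes a
static posture (the paralysis reading).  The relative rotation between the
two planes is unknowable from the neural side alone and defaults to
identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .neural_modes import PlaneTrajectory
from .shape_analysis import Shape


class BehaviorMapError(ValueError):
    pass


@dataclass
class CircleCalibration:
    A: np.ndarray            # 2x2 linear map
    offset: np.ndarray       # 2-vector
    residual: float          # mean squared distance to the target circle

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) @ self.A.T + self.offset


def calibrate_circle_map(
    healthy: Shape,
    rotation: float = 0.0,
    affine: bool = True,
) -> CircleCalibration:
    """Least-squares affine map of the healthy cycle onto the unit circle.

    The uniformly resampled cycle point ``k`` of ``N`` is matched to the
    circle point at phase ``2 pi k / N + rotation``; the free ``rotation``
    angle encodes the unknown relative orientation of the two planes.  With
    ``affine=False`` the offset is forced to zero (pure linear map).
    """
    P = healthy.points
    N = P.shape[0]
    if N < 4:
        raise BehaviorMapError("need at least 4 cycle points")
    if float(np.abs(P - P.mean(axis=0)).max()) <= 0:
        raise BehaviorMapError("degenerate cycle")
    theta = 2.0 * np.pi * np.arange(N) / N + rotation
    target = np.column_stack([np.cos(theta), np.sin(theta)])
    if affine:
        design = np.column_stack([P, np.ones(N)])
    else:
        design = P
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    A = coef[:2].T
    offset = coef[2] if affine else np.zeros(2)
    if abs(np.linalg.det(A)) < 1e-12:
        raise BehaviorMapError("calibrated map is singular (degenerate cycle)")
    mapped = design @ coef
    residual = float(np.mean(np.sum((mapped - target) ** 2, axis=1)))
    return CircleCalibration(A=A, offset=offset, residual=residual)


def map_to_behavior(
    pt: PlaneTrajectory,
    cal: CircleCalibration,
    basis: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Behavioral mode coefficients (and optional body-angle reconstruction).

    Returns ``(coefficients, angles)`` where ``coefficients`` is (n_t, 2).
    ``basis`` is a (n_segments, 2) eigenworm mode matrix over body segments;
    when given, ``angles = coefficients @ basis.T`` reconstructs the body
    angle profile per time sample.
    """
    coeffs = cal.apply(pt.xy)
    if basis is None:
        return coeffs, None
    basis = np.asarray(basis, dtype=float)
    if basis.ndim != 2 or basis.shape[1] != 2:
        raise BehaviorMapError("basis must be (n_segments, 2)")
    return coeffs, coeffs @ basis.T


def synthetic_eigenworm_basis(n_segments: int = 48) -> np.ndarray:
    """SYNTHETIC sinusoidal 2-mode posture basis for demos.

    A quadrature pair of single-wavelength sinusoids along the body — *not*
    the biological eigenworm modes (those are user-supplied from posture
    data); this stand-in merely has the right quadrature structure so that a
    circular coefficient orbit produces a traveling body wave.
    """
    s = np.arange(n_segments) / n_segments
    return np.column_stack([np.sin(2 * np.pi * s), np.cos(2 * np.pi * s)])


def read_basis(path: str | Path) -> np.ndarray:
    """Read an eigenworm basis CSV with columns (segment, mode1, mode2)."""
    df = pd.read_csv(path)
    return df[["mode1", "mode2"]].to_numpy(dtype=float)


def write_basis(path: str | Path, basis: np.ndarray) -> None:
    basis = np.asarray(basis, dtype=float)
    pd.DataFrame(
        {"segment": np.arange(basis.shape[0]), "mode1": basis[:, 0], "mode2": basis[:, 1]}
    ).to_csv(path, index=False)
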