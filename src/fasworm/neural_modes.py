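"""The two-mode response plane of the forward-motion motorneurons.

Constant stimulation of the input pair drives an oscillation that is almost
entirely captured by the two leading left singular vectors of the
motorneuron voltage snapshot matrix ``V = [v(t0), v(t1), ...] = P S Q^T``.
The plane is computed once from healthy dynamics and reused unchanged for
every injured trajectory, so that injured orbits are directly comparable in
the same coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Trajectory


class PlaneError(ValueError):
    pass


@dataclass
class NeuralPlane:
    """First two principal orthogonal modes plus the full singular spectrum."""

    mode1: np.ndarray
    mode2: np.ndarray
    singular_values: np.ndarray
    subset: list[str]

    def __post_init__(self) -> None:
        self.mode1 = np.asarray(self.mode1, dtype=float)
        self.mode2 = np.asarray(self.mode2, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)

    def to_files(self, csv_path: str | Path, spectrum_path: str | Path) -> None:
        pd.DataFrame(
            {"neuron": self.subset, "mode1": self.mode1, "mode2": self.mode2}
        ).to_csv(csv_path, index=False)
        Path(spectrum_path).write_text(
            json.dumps({"singular_values": self.singular_values.tolist()})
        )

    @classmethod
    def from_files(cls, csv_path: str | Path, spectrum_path: str | Path) -> "NeuralPlane":
        df = pd.read_csv(csv_path)
        spec = json.loads(Path(spectrum_path).read_text())
        return cls(
            df["mode1"].to_numpy(),
            df["mode2"].to_numpy(),
            np.asarray(spec["singular_values"]),
            list(df["neuron"]),
        )


@dataclass
class PlaneTrajectory:
    """2-D projection of a voltage trajectory onto the response plane."""

    times: np.ndarray
    xy: np.ndarray    # (n_samples, 2)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (self.times.size, 2):
            raise PlaneError("xy must be (len(times), 2)")

    @property
    def dt_sample(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times.size else 0.0

    def after(self, t: float) -> "PlaneTrajectory":
        mask = self.times >= t
        return PlaneTrajectory(self.times[mask], self.xy[mask])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.times, "x": self.xy[:, 0], "y": self.xy[:, 1]}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlaneTrajectory":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df[["x", "y"]].to_numpy())


def _fix_sign(mode: np.ndarray) -> np.ndarray:
    # deterministic convention: the largest-magnitude component is positive
    k = int(np.argmax(np.abs(mode)))
    return -mode if mode[k] < 0 else mode


def compute_plane(
    traj: Trajectory,
    transient: float = 5.0,
    center: bool = False,
) -> NeuralPlane:
    """SVD of the voltage snapshot matrix after transient removal.

    Snapshots are *not* mean-centered by default (the decomposition acts on
    the raw voltage matrix); pass ``center=True`` for conventional PCA.
    """
    mask = traj.times >= traj.times[0] + transient
    X = traj.V[mask].T.copy()           # neurons x snapshots
    if X.shape[1] < 2:
        raise PlaneError("need at least 2 snapshots after transient removal")
    if center:
        X -= X.mean(axis=1, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    if S[0] <= 0:
        raise PlaneError("rank-0 snapshot matrix")
    return NeuralPlane(
        mode1=_fix_sign(U[:, 0]),
        mode2=_fix_sign(U[:, 1]),
        singular_values=S,
        subset=list(traj.names),
    )


def energy_fraction(plane: NeuralPlane, k: int) -> float:
    """Fraction of total snapshot energy captured by the leading k modes."""
    if k < 1:
        raise PlaneError("k must be >= 1")
    s2 = plane.singular_values**2
    return float(s2[:k].sum() / s2.sum())


def project(traj: Trajectory, plane: NeuralPlane) -> PlaneTrajectory:
    """Project each voltage snapshot onto (mode1, mode2)."""
    if list(traj.names) != list(plane.subset):
        raise PlaneError(
            f"trajectory subset {traj.names} does not match plane subset {plane.subset}"
        )
    P = np.column_stack([plane.mode1, plane.mode2])
    return PlaneTrajectory(traj.times, traj.V @ P)
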