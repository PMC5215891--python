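"""Synthetic generators: analytic trajectories, planted ensembles, demo data.

Everything here is deterministic under a seed and writes files in the same
dialects the real pipeline reads, so the generators double as format
conformance tests.  None of it is biological data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .connectome import (
    OSCILLATOR_BETA,
    OSCILLATOR_INPUT,
    Connectome,
    oscillator_motif,
)
from .dynamics import ModelParams
from .injury import SwellingDistribution, synthetic_swelling_distribution
from .neural_modes import PlaneTrajectory


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# analytic plane trajectories


def analytic_trajectory(
    kind: str,
    T: float = 20.0,
    dt: float = 1e-3,
    radius: float = 1.0,
    radius_b: float | None = None,
    frequency: float = 0.5,
    center: tuple[float, float] = (0.0, 0.0),
    phase: float = 0.0,
    decay: float = 0.2,
    noise: float = 0.0,
    seed: int = 0,
) -> PlaneTrajectory:
    """Closed-form plane trajectories with known period/endpoint.

    Kinds: ``circle``, ``ellipse`` (semi-axes ``radius``/``radius_b``),
    ``shrinking_cycle`` (radius decays exponentially at rate ``decay`` while
    orbiting), ``decaying_spiral`` (same, but read as a transient to a fixed
    point), ``fixed_point`` (constant at ``center``).  Optional additive
    Gaussian noise of standard deviation ``noise``.
    """
    t = np.arange(0.0, T, dt)
    w = 2.0 * np.pi * frequency
    cx, cy = center
    if kind == "circle":
        xy = np.column_stack([cx + radius * np.cos(w * t + phase), cy + radius * np.sin(w * t + phase)])
    elif kind == "ellipse":
        b = radius_b if radius_b is not None else radius / 2.0
        xy = np.column_stack([cx + radius * np.cos(w * t + phase), cy + b * np.sin(w * t + phase)])
    elif kind in ("shrinking_cycle", "decaying_spiral"):
        r = radius * np.exp(-decay * t)
        xy = np.column_stack([cx + r * np.cos(w * t + phase), cy + r * np.sin(w * t + phase)])
    elif kind == "fixed_point":
        xy = np.tile([cx, cy], (t.size, 1)).astype(float)
    else:
        raise FixtureError(f"unknown trajectory kind {kind!r}")
    if noise > 0:
        rng = np.random.default_rng(seed)
        xy = xy + rng.normal(scale=noise, size=xy.shape)
    return PlaneTrajectory(t, xy)


# ---------------------------------------------------------------------------
# oscillator fixture setup


def oscillator_setup() -> tuple[Connectome, ModelParams, dict[str, float]]:
    """The frozen oscillator motif with its fixture parameters and drive.

    Returns ``(connectome, params, I_ext)`` ready for
    :func:`fasworm.dynamics.simulate`.  The sigmoid width and input current
    are the motif's frozen constants, not the full-network defaults.
    """
    c = oscillator_motif()
    params = ModelParams(beta=OSCILLATOR_BETA)
    I_ext = {name: OSCILLATOR_INPUT for name in c.group("input")}
    return c, params, I_ext


# ---------------------------------------------------------------------------
# planted-structure ensembles


@dataclass
class PlantedEnsembleSpec:
    """Injury-like feature matrix with labels planted on two driver neurons.

    Labels follow an axis-aligned rule on the two driver columns — sample k
    is "upper" when either driver's swelling exceeds the ``quantile`` of its
    marginal — then flipped independently with probability ``noise``.  The
    Bayes error is therefore exactly ``noise`` and the expected upper
    fraction is ``(1 - q^2)(1 - noise) + q^2 noise`` for quantile ``q``.
    """

    K: int = 100
    n: int = 12
    drivers: tuple[int, int] = (2, 7)
    quantile: float = 0.5
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 10:
            raise FixtureError("need K >= 10")
        if not 0 <= self.noise <= 1 or not 0 < self.quantile < 1:
            raise FixtureError("noise in [0,1], quantile in (0,1)")
        if len(set(self.drivers)) != 2 or max(self.drivers) >= self.n:
            raise FixtureError("drivers must be two distinct feature indices < n")

    @property
    def expected_upper_fraction(self) -> float:
        q, p = self.quantile, self.noise
        return (1 - q**2) * (1 - p) + q**2 * p


def planted_ensemble(
    spec: PlantedEnsembleSpec,
    dist: SwellingDistribution | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``(X, y)``: row-normalized injury matrix and planted labels."""
    if dist is None:
        dist = synthetic_swelling_distribution()
    rng = np.random.default_rng(spec.seed)
    raw = dist.sample((spec.K, spec.n), rng).astype(float)
    # jitter within bins so feature values are continuous and quantiles sharp
    bin_width = np.diff(np.sort(np.unique(dist.bin_values))).min()
    raw = raw + rng.uniform(0, bin_width, size=raw.shape)
    X = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    d0, d1 = spec.drivers
    t0 = np.quantile(X[:, d0], spec.quantile)
    t1 = np.quantile(X[:, d1], spec.quantile)
    y_clean = (X[:, d0] >= t0) | (X[:, d1] >= t1)
    flip = rng.random(spec.K) < spec.noise
    y = np.where(y_clean ^ flip, "upper", "lower").astype(object)
    return X, y


# ---------------------------------------------------------------------------
# demo workspace


def write_demo_workspace(directory: str | Path, seed: int = 0) -> Path:
    """Write a self-contained demo workspace: connectome tables, swelling
    histogram, and a run config, in the formats the pipeline reads."""
    from .pipeline import EnsembleConfig, write_config

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    c = oscillator_motif()
    c.write_tables(d / "connectome")
    synthetic_swelling_distribution().to_csv(d / "swelling_histogram.csv")
    cfg = EnsembleConfig(
        connectome="oscillator",
        histogram=str(d / "swelling_histogram.csv"),
        K=3,
        seed=seed,
        out_dir=str(d / "run"),
    )
    write_config(cfg, d / "config.yaml")
    return d
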