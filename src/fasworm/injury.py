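"""Focal-axonal-swelling (FAS) injury vectors.

An injury assigns every non-protected neuron a relative swelling ``m_i``
drawn i.i.d. from an empirical distribution of axonal swelling magnitudes;
the vector is then L2-normalized, ``||m||_2 = 1``.  A single global
amplitude ``mu >= 0`` scales the whole injury: the effective swelling factor
of neuron ``i`` is ``1 + mu * m_i``, which multiplies its membrane
capacitance and leak conductance — equivalently, divides its gap and
synaptic input currents.  The stimulated input pair is left uninjured by
default.  ``mu`` relates to the mean relative swollen-to-healthy area ratio
through ``mu = (<a_i/a_H> - 1) / <m_i>``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome

logger = logging.getLogger(__name__)


class InjuryError(ValueError):
    pass


@dataclass
class SwellingDistribution:
    """Discrete histogram of relative swelling magnitudes."""

    bin_values: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.bin_values = np.asarray(self.bin_values, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.bin_values.shape != self.probabilities.shape or self.bin_values.ndim != 1:
            raise InjuryError("bin_values and probabilities must be equal-length vectors")
        if np.any(self.bin_values < 0) or np.any(self.probabilities < 0):
            raise InjuryError("negative histogram entries")
        total = self.probabilities.sum()
        if total <= 0:
            raise InjuryError("all-zero histogram")
        self.probabilities = self.probabilities / total

    @property
    def mean(self) -> float:
        return float(self.bin_values @ self.probabilities)

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.bin_values, size=size, p=self.probabilities)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"value": self.bin_values, "probability": self.probabilities}).to_csv(
            path, index=False
        )


def distribution_from_histogram(path: str | Path) -> SwellingDistribution:
    """Read a two-column (value, probability) histogram; normalize to sum 1."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InjuryError("histogram file needs two columns: value, probability")
    return SwellingDistribution(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def synthetic_swelling_distribution(
    median: float = 0.3,
    sigma: float = 0.5,
    n_bins: int = 30,
    max_value: float = 2.0,
) -> SwellingDistribution:
    """SYNTHETIC stand-in swelling histogram (discretized log-normal).

    The empirically measured mouse optic-nerve swelling histogram is not
    distributed in numeric form; this clearly-labeled synthetic surrogate has
    the same qualitative character (nonnegative, unimodal, right-skewed).
    Any user histogram file is accepted by :func:`distribution_from_histogram`
    instead.
    """
    edges = np.linspace(1e-3, max_value, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu_log = np.log(median)
    dens = np.exp(-((np.log(centers) - mu_log) ** 2) / (2 * sigma**2)) / centers
    return SwellingDistribution(centers, dens)


@dataclass
class InjuryVector:
    """Per-neuron swellings ``m`` (unit L2 norm) plus global amplitude ``mu``."""

    m: np.ndarray
    neuron_names: list[str]
    protected: list[str] = field(default_factory=list)
    mu: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if np.any(self.m < 0):
            raise InjuryError("swellings must be nonnegative")
        if self.mu < 0:
            raise InjuryError("mu must be nonnegative")
        norm = np.linalg.norm(self.m)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise InjuryError(f"||m||_2 = {norm:.6g}, expected 1")
        idx = {nm: i for i, nm in enumerate(self.neuron_names)}
        for nm in self.protected:
            if self.m[idx[nm]] != 0.0:
                raise InjuryError(f"protected neuron {nm} has nonzero swelling")

    def with_mu(self, mu: float) -> "InjuryVector":
        return InjuryVector(self.m, self.neuron_names, list(self.protected), mu, self.seed)

    def scale(self, mu: float | None = None) -> np.ndarray:
        """Per-neuron swelling factor ``1 + mu * m_i``."""
        mu = self.mu if mu is None else mu
        if mu < 0:
            raise InjuryError("mu must be nonnegative")
        return 1.0 + mu * self.m


def sample_injury(
    dist: SwellingDistribution,
    c: Connectome,
    protected: list[str] | None = None,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> InjuryVector:
    """Draw an injury vector: i.i.d. swellings, zero on protected neurons.

    ``protected`` defaults to the connectome's ``input`` group (the
    stimulated pair is left uninjured).  ``weights`` is an optional
    per-neuron multiplicative hook for spatially-biased variants; the default
    random assignment deliberately ignores spatial structure.
    """
    if protected is None:
        protected = c.groups.get("input", [])
    unknown = set(protected) - set(c.neuron_names)
    if unknown:
        raise InjuryError(f"protected set references unknown neurons: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    prot_idx = c.index(list(protected)) if protected else np.array([], dtype=int)
    for _ in range(100):
        m = dist.sample(c.n, rng).astype(float)
        if weights is not None:
            m = m * np.asarray(weights, dtype=float)
        m[prot_idx] = 0.0
        norm = np.linalg.norm(m)
        if norm > 0:
            return InjuryVector(m / norm, list(c.neuron_names), list(protected), seed=seed)
        logger.warning("all swelling draws were zero; resampling")
    raise InjuryError("could not draw a nonzero injury vector")


def mu_from_mean_swelling(target_ratio: float, injury: InjuryVector) -> float:
    """Amplitude giving a prescribed mean swollen/healthy area ratio.

    ``mu = (target_ratio - 1) / <m_i>`` so that ``mean(1 + mu m_i)`` equals
    ``target_ratio``.  The mean runs over all non-protected neurons.
    """
    if target_ratio < 1.0:
        raise InjuryError("mean area ratio cannot be below 1")
    mask = np.ones(len(injury.m), dtype=bool)
    if injury.protected:
        idx = {nm: i for i, nm in enumerate(injury.neuron_names)}
        mask[[idx[nm] for nm in injury.protected]] = False
    mean_m = float(injury.m[mask].mean()) if mask.any() else 0.0
    if mean_m <= 0:
        raise InjuryError("mean swelling is zero; amplitude undefined")
    return (target_ratio - 1.0) / mean_m


def injury_scale(injury: InjuryVector, mu: float) -> np.ndarray:
    """Per-neuron factor ``1 + mu * m_i`` (1 at mu=0 and on protected neurons)."""
    return injury.scale(mu)


# ---------------------------------------------------------------------------
# ensemble serialization


def write_injury_ensemble(
    path_matrix: str | Path,
    path_meta: str | Path,
    injuries: list[InjuryVector],
    distribution_id: str = "",
) -> None:
    """Rows = injuries, columns = neurons; JSON sidecar with seeds/protected set."""
    if not injuries:
        raise InjuryError("empty ensemble")
    names = injuries[0].neuron_names
    M = np.vstack([iv.m for iv in injuries])
    pd.DataFrame(M, columns=names).to_csv(path_matrix, index=False)
    meta = {
        "seeds": [iv.seed for iv in injuries],
        "protected": injuries[0].protected,
        "distribution_id": distribution_id,
    }
    Path(path_meta).write_text(json.dumps(meta, indent=1))


def read_injury_ensemble(path_matrix: str | Path, path_meta: str | Path) -> list[InjuryVector]:
    df = pd.read_csv(path_matrix)
    meta = json.loads(Path(path_meta).read_text())
    names = list(df.columns)
    out = []
    for k, row in enumerate(df.to_numpy()):
        seed = meta["seeds"][k] if k < len(meta.get("seeds", [])) else None
        out.append(InjuryVector(row, names, list(meta.get("protected", [])), seed=seed))
    return out
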