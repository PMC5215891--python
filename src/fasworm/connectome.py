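"""Connectome connectivity data: loading, validation, synthesis, conductances.

The wiring of the somatic nervous system is represented by two count
matrices over an ordered list of named neurons:

* ``Ng`` — gap-junction counts, symmetric (junctions are ohmic and
  undirected);
* ``Ns`` — chemical-synapse counts with the orientation convention
  ``Ns[i, j]`` = number of synapses from presynaptic neuron ``j`` onto
  postsynaptic neuron ``i``.  This matches the synaptic-current sum
  ``I_i = sum_j Gs[i, j] * s_j * (V_i - E_j)`` where ``s_j`` and the
  reversal potential ``E_j`` belong to the *sender*.

Each neuron carries an excitatory/inhibitory polarity (fixing its reversal
potential as a sender) and optionally an anatomical class label (e.g. the
forward-motion motorneuron classes DB, VB, DD, VD).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"

#: Frozen fixture constants for the built-in oscillator motif (see
#: :func:`oscillator_motif`).  Verified once, numerically, to yield a
#: sustained periodic orbit under constant input to the sensory pair.
OSCILLATOR_BETA = 1.0                 # mV^-1, steeper than the full-network default
OSCILLATOR_INPUT = 5.0                # arb. units, constant current per input neuron
OSCILLATOR_RING_COUNTS = (10, 12, 9)  # synapses per inhibitory ring edge (asymmetric)
OSCILLATOR_DRIVE_COUNTS = (5, 6, 4)   # synapses from each input onto each ring neuron


class ConnectomeError(ValueError):
    """Invalid connectivity data."""


@dataclass
class Connectome:
    """Validated connectivity tables over an ordered neuron universe."""

    neuron_names: list[str]
    Ng: np.ndarray
    Ns: np.ndarray
    polarity: np.ndarray          # per-neuron, EXCITATORY or INHIBITORY
    classes: np.ndarray | None = None
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.neuron_names = list(self.neuron_names)
        self.Ng = np.asarray(self.Ng, dtype=float)
        self.Ns = np.asarray(self.Ns, dtype=float)
        self.polarity = np.asarray(self.polarity, dtype=object)
        if self.classes is not None:
            self.classes = np.asarray(self.classes, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = self.n
        if len(set(self.neuron_names)) != n:
            raise ConnectomeError("duplicate neuron names")
        for name, M in (("Ng", self.Ng), ("Ns", self.Ns)):
            if M.shape != (n, n):
                raise ConnectomeError(f"{name} has shape {M.shape}, expected {(n, n)}")
            if np.any(M < 0):
                raise ConnectomeError(f"negative counts in {name}")
            if np.any(np.diag(M) != 0):
                raise ConnectomeError(f"nonzero diagonal in {name}")
        if not np.array_equal(self.Ng, self.Ng.T):
            raise ConnectomeError("gap-junction matrix Ng must be symmetric")
        if self.polarity.shape != (n,):
            raise ConnectomeError("polarity must be defined for every neuron")
        bad = set(self.polarity) - {EXCITATORY, INHIBITORY}
        if bad:
            raise ConnectomeError(f"unknown polarity labels: {sorted(bad)}")
        for gname, members in self.groups.items():
            unknown = set(members) - set(self.neuron_names)
            if unknown:
                raise ConnectomeError(
                    f"group {gname!r} references unknown neurons: {sorted(unknown)}"
                )

    # -- basic accessors ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.neuron_names)

    def index(self, names: str | list[str]) -> np.ndarray | int:
        lookup = {name: i for i, name in enumerate(self.neuron_names)}
        if isinstance(names, str):
            return lookup[names]
        return np.array([lookup[nm] for nm in names], dtype=int)

    def group(self, name: str) -> list[str]:
        try:
            return list(self.groups[name])
        except KeyError:
            raise ConnectomeError(f"no group named {name!r}") from None

    def reversal_potentials(self, e_exc: float, e_inh: float) -> np.ndarray:
        """Per-neuron reversal potential as a *sender*, set by polarity."""
        return np.where(self.polarity == INHIBITORY, e_inh, e_exc).astype(float)

    def subset(self, names: list[str]) -> "Connectome":
        """Restrict all tables to ``names`` (kept in the given order)."""
        idx = self.index(names)
        groups = {
            g: [m for m in members if m in set(names)]
            for g, members in self.groups.items()
        }
        return Connectome(
            neuron_names=list(names),
            Ng=self.Ng[np.ix_(idx, idx)],
            Ns=self.Ns[np.ix_(idx, idx)],
            polarity=self.polarity[idx],
            classes=None if self.classes is None else self.classes[idx],
            groups=groups,
        )

    # -- serialization ------------------------------------------------------
    def write_tables(self, directory: str | Path) -> None:
        """Write dense-matrix gap/synapse tables plus polarity and groups."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.Ng, index=self.neuron_names, columns=self.neuron_names).to_csv(
            d / "gap.csv"
        )
        pd.DataFrame(self.Ns, index=self.neuron_names, columns=self.neuron_names).to_csv(
            d / "syn.csv"
        )
        pol = pd.DataFrame(
            {
                "neuron": self.neuron_names,
                "polarity": self.polarity,
                "class": self.classes if self.classes is not None else "",
            }
        )
        pol.to_csv(d / "polarity.csv", index=False)
        (d / "groups.json").write_text(json.dumps(self.groups, indent=1))

    @classmethod
    def read_tables(cls, directory: str | Path) -> "Connectome":
        d = Path(directory)
        groups = json.loads((d / "groups.json").read_text()) if (d / "groups.json").exists() else {}
        return load_connectome(d / "gap.csv", d / "syn.csv", d / "polarity.csv", groups=groups)


@dataclass
class ConductanceSet:
    """Gap (``Gg``) and maximum synaptic (``Gs``) conductivities, pS."""

    Gg: np.ndarray
    Gs: np.ndarray


# ---------------------------------------------------------------------------
# loading


def _read_count_table(path: str | Path, names_hint: list[str] | None = None) -> pd.DataFrame:
    """Read a connectivity table in either edge-list or dense-matrix dialect.

    Edge-list dialect: header columns ``pre, post, count``.  Dense dialect:
    first column holds neuron names, header holds neuron names.  Returns a
    dense DataFrame indexed by postsynaptic (row) / presynaptic (column)
    neuron name.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    head = pd.read_csv(path, sep=sep, nrows=0)
    cols = [c.strip().lower() for c in head.columns]
    if {"pre", "post", "count"} <= set(cols):
        edges = pd.read_csv(path, sep=sep)
        edges.columns = [c.strip().lower() for c in edges.columns]
        names = names_hint
        if names is None:
            names = sorted(set(edges["pre"]) | set(edges["post"]))
        dense = pd.DataFrame(0.0, index=names, columns=names)
        for pre, post, count in edges[["pre", "post", "count"]].itertuples(index=False):
            if pre not in dense.index or post not in dense.index:
                raise ConnectomeError(f"edge references unknown neuron: {pre}->{post}")
            # rows are postsynaptic, columns presynaptic
            dense.loc[post, pre] += count
        return dense
    dense = pd.read_csv(path, sep=sep, index_col=0)
    dense.index = dense.index.astype(str)
    dense.columns = dense.columns.astype(str)
    return dense.astype(float)


def load_connectome(
    gap_table: str | Path,
    syn_table: str | Path,
    polarity_table: str | Path,
    groups: dict[str, list[str]] | None = None,
) -> Connectome:
    """Read gap/synapse/polarity tables and build a validated :class:`Connectome`.

    Both a ``pre, post, count`` edge-list dialect and a dense-matrix dialect
    (names in first row/column) are accepted.  Asymmetric gap tables are
    symmetrized by averaging reciprocal entries, with a logged warning.
    """
    pol = pd.read_csv(polarity_table)
    pol.columns = [c.strip().lower() for c in pol.columns]
    if "neuron" not in pol.columns or "polarity" not in pol.columns:
        raise ConnectomeError("polarity table must have columns: neuron, polarity[, class]")
    names = [str(x) for x in pol["neuron"]]

    gap = _read_count_table(gap_table, names_hint=names).reindex(index=names, columns=names).fillna(0.0)
    syn = _read_count_table(syn_table, names_hint=names).reindex(index=names, columns=names).fillna(0.0)

    Ng = gap.to_numpy()
    if np.any(Ng < 0) or np.any(syn.to_numpy() < 0):
        raise ConnectomeError("negative connection counts")
    if not np.array_equal(Ng, Ng.T):
        logger.warning(
            "gap-junction table is asymmetric; symmetrizing by averaging reciprocal entries"
        )
        Ng = (Ng + Ng.T) / 2.0
    np.fill_diagonal(Ng, 0.0)
    Ns = syn.to_numpy().copy()
    np.fill_diagonal(Ns, 0.0)

    classes = None
    if "class" in pol.columns:
        classes = pol["class"].fillna("").astype(str).to_numpy(dtype=object)
    return Connectome(
        neuron_names=names,
        Ng=Ng,
        Ns=Ns,
        polarity=pol["polarity"].astype(str).to_numpy(dtype=object),
        classes=classes,
        groups=dict(groups or {}),
    )


def filter_somatic(c: Connectome, pharyngeal: list[str] | None = None) -> Connectome:
    """Drop pharyngeal neurons and neurons making no synaptic connections.

    A neuron is dropped when both its row and column sums of ``Ns`` are zero
    (it neither receives nor makes chemical synapses).  The drop is iterated
    to a fixed point, since removing one neuron can orphan another; the
    operation is therefore idempotent.
    """
    pharyngeal = set(pharyngeal or [])
    unknown = pharyngeal - set(c.neuron_names)
    if unknown:
        raise ConnectomeError(f"pharyngeal list references unknown neurons: {sorted(unknown)}")
    keep = [nm for nm in c.neuron_names if nm not in pharyngeal]
    out = c.subset(keep) if len(keep) < c.n else c
    while True:
        connected = (out.Ns.sum(axis=0) + out.Ns.sum(axis=1)) > 0
        if connected.all():
            return out
        keep = [nm for nm, ok in zip(out.neuron_names, connected) if ok]
        out = out.subset(keep)


def build_conductances(c: Connectome, g: float) -> ConductanceSet:
    """Assign every individual synapse and gap junction an equal conductivity.

    ``Gg = g * Ng`` and ``Gs = g * Ns`` elementwise (pS).
    """
    if g <= 0:
        raise ConnectomeError(f"conductivity must be positive, got {g}")
    return ConductanceSet(Gg=g * c.Ng, Gs=g * c.Ns)


# ---------------------------------------------------------------------------
# synthetic networks


def synthetic_connectome(
    n: int,
    density: float,
    inhibitory_fraction: float = 0.3,
    seed: int = 0,
) -> Connectome:
    """Random connectome fixture: directed synapses + symmetric gap junctions.

    Deterministic under ``seed``.  The first two neurons form the ``input``
    group; the trailing third (at least two neurons) form the ``motor`` group.
    """
    if n < 2:
        raise ConnectomeError("need at least two neurons")
    if not 0.0 <= density <= 1.0:
        raise ConnectomeError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"N{i:03d}" for i in range(n)]
    Ns = np.where(rng.random((n, n)) < density, rng.integers(1, 5, size=(n, n)), 0).astype(float)
    np.fill_diagonal(Ns, 0.0)
    upper = np.triu(np.where(rng.random((n, n)) < density, rng.integers(1, 4, size=(n, n)), 0), 1)
    Ng = (upper + upper.T).astype(float)
    polarity = np.where(rng.random(n) < inhibitory_fraction, INHIBITORY, EXCITATORY).astype(object)
    n_motor = max(2, n // 3)
    groups = {"input": names[:2], "motor": names[-n_motor:]}
    return Connectome(names, Ng, Ns, polarity, classes=None, groups=groups)


def oscillator_motif() -> Connectome:
    """Hand-crafted 5-neuron network with a verified periodic orbit.

    Two excitatory sensory neurons (gap-coupled, the ``input`` group —
    analogous to the stimulated PLM pair) drive a 3-neuron inhibitory ring
    (the ``motor`` group, whose voltages define the response plane for this
    fixture).  Under constant input :data:`OSCILLATOR_INPUT` to the sensory
    pair and sigmoid width :data:`OSCILLATOR_BETA`, the ring sustains a limit
    cycle with period ~0.7 s and ~10 mV amplitude; distributed injury of the
    ring collapses it to a stable fixed point (mu* of order 20 for typical
    random injuries).  All counts are frozen constants — tests depend on the
    recorded behavior, not a hoped-for one.
    """
    names = ["SENL", "SENR", "OSC1", "OSC2", "OSC3"]
    n = 5
    Ns = np.zeros((n, n))
    # inhibitory ring OSC1 -> OSC2 -> OSC3 -> OSC1 (Ns[post, pre]); counts are
    # deliberately unequal so no rotation-symmetric subspace is invariant and
    # the oscillation self-starts from the exact resting state
    Ns[3, 2], Ns[4, 3], Ns[2, 4] = OSCILLATOR_RING_COUNTS
    for post, cnt in zip((2, 3, 4), OSCILLATOR_DRIVE_COUNTS):
        Ns[post, 0] = cnt
        Ns[post, 1] = cnt
    Ng = np.zeros((n, n))
    Ng[0, 1] = Ng[1, 0] = 2.0
    polarity = np.array(
        [EXCITATORY, EXCITATORY, INHIBITORY, INHIBITORY, INHIBITORY], dtype=object
    )
    classes = np.array(["sensory", "sensory", "inter", "inter", "inter"], dtype=object)
    groups = {"input": ["SENL", "SENR"], "motor": ["OSC1", "OSC2", "OSC3"]}
    return Connectome(names, Ng, Ns, polarity, classes=classes, groups=groups)
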