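"""Single-compartment membrane dynamics on a connectome, forward Euler.

Each neuron ``i`` is a passive isopotential unit:

    C dV_i/dt = -Gc (V_i - E_cell) - (I_gap_i + I_syn_i) / (1 + mu m_i) + I_ext_i

with ohmic gap junctions ``I_gap_i = sum_j Gg_ij (V_i - V_j)`` and graded
chemical synapses ``I_syn_i = sum_j Gs_ij s_j (V_i - E_j)`` whose activation
obeys

    ds_i/dt = a_r phi(V_i) (1 - s_i) - a_d s_i,
    phi(v) = 1 / (1 + exp(-beta (v - V_th_i))).

The per-neuron factor ``1 + mu m_i`` models focal axonal swelling: membrane
area growth scales capacitance and leak conductance together, which is
algebraically equivalent to dividing the coupling currents by the swelling
factor.  ``mu = 0`` (or an uninjured neuron, ``m_i = 0``) recovers the healthy
equation exactly — the division by 1.0 is bitwise exact.

Units follow the model's convention: mV, pS, pF, s; currents are then in
pS*mV "arbitrary units".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome, ConductanceSet, build_conductances

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


class SimulationError(RuntimeError):
    """Numerical failure (divergence or non-finite state) during integration."""


@dataclass
class ModelParams:
    """Membrane and synapse parameters.

    Defaults are the full-network values: C = 1 pF, Gc = 10 pS,
    E_cell = -35 mV, g = 100 pS per connection, E_exc = 0 mV, E_inh = -45 mV,
    beta = 0.125 mV^-1, a_r = 1 s^-1, a_d = 5 s^-1, dt = 1e-4 s.  ``V_th`` is
    not part of the published parameter set; when left ``None`` it is derived
    from the zero-input resting equilibrium (see :func:`resting_state`).
    """

    C: float = 1.0            # pF
    Gc: float = 10.0          # pS
    E_cell: float = -35.0     # mV
    g: float = 100.0          # pS per synapse / gap junction
    E_exc: float = 0.0        # mV
    E_inh: float = -45.0      # mV
    beta: float = 0.125       # mV^-1
    V_th: np.ndarray | float | None = None   # mV, per-neuron or scalar
    a_r: float = 1.0          # s^-1
    a_d: float = 5.0          # s^-1
    dt: float = 1e-4          # s

    def __post_init__(self) -> None:
        for name in ("C", "Gc", "g", "a_r", "a_d", "dt", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def v_th_array(self, n: int) -> np.ndarray:
        if self.V_th is None:
            raise ValueError("V_th unset; call resting_state first or provide it")
        return np.broadcast_to(np.asarray(self.V_th, dtype=float), (n,)).copy()


@dataclass
class NetworkState:
    """Instantaneous state: membrane voltages (mV), synaptic activities, time."""

    V: np.ndarray
    s: np.ndarray
    t: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(self.V.copy(), self.s.copy(), self.t)


@dataclass
class Trajectory:
    """Decimated voltage recording of a named neuron subset."""

    times: np.ndarray
    V: np.ndarray                 # (n_samples, n_recorded)
    names: list[str]
    sample_stride: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.V.shape != (self.times.size, len(self.names)):
            raise ValueError("V shape inconsistent with times/names")

    @property
    def dt_sample(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.V, columns=self.names)
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df.drop(columns="time").to_numpy(), list(df.columns[1:]))

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("V", data=self.V)
            f.attrs["names"] = ",".join(self.names)
            f.attrs["sample_stride"] = self.sample_stride

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                f["times"][:],
                f["V"][:],
                f.attrs["names"].split(","),
                int(f.attrs["sample_stride"]),
            )


# ---------------------------------------------------------------------------
# elementary pieces


def sigmoid_activation(v, beta: float, v_th) -> np.ndarray:
    """phi(v) = 1/(1 + exp(-beta (v - v_th))), overflow-guarded."""
    x = np.clip(beta * (np.asarray(v, dtype=float) - v_th), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(-x))


def synaptic_equilibrium(phi, a_r: float, a_d: float) -> np.ndarray:
    """The ds/dt = 0 activation level: a_r phi / (a_r phi + a_d)."""
    phi = np.asarray(phi, dtype=float)
    return a_r * phi / (a_r * phi + a_d)


def membrane_currents(
    state: NetworkState,
    cond: ConductanceSet,
    params: ModelParams,
    erev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Gap and synaptic input currents (pS*mV) for every neuron.

    ``erev`` is the per-neuron reversal potential as a *sender* (set by its
    excitatory/inhibitory polarity).
    """
    V, s = state.V, state.s
    I_gap = cond.Gg.sum(axis=1) * V - cond.Gg @ V
    I_syn = (cond.Gs * (V[:, None] - erev[None, :])) @ s
    return I_gap, I_syn


def euler_step(
    state: NetworkState,
    cond: ConductanceSet,
    params: ModelParams,
    erev: np.ndarray,
    injury_scale: np.ndarray | None = None,
    I_ext: np.ndarray | None = None,
) -> NetworkState:
    """One explicit Euler step of the (possibly injured) governing equations.

    With ``injury_scale`` identically 1 this reduces exactly to the healthy
    equations.  Synaptic activities are clipped to [0, 1] after the step to
    guard explicit-integration overshoot.
    """
    n = state.V.size
    if not np.all(np.isfinite(state.V)) or not np.all(np.isfinite(state.s)):
        bad = int(np.argmax(~(np.isfinite(state.V) & np.isfinite(state.s))))
        raise SimulationError(f"non-finite state at neuron index {bad} (t={state.t})")
    scale = np.ones(n) if injury_scale is None else np.asarray(injury_scale, dtype=float)
    ext = np.zeros(n) if I_ext is None else np.asarray(I_ext, dtype=float)
    I_gap, I_syn = membrane_currents(state, cond, params, erev)
    v_th = params.v_th_array(n)
    dV = (-params.Gc * (state.V - params.E_cell) - (I_gap + I_syn) / scale + ext) * (
        params.dt / params.C
    )
    phi = sigmoid_activation(state.V, params.beta, v_th)
    ds = (params.a_r * phi * (1.0 - state.s) - params.a_d * state.s) * params.dt
    return NetworkState(
        V=state.V + dV,
        s=np.clip(state.s + ds, 0.0, 1.0),
        t=state.t + params.dt,
    )


# ---------------------------------------------------------------------------
# fast integration kernel


@njit(cache=True)
def _euler_kernel(
    V, s, Gg, Gs, erev, scale, Iext, Vth,
    C, Gc, Ecell, beta, ar, ad, dt,
    nsteps, stride, rec_idx, out, v_bound,
):  # pragma: no cover - compiled
    n = V.shape[0]
    r = 0
    newV = np.empty(n)
    for step in range(nsteps):
        if step % stride == 0:
            for k in range(rec_idx.shape[0]):
                out[r, k] = V[rec_idx[k]]
            r += 1
        for i in range(n):
            ig = 0.0
            isyn = 0.0
            for j in range(n):
                ig += Gg[i, j] * (V[i] - V[j])
                isyn += Gs[i, j] * s[j] * (V[i] - erev[j])
            newV[i] = V[i] + (-Gc * (V[i] - Ecell) - (ig + isyn) / scale[i] + Iext[i]) * dt / C
        for i in range(n):
            x = beta * (V[i] - Vth[i])
            if x > 500.0:
                x = 500.0
            elif x < -500.0:
                x = -500.0
            phi = 1.0 / (1.0 + np.exp(-x))
            si = s[i] + (ar * phi * (1.0 - s[i]) - ad * s[i]) * dt
            if si < 0.0:
                si = 0.0
            elif si > 1.0:
                si = 1.0
            s[i] = si
            V[i] = newV[i]
            if not np.isfinite(V[i]) or abs(V[i]) > v_bound:
                return step
    return -1


def simulate(
    c: Connectome,
    params: ModelParams,
    injury=None,
    I_ext: dict[str, float] | np.ndarray | None = None,
    T: float = 10.0,
    record: list[str] | None = None,
    stride: int = 100,
    initial: NetworkState | None = None,
    v_bound: float = 1e6,
    return_final: bool = False,
):
    """Integrate the network for ``T`` seconds, recording decimated snapshots.

    Parameters
    ----------
    injury : InjuryVector or None
        When given, couples through the per-neuron factor ``1 + mu m_i``.
    I_ext : dict or array
        Constant external currents, either named (e.g. the stimulated input
        pair) or as a full per-neuron array.
    record : list of neuron names
        Subset to record; defaults to all neurons.
    initial : NetworkState
        Starting state; defaults to the self-consistent resting state.
    return_final : bool
        Also return the final :class:`NetworkState` (for continuation).
    """
    if T <= 0:
        raise ValueError("duration T must be positive")
    cond = build_conductances(c, params.g)
    erev = c.reversal_potentials(params.E_exc, params.E_inh)
    n = c.n

    if params.V_th is None:
        rest, vth = resting_state(c, params)
        params = replace(params, V_th=vth)
        if initial is None:
            initial = rest
    elif initial is None:
        initial, _ = resting_state(c, params)
    vth = params.v_th_array(n)

    ext = np.zeros(n)
    if I_ext is not None:
        if isinstance(I_ext, dict):
            for name, val in I_ext.items():
                ext[c.index(name)] = val
        else:
            ext[:] = np.asarray(I_ext, dtype=float)

    scale = np.ones(n)
    if injury is not None:
        scale = injury.scale()

    rec_names = list(record) if record is not None else list(c.neuron_names)
    rec_idx = np.asarray(c.index(rec_names), dtype=np.int64).reshape(-1)

    nsteps = int(round(T / params.dt))
    n_rec = (nsteps + stride - 1) // stride
    out = np.empty((n_rec, rec_idx.size))
    V = initial.V.astype(float).copy()
    s = initial.s.astype(float).copy()
    bad_step = _euler_kernel(
        V, s, cond.Gg, cond.Gs, erev, scale, ext, vth,
        params.C, params.Gc, params.E_cell, params.beta, params.a_r, params.a_d,
        params.dt, nsteps, stride, rec_idx, out, v_bound,
    )
    if bad_step >= 0:
        raise SimulationError(
            f"voltage diverged (|V| > {v_bound:g}) at t={initial.t + bad_step * params.dt:.4f} s"
        )
    times = initial.t + params.dt * stride * np.arange(n_rec)
    traj = Trajectory(times, out, rec_names, sample_stride=stride)
    if return_final:
        return traj, NetworkState(V, s, initial.t + nsteps * params.dt)
    return traj


# ---------------------------------------------------------------------------
# resting state


def resting_state(
    c: Connectome,
    params: ModelParams,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> tuple[NetworkState, np.ndarray]:
    """Zero-input fixed point of the network, and the thresholds making it so.

    With ``params.V_th`` unset, the threshold of each neuron is placed at its
    own equilibrium voltage, making rest exactly self-consistent: every
    sigmoid sits at 1/2, all activations at ``a_r/2 / (a_r/2 + a_d)``, and the
    voltage balance is a single linear solve.  With thresholds supplied, the
    fixed point is found by alternating the activation equilibrium and the
    linear voltage balance until the update falls below ``tol``.

    Returns ``(state, V_th)``.
    """
    cond = build_conductances(c, params.g)
    erev = c.reversal_potentials(params.E_exc, params.E_inh)
    n = c.n
    gap_deg = cond.Gg.sum(axis=1)

    def solve_voltage(s: np.ndarray) -> np.ndarray:
        A = np.diag(params.Gc + gap_deg + cond.Gs @ s) - cond.Gg
        b = params.Gc * params.E_cell + cond.Gs @ (s * erev)
        return np.linalg.solve(A, b)

    if params.V_th is None:
        s_eq = np.full(n, synaptic_equilibrium(0.5, params.a_r, params.a_d))
        V = solve_voltage(s_eq)
        return NetworkState(V=V, s=s_eq, t=0.0), V.copy()

    vth = params.v_th_array(n)
    V = np.full(n, params.E_cell)
    for _ in range(max_iter):
        s = synaptic_equilibrium(sigmoid_activation(V, params.beta, vth), params.a_r, params.a_d)
        V_new = solve_voltage(s)
        if np.max(np.abs(V_new - V)) < tol:
            return NetworkState(V=V_new, s=s, t=0.0), vth
        V = V_new
    resid = float(np.max(np.abs(V_new - V)))
    raise SimulationError(f"resting state failed to converge (residual {resid:.3g} mV)")
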