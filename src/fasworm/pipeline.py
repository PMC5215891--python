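"""End-to-end study orchestration: ensembles, deficit curves, classification.

The full experiment, per injury drawn from the swelling distribution:

1. compute the healthy resting state, response plane, cycle shape and
   frequency (once);
2. bisect for the collapse amplitude mu*, recording the paralysis endpoint;
3. sample 15 amplitudes below mu* (5 across (0, 0.9 mu*), 10 across
   (0.9 mu*, mu*)) and build the PD / scaling / translation / frequency
   profile;
4. split the endpoint cloud into upper/lower classes and fit classification
   trees predicting the class from the injury vector and from the
   normalized PD-curve shape, with k-fold cross-validation and
   shuffled-label baselines.

Every stage is a pure function of (inputs, config, seed); per-injury
artifacts are checkpointed under the output directory keyed by a config
hash, so interrupted ensembles resume bit-identically and injuries may be
computed in any order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import attractor as att
from .attractor import FIXED_POINT, PERIODIC, AttractorResult, AttractorUndetermined, MuProfile
from .connectome import Connectome
from .dynamics import ModelParams, SimulationError, Trajectory, resting_state, simulate
from .injury import (
    InjuryVector,
    SwellingDistribution,
    distribution_from_histogram,
    sample_injury,
    synthetic_swelling_distribution,
)
from .neural_modes import NeuralPlane, PlaneTrajectory, compute_plane, energy_fraction, project
from .outcome_classification import (
    DEFAULT_MIN_LEAF,
    EndpointSet,
    fit_tree,
    implicated_features,
    kfold_cv_error,
    pd_curve_features,
    shuffled_baseline,
    split_endpoints,
)
from .shape_analysis import PDCurve, Shape, normalize_and_average, pd_curve, shape_from_trajectory

logger = logging.getLogger(__name__)


@dataclass
class EnsembleConfig:
    """Run configuration; serializable to/from YAML or JSON."""

    connectome: str = "oscillator"   # "oscillator" or a directory of tables
    histogram: str | None = None     # swelling histogram CSV; None -> synthetic stand-in
    K: int = 3                       # ensemble size (number of injuries)
    seed: int = 0
    out_dir: str | None = None

    input_current: float | None = None   # None -> 2e4 for loaded nets, motif constant otherwise
    input_group: str = "input"
    record_group: str = "motor"
    stride: int = 100                # recording decimation (1 ms at dt = 1e-4)
    transient: float = 5.0           # s discarded before analysis
    plane_duration: float = 20.0     # s of post-transient snapshots for the SVD plane
    classify_duration: float = 15.0  # s simulated before the first convergence check
    max_time: float = 60.0           # s cap per classification
    radius: float = 0.01             # convergence disc radius (plane units)
    rel_tol: float = 1e-3            # relative mu* bracket tolerance

    n_shape_points: int = 200
    min_leaf: int | None = None      # None -> 40, shrunk for small ensembles
    folds: int = 10
    shuffle_trials: int = 100
    feature_grid: int = 25
    threshold: float = -0.01

    def resolved_min_leaf(self) -> int:
        if self.min_leaf is not None:
            return self.min_leaf
        return DEFAULT_MIN_LEAF if self.K >= 10 * DEFAULT_MIN_LEAF // 2 else max(1, self.K // 10)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_config(path: str | Path) -> EnsembleConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    known = {f.name for f in dataclasses.fields(EnsembleConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return EnsembleConfig(**data)


def write_config(cfg: EnsembleConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))


def child_seed(master: int, k: int) -> int:
    """Counter-based per-injury seed: stable when K changes."""
    return int(np.random.SeedSequence((master, k)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# setup


def build_setup(cfg: EnsembleConfig) -> tuple[Connectome, ModelParams, dict[str, float]]:
    """Connectome, parameters, and constant input currents for a config."""
    if cfg.connectome == "oscillator":
        from .fixtures import oscillator_setup

        c, params, I_ext = oscillator_setup()
        if cfg.input_current is not None:
            I_ext = {k: cfg.input_current for k in I_ext}
        return c, params, I_ext
    c = Connectome.read_tables(cfg.connectome)
    params = ModelParams()
    amp = cfg.input_current if cfg.input_current is not None else 2.0e4
    I_ext = {name: amp for name in c.group(cfg.input_group)}
    return c, params, I_ext


def load_distribution(cfg: EnsembleConfig) -> SwellingDistribution:
    if cfg.histogram is None:
        return synthetic_swelling_distribution()
    return distribution_from_histogram(cfg.histogram)


# ---------------------------------------------------------------------------
# per-injury dynamics


class _Continuation:
    """Chunked simulation that accumulates a uniformly sampled projection."""

    def __init__(self, c, params, I_ext, injury, plane, cfg: EnsembleConfig, initial):
        self.c, self.params, self.I_ext = c, params, I_ext
        self.injury, self.plane, self.cfg = injury, plane, cfg
        self.state = initial.copy()
        self.times: list[np.ndarray] = []
        self.xy: list[np.ndarray] = []

    def _round_chunk(self, T: float) -> float:
        quantum = self.cfg.stride * self.params.dt
        return max(quantum, round(T / quantum) * quantum)

    def extend(self, additional: float) -> PlaneTrajectory:
        T = self._round_chunk(additional)
        traj, self.state = simulate(
            self.c, self.params, injury=self.injury, I_ext=self.I_ext, T=T,
            record=self.plane.subset, stride=self.cfg.stride,
            initial=self.state, return_final=True,
        )
        pt = project(traj, self.plane)
        self.times.append(pt.times)
        self.xy.append(pt.xy)
        return self.trajectory()

    def trajectory(self) -> PlaneTrajectory:
        return PlaneTrajectory(np.concatenate(self.times), np.vstack(self.xy))


def classify_at_mu(
    c: Connectome,
    params: ModelParams,
    I_ext: dict[str, float],
    injury: InjuryVector | None,
    mu: float,
    plane: NeuralPlane,
    cfg: EnsembleConfig,
    initial,
) -> tuple[AttractorResult, PlaneTrajectory]:
    """Simulate at amplitude ``mu`` until the attractor criteria resolve.

    An undetermined classification at the simulation cap is conservatively
    read as a fixed point (slow sub-threshold transients near collapse),
    with the trailing-window mean as endpoint; this is logged.
    """
    iv = injury.with_mu(mu) if injury is not None else None
    cont = _Continuation(c, params, I_ext, iv, plane, cfg, initial)
    pt = cont.extend(cfg.classify_duration)
    try:
        res = att.classify_attractor(
            pt,
            transient=cfg.transient,
            radius=cfg.radius,
            extend=cont.extend,
            max_time=cfg.max_time,
        )
    except AttractorUndetermined as exc:
        pt = cont.trajectory()
        tail = pt.after(pt.times[-1] - 5.0)
        logger.warning("undetermined at mu=%.4g (%s); treating as fixed point", mu, exc)
        res = AttractorResult(FIXED_POINT, endpoint=tail.xy.mean(axis=0))
    return res, cont.trajectory()


def find_mu_star_dynamics(
    c: Connectome,
    params: ModelParams,
    I_ext: dict[str, float],
    injury: InjuryVector,
    plane: NeuralPlane,
    cfg: EnsembleConfig,
    initial,
) -> MuProfile:
    """Bisect the collapse amplitude for one injury on the live dynamics."""

    def classify(mu: float) -> AttractorResult:
        res, _ = classify_at_mu(c, params, I_ext, injury, mu, plane, cfg, initial)
        return res

    return att.find_mu_star(classify, rel_tol=cfg.rel_tol)


# ---------------------------------------------------------------------------
# ensemble run


@dataclass
class InjuryOutcome:
    index: int
    seed: int
    injury: InjuryVector
    mu_star: float
    endpoint: np.ndarray
    curve: PDCurve


@dataclass
class EnsembleRun:
    config: EnsembleConfig
    connectome: Connectome
    plane: NeuralPlane
    healthy_shape: Shape
    healthy_frequency: float
    outcomes: list[InjuryOutcome]
    endpoint_set: EndpointSet | None = None
    labels: np.ndarray | None = None
    classifier_report: dict = field(default_factory=dict)

    @property
    def injury_matrix(self) -> np.ndarray:
        return np.vstack([o.injury.m for o in self.outcomes])


def healthy_baseline(cfg: EnsembleConfig):
    """Stage 1: resting state, healthy plane, cycle shape and frequency."""
    c, params, I_ext = build_setup(cfg)
    rest, vth = resting_state(c, params)
    params = replace(params, V_th=vth)
    record = c.group(cfg.record_group)
    T = cfg.transient + cfg.plane_duration
    traj = simulate(c, params, I_ext=I_ext, T=T, record=record,
                    stride=cfg.stride, initial=rest)
    plane = compute_plane(traj, transient=cfg.transient)
    pt = project(traj, plane)
    healthy_res = att.classify_attractor(pt, transient=cfg.transient, radius=cfg.radius)
    if healthy_res.kind != PERIODIC:
        raise SimulationError("healthy dynamics did not classify periodic")
    shape = shape_from_trajectory(pt, transient=cfg.transient, N=cfg.n_shape_points)
    freq = att.cycle_frequency(pt, transient=cfg.transient)
    return c, params, I_ext, rest, plane, shape, freq


def _checkpoint_path(cfg: EnsembleConfig, k: int) -> Path | None:
    if cfg.out_dir is None:
        return None
    d = Path(cfg.out_dir) / "checkpoints"
    d.mkdir(parents=True, exist_ok=True)
    return d / f"injury_{k:05d}.json"


def _save_outcome(path: Path, cfg_hash: str, out: InjuryOutcome) -> None:
    payload = {
        "config_hash": cfg_hash,
        "index": out.index,
        "seed": out.seed,
        "m": out.injury.m.tolist(),
        "neuron_names": out.injury.neuron_names,
        "protected": out.injury.protected,
        "mu_star": out.mu_star,
        "endpoint": np.asarray(out.endpoint).tolist(),
        "curve": {
            "mu": out.curve.mu_values.tolist(),
            "pd": out.curve.pd_values.tolist(),
            "scaling": out.curve.scaling_values.tolist(),
            "translation": out.curve.translation_values.tolist(),
            "frequency": out.curve.frequency_values.tolist(),
            "gaps": out.curve.gaps,
        },
    }
    path.write_text(json.dumps(payload))


def _load_outcome(path: Path, cfg_hash: str) -> InjuryOutcome | None:
    if not path.exists():
        return None
    data = json.loads(path.read_text())
    if data.get("config_hash") != cfg_hash:
        return None
    iv = InjuryVector(np.array(data["m"]), data["neuron_names"], data["protected"], seed=data["seed"])
    curve = PDCurve(
        data["curve"]["mu"], data["curve"]["pd"], data["curve"]["scaling"],
        data["curve"]["translation"], data["curve"]["frequency"],
        mu_star=data["mu_star"], gaps=list(data["curve"]["gaps"]),
    )
    return InjuryOutcome(
        data["index"], data["seed"], iv, data["mu_star"], np.array(data["endpoint"]), curve
    )


def run_injury(
    k: int,
    cfg: EnsembleConfig,
    c: Connectome,
    params: ModelParams,
    I_ext: dict[str, float],
    rest,
    plane: NeuralPlane,
    healthy_shape: Shape,
    healthy_freq: float,
    dist: SwellingDistribution,
) -> InjuryOutcome:
    """Stage 2+3 for one injury: mu* bisection, schedule, deficit curve."""
    seed = child_seed(cfg.seed, k)
    injury = sample_injury(dist, c, seed=seed)
    profile = find_mu_star_dynamics(c, params, I_ext, injury, plane, cfg, rest)
    schedule = att.mu_schedule(profile.mu_star)

    def traj_at(mu: float) -> PlaneTrajectory | None:
        res, pt = classify_at_mu(c, params, I_ext, injury, mu, plane, cfg, rest)
        return pt if res.kind == PERIODIC else None

    curve = pd_curve(
        traj_at, schedule, healthy_shape, profile.mu_star,
        transient=cfg.transient, N=cfg.n_shape_points, healthy_frequency=healthy_freq,
    )
    return InjuryOutcome(k, seed, injury, profile.mu_star, profile.endpoint, curve)


def run_ensemble(cfg: EnsembleConfig) -> EnsembleRun:
    """Execute the full study for ``cfg.K`` injuries (resumable)."""
    c, params, I_ext, rest, plane, healthy_shape, healthy_freq = healthy_baseline(cfg)
    dist = load_distribution(cfg)
    cfg_hash = cfg.hash()
    outcomes: list[InjuryOutcome] = []
    for k in range(cfg.K):
        ckpt = _checkpoint_path(cfg, k)
        out = _load_outcome(ckpt, cfg_hash) if ckpt else None
        if out is None:
            try:
                out = run_injury(
                    k, cfg, c, params, I_ext, rest, plane, healthy_shape, healthy_freq, dist
                )
            except (SimulationError, ValueError) as exc:
                logger.error("injury %d failed: %s", k, exc)
                continue
            if ckpt:
                _save_outcome(ckpt, cfg_hash, out)
        outcomes.append(out)
    run = EnsembleRun(
        config=cfg, connectome=c, plane=plane, healthy_shape=healthy_shape,
        healthy_frequency=healthy_freq, outcomes=outcomes,
    )
    classify_outcomes(run)
    return run


def classify_outcomes(run: EnsembleRun) -> None:
    """Stage 4: endpoint split, trees, cross-validation, baselines."""
    cfg = run.config
    if len(run.outcomes) < 2:
        run.classifier_report = {"notice": "fewer than 2 endpoints; classification skipped"}
        return
    endpoints = np.vstack([o.endpoint for o in run.outcomes])
    run.endpoint_set = split_endpoints(endpoints, threshold=cfg.threshold)
    run.labels = run.endpoint_set.labels
    report: dict = {
        "upper_fraction": run.endpoint_set.upper_fraction,
        "n": len(run.outcomes),
    }
    n = len(run.outcomes)
    if n >= cfg.folds and len(set(run.labels.tolist())) > 1:
        min_leaf = cfg.resolved_min_leaf()
        X_inj = run.injury_matrix
        X_pd = np.vstack(
            [pd_curve_features(o.curve, grid_size=cfg.feature_grid) for o in run.outcomes]
        )
        for name, X, feat_names in (
            ("injury", X_inj, run.connectome.neuron_names),
            ("pd_curve", X_pd, [f"g{i}" for i in range(X_pd.shape[1])]),
        ):
            tree = fit_tree(X, run.labels, min_leaf=min_leaf)
            cv = kfold_cv_error(X, run.labels, min_leaf=min_leaf, folds=cfg.folds, seed=cfg.seed)
            base_mean, base_std = shuffled_baseline(
                X, run.labels, min_leaf=min_leaf, trials=cfg.shuffle_trials,
                folds=cfg.folds, seed=cfg.seed,
            )
            report[name] = {
                "cv_error": cv,
                "baseline_mean": base_mean,
                "baseline_std": base_std,
                "implicated": implicated_features(tree, feat_names),
                "min_leaf": min_leaf,
            }
    else:
        report["notice"] = "ensemble too small or single-class; tree stage skipped"
    run.classifier_report = report


# ---------------------------------------------------------------------------
# reporting


def frequency_reduction(run: EnsembleRun) -> float:
    """Mean fractional slowing of the cycle in the highly injured regime.

    For each injury, the frequencies at schedule samples with
    mu in (0.9 mu*, mu*) are compared to the healthy frequency; the statistic
    is the mean over injuries of the mean over those samples of
    ``1 - f(mu)/f(0)``.  Returns 0 for an ensemble with no such samples.
    """
    per_injury = []
    f0 = run.healthy_frequency
    for o in run.outcomes:
        mask = o.curve.mu_values > 0.9 * o.mu_star
        vals = o.curve.frequency_values[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            per_injury.append(float(np.mean(1.0 - vals / f0)))
    return float(np.mean(per_injury)) if per_injury else 0.0


def report(run: EnsembleRun) -> dict:
    """Summary document: class fractions, averaged class curves, CV errors,
    implicated neurons, and the high-injury frequency-reduction statistic."""
    out: dict = {
        "config_hash": run.config.hash(),
        "seed": run.config.seed,
        "n_injuries": len(run.outcomes),
        "healthy_frequency_hz": run.healthy_frequency,
        "two_mode_energy_fraction": energy_fraction(run.plane, 2),
        "mu_star": [o.mu_star for o in run.outcomes],
        "frequency_reduction": frequency_reduction(run),
        "classification": run.classifier_report,
    }
    if run.labels is not None:
        curves_by_class: dict = {}
        for cls in (label for label in ("upper", "lower")):
            curves = [o.curve for o, lab in zip(run.outcomes, run.labels) if lab == cls]
            if not curves:
                curves_by_class[cls] = {"notice": "no injuries in this class"}
                continue
            entry = {}
            for which in ("pd", "scaling", "translation"):
                grid, mean, std = normalize_and_average(curves, which=which)
                entry[which] = {"grid": grid.tolist(), "mean": mean.tolist(), "std": std.tolist()}
            curves_by_class[cls] = entry
        out["class_average_curves"] = curves_by_class
    if run.config.out_dir is not None:
        d = Path(run.config.out_dir)
        d.mkdir(parents=True, exist_ok=True)
        (d / "report.json").write_text(json.dumps(out, indent=1, default=float))
        rollup = {
            "index": [o.index for o in run.outcomes],
            "seed": [o.seed for o in run.outcomes],
            "mu_star": [o.mu_star for o in run.outcomes],
            "endpoint_x": [float(o.endpoint[0]) for o in run.outcomes],
            "endpoint_y": [float(o.endpoint[1]) for o in run.outcomes],
        }
        if run.labels is not None:
            rollup["label"] = run.labels.tolist()
        import pandas as pd

        pd.DataFrame(rollup).to_csv(d / "ensemble.csv", index=False)
    return out


# ---------------------------------------------------------------------------
# planted-structure analog (classification stages without dynamics)


def run_planted_classification(
    K: int = 50,
    n: int = 12,
    noise: float = 0.0,
    seed: int = 0,
    min_leaf: int | None = None,
    folds: int = 10,
    trials: int = 100,
) -> dict:
    """Scaled-down analog of the study's classification stage.

    Generates a planted-structure injury ensemble (labels carried by two
    driver neurons plus label noise), fits the injury-features tree, and
    compares its CV error with the shuffled-label baseline.
    """
    from .fixtures import PlantedEnsembleSpec, planted_ensemble

    spec = PlantedEnsembleSpec(K=K, n=n, noise=noise, seed=seed)
    X, y = planted_ensemble(spec)
    if min_leaf is None:
        min_leaf = max(1, K // 10)
    cv = kfold_cv_error(X, y, min_leaf=min_leaf, folds=folds, seed=seed)
    base_mean, base_std = shuffled_baseline(
        X, y, min_leaf=min_leaf, trials=trials, folds=folds, seed=seed
    )
    tree = fit_tree(X, y, min_leaf=min_leaf)
    return {
        "K": K,
        "noise": noise,
        "min_leaf": min_leaf,
        "cv_error": cv,
        "baseline_mean": base_mean,
        "baseline_std": base_std,
        "separation_sigmas": (base_mean - cv) / base_std if base_std > 0 else float("inf"),
        "implicated": implicated_features(tree, [f"N{i:03d}" for i in range(n)]),
        "drivers": [f"N{i:03d}" for i in spec.drivers],
    }
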