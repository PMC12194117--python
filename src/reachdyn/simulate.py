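"""Synthetic center-out reaching sessions with parameterized block effects.

The generator emulates the structure of a multi-session center-out reaching
study in an arm-supporting exoskeleton: 4 subjects, sessions split into 3-4
sub-sessions, each holding a block of ~80 control trials followed by ~50
trials under reversible cerebellar block, 8 evenly spaced peripheral targets
4-5 cm from a central start position, kinematics sampled at 1 kHz.

Reaches follow a minimum-jerk hand path from center to target.  Condition
effects are imposed *kinematically*, so injected effect sizes are exact by
construction:

* velocity deficit — the trial is uniformly time-dilated, scaling peak hand
  speed by exactly the velocity factor;
* trial-sequence adaptation — the deficit for high-coupling targets grows
  with the within-block presentation rank of that target group,
  ``deficit + extra * (1 - exp(-(rank-1)/tau))``, saturating by rank ~11-20;
* movement decomposition — with some probability a single-joint pause is
  inserted after the hand-speed peak: one joint's angle profile is frozen
  for a normalized duration while the other continues and then holds at its
  endpoint, extending the trial.  The pre-peak kinematics (and hence peak
  velocity and acceleration-phase torque impulses) are untouched;
* trajectory noise — a smooth lateral half-sine perturbation with Gaussian
  amplitude, inflated by a configurable factor in the block condition;
* slower control trials pause more often (pause probability rises with the
  trial's natural slowness), emulating the velocity dependence of
  decomposition in intact movements.

Target 1 is placed along the tangent of the shoulder circle at the central
position, so reaching it is approximately a single-joint shoulder rotation
(minimal elbow net torque and minimal coupling); the remaining targets step
around the circle in 45 degree increments and require combined
shoulder-elbow motion.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
import pandas as pd

from .limb import (
    ArmGeometry,
    HandSeries,
    InertialParams,
    JointSeries,
    forward_kinematics,
    inertial_params_from_anthropometry,
    inverse_kinematics,
)
from .preprocess import TrialMeta, TrialRecord

__all__ = [
    "MonkeyConfig",
    "SimulationConfig",
    "BlockEffectParams",
    "Session",
    "min_jerk_profile",
    "generate_trial",
    "generate_session",
    "generate_experiment",
    "simulate_null_summaries",
]

OUTWARD_TARGETS = (1, 2, 3, 4)
INWARD_TARGETS = (5, 6, 7, 8)


@dataclass(frozen=True)
class MonkeyConfig:
    """Per-subject geometry and body mass."""

    name: str
    l1: float
    l2: float
    body_mass: float


def _default_monkeys() -> tuple[MonkeyConfig, ...]:
    # body masses span the adult female macaque range (4.5-8 kg)
    return (
        MonkeyConfig("S", 0.140, 0.190, 4.5),
        MonkeyConfig("C", 0.150, 0.200, 6.0),
        MonkeyConfig("M", 0.145, 0.195, 5.5),
        MonkeyConfig("P", 0.160, 0.210, 8.0),
    )


@dataclass
class SimulationConfig:
    """Study-structure parameters of the synthetic experiment."""

    n_monkeys: int = 4
    sessions_per_monkey: int = 10
    subsession_choices: tuple[int, ...] = (3, 4)
    control_trials: int = 80
    block_trials: int = 50
    n_targets: int = 8
    reach_distance: float = 0.045
    fs: float = 1000.0
    duration_mean: float = 0.4
    velocity_cv: float = 0.12
    include_returns: bool = True
    base_posture: tuple[float, float] = (np.pi / 4, np.pi / 2)
    monkeys: tuple[MonkeyConfig, ...] = field(default_factory=_default_monkeys)

    def __post_init__(self) -> None:
        if min(self.n_monkeys, self.sessions_per_monkey, self.control_trials,
               self.block_trials, self.n_targets) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_monkeys > len(self.monkeys):
            raise ValueError("not enough monkey configs for n_monkeys")
        if not (self.reach_distance > 0 and self.duration_mean > 0 and self.fs > 0):
            raise ValueError("distance, duration and sampling rate must be positive")
        for mk in self.monkeys[: self.n_monkeys]:
            geom = ArmGeometry(mk.l1, mk.l2)
            center = _workspace_center(geom, self.base_posture)
            r = np.linalg.norm(center)
            lo, hi = abs(geom.l1 - geom.l2), geom.l1 + geom.l2
            if not (lo + self.reach_distance < r < hi - self.reach_distance):
                raise ValueError(
                    f"reach distance {self.reach_distance} m leaves the reachable "
                    f"annulus for monkey {mk.name}"
                )


def _frac(name: str, v: float) -> None:
    if not 0 <= v < 1:
        raise ValueError(f"{name} must be a fraction in [0, 1), got {v}")


@dataclass
class BlockEffectParams:
    """Parameterized effects of the cerebellar-block condition.

    Deficits are fractional reductions of peak hand velocity.  Pause
    parameters give the probability and normalized-duration range of
    single-joint pause insertion per condition; the control probability rises
    by ``pause_velocity_slope`` per unit of natural slowness ``(1 - v)``.
    ``lateral_noise_sd`` is the SD (m) of the lateral path-perturbation
    amplitude at unit velocity factor; it scales as
    ``velocity_factor ** noise_speed_exponent`` (slower movements are less
    noisy, a speed-accuracy tradeoff) and is multiplied by
    ``block_noise_mult`` under block.
    """

    outward_deficit: float = 0.10
    inward_deficit: float = 0.02
    adapt_extra: float = 0.05
    adapt_tau: float = 4.0
    adapt_targets: tuple[int, ...] = (2, 3, 4)
    return_deficit: float = 0.02
    control_pause_prob: float = 0.35
    block_pause_prob: float = 0.85
    pause_velocity_slope: float = 1.5
    control_pause_duration: tuple[float, float] = (0.06, 0.14)
    block_pause_duration: tuple[float, float] = (0.10, 0.20)
    pause_onset: tuple[float, float] = (0.55, 0.75)
    lateral_noise_sd: float = 0.0025
    block_noise_mult: float = 1.35
    noise_speed_exponent: float = 0.5
    success_p_control: float = 0.865
    success_p_block: float = 0.753

    def __post_init__(self) -> None:
        for nm in ("outward_deficit", "inward_deficit", "adapt_extra",
                   "return_deficit"):
            _frac(nm, getattr(self, nm))
        for nm in ("success_p_control", "success_p_block",
                   "control_pause_prob", "block_pause_prob"):
            if not 0 <= getattr(self, nm) <= 1:
                raise ValueError(f"{nm} must be a probability")
        if self.block_noise_mult <= 0:
            raise ValueError("noise multiplier must be positive")
        if self.adapt_tau <= 0:
            raise ValueError("adaptation time constant must be positive")

    @classmethod
    def null(cls) -> "BlockEffectParams":
        """Zero injected effects: block condition indistinguishable from control."""
        return cls(
            outward_deficit=0.0, inward_deficit=0.0, adapt_extra=0.0,
            return_deficit=0.0,
            block_pause_prob=0.35, block_pause_duration=(0.06, 0.14),
            block_noise_mult=1.0, success_p_block=0.865,
        )

    def deficit(self, target: int, condition: str, group_rank: int,
                movement_class: str) -> float:
        """Fractional velocity deficit for one trial."""
        if condition != "block":
            return 0.0
        if movement_class == "return":
            return self.return_deficit
        base = self.outward_deficit if target in OUTWARD_TARGETS else self.inward_deficit
        extra = 0.0
        if target in self.adapt_targets and self.adapt_extra > 0:
            extra = self.adapt_extra * (1 - np.exp(-(group_rank - 1) / self.adapt_tau))
        return base + extra


def _workspace_center(geom: ArmGeometry, posture: tuple[float, float]) -> np.ndarray:
    ts, te = posture
    return np.array([
        geom.l1 * np.cos(ts) + geom.l2 * np.cos(ts + te),
        geom.l1 * np.sin(ts) + geom.l2 * np.sin(ts + te),
    ])


def target_angles(geom: ArmGeometry, posture: tuple[float, float],
                  n_targets: int = 8) -> np.ndarray:
    """Target direction angles (rad); target 1 along the shoulder-rotation
    tangent at the central posture (the near-single-joint direction)."""
    cx, cy = _workspace_center(geom, posture)
    psi1 = np.arctan2(cx, -cy)  # direction of d(hand)/d(theta_s) = (-y, x)
    # step clockwise so targets 2-4 demand combined shoulder-elbow motion
    return psi1 - np.arange(n_targets) * (2 * np.pi / n_targets)


def min_jerk_profile(D: float, T: float, fs: float):
    """Minimum-jerk scalar path: s, s', s'' sampled at fs over [0, T].

    s(t) = D (10 tau^3 - 15 tau^4 + 6 tau^5), tau = t/T, with zero velocity
    and acceleration at both ends; peak speed 15 D / (8 T) at t = T/2, peak
    acceleration 10 D / (sqrt(3) T^2).
    """
    if D <= 0 or T <= 0:
        raise ValueError("amplitude and duration must be positive")
    n = int(round(T * fs)) + 1
    t = np.arange(n) / fs
    tau = t / T
    s = D * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    sd = D * (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / T
    sdd = D * (60 * tau - 180 * tau**2 + 120 * tau**3) / T**2
    return t, s, sd, sdd


@dataclass
class SessionContext:
    """Precomputed per-monkey quantities shared by all trials of a session."""

    monkey: MonkeyConfig
    geometry: ArmGeometry
    inertial: InertialParams
    center: np.ndarray
    angles: np.ndarray
    config: SimulationConfig
    effects: BlockEffectParams

    @classmethod
    def build(cls, monkey: MonkeyConfig, config: SimulationConfig,
              effects: BlockEffectParams) -> "SessionContext":
        geom = ArmGeometry(monkey.l1, monkey.l2)
        return cls(
            monkey=monkey,
            geometry=geom,
            inertial=inertial_params_from_anthropometry(monkey.body_mass, geom),
            center=_workspace_center(geom, config.base_posture),
            angles=target_angles(geom, config.base_posture, config.n_targets),
            config=config,
            effects=effects,
        )


def _insert_pause(theta: np.ndarray, joint: int, u0: float, dur: float):
    """Freeze one joint's angle profile for a normalized duration.

    The paused joint holds its angle over ``[u0, u0 + dur]`` (normalized to
    the original trial) and then resumes at its original rate, extending the
    trial; the other joint completes on the original schedule and holds its
    final angle.  Index maps are integer, so the plateau is exact.
    """
    n = theta.shape[0]
    i0 = int(round(u0 * (n - 1)))
    npause = int(round(dur * (n - 1)))
    n_new = n + npause
    i = np.arange(n_new)
    idx_paused = np.where(i < i0, i, np.where(i < i0 + npause, i0, i - npause))
    idx_other = np.minimum(i, n - 1)
    out = np.empty((n_new, 2))
    out[:, joint] = theta[idx_paused, joint]
    out[:, 1 - joint] = theta[idx_other, 1 - joint]
    return out


def _series_from_theta(theta: np.ndarray, geom: ArmGeometry, fs: float):
    dt = 1.0 / fs
    omega = np.gradient(theta, dt, axis=0)
    alpha = np.gradient(omega, dt, axis=0)
    js = JointSeries(theta=theta, omega=omega, alpha=alpha, fs=fs)
    return js, forward_kinematics(js, geom)


def _retime_to_peak(theta: np.ndarray, geom: ArmGeometry, fs: float,
                    target_peak: float):
    """Uniformly time-dilate an angle series so peak hand speed does not
    exceed ``target_peak``.

    Desynchronizing the joints (pause insertion) can expose velocity
    contributions that cancel in the synchronized reach, raising hand speed
    above the intended trial peak; a uniform dilation restores the
    construction contract (peak speed = velocity factor x baseline) while
    preserving all normalized-time structure, including exact pauses.
    """
    js, hand = _series_from_theta(theta, geom, fs)
    for _ in range(3):
        peak = float(hand.speed().max())
        if peak <= target_peak * 1.001:
            break
        rho = peak / target_peak
        n = theta.shape[0]
        n_new = int(round((n - 1) * rho)) + 1
        old_t = np.arange(n, dtype=float)
        new_t = np.linspace(0.0, n - 1, n_new)
        theta = np.column_stack([np.interp(new_t, old_t, theta[:, j])
                                 for j in (0, 1)])
        js, hand = _series_from_theta(theta, geom, fs)
    return js, hand


def generate_trial(
    target: int,
    condition: str,
    group_rank: int,
    ctx: SessionContext,
    rng: np.random.Generator,
    movement_class: str = "target_directed",
    meta: TrialMeta | None = None,
) -> TrialRecord:
    """Generate one reaching trial.

    ``group_rank`` is the presentation rank of the trial's target group
    within its block (drives the adaptive component of the block deficit).
    Generation is a pure function of the inputs and the rng state.
    """
    cfg, eff = ctx.config, ctx.effects
    psi = ctx.angles[target - 1]
    u_hat = np.array([np.cos(psi), np.sin(psi)])
    n_hat = np.array([-np.sin(psi), np.cos(psi)])
    D = cfg.reach_distance
    if movement_class == "return":
        p0 = ctx.center + D * u_hat
        u_hat = -u_hat
    else:
        p0 = ctx.center

    # natural trial-to-trial speed variability x injected deficit
    v_nat = float(np.exp(rng.normal(0.0, cfg.velocity_cv)))
    deficit = eff.deficit(target, condition, group_rank, movement_class)
    v_factor = v_nat * (1 - deficit)
    T = cfg.duration_mean / v_factor

    # lateral half-sine perturbation; amplitude shrinks for slower movements
    sd_lat = eff.lateral_noise_sd * v_factor**eff.noise_speed_exponent
    if condition == "block":
        sd_lat *= eff.block_noise_mult
    amp = float(rng.normal(0.0, sd_lat))

    _, s, sdot, sddot = min_jerk_profile(D, T, cfg.fs)
    tau = s / D  # normalized progress
    n = s.size
    t = np.arange(n) / cfg.fs
    phase = t / T
    lat = amp * np.sin(np.pi * phase)
    latd = amp * np.pi * np.cos(np.pi * phase) / T
    latdd = -amp * np.pi**2 * np.sin(np.pi * phase) / T**2

    pos = p0 + np.outer(s, u_hat) + np.outer(lat, n_hat)
    vel = np.outer(sdot, u_hat) + np.outer(latd, n_hat)
    acc = np.outer(sddot, u_hat) + np.outer(latdd, n_hat)
    hand = HandSeries(pos=pos, vel=vel, acc=acc, fs=cfg.fs)
    js = inverse_kinematics(hand, ctx.geometry, elbow_sign=1, derivatives="jacobian")

    # single-joint pause insertion (decomposition injection)
    if condition == "block":
        p_pause = eff.block_pause_prob
        dur_rng = eff.block_pause_duration
    else:
        p_pause = float(np.clip(
            eff.control_pause_prob + eff.pause_velocity_slope * (1 - v_nat),
            0.0, 0.99))
        dur_rng = eff.control_pause_duration
    if rng.random() < p_pause and dur_rng[1] > 0:
        joint = int(rng.integers(0, 2))
        u0 = float(rng.uniform(*eff.pause_onset))
        dur = float(rng.uniform(*dur_rng))
        theta = _insert_pause(js.theta, joint, u0, dur)
        js, hand = _retime_to_peak(theta, ctx.geometry, cfg.fs,
                                   float(hand.speed().max()))

    success_p = eff.success_p_block if condition == "block" else eff.success_p_control
    if meta is None:
        meta = TrialMeta(monkey=ctx.monkey.name, session="s1", subsession=1,
                         block=1, condition=condition, target=target,
                         within_block_index=1, movement_class=movement_class)
    meta.success = bool(rng.random() < success_p)
    return TrialRecord(joint=js, hand=hand, meta=meta)


@dataclass
class Session:
    """One synthetic session: trials, event schedule, provenance manifest."""

    trials: list[TrialRecord]
    events: pd.DataFrame
    manifest: dict


def _balanced_target_order(n_trials: int, n_targets: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Pseudorandom order in which each target count differs by at most 1."""
    reps = int(np.ceil(n_trials / n_targets))
    order = np.concatenate([rng.permutation(n_targets) + 1 for _ in range(reps)])
    return order[:n_trials]


def _config_hash(config: SimulationConfig, effects: BlockEffectParams) -> str:
    blob = json.dumps({"config": asdict(config), "effects": asdict(effects)},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def generate_session(
    monkey_index: int,
    session_index: int,
    config: SimulationConfig,
    effects: BlockEffectParams,
    seed: int,
) -> Session:
    """Generate one session (3-4 sub-sessions of control + block blocks).

    Reproducibility: the session draws its randomness from substreams derived
    deterministically from ``(seed, monkey_index, session_index)`` and, per
    trial, from ``(seed, monkey_index, session_index, block, trial)``, so any
    subset regenerates identically.
    """
    monkey = config.monkeys[monkey_index]
    ctx = SessionContext.build(monkey, config, effects)
    srng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(monkey_index, session_index)))
    n_sub = int(srng.choice(config.subsession_choices))
    session_id = f"{monkey.name}{session_index + 1:02d}"

    trials: list[TrialRecord] = []
    events = []
    trial_id = 0
    block_id = 0
    clock = 0.0
    for sub in range(1, n_sub + 1):
        for condition, n_trials in (("control", config.control_trials),
                                    ("block", config.block_trials)):
            block_id += 1
            order = _balanced_target_order(n_trials, config.n_targets, srng)
            group_counts: dict[tuple[int, ...] | int, int] = {}
            for w, target in enumerate(order, start=1):
                target = int(target)
                # presentation rank of this target's adaptation group
                if target in effects.adapt_targets:
                    key: tuple[int, ...] | int = tuple(effects.adapt_targets)
                else:
                    key = target
                group_counts[key] = group_counts.get(key, 0) + 1
                rank = group_counts[key]
                trng = np.random.default_rng(np.random.SeedSequence(
                    seed, spawn_key=(monkey_index, session_index, block_id, w)))
                trial_id += 1
                meta = TrialMeta(
                    monkey=monkey.name, session=session_id, subsession=sub,
                    block=block_id, condition=condition, target=target,
                    within_block_index=w, movement_class="target_directed",
                    trial_id=trial_id,
                )
                tr = generate_trial(target, condition, rank, ctx, trng,
                                    movement_class="target_directed", meta=meta)
                trials.append(tr)
                dur = (tr.joint.n - 1) / config.fs
                cue = clock + float(trng.uniform(0.5, 0.8))
                go = cue + float(trng.uniform(0.45, 0.85))
                entry = go + 0.2 + dur
                events.append({
                    "trial_id": trial_id, "cue_time": cue, "go_time": go,
                    "entry_time": entry, "block": block_id,
                    "condition": condition, "target": target,
                    "success": tr.meta.success, "monkey": monkey.name,
                    "session": session_id, "subsession": sub,
                })
                clock = entry + 0.3
                if config.include_returns:
                    trial_id += 1
                    rmeta = TrialMeta(
                        monkey=monkey.name, session=session_id, subsession=sub,
                        block=block_id, condition=condition, target=target,
                        within_block_index=w, movement_class="return",
                        trial_id=trial_id,
                    )
                    rtr = generate_trial(target, condition, rank, ctx, trng,
                                         movement_class="return", meta=rmeta)
                    trials.append(rtr)
                    clock += (rtr.joint.n - 1) / config.fs + 0.3

    manifest = {
        "seed": seed,
        "monkey": monkey.name,
        "session": session_id,
        "monkey_index": monkey_index,
        "session_index": session_index,
        "fs": config.fs,
        "geometry": {"l1": monkey.l1, "l2": monkey.l2},
        "body_mass": monkey.body_mass,
        "n_subsessions": n_sub,
        "n_trials": len(trials),
        "config_hash": _config_hash(config, effects),
    }
    return Session(trials=trials, events=pd.DataFrame(events), manifest=manifest)


def generate_experiment(
    config: SimulationConfig,
    effects: BlockEffectParams,
    seed: int,
) -> Iterator[Session]:
    """Yield sessions for all monkeys, one at a time (memory-friendly)."""
    for m in range(config.n_monkeys):
        for s in range(config.sessions_per_monkey):
            yield generate_session(m, s, config, effects, seed)


def simulate_null_summaries(
    rng: np.random.Generator,
    n_monkeys: int = 4,
    n_sessions: int = 10,
    sd_monkey: float = 2.0,
    sd_resid: float = 5.0,
    n_targets: int = 8,
    effect: float = 0.0,
) -> pd.DataFrame:
    """Session-level percent-change summaries from a (null) mixed model.

    Each row is one session x target percent change drawn as
    ``monkey offset + group effect + noise``; with ``effect = 0`` the
    outward/inward group difference is exactly null.  Used for type-I
    calibration of the contrast machinery at the summary level.
    """
    rows = []
    for m in range(n_monkeys):
        off = rng.normal(0.0, sd_monkey)
        for s in range(n_sessions):
            for tgt in range(1, n_targets + 1):
                grp = "outward" if tgt in OUTWARD_TARGETS else "inward"
                val = off + (effect if grp == "outward" else 0.0) + \
                    rng.normal(0.0, sd_resid)
                rows.append({"monkey": f"m{m}", "session": f"m{m}s{s}",
                             "target": tgt, "group": grp, "value": val})
    return pd.DataFrame(rows)
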