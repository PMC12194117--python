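"""Filtering, epoching and movement-onset detection for reaching trials.

Raw kinematics (1 kHz by default) are low-pass filtered with a zero-phase
second-order Butterworth filter (10 Hz cutoff), cut into trials spanning cue
presentation to peripheral-target entry, and aligned to movement onset,
defined as the first sample at which hand speed exceeds 5% of its trial peak.
Because a trial ends at target entry, the extracted segment covers mainly the
acceleration phase of the reach; downstream measures are defined on that
phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal

from .limb import HandSeries, JointSeries

__all__ = [
    "TrialMeta",
    "TrialRecord",
    "lowpass_filter",
    "epoch_trials",
    "hand_speed",
    "detect_movement_onset",
]

CONDITIONS = ("control", "block")
MOVEMENT_CLASSES = ("target_directed", "return")


class NoMovementError(ValueError):
    """Speed trace contains no movement (all-zero)."""


@dataclass
class TrialMeta:
    """Metadata identifying one trial within the session hierarchy."""

    monkey: str
    session: str
    subsession: int
    block: int
    condition: str
    target: int
    within_block_index: int
    movement_class: str = "target_directed"
    success: bool = True
    trial_id: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.movement_class not in MOVEMENT_CLASSES:
            raise ValueError(f"movement_class must be one of {MOVEMENT_CLASSES}")
        if not 1 <= int(self.target) <= 8:
            raise ValueError("target must be in 1..8")


@dataclass
class TrialRecord:
    """One epoched trial: joint series + hand series + metadata."""

    joint: JointSeries
    hand: HandSeries
    meta: TrialMeta
    onset_index: int | None = None

    @property
    def fs(self) -> float:
        return self.joint.fs

    @property
    def onset_time(self) -> float | None:
        return None if self.onset_index is None else self.onset_index / self.fs

    def detect_onset(self, fraction: float = 0.05) -> int:
        """Detect and store the movement onset index; returns it."""
        self.onset_index = detect_movement_onset(hand_speed(self.hand), fraction)
        return self.onset_index


def lowpass_filter(x: np.ndarray, fs: float, cutoff_hz: float = 10.0,
                   order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter, per channel.

    Filtering twice squares the magnitude response and cancels the phase, so
    onset times are not delayed.  Output length equals input length.
    """
    if fs <= 2 * cutoff_hz:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the cutoff {cutoff_hz} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def hand_speed(hand: HandSeries) -> np.ndarray:
    """Hand speed (tangential velocity magnitude), m/s per sample.

    The radial-component alternative (velocity projected on the centre-to-
    target axis) is available via :func:`radial_velocity`.
    """
    return hand.speed()


def radial_velocity(hand: HandSeries, origin: np.ndarray) -> np.ndarray:
    """Component of hand velocity along the instantaneous radius from origin."""
    rel = hand.pos - np.asarray(origin, dtype=float)
    r = np.linalg.norm(rel, axis=1)
    r = np.where(r == 0, np.inf, r)
    return (rel * hand.vel).sum(axis=1) / r


def detect_movement_onset(speed: np.ndarray, fraction: float = 0.05) -> int:
    """First sample index at which speed exceeds ``fraction`` of its peak."""
    speed = np.asarray(speed, dtype=float)
    peak = speed.max() if speed.size else 0.0
    if peak <= 0:
        raise NoMovementError("speed trace has no positive maximum")
    above = np.flatnonzero(speed > fraction * peak)
    return int(above[0])


def epoch_trials(
    joint: JointSeries,
    hand: HandSeries,
    events: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
) -> list[TrialRecord]:
    """Cut a continuous record into per-trial records.

    ``events`` needs columns ``trial_id``, ``cue_time``, ``go_time``,
    ``entry_time`` plus the trial descriptors ``block``, ``condition``,
    ``target``, ``success`` (and optionally ``monkey``, ``session``,
    ``subsession``, ``movement_class``).  Epochs span cue presentation to
    peripheral-target entry; ``within_block_index`` is assigned by temporal
    order within each block.
    """
    n = joint.n
    fs = joint.fs
    required = {"trial_id", "cue_time", "go_time", "entry_time",
                "block", "condition", "target", "success"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    ev = events.sort_values("cue_time").reset_index(drop=True)
    if not ((ev["cue_time"] < ev["go_time"]) & (ev["go_time"] < ev["entry_time"])).all():
        raise ValueError("event times must be ordered cue < go < entry within a trial")

    trials: list[TrialRecord] = []
    counters: dict[int, int] = {}
    for _, row in ev.iterrows():
        i0 = int(round(row["cue_time"] * fs))
        i1 = int(round(row["entry_time"] * fs)) + 1
        if i0 < 0 or i1 > n:
            raise IndexError(
                f"trial {row['trial_id']} events fall outside the record "
                f"(samples {i0}:{i1} of {n})"
            )
        blk = int(row["block"])
        counters[blk] = counters.get(blk, 0) + 1
        meta = TrialMeta(
            monkey=str(row.get("monkey", "m1")),
            session=str(row.get("session", "s1")),
            subsession=int(row.get("subsession", 1)),
            block=blk,
            condition=str(row["condition"]),
            target=int(row["target"]),
            within_block_index=counters[blk],
            movement_class=str(row.get("movement_class", "target_directed")),
            success=bool(row["success"]),
            trial_id=int(row["trial_id"]),
        )
        js = JointSeries(theta=joint.theta[i0:i1], omega=joint.omega[i0:i1],
                         alpha=joint.alpha[i0:i1], fs=fs)
        hs = HandSeries(pos=hand.pos[i0:i1], vel=hand.vel[i0:i1], fs=fs)
        trials.append(TrialRecord(joint=js, hand=hs, meta=meta))
    return trials


def trials_metadata(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Tidy metadata table, one row per trial."""
    rows = []
    for tr in trials:
        m = tr.meta
        rows.append({
            "trial_id": m.trial_id, "monkey": m.monkey, "session": m.session,
            "subsession": m.subsession, "block": m.block,
            "condition": m.condition, "target": m.target,
            "within_block_index": m.within_block_index,
            "movement_class": m.movement_class, "success": m.success,
        })
    return pd.DataFrame(rows)
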