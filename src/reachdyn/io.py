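"""Delimited-text persistence for sessions: samples, metadata, events, manifest.

One directory per session holds ``samples.csv`` (long-format per-sample
kinematics), ``metadata.csv`` (one row per trial), ``events.csv`` (cue / go /
target-entry schedule) and ``manifest.yaml`` (sampling rate, geometry, body
mass, seed, config hash).  An experiment directory holds a top-level
``manifest.yaml`` listing its session directories.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .limb import ArmGeometry, HandSeries, JointSeries, forward_kinematics
from .preprocess import TrialMeta, TrialRecord
from .simulate import Session

__all__ = ["write_session", "read_session", "write_experiment_manifest",
           "read_experiment", "DataIntegrityError"]

SAMPLE_COLUMNS = ["trial_id", "t", "theta_s", "theta_e", "omega_s", "omega_e",
                  "alpha_s", "alpha_e", "hand_x", "hand_y"]
META_COLUMNS = ["trial_id", "monkey", "session", "subsession", "block",
                "condition", "target", "within_block_index", "movement_class",
                "success"]


class DataIntegrityError(RuntimeError):
    """Session files are inconsistent with their manifest or each other."""


def write_session(session: Session, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_frames = []
    meta_rows = []
    for tr in session.trials:
        m = tr.meta
        n = tr.joint.n
        sample_frames.append(pd.DataFrame({
            "trial_id": np.full(n, m.trial_id, dtype=int),
            "t": tr.joint.t,
            "theta_s": tr.joint.theta[:, 0], "theta_e": tr.joint.theta[:, 1],
            "omega_s": tr.joint.omega[:, 0], "omega_e": tr.joint.omega[:, 1],
            "alpha_s": tr.joint.alpha[:, 0], "alpha_e": tr.joint.alpha[:, 1],
            "hand_x": tr.hand.pos[:, 0], "hand_y": tr.hand.pos[:, 1],
        }))
        meta_rows.append({
            "trial_id": m.trial_id, "monkey": m.monkey, "session": m.session,
            "subsession": m.subsession, "block": m.block,
            "condition": m.condition, "target": m.target,
            "within_block_index": m.within_block_index,
            "movement_class": m.movement_class, "success": m.success,
        })
    pd.concat(sample_frames, ignore_index=True).to_csv(
        outdir / "samples.csv", index=False, float_format="%.9g")
    pd.DataFrame(meta_rows, columns=META_COLUMNS).to_csv(
        outdir / "metadata.csv", index=False)
    session.events.to_csv(outdir / "events.csv", index=False)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(session.manifest, fh, sort_keys=True)
    return outdir


def read_session(path: str | Path) -> Session:
    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    samples = pd.read_csv(path / "samples.csv")
    meta = pd.read_csv(path / "metadata.csv")
    missing_cols = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing_cols:
        raise DataIntegrityError(
            f"{path / 'samples.csv'}: missing columns {sorted(missing_cols)}")
    sample_ids = set(samples["trial_id"].unique())
    meta_ids = set(meta["trial_id"])
    if not meta_ids <= sample_ids:
        raise DataIntegrityError(
            f"{path / 'metadata.csv'}: trials {sorted(meta_ids - sample_ids)} "
            "have no samples")
    fs = float(manifest["fs"])
    geom = ArmGeometry(**manifest["geometry"])
    trials = []
    grouped = dict(tuple(samples.groupby("trial_id", sort=False)))
    for _, row in meta.iterrows():
        g = grouped[row["trial_id"]]
        js = JointSeries(
            theta=g[["theta_s", "theta_e"]].to_numpy(),
            omega=g[["omega_s", "omega_e"]].to_numpy(),
            alpha=g[["alpha_s", "alpha_e"]].to_numpy(), fs=fs)
        # hand velocity is reconstructed from the joint state (forward
        # kinematics); stored positions are used verbatim
        hand = forward_kinematics(js, geom)
        hand = HandSeries(pos=g[["hand_x", "hand_y"]].to_numpy(),
                          vel=hand.vel, fs=fs)
        tm = TrialMeta(
            monkey=str(row["monkey"]), session=str(row["session"]),
            subsession=int(row["subsession"]), block=int(row["block"]),
            condition=str(row["condition"]), target=int(row["target"]),
            within_block_index=int(row["within_block_index"]),
            movement_class=str(row["movement_class"]),
            success=bool(row["success"]), trial_id=int(row["trial_id"]))
        trials.append(TrialRecord(joint=js, hand=hand, meta=tm))
    events = pd.read_csv(path / "events.csv") if (path / "events.csv").exists() \
        else pd.DataFrame()
    return Session(trials=trials, events=events, manifest=manifest)


def write_experiment_manifest(root: str | Path, session_dirs: list[str],
                              extra: dict) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    doc = {"sessions": sorted(session_dirs), **extra}
    with open(root / "manifest.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    return root / "manifest.yaml"


def read_experiment(root: str | Path):
    """Yield sessions listed in an experiment manifest."""
    root = Path(root)
    with open(root / "manifest.yaml") as fh:
        doc = yaml.safe_load(fh)
    for rel in doc["sessions"]:
        sdir = root / rel
        if not (sdir / "manifest.yaml").exists():
            raise DataIntegrityError(f"manifest lists missing session dir {sdir}")
        yield read_session(sdir)
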