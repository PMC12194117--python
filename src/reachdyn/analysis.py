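"""End-to-end analysis: trial measures -> session summaries -> effect estimates.

The central objects follow the model/results idiom: a
:class:`ReachEffectsModel` is built from per-trial measures (computed from
trial records, loaded from disk, or simulated on the fly) and its
:meth:`~ReachEffectsModel.fit` returns a :class:`ReachEffectsResults` holding
every effect estimate of the standard analysis battery:

1. target-wise percent change in peak hand velocity, with outward (targets
   1-4) vs inward (targets 5-8) contrasts;
2. the same for muscle torque impulse per joint (control-referenced
   normalization);
3. partial correlation (controlling for monkey) between the control-trial
   net coupling impulse and the velocity change, outward targets;
4. trial-sequence analysis: early (ranks 1-2) vs late (ranks 11-20)
   velocity deficits and the condition x sequence interaction for the
   high-coupling target group;
5. movement decomposition: block vs velocity-matched-control decomposition
   index, plus the overall index change;
6. trajectory variability of velocity-matched trials (block / control SD
   ratio);
7. target-directed vs return-movement velocity change and success rates.

All estimates come from linear mixed-effects fits on session-level medians
with a monkey random intercept; post hoc families are BH-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as mx
from .inference import (
    EffectEstimate,
    MixedEffectsModel,
    bh_adjust,
    partial_correlation,
    percent_change,
)
from .limb import InertialParams, inverse_dynamics
from .preprocess import TrialRecord
from .simulate import (
    BlockEffectParams,
    OUTWARD_TARGETS,
    INWARD_TARGETS,
    SessionContext,
    SimulationConfig,
    generate_experiment,
)

__all__ = [
    "AnalysisOptions",
    "ReachEffectsModel",
    "ReachEffectsResults",
    "trial_measures",
    "measures_table",
]

MEASURE_COLUMNS = [
    "monkey", "session", "subsession", "block", "condition", "target",
    "within_block_index", "movement_class", "success", "peak_velocity",
    "muscle_impulse_shoulder", "muscle_impulse_elbow",
    "coupling_impulse_shoulder", "coupling_impulse_elbow",
    "net_coupling_impulse", "decomposition_index", "max_deviation", "duration",
]


@dataclass
class AnalysisOptions:
    """Tunable analysis parameters (thresholds, bins, tolerances)."""

    matching_tolerance: float = 0.05
    di_threshold_deg: float = 20.0
    di_bins: int = 1000
    sequence_targets: tuple[int, ...] = (2, 3, 4)
    di_targets: tuple[int, ...] = (2, 3, 4)
    success_only: bool = False


def trial_measures(trial: TrialRecord, inertial: InertialParams,
                   options: AnalysisOptions | None = None) -> dict:
    """All per-trial response measures as one flat record."""
    opt = options or AnalysisOptions()
    m = trial.meta
    trial.detect_onset()
    phase = mx.acceleration_phase(trial)
    decomp = inverse_dynamics(trial.joint, inertial)
    fs = trial.fs
    raster = mx.decomposition_raster(trial, speed_threshold_deg=opt.di_threshold_deg,
                                     n_bins=opt.di_bins)
    aligned = mx.align_and_rotate(trial.hand.pos[trial.onset_index:])
    return {
        "monkey": m.monkey, "session": m.session, "subsession": m.subsession,
        "block": m.block, "condition": m.condition, "target": m.target,
        "within_block_index": m.within_block_index,
        "movement_class": m.movement_class, "success": m.success,
        "peak_velocity": mx.peak_hand_velocity(trial),
        "muscle_impulse_shoulder": mx.torque_impulse(decomp["muscle", "shoulder"], phase, fs),
        "muscle_impulse_elbow": mx.torque_impulse(decomp["muscle", "elbow"], phase, fs),
        "coupling_impulse_shoulder": mx.torque_impulse(decomp["coupling", "shoulder"], phase, fs),
        "coupling_impulse_elbow": mx.torque_impulse(decomp["coupling", "elbow"], phase, fs),
        "net_coupling_impulse": mx.net_coupling_impulse(decomp, phase),
        "decomposition_index": mx.decomposition_index(raster),
        "max_deviation": mx.max_perpendicular_deviation(aligned),
        "duration": (trial.joint.n - 1) / fs,
    }


def measures_table(trials: list[TrialRecord], inertial: InertialParams,
                   options: AnalysisOptions | None = None) -> pd.DataFrame:
    """Tidy per-trial measures table for one session's trials."""
    return pd.DataFrame([trial_measures(tr, inertial, options) for tr in trials],
                        columns=MEASURE_COLUMNS)


def _cond_pct(df: pd.DataFrame, value: str, by: list[str]) -> pd.DataFrame:
    """Per-group percent change of the block-condition median vs control."""
    med = df.groupby(by + ["condition"], observed=True)[value].median().unstack("condition")
    med = med.dropna(subset=["control", "block"])
    med = med[med["control"] != 0]
    out = med.reset_index()
    out["value"] = [percent_change(b, c)
                    for b, c in zip(out["block"], out["control"])]
    return out


class ReachEffectsModel:
    """The full analysis battery over a per-trial measures table.

    Build with :meth:`from_measures` (a precomputed tidy table),
    :meth:`from_trials` (epoched trial records), or
    :meth:`from_simulation` (generates and measures sessions one at a time,
    so memory stays bounded).  :meth:`fit` runs every analysis and returns a
    :class:`ReachEffectsResults`.
    """

    def __init__(self, measures: pd.DataFrame,
                 options: AnalysisOptions | None = None):
        missing = set(MEASURE_COLUMNS) - set(measures.columns)
        if missing:
            raise ValueError(f"measures table missing columns: {sorted(missing)}")
        self.options = options or AnalysisOptions()
        df = measures.copy()
        if self.options.success_only:
            df = df[df["success"]]
        self.measures = df.reset_index(drop=True)

    @classmethod
    def from_measures(cls, measures: pd.DataFrame,
                      options: AnalysisOptions | None = None) -> "ReachEffectsModel":
        return cls(measures, options)

    @classmethod
    def from_trials(cls, trials: list[TrialRecord], inertial: InertialParams,
                    options: AnalysisOptions | None = None) -> "ReachEffectsModel":
        return cls(measures_table(trials, inertial, options), options)

    @classmethod
    def from_simulation(cls, config: SimulationConfig, effects: BlockEffectParams,
                        seed: int, options: AnalysisOptions | None = None,
                        ) -> "ReachEffectsModel":
        frames = []
        for session in generate_experiment(config, effects, seed):
            mk = config.monkeys[session.manifest["monkey_index"]]
            ctx = SessionContext.build(mk, config, effects)
            frames.append(measures_table(session.trials, ctx.inertial, options))
        return cls(pd.concat(frames, ignore_index=True), options)

    # ------------------------------------------------------------------ #

    def _reaches(self) -> pd.DataFrame:
        return self.measures[self.measures["movement_class"] == "target_directed"]

    def _fit_cellmeans(self, table: pd.DataFrame, factor: str):
        return MixedEffectsModel(table, f"value ~ 0 + C({factor})").fit()

    def _velocity_effects(self, effects_rows: list, fits: dict) -> None:
        df = self._reaches()
        tab = _cond_pct(df, "peak_velocity", ["monkey", "session", "target"])
        fit = self._fit_cellmeans(tab, "target")
        fits["velocity"] = fit
        names = fit.coef_names
        per_target = []
        for tgt in sorted(tab["target"].unique()):
            w = np.array([1.0 if f"[{tgt}]" in nm else 0.0 for nm in names])
            per_target.append(fit.contrast(w, label=f"velocity change target {tgt}"))
        for p_adj, est in zip(bh_adjust([e.p for e in per_target]), per_target):
            est.p_bh = float(p_adj)
        effects_rows.extend(("velocity", e) for e in per_target)
        w_out = np.array([0.25 if any(f"[{t}]" in nm for t in OUTWARD_TARGETS)
                          else 0.0 for nm in names])
        w_in = np.array([0.25 if any(f"[{t}]" in nm for t in INWARD_TARGETS)
                         else 0.0 for nm in names])
        effects_rows.append(("velocity", fit.contrast(
            w_out, label="velocity change outward targets 1-4")))
        effects_rows.append(("velocity", fit.contrast(
            w_in, label="velocity change inward targets 5-8")))
        effects_rows.append(("velocity", fit.contrast(
            w_out - w_in, label="velocity change outward - inward")))

    def _torque_effects(self, effects_rows: list, fits: dict) -> None:
        df = self._reaches()
        for joint in ("shoulder", "elbow"):
            col = f"muscle_impulse_{joint}"
            rows = []
            for (mk, ses), g in df.groupby(["monkey", "session"], observed=True):
                med = g.groupby(["target", "condition"], observed=True)[col] \
                    .median().unstack("condition").dropna()
                if med.empty:
                    continue
                ref = med["control"].abs().max()
                if not ref > 0:
                    continue
                for tgt, r in med.iterrows():
                    rows.append({"monkey": mk, "session": ses, "target": tgt,
                                 "value": 100.0 * (r["block"] - r["control"]) / ref})
            tab = pd.DataFrame(rows)
            fit = self._fit_cellmeans(tab, "target")
            fits[f"torque_{joint}"] = fit
            names = fit.coef_names
            w_out = np.array([0.25 if any(f"[{t}]" in nm for t in OUTWARD_TARGETS)
                              else 0.0 for nm in names])
            w_in = np.array([0.25 if any(f"[{t}]" in nm for t in INWARD_TARGETS)
                             else 0.0 for nm in names])
            effects_rows.append((f"torque_{joint}", fit.contrast(
                w_out, label=f"{joint} muscle impulse change outward targets 1-4")))
            effects_rows.append((f"torque_{joint}", fit.contrast(
                w_in, label=f"{joint} muscle impulse change inward targets 5-8")))
            effects_rows.append((f"torque_{joint}", fit.contrast(
                w_out - w_in, label=f"{joint} muscle impulse change outward - inward")))

    def _movement_class_effects(self, effects_rows: list, fits: dict) -> None:
        df = self.measures
        tab = _cond_pct(df, "peak_velocity", ["monkey", "session", "movement_class"])
        if tab["movement_class"].nunique() < 2:
            return
        fit = self._fit_cellmeans(tab, "movement_class")
        fits["movement_class"] = fit
        names = fit.coef_names
        w_t = np.array([1.0 if "[target_directed]" in nm else 0.0 for nm in names])
        w_r = np.array([1.0 if "[return]" in nm else 0.0 for nm in names])
        effects_rows.append(("movement_class", fit.contrast(
            w_t, label="velocity change target-directed movements")))
        effects_rows.append(("movement_class", fit.contrast(
            w_r, label="velocity change return movements")))
        effects_rows.append(("movement_class", fit.contrast(
            w_t - w_r, label="velocity change target-directed - return")))

    def _sequence_table(self, targets: tuple[int, ...]) -> pd.DataFrame:
        df = self._reaches()
        sel = df[df["target"].isin(targets)].copy()
        sel = sel.sort_values(["monkey", "session", "block", "within_block_index"])
        sel["rank"] = sel.groupby(["monkey", "session", "block"],
                                  observed=True).cumcount() + 1
        sel["rank_bin"] = sel["rank"].map(mx._rank_bin)
        is_ref = (sel["condition"] == "control") & (sel["rank"] <= 2)
        sel["norm_velocity"] = mx.normalize_to_early_control(
            sel.rename(columns={"peak_velocity": "value"}),
            value_col="value", reference_mask=is_ref.to_numpy())
        return sel

    def _sequence_effects(self, effects_rows: list, fits: dict) -> None:
        seq = self._sequence_table(self.options.sequence_targets)
        seq = seq[seq["rank_bin"].isin(["early", "late"])]
        summ = seq.groupby(["monkey", "session", "condition", "rank_bin"],
                           observed=True)["norm_velocity"].median().reset_index()
        summ["cell"] = summ["condition"] + "_" + summ["rank_bin"]
        summ = summ.rename(columns={"norm_velocity": "value"})
        if summ["cell"].nunique() < 4:
            return
        fit = self._fit_cellmeans(summ, "cell")
        fits["sequence"] = fit
        names = fit.coef_names

        def cell_w(cell: str) -> np.ndarray:
            return np.array([1.0 if f"[{cell}]" in nm else 0.0 for nm in names])

        ce, cl = cell_w("control_early"), cell_w("control_late")
        be, bl = cell_w("block_early"), cell_w("block_late")
        effects_rows.append(("sequence", fit.contrast(
            100.0 * (ce - be), label="early-trial velocity deficit (%)")))
        effects_rows.append(("sequence", fit.contrast(
            100.0 * (cl - bl), label="late-trial velocity deficit (%)")))
        effects_rows.append(("sequence", fit.contrast(
            100.0 * ((cl - bl) - (ce - be)),
            label="condition x trial-sequence interaction (%)")))

    def _coupling_correlation(self, df: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
        reaches = df
        norm = reaches.groupby("monkey", observed=True)["net_coupling_impulse"].median()
        ctrl = reaches[(reaches["condition"] == "control")
                       & reaches["target"].isin(OUTWARD_TARGETS)]
        x = ctrl.groupby(["monkey", "session", "target"], observed=True)[
            "net_coupling_impulse"].median().reset_index()
        x["coupling_pct"] = 100.0 * x["net_coupling_impulse"] / x["monkey"].map(norm)
        vel = _cond_pct(reaches[reaches["target"].isin(OUTWARD_TARGETS)],
                        "peak_velocity", ["monkey", "session", "target"])
        merged = x.merge(vel[["monkey", "session", "target", "value"]],
                         on=["monkey", "session", "target"]).dropna()
        # correlate on the reduction scale: positive rho = movements with
        # larger coupling impulses slow down more under block
        merged["velocity_reduction"] = -merged["value"]
        rho, p = partial_correlation(merged["coupling_pct"].to_numpy(),
                                     merged["velocity_reduction"].to_numpy(),
                                     merged[["monkey"]])
        return rho, p, merged

    def _matching_analysis(self) -> pd.DataFrame:
        """Velocity matching per session over the decomposition targets."""
        df = self._reaches()
        df = df[df["target"].isin(self.options.di_targets)]
        rows = []
        for (mk, ses), g in df.groupby(["monkey", "session"], observed=True):
            mc_idx: list[int] = []
            mb_idx: list[int] = []
            dvs: list[float] = []
            for tgt, gt in g.groupby("target", observed=True):
                ctrl = gt[gt["condition"] == "control"]
                blk = gt[gt["condition"] == "block"].sort_values(
                    ["block", "within_block_index"])
                if ctrl.empty or blk.empty:
                    continue
                match = mx.match_by_peak_velocity(
                    ctrl["peak_velocity"].to_numpy(),
                    blk["peak_velocity"].to_numpy(),
                    tolerance=self.options.matching_tolerance)
                if match.empty:
                    continue
                mc_idx.extend(ctrl.index[match.control_idx])
                mb_idx.extend(blk.index[match.block_idx])
                dvs.extend(np.abs(ctrl["peak_velocity"].to_numpy()[match.control_idx]
                                  - blk["peak_velocity"].to_numpy()[match.block_idx]))
            all_ctrl = g[g["condition"] == "control"]
            row = {
                "monkey": mk, "session": ses, "n_matched": len(mc_idx),
                "median_abs_dv": float(np.median(dvs)) if dvs else np.nan,
                "di_all_control": all_ctrl["decomposition_index"].median(),
                "di_all_block": g.loc[g["condition"] == "block",
                                      "decomposition_index"].median(),
            }
            if mc_idx:
                mc = g.loc[mc_idx]
                mb = g.loc[mb_idx]
                row.update({
                    "matched_control_velocity": mc["peak_velocity"].median(),
                    "matched_block_velocity": mb["peak_velocity"].median(),
                    "di_matched_control": mc["decomposition_index"].median(),
                    "di_matched_block": mb["decomposition_index"].median(),
                    "sd_dev_matched_control": (
                        mx.trajectory_variability(mc["max_deviation"].to_numpy())
                        if len(mc) >= 2 else np.nan),
                    "sd_dev_matched_block": (
                        mx.trajectory_variability(mb["max_deviation"].to_numpy())
                        if len(mb) >= 2 else np.nan),
                })
            rows.append(row)
        return pd.DataFrame(rows)

    def _decomposition_effects(self, audit: pd.DataFrame, effects_rows: list,
                               fits: dict) -> None:
        ok = audit.dropna(subset=["di_matched_control", "di_matched_block",
                                  "di_all_control"])
        ok = ok[ok["di_all_control"] > 0]
        long = []
        for _, r in ok.iterrows():
            for setname, col in (("matched_control", "di_matched_control"),
                                 ("block", "di_matched_block")):
                long.append({
                    "monkey": r["monkey"], "session": r["session"], "set": setname,
                    "value": 100.0 * (r[col] - r["di_all_control"]) / r["di_all_control"],
                })
        tab = pd.DataFrame(long)
        if tab.empty or tab["set"].nunique() < 2:
            return
        fit = self._fit_cellmeans(tab, "set")
        fits["decomposition"] = fit
        names = fit.coef_names
        w_b = np.array([1.0 if "[block]" in nm else 0.0 for nm in names])
        w_m = np.array([1.0 if "[matched_control]" in nm else 0.0 for nm in names])
        effects_rows.append(("decomposition", fit.contrast(
            w_b, label="decomposition index change, block vs all control (%)")))
        effects_rows.append(("decomposition", fit.contrast(
            w_m, label="decomposition index change, matched control vs all control (%)")))
        effects_rows.append(("decomposition", fit.contrast(
            w_b - w_m, label="decomposition index, block - matched control (%)")))
        # overall (unmatched) index change
        overall = ok.assign(value=100.0 * (ok["di_all_block"] - ok["di_all_control"])
                            / ok["di_all_control"])
        ofit = MixedEffectsModel(overall, "value ~ 1").fit()
        effects_rows.append(("decomposition", ofit.contrast(
            np.array([1.0]), label="decomposition index change, all trials (%)")))

    def _variability_effects(self, audit: pd.DataFrame, effects_rows: list,
                             fits: dict) -> None:
        ok = audit.dropna(subset=["sd_dev_matched_control", "sd_dev_matched_block"])
        ok = ok[(ok["sd_dev_matched_control"] > 0) & (ok["sd_dev_matched_block"] > 0)]
        if ok.empty:
            return
        tab = ok.assign(value=np.log(ok["sd_dev_matched_block"]
                                     / ok["sd_dev_matched_control"]))
        fit = MixedEffectsModel(tab, "value ~ 1").fit()
        fits["variability"] = fit
        est = fit.contrast(np.array([1.0]),
                           label="log trajectory-variability ratio, block / matched control")
        effects_rows.append(("variability", est))
        pct = ok.assign(value=100.0 * (ok["sd_dev_matched_block"]
                                       - ok["sd_dev_matched_control"])
                        / ok["sd_dev_matched_control"])
        pfit = MixedEffectsModel(pct, "value ~ 1").fit()
        effects_rows.append(("variability", pfit.contrast(
            np.array([1.0]),
            label="trajectory variability change, block vs matched control (%)")))

    def fit(self) -> "ReachEffectsResults":
        effects_rows: list[tuple[str, EffectEstimate]] = []
        fits: dict = {}
        self._velocity_effects(effects_rows, fits)
        self._torque_effects(effects_rows, fits)
        self._movement_class_effects(effects_rows, fits)
        self._sequence_effects(effects_rows, fits)
        rho, rho_p, coupling_table = self._coupling_correlation(self._reaches())
        audit = self._matching_analysis()
        self._decomposition_effects(audit, effects_rows, fits)
        self._variability_effects(audit, effects_rows, fits)
        reaches = self._reaches()
        succ = {c: 100.0 * g["success"].mean()
                for c, g in reaches.groupby("condition", observed=True)}
        return ReachEffectsResults(
            model=self,
            effects=pd.DataFrame(
                [{"analysis": a, "label": e.label, "estimate": e.estimate,
                  "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p,
                  "p_bh": e.p_bh, "n": e.n} for a, e in effects_rows]),
            fits=fits,
            matching_audit=audit,
            coupling_rho=rho,
            coupling_rho_p=rho_p,
            coupling_table=coupling_table,
            success_rates=succ,
        )


@dataclass
class ReachEffectsResults:
    """Every effect estimate of the analysis battery, plus diagnostics."""

    model: ReachEffectsModel
    effects: pd.DataFrame
    fits: dict
    matching_audit: pd.DataFrame
    coupling_rho: float
    coupling_rho_p: float
    coupling_table: pd.DataFrame = field(repr=False)
    success_rates: dict = field(default_factory=dict)

    def plot_effects(self, ax=None):
        """Forest plot of all effect estimates (see reachdyn.plots)."""
        from .plots import plot_effects
        return plot_effects(self, ax=ax)

    def get(self, label: str) -> pd.Series:
        """Row of the effects table whose label contains ``label``."""
        hits = self.effects[self.effects["label"].str.contains(label, regex=False)]
        if hits.empty:
            raise KeyError(f"no effect labelled like {label!r}")
        return hits.iloc[0]

    @property
    def variability_ratio(self) -> float:
        """Geometric-mean block/matched-control trajectory-variability ratio."""
        row = self.get("log trajectory-variability ratio")
        return float(np.exp(row["estimate"]))

    def variability_ratio_ci(self) -> tuple[float, float]:
        row = self.get("log trajectory-variability ratio")
        return float(np.exp(row["ci_low"])), float(np.exp(row["ci_high"]))

    def summary(self) -> str:
        lines = [
            "Reach effects analysis",
            "=" * 70,
            f"trials analysed: {len(self.model.measures)}   "
            f"sessions: {self.model.measures['session'].nunique()}   "
            f"monkeys: {self.model.measures['monkey'].nunique()}",
            f"success rate: control {self.success_rates.get('control', float('nan')):.1f}%"
            f"   block {self.success_rates.get('block', float('nan')):.1f}%",
            f"coupling-velocity partial correlation (outward targets): "
            f"rho = {self.coupling_rho:.3f}, p = {self.coupling_rho_p:.2g}",
            "",
            f"{'effect':<58s}{'est':>8s}{'95% CI':>20s}{'p':>10s}",
            "-" * 96,
        ]
        for _, r in self.effects.iterrows():
            ci = f"[{r['ci_low']:7.2f}, {r['ci_high']:7.2f}]"
            lines.append(f"{r['label']:<58s}{r['estimate']:>8.2f}{ci:>20s}"
                         f"{r['p']:>10.2g}")
        return "\n".join(lines)
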