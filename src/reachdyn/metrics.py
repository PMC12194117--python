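"""Per-trial and per-set behavioral measures for center-out reaching.

These are the response measures used throughout the analysis: peak hand
velocity, torque impulses over the acceleration phase, the movement
decomposition index (fraction of normalized movement time during which
exactly one joint is paused while the other moves), trial-to-trial trajectory
variability (SD of maximum perpendicular deviation of aligned hand paths),
velocity matching between conditions, and per-target trial-sequence
extraction with early/mid/late presentation-rank bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .limb import TorqueDecomposition
from .preprocess import TrialRecord, hand_speed

__all__ = [
    "AccelPhase",
    "AlignedPath",
    "MatchResult",
    "peak_hand_velocity",
    "acceleration_phase",
    "torque_impulse",
    "net_coupling_impulse",
    "normalize_impulses",
    "decomposition_raster",
    "decomposition_index",
    "align_and_rotate",
    "max_perpendicular_deviation",
    "trajectory_variability",
    "match_by_peak_velocity",
    "extract_target_sequences",
    "normalize_to_early_control",
    "success_rate",
]

#: Presentation-rank bins: early trials 1-2, mid 3-10, late 11-20.
RANK_BINS = {"early": (1, 2), "mid": (3, 10), "late": (11, 20)}


@dataclass(frozen=True)
class AccelPhase:
    """Sample span of the acceleration phase: movement onset to speed peak."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("acceleration phase must satisfy start < end")


@dataclass
class AlignedPath:
    """Hand path translated to start at the origin and rotated so the
    endpoint lies on the positive Y-axis."""

    xy: np.ndarray


def peak_hand_velocity(trial: TrialRecord) -> float:
    """Maximum hand speed over the trial epoch, m/s."""
    speed = hand_speed(trial.hand)
    if speed.size == 0:
        raise ValueError("empty trial epoch")
    return float(speed.max())


def acceleration_phase(trial: TrialRecord) -> AccelPhase:
    """Onset-to-peak span of hand speed.

    The end is the first sample after onset where the hand-speed derivative
    crosses from positive to non-positive (i.e. the first local speed
    maximum); if the speed rises monotonically to the end of the (truncated)
    epoch, the phase extends to the last sample.
    """
    if trial.onset_index is None:
        trial.detect_onset()
    start = trial.onset_index
    speed = hand_speed(trial.hand)
    n = speed.size
    if start >= n - 1:
        raise ValueError("movement onset at trial end; no acceleration phase")
    ds = np.diff(speed)
    end = n - 1
    for i in range(start + 1, n - 1):
        if ds[i - 1] > 0 and ds[i] <= 0:
            end = i
            break
    return AccelPhase(start=start, end=end)


def torque_impulse(torque: np.ndarray, phase: AccelPhase, fs: float) -> float:
    """Signed time integral (trapezoidal) of a torque series over the phase."""
    torque = np.asarray(torque, dtype=float)
    if phase.end >= torque.size:
        raise ValueError("acceleration phase extends beyond the torque series")
    return float(np.trapezoid(torque[phase.start:phase.end + 1], dx=1.0 / fs))


def net_coupling_impulse(decomp: TorqueDecomposition, phase: AccelPhase) -> float:
    """Sum of absolute coupling torque impulses at shoulder and elbow."""
    return abs(torque_impulse(decomp["coupling", "shoulder"], phase, decomp.fs)) + \
        abs(torque_impulse(decomp["coupling", "elbow"], phase, decomp.fs))


def normalize_impulses(medians: pd.Series | np.ndarray,
                       reference: pd.Series | np.ndarray | None = None):
    """Divide target-wise medians by the maximum absolute median.

    With ``reference`` given (e.g. the control-condition medians), the
    denominator is the max absolute value of the reference medians instead —
    the control-referenced normalization used for change measures.
    """
    med = pd.Series(medians, dtype=float) if not isinstance(medians, pd.Series) else medians.astype(float)
    ref = med if reference is None else (
        pd.Series(reference, dtype=float) if not isinstance(reference, pd.Series)
        else reference.astype(float))
    denom = ref.abs().max()
    if not denom > 0:
        raise ValueError("degenerate normalization: all reference medians are zero")
    return med / denom


def decomposition_raster(
    trial: TrialRecord,
    speed_threshold_deg: float = 20.0,
    n_bins: int = 1000,
    aggregation: str = "center",
) -> np.ndarray:
    """Binary decomposition raster over normalized movement time.

    The onset-to-epoch-end span is normalized to [0, 1] and divided into
    ``n_bins`` bins.  A bin is 1 iff exactly one of the two joints' absolute
    angular speeds is below ``speed_threshold_deg`` (deg/s) — one joint
    paused while the other moves; both joints paused does *not* count.

    ``aggregation`` controls how samples map to bins: ``'center'`` (default)
    evaluates the sample nearest each bin center; ``'any'``/``'all'``
    aggregate the per-sample condition over all samples falling in the bin.
    """
    if trial.onset_index is None:
        trial.detect_onset()
    start = trial.onset_index
    omega = trial.joint.omega[start:]
    n = omega.shape[0]
    if n < 2:
        raise ValueError("onset-to-end span too short for a raster")
    thr = np.deg2rad(speed_threshold_deg)
    below = np.abs(omega) < thr
    decomposed = below[:, 0] ^ below[:, 1]
    if aggregation == "center":
        centers = (np.arange(n_bins) + 0.5) / n_bins
        idx = np.rint(centers * (n - 1)).astype(int)
        return decomposed[idx].astype(np.int8)
    if aggregation in ("any", "all"):
        edges = np.linspace(0, n, n_bins + 1)
        raster = np.zeros(n_bins, dtype=np.int8)
        for b in range(n_bins):
            lo, hi = int(np.floor(edges[b])), max(int(np.floor(edges[b])) + 1,
                                                  int(np.ceil(edges[b + 1])))
            seg = decomposed[lo:min(hi, n)]
            raster[b] = seg.any() if aggregation == "any" else seg.all()
        return raster
    raise ValueError("aggregation must be 'center', 'any' or 'all'")


def decomposition_index(raster: np.ndarray) -> float:
    """Proportion of normalized movement time spent decomposed."""
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("empty raster")
    return float(raster.mean())


def align_and_rotate(path_xy: np.ndarray) -> AlignedPath:
    """Translate a hand path to start at the origin, rotate endpoint to +Y.

    A rigid transform: inter-point distances are preserved.
    """
    xy = np.asarray(path_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
        raise ValueError("path must be an (n >= 2, 2) array")
    rel = xy - xy[0]
    dx, dy = rel[-1]
    norm = np.hypot(dx, dy)
    if norm == 0:
        raise ValueError("degenerate path: zero net displacement")
    ang = np.pi / 2 - np.arctan2(dy, dx)
    c, s = np.cos(ang), np.sin(ang)
    rot = rel @ np.array([[c, s], [-s, c]])
    return AlignedPath(xy=rot)


def max_perpendicular_deviation(path: AlignedPath) -> float:
    """Maximum |x| of an aligned path — largest deviation from the Y-axis."""
    return float(np.abs(path.xy[:, 0]).max())


def trajectory_variability(deviations: np.ndarray) -> float:
    """Sample standard deviation of per-trial maximum perpendicular deviations."""
    dev = np.asarray(deviations, dtype=float)
    if dev.size < 2:
        raise ValueError("trajectory variability needs at least 2 trials")
    return float(dev.std(ddof=1))


@dataclass
class MatchResult:
    """Outcome of velocity matching: indices into the two input sets plus an
    audit of the achieved balance."""

    control_idx: np.ndarray
    block_idx: np.ndarray
    median_abs_dv: float
    n_matched: int
    empty: bool


def match_by_peak_velocity(
    control_velocities: np.ndarray,
    block_velocities: np.ndarray,
    tolerance: float = 0.05,
) -> MatchResult:
    """Greedy nearest-neighbour velocity matching without replacement.

    Block trials are visited in their given (within-block) order; each takes
    the closest remaining control trial by peak velocity.  Pairs whose
    relative velocity difference exceeds ``tolerance`` are dropped.  Returns
    the matched index pairs and a matching report; an empty match is flagged
    rather than raised.
    """
    cv = np.asarray(control_velocities, dtype=float)
    bv = np.asarray(block_velocities, dtype=float)
    if cv.size == 0 or bv.size == 0:
        raise ValueError("both trial sets must be nonempty")
    available = np.ones(cv.size, dtype=bool)
    c_idx, b_idx, dvs = [], [], []
    for j, v in enumerate(bv):
        if not available.any():
            break
        cand = np.flatnonzero(available)
        i = cand[np.argmin(np.abs(cv[cand] - v))]
        if abs(cv[i] - v) / v <= tolerance:
            available[i] = False
            c_idx.append(i)
            b_idx.append(j)
            dvs.append(abs(cv[i] - v))
    n = len(c_idx)
    return MatchResult(
        control_idx=np.array(c_idx, dtype=int),
        block_idx=np.array(b_idx, dtype=int),
        median_abs_dv=float(np.median(dvs)) if n else float("nan"),
        n_matched=n,
        empty=n == 0,
    )


def _rank_bin(rank: int) -> str:
    for name, (lo, hi) in RANK_BINS.items():
        if lo <= rank <= hi:
            return name
    return "post"


def extract_target_sequences(trials: list[TrialRecord], target: int) -> pd.DataFrame:
    """Order the trials to one target by their within-block presentation.

    Returns one row per matching trial with its presentation rank (1..K in
    within-block order) and rank bin (early: ranks 1-2, mid: 3-10, late:
    11-20, post: beyond).  Empty frame if the target never appeared.
    """
    sel = [tr for tr in trials if tr.meta.target == target]
    sel.sort(key=lambda tr: tr.meta.within_block_index)
    rows = [{
        "trial_id": tr.meta.trial_id,
        "within_block_index": tr.meta.within_block_index,
        "rank": k + 1,
        "rank_bin": _rank_bin(k + 1),
    } for k, tr in enumerate(sel)]
    return pd.DataFrame(rows, columns=["trial_id", "within_block_index",
                                       "rank", "rank_bin"])


def normalize_to_early_control(
    values: pd.DataFrame,
    value_col: str = "value",
    monkey_col: str = "monkey",
    reference_mask: pd.Series | np.ndarray | None = None,
) -> pd.Series:
    """Divide each value by its monkey's early-control reference median.

    ``reference_mask`` selects the reference rows (e.g. early trials 1-2 of
    all control blocks); by default a boolean ``is_reference`` column is
    expected.  Raises if any monkey lacks reference values.
    """
    if reference_mask is None:
        if "is_reference" not in values.columns:
            raise ValueError("provide reference_mask or an is_reference column")
        reference_mask = values["is_reference"].to_numpy(bool)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    ref = values.loc[reference_mask].groupby(monkey_col)[value_col].median()
    missing = set(values[monkey_col].unique()) - set(ref.index)
    if missing:
        raise ValueError(f"no early-control reference for monkey(s): {sorted(missing)}")
    return values[value_col] / values[monkey_col].map(ref)


def success_rate(trials: list[TrialRecord]) -> float:
    """Percentage of trials flagged successful."""
    if not trials:
        raise ValueError("empty trial set")
    return 100.0 * sum(tr.meta.success for tr in trials) / len(trials)
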