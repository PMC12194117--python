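"""Per-trial and per-set behavioral measures."""

import numpy as np
import pandas as pd
import pytest

from reachdyn.limb import HandSeries, JointSeries
from reachdyn.metrics import (
    AccelPhase,
    acceleration_phase,
    align_and_rotate,
    decomposition_index,
    decomposition_raster,
    extract_target_sequences,
    match_by_peak_velocity,
    max_perpendicular_deviation,
    net_coupling_impulse,
    normalize_impulses,
    normalize_to_early_control,
    peak_hand_velocity,
    success_rate,
    torque_impulse,
    trajectory_variability,
)
from reachdyn.preprocess import TrialMeta, TrialRecord
from reachdyn.simulate import min_jerk_profile


def make_trial(speed=None, omega=None, pos=None, fs=1000.0, onset=0,
               **meta_kw):
    """Assemble a minimal TrialRecord from explicit channel arrays."""
    n = None
    for arr in (speed, omega, pos):
        if arr is not None:
            n = len(arr)
            break
    assert n is not None
    if omega is None:
        omega = np.zeros((n, 2))
    if pos is None:
        pos = np.zeros((n, 2))
    if speed is None:
        vel = np.zeros((n, 2))
    else:
        vel = np.column_stack([np.asarray(speed), np.zeros(n)])
    js = JointSeries(theta=np.zeros((n, 2)), omega=omega,
                     alpha=np.zeros((n, 2)), fs=fs)
    hand = HandSeries(pos=np.asarray(pos, dtype=float), vel=vel, fs=fs)
    defaults = dict(monkey="m", session="s", subsession=1, block=1,
                    condition="control", target=1, within_block_index=1)
    defaults.update(meta_kw)
    tr = TrialRecord(joint=js, hand=hand, meta=TrialMeta(**defaults))
    tr.onset_index = onset
    return tr


def min_jerk_trial(D=0.04, T=0.4, fs=1000.0):
    _, s, sd, _ = min_jerk_profile(D, T, fs)
    n = len(s)
    js = JointSeries(theta=np.zeros((n, 2)), omega=np.zeros((n, 2)),
                     alpha=np.zeros((n, 2)), fs=fs)
    hand = HandSeries(pos=np.column_stack([s, np.zeros(n)]),
                      vel=np.column_stack([sd, np.zeros(n)]), fs=fs)
    return TrialRecord(joint=js, hand=hand,
                       meta=TrialMeta(monkey="m", session="s", subsession=1,
                                      block=1, condition="control", target=1,
                                      within_block_index=1))


class TestPeakVelocityAndPhase:
    def test_constant_speed(self):
        tr = make_trial(speed=np.full(100, 0.2))
        assert peak_hand_velocity(tr) == pytest.approx(0.2)

    def test_min_jerk_peak(self):
        tr = min_jerk_trial(D=0.04, T=0.4)
        assert peak_hand_velocity(tr) == pytest.approx(0.1875, rel=1e-3)

    def test_accel_phase_ends_at_speed_peak(self):
        tr = min_jerk_trial(D=0.04, T=0.4, fs=1000.0)
        phase = acceleration_phase(tr)
        # min-jerk speed peaks at T/2 (sample 200) +- one sample
        assert abs(phase.end - 200) <= 1

    def test_accel_phase_truncated_trial(self):
        tr = make_trial(speed=np.linspace(0, 0.3, 300), onset=10)
        phase = acceleration_phase(tr)
        assert phase.end == 299

    def test_accel_phase_two_maxima_matches_bruteforce(self):
        t = np.linspace(0, 1, 1000)
        speed = np.sin(np.pi * t) + 0.5 * np.sin(3 * np.pi * t) + 0.01
        tr = make_trial(speed=speed, onset=5)
        phase = acceleration_phase(tr)
        ds = np.diff(speed)
        brute = next(i for i in range(6, 999)
                     if ds[i - 1] > 0 and ds[i] <= 0)
        assert phase.end == brute

    def test_phase_validation(self):
        with pytest.raises(ValueError):
            AccelPhase(start=5, end=5)


class TestTorqueImpulse:
    def test_constant_torque(self):
        phase = AccelPhase(0, 200)
        tq = np.full(300, 0.5)
        assert torque_impulse(tq, phase, fs=1000.0) == pytest.approx(0.1)

    def test_zero_torque(self):
        assert torque_impulse(np.zeros(100), AccelPhase(0, 50), 1000.0) == 0.0

    def test_triangle_area(self):
        tq = np.concatenate([np.linspace(0, 1, 101), np.linspace(1, 0, 101)[1:]])
        got = torque_impulse(tq, AccelPhase(0, 200), fs=1000.0)
        assert got == pytest.approx(0.1, rel=1e-3)

    def test_phase_beyond_series_rejected(self):
        with pytest.raises(ValueError):
            torque_impulse(np.zeros(100), AccelPhase(0, 100), 1000.0)

    def test_additive_over_subintervals(self):
        rng = np.random.default_rng(1)
        tq = rng.normal(size=500)
        whole = torque_impulse(tq, AccelPhase(10, 400), 1000.0)
        parts = (torque_impulse(tq, AccelPhase(10, 200), 1000.0)
                 + torque_impulse(tq, AccelPhase(200, 400), 1000.0))
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_net_coupling_absolute_sum(self, inertial):
        from reachdyn.limb import TorqueDecomposition
        n = 300
        coupling = np.column_stack([np.full(n, -0.5), np.full(n, 0.25)])
        dec = TorqueDecomposition(net=np.zeros((n, 2)), coupling=coupling,
                                  muscle=-coupling, fs=1000.0)
        got = net_coupling_impulse(dec, AccelPhase(0, 200))
        assert got == pytest.approx(0.1 + 0.05)


class TestNormalizeImpulses:
    def test_division_by_max_abs(self):
        out = normalize_impulses(pd.Series([2.0, -4.0, 1.0]))
        np.testing.assert_allclose(out, [0.5, -1.0, 0.25])

    def test_single_target(self):
        assert normalize_impulses(pd.Series([-3.0])).iloc[0] == -1.0

    def test_permutation_equivariance(self):
        vals = pd.Series([2.0, -4.0, 1.0, 3.0])
        perm = [2, 0, 3, 1]
        out1 = normalize_impulses(vals).to_numpy()[perm]
        out2 = normalize_impulses(vals.iloc[perm].reset_index(drop=True)).to_numpy()
        np.testing.assert_allclose(out1, out2)

    def test_control_reference(self):
        out = normalize_impulses(pd.Series([1.0, 2.0]),
                                 reference=pd.Series([-5.0, 2.0]))
        np.testing.assert_allclose(out, [0.2, 0.4])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_impulses(pd.Series([0.0, 0.0]))


class TestDecompositionRaster:
    def test_both_fast_all_zero(self):
        omega = np.full((1000, 2), 1.0)  # 57 deg/s both joints
        tr = make_trial(omega=omega, speed=np.ones(1000))
        assert decomposition_raster(tr).sum() == 0

    def test_single_joint_movement_all_one(self):
        omega = np.column_stack([np.full(1000, 1.0), np.zeros(1000)])
        tr = make_trial(omega=omega, speed=np.ones(1000))
        assert decomposition_raster(tr).sum() == 1000

    def test_exact_pause_window_bins(self):
        n = 2001
        omega = np.full((n, 2), 1.0)
        u = np.arange(n) / (n - 1)
        omega[(u >= 0.2) & (u < 0.5), 0] = 0.0  # shoulder paused [0.2, 0.5)
        tr = make_trial(omega=omega, speed=np.ones(n))
        raster = decomposition_raster(tr)
        expected = np.zeros(1000, dtype=int)
        expected[200:500] = 1
        np.testing.assert_array_equal(raster, expected)

    def test_matches_bruteforce_on_random_patterns(self):
        thr = np.deg2rad(20.0)
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(40, 2000))
            omega = rng.uniform(-1, 1, size=(n, 2))
            tr = make_trial(omega=omega, speed=np.ones(n))
            raster = decomposition_raster(tr)
            below = np.abs(omega) < thr
            flags = below[:, 0] ^ below[:, 1]
            centers = (np.arange(1000) + 0.5) / 1000
            idx = np.rint(centers * (n - 1)).astype(int)
            np.testing.assert_array_equal(raster, flags[idx].astype(int))

    def test_index_time_rescaling_invariant(self):
        rng = np.random.default_rng(3)
        omega = rng.uniform(-1, 1, size=(500, 2))
        tr1 = make_trial(omega=omega, speed=np.ones(500))
        # same motion sampled 3x finer (values repeated): identical
        # normalized-time structure
        omega3 = np.repeat(omega, 3, axis=0)
        tr3 = make_trial(omega=omega3, speed=np.ones(1500))
        i1 = decomposition_index(decomposition_raster(tr1))
        i3 = decomposition_index(decomposition_raster(tr3))
        assert abs(i1 - i3) <= 0.005

    def test_index_values(self):
        assert decomposition_index(np.zeros(1000)) == 0.0
        r = np.zeros(1000)
        r[:300] = 1
        assert decomposition_index(r) == pytest.approx(0.3)


class TestTrajectoryGeometry:
    def test_three_four_five_alignment(self):
        path = np.array([[1.0, 1.0], [2.0, 2.0], [4.0, 5.0]])
        aligned = align_and_rotate(path)
        np.testing.assert_allclose(aligned.xy[0], [0, 0], atol=1e-12)
        np.testing.assert_allclose(aligned.xy[-1], [0, 5.0], atol=1e-12)

    def test_straight_line_zero_deviation(self):
        t = np.linspace(0, 1, 50)[:, None]
        path = np.array([[0.2, 0.1]]) + t * np.array([[0.03, 0.04]])
        aligned = align_and_rotate(path)
        assert np.max(np.abs(aligned.xy[:, 0])) < 1e-12
        assert max_perpendicular_deviation(aligned) < 1e-12

    def test_isometry(self):
        rng = np.random.default_rng(2)
        path = rng.normal(size=(40, 2)).cumsum(axis=0)
        aligned = align_and_rotate(path)
        d0 = np.linalg.norm(np.diff(path, axis=0), axis=1)
        d1 = np.linalg.norm(np.diff(aligned.xy, axis=0), axis=1)
        np.testing.assert_allclose(d0, d1, atol=1e-12)

    def test_semicircle_deviation(self):
        r = 0.02
        ang = np.linspace(-np.pi / 2, np.pi / 2, 201)  # includes the apex
        path = np.column_stack([r * np.cos(ang), r + r * np.sin(ang)])
        aligned = align_and_rotate(path)
        assert max_perpendicular_deviation(aligned) == pytest.approx(r, rel=1e-6)

    def test_injected_bump(self):
        t = np.linspace(0, 1, 500)
        path = np.column_stack([0.003 * np.sin(np.pi * t), 0.05 * t])
        assert max_perpendicular_deviation(align_and_rotate(path)) == \
            pytest.approx(0.003, rel=1e-4)

    def test_degenerate_path_rejected(self):
        with pytest.raises(ValueError):
            align_and_rotate(np.zeros((5, 2)))

    def test_variability(self):
        assert trajectory_variability(np.array([1e-3, 2e-3, 3e-3])) == \
            pytest.approx(1e-3)
        assert trajectory_variability(np.full(5, 0.004)) == 0.0
        with pytest.raises(ValueError):
            trajectory_variability(np.array([0.001]))

    def test_variability_estimates_generator_sd(self):
        rng = np.random.default_rng(0)
        sigma = 0.002
        devs = np.abs(rng.normal(0, sigma, size=500))
        est = trajectory_variability(devs)
        truth = sigma * np.sqrt(1 - 2 / np.pi)  # SD of |N(0, sigma)|
        assert abs(est - truth) / truth < 0.15


class TestVelocityMatching:
    def test_identical_multisets(self):
        v = np.array([0.2, 0.21, 0.19])
        m = match_by_peak_velocity(v, v.copy())
        assert m.n_matched == 3
        assert m.median_abs_dv == 0.0

    def test_disjoint_ranges_empty_with_flag(self):
        m = match_by_peak_velocity(np.array([0.4, 0.45]), np.array([0.1, 0.12]))
        assert m.empty and m.n_matched == 0

    def test_greedy_example_agrees_with_exhaustive(self):
        controls = np.array([0.20, 0.18, 0.16])
        blocks = np.array([0.185, 0.155])
        m = match_by_peak_velocity(controls, blocks)
        assert sorted(controls[m.control_idx]) == [0.16, 0.18]
        # exhaustive optimal assignment over all injective maps
        import itertools
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(3), 2):
            cost = sum(abs(controls[c] - blocks[b])
                       for b, c in enumerate(perm))
            if cost < best_cost:
                best, best_cost = perm, cost
        assert sorted(controls[list(best)]) == sorted(controls[m.control_idx])

    def test_tolerance_drops_far_pairs(self):
        m = match_by_peak_velocity(np.array([0.2]), np.array([0.3, 0.201]))
        assert m.n_matched == 1
        assert m.block_idx.tolist() == [1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            match_by_peak_velocity(np.array([]), np.array([0.2]))


class TestSequencesAndNormalization:
    def _trials(self, idx_targets):
        out = []
        for i, (w, tgt) in enumerate(idx_targets):
            out.append(make_trial(speed=np.ones(10), within_block_index=w,
                                  target=tgt, trial_id=i + 1))
        return out

    def test_rank_assignment(self):
        trials = self._trials([(3, 1), (7, 1), (21, 1), (5, 2)])
        seq = extract_target_sequences(trials, target=1)
        assert seq["rank"].tolist() == [1, 2, 3]
        assert seq["within_block_index"].tolist() == [3, 7, 21]

    def test_absent_target_empty(self):
        trials = self._trials([(1, 2)])
        assert extract_target_sequences(trials, target=5).empty

    def test_rank_bins(self):
        trials = self._trials([(i, 1) for i in range(1, 26)])
        seq = extract_target_sequences(trials, target=1)
        assert (seq.loc[seq["rank"] <= 2, "rank_bin"] == "early").all()
        assert (seq.loc[(seq["rank"] >= 3) & (seq["rank"] <= 10),
                        "rank_bin"] == "mid").all()
        assert (seq.loc[(seq["rank"] >= 11) & (seq["rank"] <= 20),
                        "rank_bin"] == "late").all()
        assert (seq.loc[seq["rank"] > 20, "rank_bin"] == "post").all()

    def test_normalize_to_early_control(self):
        df = pd.DataFrame({
            "monkey": ["a"] * 3 + ["b"] * 3,
            "value": [0.2, 0.2, 0.19, 0.4, 0.4, 0.35],
            "is_reference": [True, True, False, True, True, False],
        })
        out = normalize_to_early_control(df)
        assert out.iloc[2] == pytest.approx(0.95)
        assert out.iloc[5] == pytest.approx(0.875)
        # normalization removes the between-monkey baseline difference
        assert out.iloc[0] == out.iloc[3] == 1.0

    def test_missing_reference_names_monkey(self):
        df = pd.DataFrame({"monkey": ["a", "b"], "value": [1.0, 2.0],
                           "is_reference": [True, False]})
        with pytest.raises(ValueError, match="b"):
            normalize_to_early_control(df)


class TestSuccessRate:
    def test_fraction(self):
        trials = [make_trial(speed=np.ones(5), success=(i < 86))
                  for i in range(100)]
        assert success_rate(trials) == pytest.approx(86.0)

    def test_all_success(self):
        trials = [make_trial(speed=np.ones(5), success=True) for _ in range(5)]
        assert success_rate(trials) == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            success_rate([])
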