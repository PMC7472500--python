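"""Cardan decomposition, filtering, baseline subtraction and peaks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from footkin import (
    JointAngleSeries,
    TrajectorySet,
    compose_zxy,
    compute_baseline,
    euler_zxy,
    extract_peaks,
    filter_trajectories,
    joint_angles,
    register_model,
    relative_rotation,
    rotation_matrix,
    subtract_baseline,
)
from footkin.core import PoseSeries

from conftest import random_rotation


def _pose(R, n=1):
    R = np.broadcast_to(R, (n, 3, 3))
    return PoseSeries("seg", R.copy(), np.zeros((n, 3)))


class TestRelativeRotation:
    def test_identical_poses_give_identity(self, rng):
        R = random_rotation(rng)
        rel = relative_rotation(_pose(R, 5), _pose(R, 5))
        np.testing.assert_allclose(rel, np.broadcast_to(np.eye(3), (5, 3, 3)), atol=1e-14)

    def test_identity_parent_passes_child_through(self):
        Rz30 = rotation_matrix("z", 30.0)
        rel = relative_rotation(_pose(Rz30), _pose(np.eye(3)))
        np.testing.assert_allclose(rel[0], Rz30, atol=1e-14)

    def test_reconstruction_oracle(self, rng):
        # R_parent @ R_rel must reproduce R_child
        for _ in range(25):
            Rc, Rp = random_rotation(rng), random_rotation(rng)
            rel = relative_rotation(_pose(Rc), _pose(Rp))
            np.testing.assert_allclose(Rp @ rel[0], Rc, atol=1e-12)

    def test_inverse_symmetry(self, rng):
        Ra, Rb = random_rotation(rng), random_rotation(rng)
        ab = relative_rotation(_pose(Ra), _pose(Rb))[0]
        ba = relative_rotation(_pose(Rb), _pose(Ra))[0]
        np.testing.assert_allclose(ab @ ba, np.eye(3), atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            relative_rotation(_pose(np.eye(3), 3), _pose(np.eye(3), 4))


class TestEulerZXY:
    def test_identity_is_zero(self):
        ang, gim = euler_zxy(np.eye(3))
        np.testing.assert_allclose(ang, [0, 0, 0], atol=1e-14)
        assert not gim.any()

    def test_round_trip_against_composition(self):
        # independent oracle: compose with explicit per-axis matrices, decompose
        a = np.array([30.0, -150.0, 7.0])
        b = np.array([20.0, -45.0, 89.0])
        c = np.array([10.0, 120.0, -179.0])
        A, B, C = np.meshgrid(a, b, c, indexing="ij")
        R = compose_zxy(A.ravel(), B.ravel(), C.ravel())
        ang, gim = euler_zxy(R)
        expected = np.stack([A.ravel(), B.ravel(), C.ravel()], axis=-1)
        assert not gim.any()
        np.testing.assert_allclose(ang, expected, atol=1e-9)

    def test_matches_scipy_rotation(self, rng):
        # cross-check the decomposition against an independent library routine
        R = np.stack([random_rotation(rng) for _ in range(50)])
        ours, _ = euler_zxy(R)
        theirs = Rotation.from_matrix(R).as_euler("ZXY", degrees=True)
        np.testing.assert_allclose(ours, theirs, atol=1e-9)

    @settings(max_examples=60, derandomize=True)
    @given(
        a=st.floats(-179, 180), b=st.floats(-89.5, 89.5), c=st.floats(-179, 180)
    )
    def test_round_trip_property(self, a, b, c):
        ang, _ = euler_zxy(compose_zxy(a, b, c))
        np.testing.assert_allclose(ang, [a, b, c], atol=1e-7)

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_gimbal_lock_flagged(self, sign):
        ang, gim = euler_zxy(rotation_matrix("x", [sign * 90.0]))
        assert gim.all()
        assert ang[0, 1] == pytest.approx(sign * 90.0)
        assert ang[0, 2] == 0.0  # third angle fixed to zero, not NaN

    def test_gimbal_absorbs_coupled_rotation(self):
        # at theta_x = +90 only theta_z - theta_y is observable; with
        # theta_y := 0 the reported theta_z must reproduce the matrix
        R = compose_zxy(40.0, 90.0, 15.0)
        ang, gim = euler_zxy(R)
        assert gim.all()
        np.testing.assert_allclose(compose_zxy(*ang), R, atol=1e-12)

    def test_extrinsic_convention_round_trip(self):
        a, b, c = 25.0, -40.0, 110.0
        R = rotation_matrix("y", c) @ rotation_matrix("x", b) @ rotation_matrix("z", a)
        ang, _ = euler_zxy(R, convention="extrinsic")
        np.testing.assert_allclose(ang, [a, b, c], atol=1e-9)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            euler_zxy(np.eye(3) * 1.01)


class TestJointAngles:
    def test_single_rigid_body_gives_constant_zero(self, geometry, rng):
        # all segments share one rigid body -> no relative motion anywhere
        from footkin import simulate_static

        base = simulate_static(geometry, duration_s=0.1, rate_hz=100)
        R0 = random_rotation(rng)
        frames = [base.markers, {n: a @ R0.T + 5.0 for n, a in base.markers.items()}]
        traj = TrajectorySet(
            {n: np.vstack([f[n] for f in frames]) for n in base.names}, 100.0
        )
        angles = joint_angles(traj, register_model("new"))
        assert set(angles) == {"Met_Hal", "Cal_Met", "Sha_Cal"}
        for series in angles.values():
            np.testing.assert_allclose(series.angles[0], series.angles[-1], atol=1e-9)

    def test_missing_marker_only_fails_requested_joint(self, geometry):
        from footkin import simulate_static

        traj = simulate_static(geometry, duration_s=0.05, rate_hz=100)
        traj = TrajectorySet(
            {n: a for n, a in traj.markers.items() if n != "P1"}, traj.rate
        )
        spec = register_model("new")
        out = joint_angles(traj, spec, joints=("Cal_Met", "Sha_Cal"))
        assert set(out) == {"Cal_Met", "Sha_Cal"}
        with pytest.raises(KeyError, match="P1"):
            joint_angles(traj, spec, joints=("Met_Hal",))


def _sine_traj(freq_hz, rate=100.0, seconds=4.0, amp=10.0):
    t = np.arange(int(rate * seconds)) / rate
    sig = amp * np.sin(2 * np.pi * freq_hz * t)
    arr = np.stack([sig, np.full_like(sig, 3.0), np.zeros_like(sig)], axis=1)
    return TrajectorySet({"M": arr}, rate), sig


class TestFilter:
    def test_dc_preserved_exactly(self):
        traj = TrajectorySet({"M": np.full((200, 3), 17.5)}, 100.0)
        out = filter_trajectories(traj)
        np.testing.assert_allclose(out["M"], traj["M"], atol=1e-9)

    def test_passband_amplitude_and_zero_lag(self):
        traj, sig = _sine_traj(1.0)
        out = filter_trajectories(traj)["M"][:, 0]
        core = slice(50, -50)  # ignore edge transients
        assert np.abs(out[core]).max() >= 0.99 * np.abs(sig[core]).max()
        # zero phase: cross-correlation peak at zero lag
        xc = np.correlate(out[core] - out[core].mean(), sig[core] - sig[core].mean(), "full")
        assert np.argmax(xc) == len(sig[core]) - 1

    def test_stopband_attenuation(self):
        traj, sig = _sine_traj(30.0)
        out = filter_trajectories(traj)["M"][:, 0]
        assert np.abs(out[100:-100]).max() <= 0.1 * np.abs(sig).max()

    def test_linearity(self, rng):
        n = 300
        s1 = rng.normal(size=(n, 3))
        s2 = rng.normal(size=(n, 3))
        f = lambda s: filter_trajectories(TrajectorySet({"M": s}, 100.0))["M"]
        np.testing.assert_allclose(f(2.5 * s1 + s2), 2.5 * f(s1) + f(s2), atol=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            filter_trajectories(TrajectorySet({"M": np.zeros((10, 3))}, 100.0))

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            filter_trajectories(TrajectorySet({"M": np.zeros((200, 3))}, 100.0), cutoff_hz=50.0)


class TestBaselineAndPeaks:
    def test_subtraction_arithmetic(self):
        series = JointAngleSeries("J", np.array([[10.0, 0.0, 0.0]]), 100.0)
        out = subtract_baseline(series, {"J": np.array([2.0, -1.0, 0.5])})
        np.testing.assert_allclose(out.angles, [[8.0, 1.0, -0.5]])
        assert out.baseline_subtracted

    def test_self_baseline_zeroes(self):
        series = JointAngleSeries("J", np.tile([3.0, 4.0, 5.0], (10, 1)), 100.0)
        base = compute_baseline({"J": series})
        out = subtract_baseline(series, base)
        np.testing.assert_allclose(out.angles, 0.0, atol=1e-12)

    def test_missing_joint_rejected(self):
        series = JointAngleSeries("J", np.zeros((5, 3)), 100.0)
        with pytest.raises(KeyError, match="'J'"):
            subtract_baseline(series, {"other": np.zeros(3)})

    def test_noisy_static_baseline_centres_the_series(self, rng):
        # 15 s static trial with zero-mean noise sigma = 0.1 deg
        n, sigma = 1500, 0.1
        noise = rng.normal(0.0, sigma, (n, 3))
        series = JointAngleSeries("J", np.array([5.0, -3.0, 1.0]) + noise, 100.0)
        out = subtract_baseline(series, compute_baseline({"J": series}))
        assert np.all(np.abs(out.angles.mean(axis=0)) < 3 * sigma / np.sqrt(n))

    def test_peaks_match_brute_force(self, rng):
        arr = rng.normal(size=(500, 3)) * 20
        series = JointAngleSeries("J", arr, 100.0)
        pk = extract_peaks(series, window=(120, 380), task="gait")
        np.testing.assert_allclose(pk.maxima, arr[120:380].max(axis=0))
        np.testing.assert_allclose(pk.minima, arr[120:380].min(axis=0))
        assert np.all(pk.maxima >= pk.minima)

    def test_constructed_peak_value(self):
        t = np.linspace(0, np.pi, 201)  # odd count: the pi/2 sample is exact
        arr = np.zeros((201, 3))
        arr[:, 0] = 37.6 * np.sin(t)
        pk = extract_peaks(JointAngleSeries("J", arr, 100.0), task="calf_raise")
        assert pk.maxima[0] == pytest.approx(37.6, abs=1e-3)

    def test_empty_window_rejected(self):
        series = JointAngleSeries("J", np.zeros((10, 3)), 100.0)
        with pytest.raises(ValueError, match="window"):
            extract_peaks(series, window=(5, 5))

    def test_injected_peak_recovery_over_trials(self, rng):
        # seven synthetic drop-jump trials with known injected peaks: the
        # across-trial mean and SD of extracted maxima equal the closed form
        injected = np.array([24.0, 26.5, 25.1, 27.3, 23.8, 26.0, 25.5])
        maxima = []
        for peak in injected:
            t = np.linspace(0, np.pi, 151)
            arr = np.zeros((151, 3))
            arr[:, 0] = peak * np.sin(t)
            pk = extract_peaks(JointAngleSeries("J", arr, 100.0), task="drop_jump")
            maxima.append(pk.maxima[0])
        maxima = np.array(maxima)
        assert maxima.mean() == pytest.approx(injected.mean(), abs=1e-3)
        assert maxima.std(ddof=1) == pytest.approx(injected.std(ddof=1), abs=1e-3)
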