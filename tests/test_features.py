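"""The four lift-phase kinematic features and their geometric invariances."""
import numpy as np
import pytest

import transferkin as tk
from transferkin.errors import DegenerateGeometryError
from transferkin.features import (
    TrunkBasis,
    angle_between,
    dswp,
    elevation,
    extract_features,
    plane_of_elevation,
    trunk_flexion,
)
from transferkin.harmonize import CANONICAL_JOINTS, CanonicalFrame, CanonicalSequence
from transferkin.segmentation import PhaseSegmentation


def make_frame(pelvis, spine_upper, sl, sr, el):
    return CanonicalFrame(
        timestamp=0.0,
        pelvis=np.asarray(pelvis, float),
        spine_upper=np.asarray(spine_upper, float),
        shoulder_left=np.asarray(sl, float),
        shoulder_right=np.asarray(sr, float),
        elbow_left=np.asarray(el, float),
        validity={j: True for j in CANONICAL_JOINTS},
    )


def upright_frame(arm_dir, trunk_top=(0, 500, 0)):
    """Upright trunk at origin, shoulders along x, elbow displaced by arm_dir."""
    sl = np.array([-180.0, 500.0, 0.0])
    return make_frame(
        (0, 0, 0), trunk_top, sl, (180, 500, 0), sl + 300.0 * np.asarray(arm_dir, float)
    )


class TestAngleBetween:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1, 1, 0), (1, 0, 0), 45.0),
            ((1, 0, 0), (-1, 0, 0), 180.0),
        ],
    )
    def test_known_angles(self, u, v, expected):
        assert angle_between(u, v) == pytest.approx(expected, abs=1e-10)

    def test_zero_vector_raises(self):
        with pytest.raises(DegenerateGeometryError):
            angle_between((0, 0, 0), (1, 0, 0))

    @pytest.mark.parametrize("seed", range(10))
    def test_range_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=3), rng.normal(size=3)
        a = angle_between(u, v)
        assert 0.0 <= a <= 180.0
        assert a == pytest.approx(angle_between(v, u))


class TestTrunkFlexion:
    def test_upright_is_zero(self):
        assert trunk_flexion(upright_frame((0, -1, 0))) == pytest.approx(0.0)

    def test_45_degree_lean(self):
        f = make_frame((0, 0, 0), (0, 500 / np.sqrt(2), 500 / np.sqrt(2)),
                       (-180, 400, 0), (180, 400, 0), (-180, 100, 0))
        assert trunk_flexion(f) == pytest.approx(45.0)

    def test_horizontal_trunk_is_90(self):
        f = make_frame((0, 0, 0), (500, 0, 0), (-180, 0, 0), (180, 0, 0), (0, -300, 0))
        assert trunk_flexion(f) == pytest.approx(90.0)


class TestElevation:
    def test_arm_hanging_is_180(self):
        assert elevation(upright_frame((0, -1, 0))) == pytest.approx(180.0)

    def test_arm_along_trunk_is_0(self):
        assert elevation(upright_frame((0, 1, 0))) == pytest.approx(0.0)

    def test_arm_perpendicular_is_90(self):
        assert elevation(upright_frame((1, 0, 0))) == pytest.approx(90.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_arccos(self, seed):
        """Independent oracle: arccos from raw coordinates, no shared code."""
        rng = np.random.default_rng(seed)
        pts = {j: rng.normal(0, 400, 3) for j in CANONICAL_JOINTS}
        f = make_frame(pts["pelvis"], pts["spine_upper"], pts["shoulder_left"],
                       pts["shoulder_right"], pts["elbow_left"])
        t = pts["spine_upper"] - pts["pelvis"]
        a = pts["elbow_left"] - pts["shoulder_left"]
        expected = np.degrees(
            np.arccos(np.dot(t, a) / (np.linalg.norm(t) * np.linalg.norm(a)))
        )
        assert elevation(f) == pytest.approx(expected, abs=1e-9)


class TestPlaneOfElevation:
    def test_arm_straight_ahead_is_zero(self):
        # chest normal = cross(+y trunk, +x across) = -z... arm toward -z
        f = upright_frame((0, 0, -1))
        basis = TrunkBasis.from_frame(f)
        arm = f.elbow_left - f.shoulder_left
        assert np.allclose(np.cross(basis.chest_normal, arm), 0)
        assert plane_of_elevation(f) == pytest.approx(0.0, abs=1e-9)

    def test_arm_abducted_left_is_90(self):
        # straight out along -shoulder_across (away from the right shoulder)
        f = upright_frame((-1, 0, 0))
        assert plane_of_elevation(f) == pytest.approx(90.0)

    def test_arm_parallel_to_trunk_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            plane_of_elevation(upright_frame((0, 1, 0)))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_gram_schmidt_oracle(self, seed):
        """Independent projection oracle built by Gram-Schmidt."""
        rng = np.random.default_rng(seed)
        pts = {j: rng.normal(0, 400, 3) for j in CANONICAL_JOINTS}
        f = make_frame(pts["pelvis"], pts["spine_upper"], pts["shoulder_left"],
                       pts["shoulder_right"], pts["elbow_left"])
        t = pts["spine_upper"] - pts["pelvis"]
        that = t / np.linalg.norm(t)
        across = pts["shoulder_right"] - pts["shoulder_left"]
        normal = np.cross(t, across)
        arm = pts["elbow_left"] - pts["shoulder_left"]
        pn = normal - np.dot(normal, that) * that
        pa = arm - np.dot(arm, that) * that
        expected = np.degrees(
            np.arccos(
                np.clip(
                    np.dot(pn, pa) / (np.linalg.norm(pn) * np.linalg.norm(pa)), -1, 1
                )
            )
        )
        assert plane_of_elevation(f) == pytest.approx(expected, abs=1e-9)

    def test_chest_normal_orthogonality(self):
        rng = np.random.default_rng(5)
        pts = {j: rng.normal(0, 400, 3) for j in CANONICAL_JOINTS}
        basis = TrunkBasis.from_frame(
            make_frame(pts["pelvis"], pts["spine_upper"], pts["shoulder_left"],
                       pts["shoulder_right"], pts["elbow_left"])
        )
        assert abs(np.dot(basis.chest_normal, basis.trunk_vector)) < 1e-6 * np.linalg.norm(
            basis.chest_normal
        ) * np.linalg.norm(basis.trunk_vector)
        assert abs(np.dot(basis.chest_normal, basis.shoulder_across)) < 1e-6 * np.linalg.norm(
            basis.chest_normal
        ) * np.linalg.norm(basis.shoulder_across)


class TestDswp:
    def test_arithmetic(self):
        x = np.linspace(100.0, 600.0, 100)
        seg = PhaseSegmentation(0, 99, filtered_x=x)
        assert dswp(x, seg) == pytest.approx(50.0)

    def test_backward_transfer_positive_after_normalization(self):
        x = np.linspace(600.0, 100.0, 100)
        seg = PhaseSegmentation(0, 99, filtered_x=-x, direction=-1)
        assert dswp(x, seg) == pytest.approx(50.0)

    def test_simulator_ground_truth(self):
        trial = tk.simulate_trial(tk.TransferProfile(pelvis_travel=477.5), seed=0)
        canon = tk.harmonize(trial.sequence)
        seg = tk.detect_phases(canon.positions["pelvis"][:, 0], 30.0)
        assert dswp(canon.positions["pelvis"][:, 0], seg) == pytest.approx(47.75, abs=0.5)


def build_canonical(positions, timestamps=None, side="left"):
    n = len(next(iter(positions.values())))
    return CanonicalSequence(
        timestamps=np.arange(n) / 30.0 if timestamps is None else timestamps,
        positions={j: np.asarray(p, float) for j, p in positions.items()},
        valid={j: np.ones(n, bool) for j in positions},
        side=side,
    )


class TestExtractFeatures:
    def constant_pose_sequence(self, n=40):
        # arm down-and-forward: every feature, including LPOE, is defined
        f = upright_frame((0, -1, -1))
        shift = np.column_stack([np.linspace(0, 500, n), np.zeros(n), np.zeros(n)])
        pos = {j: np.tile(getattr(f, j), (n, 1)) + shift for j in CANONICAL_JOINTS}
        return build_canonical(pos)

    def test_constant_pose_means_equal_single_frame_value(self):
        canon = self.constant_pose_sequence()
        seg = PhaseSegmentation(5, 30, filtered_x=canon.positions["pelvis"][:, 0])
        fs = extract_features(canon, seg)
        f0 = canon.frame(10)
        assert fs.tf == pytest.approx(trunk_flexion(f0))
        assert fs.le == pytest.approx(elevation(f0))
        assert fs.lpoe == pytest.approx(plane_of_elevation(f0))

    def test_linear_tf_ramp_average(self):
        """TF ramping 10 -> 50 degrees over the lift averages to ~30."""
        n = 41
        angles = np.radians(np.linspace(10, 50, n))
        pelvis = np.zeros((n, 3))
        su = np.column_stack([np.zeros(n), 500 * np.cos(angles), 500 * np.sin(angles)])
        sl = su + [-180, 0, 0]
        sr = su + [180, 0, 0]
        el = sl + [0, -300, 0]
        canon = build_canonical(
            {"pelvis": pelvis, "spine_upper": su, "shoulder_left": sl,
             "shoulder_right": sr, "elbow_left": el}
        )
        seg = PhaseSegmentation(0, n - 1, filtered_x=np.linspace(0, 500, n))
        fs = extract_features(canon, seg)
        assert fs.tf == pytest.approx(30.0, abs=1e-6)

    def test_invalid_frames_dropped_per_feature_and_reported(self):
        canon = self.constant_pose_sequence()
        canon.valid["elbow_left"][10:20] = False
        seg = PhaseSegmentation(5, 34, filtered_x=canon.positions["pelvis"][:, 0])
        fs = extract_features(canon, seg)
        assert fs.dropped_fraction["le"] == pytest.approx(10 / 30)
        assert fs.low_quality  # > 25% dropped
        assert np.isfinite(fs.le)

    def test_all_frames_invalid_marks_feature_missing(self):
        canon = self.constant_pose_sequence()
        canon.valid["elbow_left"][:] = False
        seg = PhaseSegmentation(5, 30, filtered_x=canon.positions["pelvis"][:, 0])
        fs = extract_features(canon, seg)
        assert np.isnan(fs.le)
        assert "le" in fs.missing
        assert np.isfinite(fs.tf)  # trunk features unaffected

    def test_simulator_noiseless_recovery(self):
        prof = tk.TransferProfile(pelvis_travel=520.0, tf_peak=28.0, le_mean=50.0,
                                  lpoe_mean=75.0)
        trial = tk.simulate_trial(prof, seed=0)
        canon = tk.harmonize(trial.sequence)
        seg = tk.detect_phases(canon.positions["pelvis"][:, 0], 30.0)
        fs = extract_features(canon, seg)
        assert fs.dswp == pytest.approx(trial.truth.dswp, abs=0.5)
        for name in ("lpoe", "le", "tf"):
            assert getattr(fs, name) == pytest.approx(getattr(trial.truth, name), abs=1.0)


class TestGeometricInvariance:
    """Angles are invariant to translation and uniform scaling; LE and LPOE
    to all rotations; TF only to rotations about the lab vertical."""

    def random_valid_frame(self, seed):
        trial = tk.simulate_trial(tk.TransferProfile(), seed=seed)
        canon = tk.harmonize(trial.sequence)
        return canon.frame(70)  # mid-lift

    def transform(self, frame, A=None, shift=0.0, scale=1.0):
        pts = {}
        for j in CANONICAL_JOINTS:
            p = frame.position(j) * scale + shift
            if A is not None:
                p = A @ p
            pts[j] = p
        return make_frame(pts["pelvis"], pts["spine_upper"], pts["shoulder_left"],
                          pts["shoulder_right"], pts["elbow_left"])

    @staticmethod
    def rot_y(deg):
        c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

    @staticmethod
    def rot_x(deg):
        c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    def test_translation_and_scale_invariance(self):
        f = self.random_valid_frame(1)
        g = self.transform(f, shift=np.array([120.0, -40.0, 310.0]), scale=2.5)
        for fn in (trunk_flexion, elevation, plane_of_elevation):
            assert fn(g) == pytest.approx(fn(f), abs=1e-9)

    def test_rotation_about_vertical_preserves_all(self):
        f = self.random_valid_frame(2)
        g = self.transform(f, A=self.rot_y(73.0))
        for fn in (trunk_flexion, elevation, plane_of_elevation):
            assert fn(g) == pytest.approx(fn(f), abs=1e-8)

    def test_general_rotation_preserves_le_lpoe_but_not_tf(self):
        f = self.random_valid_frame(3)
        g = self.transform(f, A=self.rot_x(40.0))
        assert elevation(g) == pytest.approx(elevation(f), abs=1e-8)
        assert plane_of_elevation(g) == pytest.approx(plane_of_elevation(f), abs=1e-8)
        # TF references the lab vertical, so tilting the lab frame changes it
        assert abs(trunk_flexion(g) - trunk_flexion(f)) > 1.0

    def test_time_reversal_leaves_angle_means_unchanged(self):
        trial = tk.simulate_trial(tk.TransferProfile(), seed=5)
        canon = tk.harmonize(trial.sequence)
        seg = tk.detect_phases(canon.positions["pelvis"][:, 0], 30.0)
        fs = extract_features(canon, seg)
        n = canon.n_frames
        rev = CanonicalSequence(
            timestamps=canon.timestamps,
            positions={j: canon.positions[j][::-1].copy() for j in canon.positions},
            valid={j: canon.valid[j][::-1].copy() for j in canon.valid},
        )
        i0, i1 = n - 1 - seg.lift_end_idx, n - 1 - seg.lift_start_idx
        seg_rev = PhaseSegmentation(
            i0, i1, filtered_x=-seg.filtered_x[::-1], direction=-1
        )
        fs_rev = extract_features(rev, seg_rev)
        for name in ("lpoe", "le", "tf"):
            assert getattr(fs_rev, name) == pytest.approx(getattr(fs, name), abs=1e-9)
        # raw displacement negates; orientation normalization restores the sign
        assert fs_rev.dswp == pytest.approx(fs.dswp, abs=1e-9)
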