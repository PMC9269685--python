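"""The synthetic transfer generator: determinism, ground-truth recovery,
noise-model behaviour and session structure."""
import numpy as np
import pytest

import transferkin as tk
from transferkin.errors import MissingDataError, TransferKinError
from transferkin.simulate import simulate_session, simulate_trial


def extract(trial, **kw):
    canon = tk.harmonize(trial.sequence, side=trial.profile.side)
    px = canon.positions["pelvis"][:, 0].copy()
    px[~canon.valid["pelvis"]] = np.nan
    seg = tk.detect_phases(px, trial.profile.rate)
    return tk.extract_features(canon, seg, **kw), seg


class TestSimulateTrial:
    def test_same_seed_bit_identical(self):
        a = simulate_trial(tk.TransferProfile(), tk.SensorNoiseModel(jitter_sd=3), seed=7)
        b = simulate_trial(tk.TransferProfile(), tk.SensorNoiseModel(jitter_sd=3), seed=7)
        assert a.sequence == b.sequence

    def test_different_seed_differs(self):
        a = simulate_trial(tk.TransferProfile(), tk.SensorNoiseModel(jitter_sd=3), seed=7)
        b = simulate_trial(tk.TransferProfile(), tk.SensorNoiseModel(jitter_sd=3), seed=8)
        assert a.sequence != b.sequence

    @pytest.mark.parametrize("sensor", ["kinect_v2", "kinect_azure", "realsense"])
    def test_noiseless_end_to_end_recovery_all_sensors(self, sensor):
        """|extracted - truth| < 1 degree / 0.5 cm with no noise."""
        trial = simulate_trial(tk.TransferProfile(), seed=0, sensor=sensor)
        fs, _ = extract(trial)
        assert fs.dswp == pytest.approx(trial.truth.dswp, abs=0.5)
        for name in ("lpoe", "le", "tf"):
            assert getattr(fs, name) == pytest.approx(getattr(trial.truth, name), abs=1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_noiseless_recovery_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        prof = tk.TransferProfile(
            pelvis_travel=float(rng.uniform(300, 650)),
            tf_peak=float(rng.uniform(15, 50)),
            le_mean=float(rng.uniform(25, 70)),
            lpoe_mean=float(rng.uniform(50, 120)),
            pre_s=float(rng.uniform(1.5, 3.0)),
            lift_s=float(rng.uniform(0.7, 1.6)),
            post_s=float(rng.uniform(1.5, 3.0)),
        )
        trial = simulate_trial(prof, seed=seed)
        fs, _ = extract(trial)
        assert fs.dswp == pytest.approx(trial.truth.dswp, abs=0.5)
        for name in ("lpoe", "le", "tf"):
            assert getattr(fs, name) == pytest.approx(getattr(trial.truth, name), abs=1.0)

    def test_right_side_transfer_recovers_truth(self):
        trial = simulate_trial(tk.TransferProfile(side="right"), seed=2)
        fs, _ = extract(trial)
        for name in ("lpoe", "le", "tf"):
            assert getattr(fs, name) == pytest.approx(getattr(trial.truth, name), abs=1.0)

    def test_pelvis_lag_shifts_segmentation(self):
        """A 0.1 s pelvis reporting lag delays the detected window ~3 frames."""
        trial = simulate_trial(
            tk.TransferProfile(), tk.SensorNoiseModel(pelvis_lag=0.1), seed=1
        )
        _, seg = extract(trial)
        assert 2 <= seg.lift_start_idx - trial.truth_lift[0] <= 4
        assert 2 <= seg.lift_end_idx - trial.truth_lift[1] <= 4

    def test_heavy_dropout_fails_loudly(self):
        trial = simulate_trial(
            tk.TransferProfile(), tk.SensorNoiseModel(dropout_prob=0.9), seed=0
        )
        canon = tk.harmonize(trial.sequence)
        px = canon.positions["pelvis"][:, 0].copy()
        px[~canon.valid["pelvis"]] = np.nan
        with pytest.raises(MissingDataError):
            tk.detect_phases(px, 30.0)

    def test_bias_moves_feature(self):
        """A forward pelvis bias tilts the apparent trunk, shifting TF."""
        noise = tk.SensorNoiseModel(bias={"Pelvis": (0.0, 0.0, 200.0)})
        trial = simulate_trial(tk.TransferProfile(), noise, seed=0)
        fs, _ = extract(trial)
        assert abs(fs.tf - trial.truth.tf) > 5.0

    def test_invalid_profile_rejected(self):
        with pytest.raises(TransferKinError):
            tk.TransferProfile(pelvis_travel=50.0)
        with pytest.raises(TransferKinError):
            tk.TransferProfile(tf_peak=200.0)


class TestSimulateSession:
    def test_phase2_session_shape(self):
        """3 subjects x 50 trials x 2 sensors -> 150 recordings per sensor."""
        design = tk.SessionDesign(
            n_subjects=3,
            trials_per_subject=50,
            plan=("good", "feet", "trunk", "arm", "fist"),
        )
        session = simulate_session(design, seed=0)
        for seqs in session.recordings.values():
            assert len(seqs) == 150
        assert session.truth_scores.n_trials == 150
        assert len(session.truth_features) == 150
        # each type appears 10x per subject under the cycled plan
        counts = session.truth_features.groupby(
            ["subject_id", "transfer_type"]
        ).size()
        assert (counts == 10).all()

    def test_determinism(self):
        design = tk.SessionDesign(n_subjects=2, trials_per_subject=2)
        s1 = simulate_session(design, seed=5)
        s2 = simulate_session(design, seed=5)
        for sensor in design.sensors:
            for a, b in zip(s1.recordings[sensor], s2.recordings[sensor]):
                assert a == b

    def test_adding_sensor_does_not_perturb_existing_trials(self):
        base = tk.SessionDesign(
            n_subjects=2,
            trials_per_subject=2,
            sensors={"kinect_azure": tk.SensorNoiseModel(jitter_sd=2.0)},
        )
        extended = tk.SessionDesign(
            n_subjects=2,
            trials_per_subject=2,
            sensors={
                "kinect_azure": tk.SensorNoiseModel(jitter_sd=2.0),
                "kinect_v2": tk.SensorNoiseModel(jitter_sd=4.0),
            },
        )
        a = simulate_session(base, seed=3)
        b = simulate_session(extended, seed=3)
        for x, y in zip(a.recordings["kinect_azure"], b.recordings["kinect_azure"]):
            assert x == y

    def test_identical_sensors_give_unit_inter_icc(self):
        noise = tk.SensorNoiseModel(jitter_sd=0.0)
        design = tk.SessionDesign(
            n_subjects=4,
            trials_per_subject=3,
            sensors={"kinect_azure": noise, "kinect_v2": noise},
        )
        session = simulate_session(design, seed=1)
        feats = {}
        for sensor, seqs in session.recordings.items():
            rows = []
            for seq in seqs:
                canon = tk.harmonize(seq)
                seg = tk.detect_phases(canon.positions["pelvis"][:, 0], 30.0)
                fs = tk.extract_features(canon, seg)
                rows.append(fs.as_dict())
            import pandas as pd

            feats[sensor] = pd.DataFrame(rows)
        report = tk.reliability_report(feats)
        assert (report.inter["icc"] > 0.999).all()

    def test_icc_recovery_matches_variance_ratio(self):
        """between-subject var 9, within 1 on TF: intra ICC ~ 0.9 (feature
        level, moderate n)."""
        rng = np.random.default_rng(0)
        n = 200
        x = rng.normal(0, 3, (n, 1)) + rng.normal(0, 1.0, (n, 2))
        assert tk.icc(x, "ICC_3_1").icc == pytest.approx(0.9, abs=0.05)

    def test_jitter_monotonically_degrades_icc(self):
        """More sensor jitter never increases inter-sensor reliability."""
        import pandas as pd

        iccs = []
        for jitter in (0.0, 8.0, 25.0):
            design = tk.SessionDesign(
                n_subjects=4,
                trials_per_subject=4,
                sensors={
                    "kinect_azure": tk.SensorNoiseModel(jitter_sd=jitter),
                    "kinect_v2": tk.SensorNoiseModel(jitter_sd=jitter),
                },
            )
            session = simulate_session(design, seed=2)
            feats = {}
            for sensor, seqs in session.recordings.items():
                rows = []
                for seq in seqs:
                    canon = tk.harmonize(seq)
                    px = canon.positions["pelvis"][:, 0]
                    seg = tk.detect_phases(px, 30.0)
                    rows.append(tk.extract_features(canon, seg).as_dict())
                feats[sensor] = pd.DataFrame(rows)
            report = tk.reliability_report(feats)
            iccs.append(report.inter.set_index("feature").loc["tf", "icc"])
        assert iccs[0] >= iccs[1] >= iccs[2] - 0.02

    def test_trunk_improper_trials_have_low_tf_truth(self):
        design = tk.SessionDesign(
            n_subjects=2, trials_per_subject=4, plan=("good", "trunk")
        )
        session = simulate_session(design, seed=0)
        tf = session.truth_features.groupby("transfer_type")["tf"].mean()
        assert tf["trunk"] < 0.6 * tf["good"]

    def test_predicted_scores_flip_rate(self):
        design = tk.SessionDesign(
            n_subjects=3,
            trials_per_subject=20,
            score_error_rate={"kinect_azure": 0.2, "kinect_v2": 0.0},
        )
        session = simulate_session(design, seed=4)
        truth = session.truth_scores.scores.to_numpy()
        az = session.predicted_scores["kinect_azure"].scores.to_numpy()
        v2 = session.predicted_scores["kinect_v2"].scores.to_numpy()
        assert (v2 == truth).all()
        flip_rate = (az != truth).mean()
        assert flip_rate == pytest.approx(0.2, abs=0.05)
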