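import numpy as np
import pytest

from spa_pta.eval_pipeline import estimate_tremor_frequency
from spa_pta.pose_features import normalize_pose, prepare_dataset, select_upper_body
from spa_pta.synthetic_data import (
    SyntheticSpec,
    SyntheticSpecError,
    generate_dataset,
    generate_stratified,
    generate_subject,
    generate_synthetic_video,
    track_dot,
    write_dataset,
)


def band_power_fraction(series, fps, lo=3.0, hi=7.0):
    from scipy.signal import detrend

    x = detrend(np.asarray(series, float), axis=0)
    spec = np.abs(np.fft.rfft(x, axis=0)) ** 2
    freqs = np.fft.rfftfreq(x.shape[0], 1 / fps)
    total = spec[1:].sum()
    band = spec[(freqs >= lo) & (freqs <= hi)].sum()
    return band / max(total, 1e-12)


def wrist_band_power(seq, side):
    seq9 = normalize_pose(select_upper_body(seq))
    traj = seq9.trajectory(f"{side}_wrist")
    from scipy.signal import detrend

    x = detrend(traj, axis=0)
    spec = (np.abs(np.fft.rfft(x, axis=0)) ** 2).sum(axis=1)
    freqs = np.fft.rfftfreq(x.shape[0], 1 / seq.fps)
    return spec[(freqs >= 2.0) & (freqs <= 7.5)].sum() / x.shape[0]


class TestGenerateSubject:
    def test_static_template_without_noise_or_tremor(self):
        spec = SyntheticSpec(jitter_sd=0.0, occlusion_rate=0.0, duration=2.0)
        seq, labels = generate_subject(spec, "S0", 0, tremor_type="NT")
        assert labels.tremor_type == "NT"
        assert np.abs(seq.joints[:, :, :2] - seq.joints[0, :, :2]).max() < 1e-9

    def test_severity_monotone_amplitude(self):
        spec = SyntheticSpec(jitter_sd=0.0, occlusion_rate=0.0, duration=5.0,
                             severity_levels=(1,))
        spec3 = SyntheticSpec(jitter_sd=0.0, occlusion_rate=0.0, duration=5.0,
                              severity_levels=(3,))
        a = []
        for s in (spec, spec3):
            seq, labels = generate_subject(s, "S0", 42, tremor_type="PT")
            side = labels.affected_side
            traj = seq.trajectory(f"{side}_wrist")
            a.append(np.ptp(traj[:, 0]))
        assert a[1] > a[0]

    def test_frequency_recovered_by_estimator(self):
        spec = SyntheticSpec(duration=10.0)
        for seed in (1, 2, 3):
            seq, labels = generate_subject(spec, "S0", seed, tremor_type="PT")
            seq9 = normalize_pose(select_upper_body(seq))
            f = estimate_tremor_frequency(
                seq9.trajectory(f"{labels.affected_side}_wrist"), seq9.fps)
            assert f == pytest.approx(labels.tremor_freq, abs=0.2)

    def test_pt_unilateral_et_bilateral(self):
        # per-arm tremor detection: the spectral estimator reports a
        # dominant peak for tremulous wrists and tremor-free otherwise
        def tremulous(seq, side):
            seq9 = normalize_pose(select_upper_body(seq))
            f = estimate_tremor_frequency(seq9.trajectory(f"{side}_wrist"),
                                          seq9.fps)
            return f is not None

        spec = SyntheticSpec(duration=8.0, class_mix={"PT": 0.5, "ET": 0.5})
        for seed in (10, 11, 12):
            seq, labels = generate_subject(spec, "S0", seed, tremor_type="PT")
            flags = {s: tremulous(seq, s) for s in ("left", "right")}
            assert sum(flags.values()) == 1  # exactly one tremulous arm
            assert flags[labels.affected_side]

            seq, labels = generate_subject(spec, "S0", seed, tremor_type="ET")
            assert tremulous(seq, "left") and tremulous(seq, "right")

    def test_band_limited_tremor_power(self):
        spec = SyntheticSpec(jitter_sd=0.0, occlusion_rate=0.0, duration=10.0)
        seq, labels = generate_subject(spec, "S0", 5, tremor_type="PT")
        traj = seq.trajectory(f"{labels.affected_side}_wrist")
        assert band_power_fraction(traj, seq.fps) > 0.8

    def test_unknown_class_rejected(self):
        with pytest.raises(SyntheticSpecError):
            generate_subject(SyntheticSpec(), "S0", 0, tremor_type="XX")


class TestGenerateDataset:
    def test_deterministic_in_memory(self):
        spec = SyntheticSpec(n_subjects=4, duration=4.0, seed=9)
        d1 = generate_dataset(spec)
        d2 = generate_dataset(spec)
        for (s1, l1), (s2, l2) in zip(d1, d2):
            np.testing.assert_array_equal(s1.joints, s2.joints)
            assert l1 == l2

    def test_byte_identical_on_disk(self, tmp_path):
        spec = SyntheticSpec(n_subjects=3, duration=3.0, seed=4)
        a = write_dataset(generate_dataset(spec), tmp_path / "a")
        b = write_dataset(generate_dataset(spec), tmp_path / "b")
        assert (a / "labels.csv").read_bytes() == (b / "labels.csv").read_bytes()
        fa = sorted((a / "poses").glob("*.json"))[0]
        fb = sorted((b / "poses").glob("*.json"))[0]
        assert fa.read_bytes() == fb.read_bytes()

    def test_subject_count_and_manifest_schema(self):
        spec = SyntheticSpec(n_subjects=10, duration=4.0, seed=2)
        data = generate_dataset(spec)
        subjects = {seq.subject_id for seq, _ in data}
        assert len(subjects) == 10

    def test_class_mix_within_binomial_interval(self):
        spec = SyntheticSpec(n_subjects=40, duration=2.0, seed=3,
                             class_mix={"PT": 0.5, "NT": 0.5})
        data = generate_dataset(spec)
        n_pt = sum(lab.tremor_type == "PT" for _, lab in data)
        # 95% binomial interval around 20 of 40
        assert 14 <= n_pt <= 26

    def test_stratified_counts_exact(self):
        spec = SyntheticSpec(n_subjects=6, duration=2.0, seed=1,
                             class_mix={"PT": 0.5, "NT": 0.5})
        data = generate_stratified(spec, {"PT": 4, "NT": 2})
        counts = {}
        for _, lab in data:
            counts[lab.tremor_type] = counts.get(lab.tremor_type, 0) + 1
        assert counts == {"PT": 4, "NT": 2}

    def test_zero_probability_class_rejected(self):
        spec = SyntheticSpec(class_mix={"PT": 1.0, "NT": 0.0})
        with pytest.raises(SyntheticSpecError):
            generate_stratified(spec, {"NT": 2})

    def test_roundtrip_through_pose_pipeline(self, tmp_path):
        from spa_pta.pose_features import load_pose_dataset

        spec = SyntheticSpec(n_subjects=2, duration=5.0, seed=8,
                             occlusion_rate=0.0)
        root = write_dataset(generate_dataset(spec), tmp_path)
        items = load_pose_dataset(root)
        x, manifest, space = prepare_dataset(items, "type-binary")
        assert x.shape[1:] == (100, 9, 3)
        assert set(manifest["subject_id"]) <= {"S000", "S001"}


class TestSpecValidation:
    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(SyntheticSpecError):
            SyntheticSpec(class_mix={"PT": 0.7, "NT": 0.7})

    def test_amplitudes_must_increase(self):
        with pytest.raises(SyntheticSpecError):
            SyntheticSpec(amplitude_by_severity={1: 5.0, 2: 4.0, 3: 10.0, 4: 16.0})

    def test_fps_must_satisfy_nyquist(self):
        with pytest.raises(SyntheticSpecError):
            SyntheticSpec(fps=10.0)


class TestSyntheticVideo:
    def test_zero_amplitude_is_static(self):
        clip, traj = generate_synthetic_video(5.0, 0.0, duration=1.0, size=32)
        assert np.abs(clip.frames - clip.frames[0]).max() < 1e-12
        np.testing.assert_allclose(traj, 0.0)

    def test_trajectory_matches_analytic_sinusoid(self):
        clip, traj = generate_synthetic_video(5.0, 2.0, fps=30, duration=1.0,
                                              size=64)
        t = np.arange(30) / 30.0
        np.testing.assert_allclose(traj, 2.0 * np.sin(2 * np.pi * 5 * t),
                                   atol=1e-12)

    def test_tracked_amplitude_close_to_truth(self):
        clip, _ = generate_synthetic_video(5.0, 1.0, duration=4.0, size=96,
                                           sigma=10.0, peak=0.7)
        from spa_pta.synthetic_data import oscillation_amplitude

        amp = oscillation_amplitude(track_dot(clip), clip.fps)
        assert amp == pytest.approx(1.0, abs=0.1)

    def test_oversized_amplitude_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_video(5.0, 40.0, size=64)

    def test_nyquist_enforced(self):
        with pytest.raises(ValueError):
            generate_synthetic_video(8.0, 1.0, fps=12.0)


def test_occlusion_produces_low_confidence_gaps():
    spec = SyntheticSpec(occlusion_rate=0.05, duration=10.0)
    seq, _ = generate_subject(spec, "S0", 3, tremor_type="NT")
    low = (seq.joints[:, :, 2] < 0.05).all(axis=1)
    assert low.any()
    assert not low.all()
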