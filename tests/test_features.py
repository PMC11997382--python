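import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirscmd.errors import EpochingError, MissingROIError, WindowError
from nirscmd.features import (
    EPOCH_PRE_S,
    FEATURE_NAMES,
    Epoch,
    ROISeries,
    baseline_correct,
    block_average,
    epoch_blocks,
    epoch_length,
    extract_features,
    feature_frame,
    roi_average,
    subject_feature_vectors,
    tidy_feature_frame,
    window_features,
    window_slice,
)
from nirscmd.montage import build_schedule, sample_index
from nirscmd.recording import HbRecording


def brute_force_features(window):
    """Independent oracle: direct loops over the window."""
    xs = [float(v) for v in window]
    n = len(xs)
    mean = sum(xs) / n
    peak = max(xs)
    ptp = max(xs) - min(xs)
    ordered = sorted(xs)
    if n % 2 == 1:
        median = ordered[n // 2]
    else:
        median = 0.5 * (ordered[n // 2 - 1] + ordered[n // 2])
    var = sum((v - mean) ** 2 for v in xs) / (n - 1) if n > 1 else 0.0
    m2 = sum((v - mean) ** 2 for v in xs) / n
    m3 = sum((v - mean) ** 3 for v in xs) / n
    m4 = sum((v - mean) ** 4 for v in xs) / n
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 if m2 > 0 else 0.0
    return {
        "mean": mean,
        "peak": peak,
        "variance": var,
        "median": median,
        "peak_to_peak": ptp,
        "skewness": skew,
        "kurtosis": kurt,
    }


def _series(values, roi="LPMC", chrom="hbo", fs=11.0, n_ch=1):
    return ROISeries(roi_id=roi, chromophore=chrom, values=np.asarray(values, float),
                     sampling_rate_hz=fs, n_channels_averaged=n_ch)


def _hb(conc, channel_ids, fs=11.0, schedule=None):
    return HbRecording("s", np.asarray(conc, float), tuple(channel_ids), fs,
                       schedule=schedule)


class TestROIAverage:
    def test_single_channel_roi_passthrough(self, roi_map):
        n = 100
        conc = np.random.default_rng(0).standard_normal((63, 2, n))
        hb = _hb(conc, range(1, 64))
        series, skipped = roi_average(hb, {"LM1": frozenset({54})}, rois=["LM1"])
        assert skipped == []
        hbo = [s for s in series if s.chromophore == "hbo"][0]
        np.testing.assert_array_equal(hbo.values, conc[53, 0])
        assert hbo.n_channels_averaged == 1

    def test_two_constant_channels(self):
        conc = np.zeros((2, 2, 50))
        conc[0, 0] = 1.0
        conc[1, 0] = 3.0
        hb = _hb(conc, [10, 11])
        series, _ = roi_average(hb, {"R": frozenset({10, 11})}, rois=["R"])
        hbo = [s for s in series if s.chromophore == "hbo"][0]
        np.testing.assert_allclose(hbo.values, 2.0)

    def test_dropping_identical_channel_unchanged(self):
        conc = np.random.default_rng(1).standard_normal((2, 2, 50))
        conc[1] = conc[0]
        hb_both = _hb(conc, [10, 11])
        hb_one = _hb(conc[:1], [10])
        roi = {"R": frozenset({10, 11})}
        s_both, _ = roi_average(hb_both, roi, rois=["R"])
        s_one, _ = roi_average(hb_one, roi, rois=["R"])
        np.testing.assert_allclose(s_both[0].values, s_one[0].values)

    def test_missing_roi_skipped_and_reported(self):
        hb = _hb(np.zeros((1, 2, 10)), [1])
        series, skipped = roi_average(hb, {"R": frozenset({50})}, rois=["R"])
        assert series == [] and skipped == ["R"]
        with pytest.raises(MissingROIError):
            roi_average(hb, {"R": frozenset({50})}, rois=["R"], on_missing="raise")


class TestEpoching:
    def test_five_epochs_496_samples(self, schedule):
        n = schedule.n_samples(11.0)
        series = _series(np.arange(n, dtype=float))
        epochs = epoch_blocks(series, schedule)
        assert len(epochs) == 5
        assert all(len(e.values) == 496 for e in epochs)
        assert epoch_length(11.0) == 496

    def test_first_epoch_starts_at_45s(self, schedule):
        n = schedule.n_samples(11.0)
        series = _series(np.arange(n, dtype=float))
        epochs = epoch_blocks(series, schedule)
        assert epochs[0].values[0] == sample_index(45.0, 11.0) == 495

    def test_time_axis_covers_minus5_to_40(self, schedule):
        series = _series(np.zeros(schedule.n_samples(11.0)))
        e = epoch_blocks(series, schedule)[0]
        assert e.times[0] == pytest.approx(-5.0)
        assert e.times[-1] == pytest.approx(40.0)

    def test_translation_equivariance(self):
        fs = 11.0
        rng = np.random.default_rng(2)
        base = build_schedule()
        shifted = build_schedule(pre_baseline_s=base.pre_baseline_s + 40.0)
        x = rng.standard_normal(base.n_samples(fs))
        shift = sample_index(40.0, fs)
        x_shifted = np.concatenate([rng.standard_normal(shift), x])
        e1 = epoch_blocks(_series(x), base)
        e2 = epoch_blocks(_series(x_shifted), shifted)
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_insufficient_span_error(self, schedule):
        series = _series(np.zeros(100))
        with pytest.raises(EpochingError):
            epoch_blocks(series, schedule)


class TestBaselineCorrection:
    def _epoch(self, values):
        return Epoch("LPMC", "hbo", np.asarray(values, float), 11.0)

    def test_baseline_mean_zero(self):
        rng = np.random.default_rng(3)
        e = baseline_correct(self._epoch(rng.standard_normal(496)))
        assert abs(e.values[e.times < 0].mean()) < 1e-12
        assert e.baseline_corrected

    def test_constant_epoch_becomes_zero(self):
        e = baseline_correct(self._epoch(np.full(496, 3.3)))
        np.testing.assert_allclose(e.values, 0.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        e1 = baseline_correct(self._epoch(rng.standard_normal(496)))
        e2 = baseline_correct(e1)
        np.testing.assert_allclose(e1.values, e2.values, atol=1e-12)


class TestBlockAverage:
    def _epoch(self, values):
        return Epoch("LPMC", "hbo", np.asarray(values, float), 11.0)

    def test_identical_epochs(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(496)
        avg = block_average([self._epoch(x)] * 5)
        np.testing.assert_allclose(avg.values, x)
        assert avg.n_blocks_averaged == 5

    def test_opposite_epochs_cancel(self):
        x = np.random.default_rng(6).standard_normal(496)
        avg = block_average([self._epoch(x), self._epoch(-x)])
        np.testing.assert_allclose(avg.values, 0.0, atol=1e-15)

    def test_variance_reduction_monte_carlo(self):
        rng = np.random.default_rng(7)
        ratios = []
        for _ in range(200):
            epochs = [self._epoch(rng.standard_normal(64)) for _ in range(5)]
            ratios.append(block_average(epochs).values.var())
        assert np.mean(ratios) == pytest.approx(1 / 5, rel=0.3)

    def test_length_mismatch_error(self):
        with pytest.raises(EpochingError):
            block_average([self._epoch(np.zeros(10)), self._epoch(np.zeros(11))])

    def test_empty_error(self):
        with pytest.raises(EpochingError):
            block_average([])


class TestWindowFeatures:
    def test_worked_example(self):
        feats = window_features([0, 1, 2, 3, 4])
        assert feats["mean"] == 2
        assert feats["median"] == 2
        assert feats["peak"] == 4
        assert feats["peak_to_peak"] == 4
        assert feats["variance"] == pytest.approx(2.5)
        assert feats["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert feats["kurtosis"] == pytest.approx(1.7)

    def test_constant_window_conventions(self):
        feats = window_features(np.full(20, 1.5))
        assert feats["variance"] == 0.0
        assert feats["peak_to_peak"] == 0.0
        assert feats["skewness"] == 0.0
        assert feats["kurtosis"] == 0.0

    def test_negation_symmetry(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(50)
        f_pos, f_neg = window_features(x), window_features(-x)
        assert f_neg["mean"] == pytest.approx(-f_pos["mean"])
        assert f_neg["median"] == pytest.approx(-f_pos["median"])
        assert f_neg["skewness"] == pytest.approx(-f_pos["skewness"])
        assert f_neg["variance"] == pytest.approx(f_pos["variance"])
        assert f_neg["peak_to_peak"] == pytest.approx(f_pos["peak_to_peak"])
        assert f_neg["kurtosis"] == pytest.approx(f_pos["kurtosis"])

    def test_brute_force_oracle_1000_windows(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            n = int(rng.integers(2, 60))
            x = rng.standard_normal(n) * rng.uniform(0.1, 10)
            got = window_features(x)
            want = brute_force_features(x)
            for name in FEATURE_NAMES:
                assert got[name] == pytest.approx(want[name], rel=1e-12, abs=1e-12)

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_invariants_property(self, xs):
        feats = window_features(xs)
        assert feats["variance"] >= 0
        assert feats["peak_to_peak"] >= 0
        assert feats["peak"] >= feats["mean"] - 1e-9

    def test_empty_window_error(self):
        with pytest.raises(WindowError):
            window_features([])


class TestExtractFeatures:
    def _avg(self, values, chrom):
        from nirscmd.features import BlockAverageEpoch

        return BlockAverageEpoch("LPMC", chrom, np.asarray(values, float), 11.0,
                                 baseline_corrected=True, n_blocks_averaged=5)

    def test_labels_and_conditions(self):
        x = np.random.default_rng(10).standard_normal(496)
        fv_task, fv_rest = extract_features(
            {"hbo": self._avg(x, "hbo"), "hbr": self._avg(-x, "hbr")}, "subj"
        )
        assert fv_task.condition == "imagery" and fv_task.label == 1
        assert fv_rest.condition == "rest" and fv_rest.label == 0
        assert len(fv_task.values) == 14  # 7 features x 2 chromophores

    def test_windows_pick_correct_samples(self):
        # window values recoverable: task window = samples 110..274
        x = np.zeros(496)
        x[110:275] = 1.0
        fv_task, fv_rest = extract_features({"hbo": self._avg(x, "hbo")}, "s")
        assert fv_task.values[("hbo", "mean")] == 1.0
        assert fv_rest.values[("hbo", "mean")] == 0.0

    def test_rest_window_is_task_window_shifted_by_block(self, schedule):
        # rest command starts 20 s after the task command in every block
        for t_on, r_on in zip(schedule.task_onsets, schedule.rest_onsets):
            assert r_on - t_on == 20.0
        task_sl = window_slice(496, 11.0, (5.0, 20.0))
        rest_sl = window_slice(496, 11.0, (25.0, 40.0))
        shift = sample_index(20.0, 11.0)
        assert rest_sl.start - task_sl.start == shift
        assert rest_sl.stop - task_sl.stop == shift

    def test_window_outside_epoch_error(self):
        with pytest.raises(WindowError):
            extract_features({"hbo": self._avg(np.zeros(100), "hbo")}, "s")

    def test_mixed_rois_rejected(self):
        from nirscmd.features import BlockAverageEpoch

        a = BlockAverageEpoch("LPMC", "hbo", np.zeros(496), 11.0)
        b = BlockAverageEpoch("RPMC", "hbr", np.zeros(496), 11.0)
        with pytest.raises(WindowError):
            extract_features({"hbo": a, "hbr": b}, "s")


class TestSubjectVectors:
    def test_noisefree_responder_separation(self, noisefree_hb, roi_map):
        vecs, _ = subject_feature_vectors(noisefree_hb, roi_map, rois=["LPMC"])
        frame = feature_frame(vecs)
        task = frame[frame["condition"] == "imagery"]["hbo_mean"].iloc[0]
        rest = frame[frame["condition"] == "rest"]["hbo_mean"].iloc[0]
        assert task > rest
        assert task > 0.2

    def test_nonresponder_near_zero(self, roi_map):
        from nirscmd.preprocess import PreprocessConfig, preprocess_chain
        from nirscmd.simulate import SubjectProfile, simulate_subject

        profile = SubjectProfile("nr", "MCS-", False, noise_scale=0.0)
        rec, _ = simulate_subject(profile, seed=77)
        hb, _ = preprocess_chain(rec, PreprocessConfig(motion=None, band_hz=None))
        vecs, _ = subject_feature_vectors(hb, roi_map, rois=["LPMC"])
        frame = feature_frame(vecs)
        assert frame["hbo_mean"].abs().max() < 1e-9

    def test_per_block_mode(self, noisefree_hb, roi_map):
        vecs, _ = subject_feature_vectors(noisefree_hb, roi_map, rois=["LPMC"],
                                          per_block=True)
        assert len(vecs) == 10  # 5 blocks x 2 conditions

    def test_label_semantics_whole_table(self, noisefree_hb, roi_map):
        vecs, _ = subject_feature_vectors(noisefree_hb, roi_map)
        frame = feature_frame(vecs)
        assert ((frame["label"] == 1) == (frame["condition"] == "imagery")).all()

    def test_tidy_export(self, noisefree_hb, roi_map):
        vecs, _ = subject_feature_vectors(noisefree_hb, roi_map, rois=["LM1"])
        tidy = tidy_feature_frame(vecs)
        assert set(tidy.columns) == {
            "subject_id", "roi", "condition", "label", "chromophore",
            "feature_name", "value",
        }
        assert len(tidy) == 2 * 2 * 7  # conditions x chromophores x features
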