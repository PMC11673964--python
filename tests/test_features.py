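"""R-peak detection, delineation, and the HRV / beat feature groups."""

import math

import numpy as np
import pytest

from ecgkit import (EcgRecord, RrSeries, SynthConfig, add_noise,
                    beat_feature_vector, delineate, detect_r_peaks,
                    generate_ecg, noise_for_snr, rr_freq_features,
                    rr_from_peaks, rr_stat_features, rr_time_features,
                    rule_label)
from ecgkit.errors import (InsufficientDataError, MissingFeatureError,
                           NoBeatsError, TooShortError)
from ecgkit.features import FeatureVector
from ecgkit.record import MISSING


def _fv(hr_mean):
    return FeatureVector(hr_mean=hr_mean, hr_sd=0, qrs_amplitude_mean=1,
                         qrs_amplitude_sd=0, qrs_time_mean=0.1, qrs_time_sd=0,
                         pr_interval_mean=0.15, pr_interval_sd=0)


class TestDetect:
    def test_clean_record_all_peaks_within_25ms(self, clean_record):
        peaks = detect_r_peaks(clean_record)
        ann = clean_record.annotations.r_peak
        assert len(peaks) == len(ann)
        tol = int(0.025 * clean_record.sampling_rate)
        assert np.max(np.abs(peaks - ann)) <= tol

    def test_all_zero_signal_gives_no_peaks(self, zero_record):
        assert detect_r_peaks(zero_record).size == 0

    def test_short_record_rejected(self):
        with pytest.raises(TooShortError):
            detect_r_peaks(EcgRecord(np.zeros(360), 360.0))

    def test_refractory_enforced(self, clean_record):
        peaks = detect_r_peaks(clean_record)
        assert np.all(np.diff(peaks) >= 0.2 * clean_record.sampling_rate)

    def test_noisy_10db_sensitivity_and_ppv(self):
        tol = int(0.050 * 360)
        sens, ppv = [], []
        for seed in range(3):
            clean = generate_ecg(SynthConfig(heart_rate=75.0, duration=30.0,
                                             sampling_rate=360.0, seed=seed))
            spec = noise_for_snr(clean, "motion_artifact", 10.0, seed=seed)
            noisy = add_noise(clean, [spec])
            peaks = detect_r_peaks(noisy)
            ann = clean.annotations.r_peak
            hits = sum(1 for a in ann if np.any(np.abs(peaks - a) <= tol))
            tp = sum(1 for p in peaks if np.any(np.abs(ann - p) <= tol))
            sens.append(hits / len(ann))
            ppv.append(tp / len(peaks))
        assert min(sens) >= 0.95
        assert min(ppv) >= 0.95


class TestDelineate:
    def test_qrs_width_recovered(self, clean_record):
        marks = delineate(clean_record, clean_record.annotations.r_peak)
        ok = (marks.qrs_onset != MISSING) & (marks.qrs_offset != MISSING)
        width = (marks.qrs_offset[ok] - marks.qrs_onset[ok]) / clean_record.sampling_rate
        assert abs(np.mean(width) - clean_record.meta["qrs_width_s"]) <= 0.010

    def test_pr_interval_in_physiologic_band(self):
        durations = {"p": (70, 70), "qrs": (100, 100), "pr": (160, 160),
                     "st": (110, 110), "t": (140, 140)}
        rec = generate_ecg(SynthConfig(heart_rate=70.0, duration=30.0,
                                       wave_durations=durations, seed=2))
        marks = delineate(rec, rec.annotations.r_peak)
        fv = beat_feature_vector(rec, marks)
        assert 0.120 <= fv.pr_interval_mean <= 0.200

    def test_absent_p_wave_flagged_missing(self):
        amps = {"p": 0.0, "q": -0.1, "r": 1.0, "s": -0.15, "t": 0.3}
        rec = generate_ecg(SynthConfig(heart_rate=70.0, duration=20.0,
                                       wave_amplitudes=amps, seed=0))
        marks = delineate(rec, rec.annotations.r_peak)
        assert np.all(marks.p_peak == MISSING)
        assert np.all(marks.p_onset == MISSING)

    def test_no_peaks_rejected(self, clean_record):
        with pytest.raises(NoBeatsError):
            delineate(clean_record, np.array([], dtype=np.int64))


class TestRrTime:
    def test_constant_series(self):
        out = rr_time_features(RrSeries(np.full(10, 1.0)))
        assert out["rr_mean"] == 1.0
        assert out["rmssd"] == 0.0
        assert out["max_deviation"] == 0.0
        assert out["nn50"] == 0

    def test_three_interval_example(self):
        out = rr_time_features(RrSeries(np.array([0.8, 1.0, 1.2])))
        assert out["rr_mean"] == pytest.approx(1.0)
        assert out["rr_median"] == pytest.approx(1.0)
        assert out["rmssd"] == pytest.approx(0.2)

    def test_gaussian_series_distributional(self):
        rng = np.random.default_rng(0)
        iv = rng.normal(1.0, 0.05, 1000)
        out = rr_time_features(RrSeries(iv))
        assert abs(out["rr_mean"] - 1.0) < 0.005
        assert out["rmssd"] == pytest.approx(0.05 * math.sqrt(2), rel=0.10)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            rr_time_features(RrSeries(np.array([1.0])))

    def test_order_sensitivity_of_rmssd(self):
        rng = np.random.default_rng(5)
        iv = rng.uniform(0.7, 1.3, 50)
        shuffled = iv[rng.permutation(50)]
        a = rr_time_features(RrSeries(iv))
        b = rr_time_features(RrSeries(shuffled))
        assert a["rr_mean"] == pytest.approx(b["rr_mean"])
        assert a["rmssd"] != pytest.approx(b["rmssd"])


class TestRrFreq:
    def test_constant_series_has_no_band_power(self):
        out = rr_freq_features(RrSeries(np.full(100, 0.9)))
        for band in ("ulf", "vlf", "lf", "hf"):
            assert out[f"{band}_power"] <= 1e-12

    def test_lf_modulation_lands_in_lf_band(self):
        n = 300
        t = np.cumsum(np.full(n, 1.0))
        iv = 1.0 + 0.05 * np.sin(2 * np.pi * 0.1 * t)
        out = rr_freq_features(RrSeries(iv))
        assert out["lf_power"] > 10 * out["hf_power"]
        assert out["lf_power"] > 10 * out["vlf_power"]

    def test_split_modulation_ratio_near_unity(self):
        n = 512
        t = np.cumsum(np.full(n, 1.0))
        iv = (1.0 + 0.04 * np.sin(2 * np.pi * 0.1 * t)
              + 0.04 * np.sin(2 * np.pi * 0.3 * t))
        out = rr_freq_features(RrSeries(iv))
        assert 0.5 <= out["lf_hf_ratio"] <= 2.0

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            rr_freq_features(RrSeries(np.full(63, 1.0)))


class TestRrStat:
    def test_symmetric_series(self):
        out = rr_stat_features(RrSeries(np.array([0.9, 1.0, 1.0, 1.1])))
        assert out["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert out["range"] == pytest.approx(0.2)

    def test_constant_series_undefined_kurtosis(self):
        out = rr_stat_features(RrSeries(np.full(10, 1.0)))
        assert out["sd"] == 0.0
        assert out["range"] == 0.0
        assert math.isnan(out["kurtosis"])
        assert math.isnan(out["skewness"])

    def test_gaussian_excess_kurtosis_near_zero(self):
        rng = np.random.default_rng(0)
        out = rr_stat_features(RrSeries(rng.normal(1.0, 0.1, 10000)))
        assert abs(out["kurtosis"]) <= 0.1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        iv = rng.uniform(0.7, 1.3, 64)
        a = rr_stat_features(RrSeries(iv))
        b = rr_stat_features(RrSeries(iv[rng.permutation(64)]))
        for key in a:
            assert a[key] == pytest.approx(b[key])


class TestBeatVector:
    @pytest.mark.parametrize("hr", [45.0, 60.0, 75.0, 100.0, 120.0, 150.0])
    def test_heart_rate_recovery_within_1bpm(self, hr):
        rec = generate_ecg(SynthConfig(heart_rate=hr, duration=30.0, seed=1))
        peaks = detect_r_peaks(rec)
        fv = beat_feature_vector(rec, delineate(rec, peaks))
        assert abs(fv.hr_mean - hr) <= 1.0

    def test_tachycardic_record_labelled(self):
        rec = generate_ecg(SynthConfig(heart_rate=120.0, duration=30.0, seed=0))
        fv = beat_feature_vector(rec, delineate(rec, detect_r_peaks(rec)))
        assert abs(fv.hr_mean - 120.0) <= 1.0
        assert rule_label(fv) == "tachycardia"

    def test_identical_beats_zero_sd(self, clean_record):
        fv = beat_feature_vector(clean_record,
                                 delineate(clean_record,
                                           clean_record.annotations.r_peak))
        assert fv.hr_sd == pytest.approx(0.0, abs=1e-9)
        assert fv.qrs_time_sd == pytest.approx(0.0, abs=1e-9)

    def test_narrow_qrs_recovered(self):
        durations = dict(p=(70, 70), qrs=(60, 60), pr=(150, 150),
                         st=(110, 110), t=(140, 140))
        rec = generate_ecg(SynthConfig(heart_rate=78.0, duration=30.0,
                                       wave_durations=durations, seed=0))
        fv = beat_feature_vector(rec, delineate(rec, detect_r_peaks(rec)))
        assert fv.qrs_time_mean == pytest.approx(0.060, abs=0.010)

    def test_hr_mean_consistent_with_mean_rr(self, clean_record):
        marks = delineate(clean_record, detect_r_peaks(clean_record))
        fv = beat_feature_vector(clean_record, marks)
        rr = rr_from_peaks(marks.r_peak, clean_record.sampling_rate)
        assert fv.hr_mean * float(np.mean(rr.intervals)) == pytest.approx(
            60.0, rel=1e-6)


class TestRuleLabel:
    @pytest.mark.parametrize("hr,label", [
        (120.0, "tachycardia"), (78.06, "normal"), (45.0, "bradycardia"),
        (100.0, "normal"), (60.0, "normal"),
    ])
    def test_thresholds(self, hr, label):
        assert rule_label(_fv(hr)) == label

    def test_missing_hr_rejected(self):
        with pytest.raises(MissingFeatureError):
            rule_label(_fv(math.nan))
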