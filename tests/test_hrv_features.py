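"""Handcrafted feature extraction: brute-force oracles, band-power
localisation, detector accuracy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deepernet.hrv_features import (ALL_FEATURES, ECG_FEATURES, RESP_FEATURES,
                                    NNSeries, UnusableSegmentError,
                                    detect_r_peaks, featurize_dataset,
                                    resp_features, spectral_ecg,
                                    time_domain_ecg)
from deepernet.signal_sim import SignalTrace


def _nn(intervals):
    intervals = np.asarray(intervals, dtype=float)
    return NNSeries(r_times=np.cumsum(intervals), nn_intervals=intervals)


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------

def test_time_domain_hand_cases():
    f = time_domain_ecg(_nn([1.0, 1.0, 1.0]))
    assert f["HR_mean"] == pytest.approx(60.0)
    assert f["sdNN"] == 0.0 and f["rmssd"] == 0.0 and f["pNN50"] == 0.0

    f = time_domain_ecg(_nn([0.8, 0.9, 0.8]))
    assert f["rmssd"] == pytest.approx(100.0)       # sqrt((0.1^2+0.1^2)/2) s
    assert f["pNN50"] == pytest.approx(100.0)

    f = time_domain_ecg(_nn([0.8, 0.84]))
    assert f["pNN50"] == 0.0                        # 40 ms <= 50 ms

    with pytest.raises(ValueError):
        time_domain_ecg(_nn([0.8]))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.3, max_value=1.9), min_size=2,
                max_size=40))
def test_time_domain_matches_bruteforce(intervals):
    """Each statistic equals its one-line textbook recomputation."""
    x = np.asarray(intervals)
    f = time_domain_ecg(_nn(x))
    d = np.diff(x)
    assert f["HR_mean"] == pytest.approx(np.mean(60.0 / x), rel=1e-12)
    assert f["sdNN"] == pytest.approx(1000 * np.std(x, ddof=1), rel=1e-12,
                                      abs=1e-9)
    if len(d):
        assert f["rmssd"] == pytest.approx(
            1000 * np.sqrt(np.mean(d ** 2)), rel=1e-12, abs=1e-9)
        assert f["pNN50"] == pytest.approx(
            100.0 * np.mean(np.abs(d) > 0.05), rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# NN spectrum
# ---------------------------------------------------------------------------

def _modulated_nn(freq, n=240, depth=0.05, base=0.8):
    t = np.cumsum(np.full(n, base))
    x = base + depth * np.sin(2 * np.pi * freq * t)
    return NNSeries(r_times=t, nn_intervals=x)


def test_lf_tone_lands_in_lf_band():
    f = spectral_ecg(_modulated_nn(0.10))
    total = f["VLF"] + f["LF"] + f["HF"]
    assert f["LF"] / total > 0.8


def test_hf_tone_dominates_and_ratio_small():
    f = spectral_ecg(_modulated_nn(0.25))
    assert f["HF"] > f["LF"]
    assert f["LF2HF"] < 0.25


def test_normalized_powers_sum_to_one():
    for freq in (0.08, 0.12, 0.2, 0.3):
        f = spectral_ecg(_modulated_nn(freq))
        assert f["nLF"] + f["nHF"] == pytest.approx(1.0)


def test_degenerate_series_flagged():
    f = spectral_ecg(_nn([0.8] * 60))
    assert f["degenerate"] == 1.0
    assert f["nLF"] == 0.0 and f["nHF"] == 0.0 and f["LF2HF"] == 0.0


def test_tf_band_override():
    nn = _modulated_nn(0.08)
    printed = spectral_ecg(nn)          # TF band 0.14-0.40 Hz as printed
    wide = spectral_ecg(nn, tf_band=(0.04, 0.40))
    assert wide["TF"] > printed["TF"]  # the 0.08 Hz tone enters the band


def test_hf_power_monotone_in_modulation_depth():
    powers = [spectral_ecg(_modulated_nn(0.25, depth=d))["HF"]
              for d in (0.01, 0.03, 0.06)]
    assert powers[0] < powers[1] < powers[2]


def test_lomb_alternative_agrees_on_band_ranking():
    f = spectral_ecg(_modulated_nn(0.10), method="lomb")
    assert f["LF"] > f["HF"]


# ---------------------------------------------------------------------------
# RESP features
# ---------------------------------------------------------------------------

def test_resp_constant_clip():
    f = resp_features(SignalTrace(np.full(1250, -2.5), 25.0, "RESP"))
    assert f["RMS"] == pytest.approx(2.5)
    assert f["IQR"] == 0.0 and f["MDA"] == 0.0


def test_resp_slow_sine_in_lf1():
    t = np.arange(1250) / 25.0
    f = resp_features(SignalTrace(np.sin(2 * np.pi * 0.25 * t), 25.0, "RESP"))
    assert f["RMS"] == pytest.approx(np.sqrt(0.5), rel=1e-3)
    total = f["LF1"] + f["LF2"] + f["HF1"] + f["HF2"]
    assert f["LF1"] >= 0.95 * total


def test_resp_fast_sine_in_hf1():
    t = np.arange(1250) / 25.0
    f = resp_features(SignalTrace(np.sin(2 * np.pi * 2.5 * t), 25.0, "RESP"))
    total = f["LF1"] + f["LF2"] + f["HF1"] + f["HF2"]
    assert f["HF1"] >= 0.9 * total
    assert f["L2H"] < 0.1


def test_resp_requires_adequate_rate():
    with pytest.raises(ValueError):
        resp_features(SignalTrace(np.zeros(100), 6.0, "RESP"))


def test_resp_band_sum_bounded_by_total_power():
    """Sum of the four 0-4 Hz band powers cannot exceed the total Welch
    power up to Nyquist."""
    rng = np.random.default_rng(0)
    from scipy.signal import welch

    x = rng.standard_normal(1250)
    f = resp_features(SignalTrace(x, 25.0, "RESP"))
    freq, psd = welch(x, fs=25.0, window="hann", nperseg=256, noverlap=128,
                      detrend="constant")
    total = np.trapezoid(psd, freq)
    assert f["LF1"] + f["LF2"] + f["HF1"] + f["HF2"] <= total * 1.001


# ---------------------------------------------------------------------------
# R-peak detection and dataset featurization
# ---------------------------------------------------------------------------

def test_r_peak_recovery_within_20ms(tiny_dataset):
    """Detected R times match the simulator's ground truth with median
    absolute error below 20 ms and no spurious detections."""
    errs, extra = [], 0
    for i in range(0, len(tiny_dataset), 9):
        clip = SignalTrace(tiny_dataset.ecg[i].astype(float),
                           tiny_dataset.fs_ecg, "ECG")
        det = detect_r_peaks(clip)
        truth = tiny_dataset.ground_truth["r_times"][i]
        # exclude boundary beats the clip may truncate
        det = det[(det > 0.3) & (det < 49.7)]
        for t in det:
            d = np.min(np.abs(truth - t))
            if d > 0.1:
                extra += 1
            else:
                errs.append(d)
    assert np.median(errs) < 0.020
    assert extra == 0


def test_detector_rejects_flat_and_single_beat():
    with pytest.raises(UnusableSegmentError):
        detect_r_peaks(SignalTrace(np.zeros(16000), 320.0, "ECG"))
    one_beat = np.zeros(16000)
    one_beat[8000] = 1.0
    with pytest.raises(UnusableSegmentError):
        detect_r_peaks(SignalTrace(one_beat, 320.0, "ECG"))


def test_featurize_counts_and_order(tiny_dataset):
    table = featurize_dataset(tiny_dataset.subset(np.arange(12)))
    assert list(table.columns[:19]) == list(ALL_FEATURES)
    assert len(ECG_FEATURES) == 11 and len(RESP_FEATURES) == 8
    assert len(table) == 12
    assert set(table.columns[19:]) == {"label", "subject", "task", "clip"}


def test_featurize_drops_unusable_rows(tiny_dataset):
    ds = tiny_dataset.subset(np.arange(6))
    ds.ecg[2, :] = 0.0
    table = featurize_dataset(ds)
    assert len(table) == 5


def test_featurize_empty_dataset(tiny_dataset):
    table = featurize_dataset(tiny_dataset.subset(np.empty(0, dtype=int)))
    assert len(table) == 0
    assert list(table.columns[:19]) == list(ALL_FEATURES)


def test_stressed_heart_rate_dominates(tiny_dataset):
    """HR_mean of stressed segments stochastically dominates relaxed ones
    (one-sided Mann-Whitney)."""
    from scipy.stats import mannwhitneyu

    table = featurize_dataset(tiny_dataset)
    hr1 = table.loc[table.label == 1, "HR_mean"]
    hr0 = table.loc[table.label == 0, "HR_mean"]
    stat = mannwhitneyu(hr1, hr0, alternative="greater")
    assert stat.pvalue < 0.01
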