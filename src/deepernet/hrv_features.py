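"""Handcrafted ECG and respiration features for the classical baselines.

Eleven ECG features per 50-s clip — four time-domain statistics of the
normal-to-normal (NN) interval series (mean heart rate, sdNN, rmssd, pNN50)
and seven Welch spectral quantities (VLF/LF/HF/TF band powers, normalized
LF and HF, LF/HF ratio) — plus eight respiration features: RMS,
interquartile range, MDA (root mean square of successive differences), four
1-Hz-wide band powers up to 4 Hz and their low/high ratio.

R-peaks are detected with a Pan-Tompkins-style pipeline (5-15 Hz bandpass,
derivative, squaring, moving-window integration, adaptive threshold,
0.25 s refractory period).  The NN tachogram is resampled to a uniform
4 Hz grid by cubic interpolation before Welch estimation; a Lomb-Scargle
path is available for irregular series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks, lombscargle, welch

from .preprocess import SegmentDataset
from .signal_sim import SignalTrace

logger = logging.getLogger(__name__)

ECG_FEATURES = ("HR_mean", "sdNN", "rmssd", "pNN50",
                "VLF", "LF", "HF", "TF", "nLF", "nHF", "LF2HF")
RESP_FEATURES = ("RMS", "IQR", "MDA", "LF1", "LF2", "HF1", "HF2", "L2H")
ALL_FEATURES = ECG_FEATURES + RESP_FEATURES

#: HRV spectral bands in Hz.  TF is implemented exactly as printed in the
#: feature table (0.14-0.40 Hz); pass ``tf_band=(0.04, 0.40)`` to override.
ECG_BANDS = {"VLF": (0.00, 0.04), "LF": (0.04, 0.15),
             "HF": (0.15, 0.40), "TF": (0.14, 0.40)}
RESP_BANDS = {"LF1": (0.0, 1.0), "LF2": (1.0, 2.0),
              "HF1": (2.0, 3.0), "HF2": (3.0, 4.0)}

NN_MIN_S = 0.25
NN_MAX_S = 2.0
RESAMPLE_HZ = 4.0


class UnusableSegmentError(ValueError):
    """Raised when a clip cannot yield a valid NN series."""


@dataclass(frozen=True)
class NNSeries:
    """Accepted R-peak times and the NN intervals between them."""

    r_times: np.ndarray
    nn_intervals: np.ndarray

    @classmethod
    def from_r_times(cls, r_times: np.ndarray) -> "NNSeries":
        r_times = np.asarray(r_times, dtype=float)
        if len(r_times) < 2:
            raise UnusableSegmentError("need at least 2 R-peaks")
        rr = np.diff(r_times)
        ok = (rr > NN_MIN_S) & (rr < NN_MAX_S)
        if ok.sum() < 2:
            raise UnusableSegmentError("fewer than 2 physiological intervals")
        # keep the interval end-times so each NN interval has a timestamp
        return cls(r_times=r_times[1:][ok], nn_intervals=rr[ok])


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg_clip: SignalTrace,
                   refractory_s: float = 0.25) -> np.ndarray:
    """Pan-Tompkins-style R-peak detection on a filtered ECG clip.

    Returns strictly increasing peak times in seconds; raises
    :class:`UnusableSegmentError` if fewer than two peaks are found.
    """
    x = np.asarray(ecg_clip.samples, dtype=float)
    fs = ecg_clip.fs
    if fs < 300.0:
        raise ValueError("R-peak detection requires fs >= 300 Hz")
    if len(x) < fs:
        raise UnusableSegmentError("clip shorter than 1 s")
    if float(np.std(x)) == 0.0:
        raise UnusableSegmentError("flat clip")

    b, a = butter(3, [5.0, 15.0], btype="bandpass", fs=fs)
    bp = filtfilt(b, a, x)
    deriv = np.gradient(bp)
    sq = deriv ** 2
    win = max(int(round(0.15 * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    thr = 0.2 * np.percentile(mwi, 99)
    cand, _ = find_peaks(mwi, height=thr, distance=int(round(refractory_s * fs)))
    if len(cand) < 2:
        raise UnusableSegmentError("fewer than 2 QRS candidates")

    # refine each candidate to the local maximum of the de-noised ECG
    half = int(round(0.10 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, len(x))
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    # amplitude gate: spurious refinements (filter ringing, flat regions)
    # sit far below the R amplitude of genuine beats
    amp = x[peaks]
    peaks = peaks[amp >= 0.25 * amp.max()]
    if len(peaks) < 2:
        raise UnusableSegmentError("fewer than 2 R-peaks after refinement")
    # enforce the refractory period after refinement
    kept = [peaks[0]]
    for p in peaks[1:]:
        if (p - kept[-1]) / fs >= refractory_s:
            kept.append(p)
    if len(kept) < 2:
        raise UnusableSegmentError("fewer than 2 R-peaks after refinement")
    return np.asarray(kept) / fs


# ---------------------------------------------------------------------------
# ECG features
# ---------------------------------------------------------------------------

def time_domain_ecg(nn: NNSeries) -> dict[str, float]:
    """HR_mean (bpm), sdNN (ms), rmssd (ms), pNN50 (%)."""
    x = nn.nn_intervals
    if len(x) < 2:
        raise ValueError("need at least 2 NN intervals")
    d = np.diff(x)
    return {
        "HR_mean": float(np.mean(60.0 / x)),
        "sdNN": float(np.std(x, ddof=1) * 1000.0),
        "rmssd": float(np.sqrt(np.mean(d ** 2)) * 1000.0) if len(d) else 0.0,
        "pNN50": float(100.0 * np.mean(np.abs(d) > 0.05)) if len(d) else 0.0,
    }


def _band_power(f: np.ndarray, psd: np.ndarray,
                band: tuple[float, float]) -> float:
    lo, hi = band
    m = (f >= lo) & (f <= hi)
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[m], f[m]))


def nn_psd(nn: NNSeries, method: str = "welch",
           resample_hz: float = RESAMPLE_HZ) -> tuple[np.ndarray, np.ndarray]:
    """PSD of the (irregular) NN tachogram.

    ``welch``: cubic interpolation onto a uniform ``resample_hz`` grid,
    linear detrend, Hann window, 50% overlap, ``nperseg = min(N, 256)``.
    ``lomb``: Lomb-Scargle periodogram on the irregular samples.
    """
    t, x = nn.r_times, nn.nn_intervals
    if len(x) < 4:
        raise UnusableSegmentError("need >= 4 NN intervals for a spectrum")
    if method == "lomb":
        f = np.linspace(0.005, 0.5, 200)
        x0 = x - np.mean(x)
        if np.allclose(x0, 0.0):
            return f, np.zeros_like(f)
        pg = lombscargle(t, x0, 2 * np.pi * f, normalize=False)
        return f, pg * 2.0 / len(t) / (2 * np.pi)  # rough density scaling
    if method != "welch":
        raise ValueError(f"unknown PSD method {method!r}")
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    if len(grid) < 8:
        raise UnusableSegmentError("NN series spans too little time")
    xs = CubicSpline(t, x)(grid)
    nperseg = int(min(len(grid), 256))
    f, psd = welch(xs, fs=resample_hz, window="hann", nperseg=nperseg,
                   noverlap=nperseg // 2, detrend="linear")
    return f, psd


def spectral_ecg(nn: NNSeries, method: str = "welch",
                 tf_band: tuple[float, float] | None = None) -> dict[str, float]:
    """Welch band powers and ratio features of the NN series.

    Degenerate (near-constant) series yield all-zero powers; the ratio
    features are then emitted as 0 and flagged via the ``"degenerate"`` key.
    """
    f, psd = nn_psd(nn, method=method)
    bands = dict(ECG_BANDS)
    if tf_band is not None:
        bands["TF"] = tf_band
    out = {k: _band_power(f, psd, b) for k, b in bands.items()}
    lf, hf = out["LF"], out["HF"]
    # physiological NN-modulation powers are >> 1e-15 s^2; anything below
    # is numerical residue of a (near-)constant series
    degenerate = (lf + hf) <= 1e-15
    out["nLF"] = 0.0 if degenerate else lf / (lf + hf)
    out["nHF"] = 0.0 if degenerate else hf / (lf + hf)
    out["LF2HF"] = 0.0 if (degenerate or hf <= 1e-15) else lf / hf
    out["degenerate"] = float(degenerate)
    return out


def ecg_features(ecg_clip: SignalTrace, method: str = "welch",
                 tf_band: tuple[float, float] | None = None) -> dict[str, float]:
    nn = NNSeries.from_r_times(detect_r_peaks(ecg_clip))
    feats = time_domain_ecg(nn)
    feats.update(spectral_ecg(nn, method=method, tf_band=tf_band))
    feats.pop("degenerate", None)
    return feats


# ---------------------------------------------------------------------------
# RESP features
# ---------------------------------------------------------------------------

def resp_features(resp_clip: SignalTrace) -> dict[str, float]:
    """Time-domain statistics and 0-4 Hz Welch band powers of raw RESP."""
    fs = resp_clip.fs
    if fs < 8.0:
        raise ValueError("RESP fs must be >= 8 Hz (HF2 upper edge is 4 Hz)")
    x = np.asarray(resp_clip.samples, dtype=float)
    d = np.diff(x)
    q75, q25 = np.percentile(x, [75, 25])
    out = {
        "RMS": float(np.sqrt(np.mean(x ** 2))),
        "IQR": float(q75 - q25),
        "MDA": float(np.sqrt(np.mean(d ** 2))) if len(d) else 0.0,
    }
    nperseg = int(min(len(x), 256))
    f, psd = welch(x, fs=fs, window="hann", nperseg=nperseg,
                   noverlap=nperseg // 2, detrend="constant")
    for k, b in RESP_BANDS.items():
        out[k] = _band_power(f, psd, b)
    hi = out["HF1"] + out["HF2"]
    out["L2H"] = 0.0 if hi <= 0.0 else (out["LF1"] + out["LF2"]) / hi
    return out


# ---------------------------------------------------------------------------
# Dataset-level extraction
# ---------------------------------------------------------------------------

def featurize_dataset(ds: SegmentDataset, method: str = "welch",
                      tf_band: tuple[float, float] | None = None
                      ) -> pd.DataFrame:
    """Feature table (19 columns) plus label and provenance columns.

    Row order follows the dataset; segments whose ECG is unusable are
    dropped and logged.
    """
    rows, keep = [], []
    for i in range(len(ds)):
        ecg = SignalTrace(ds.ecg[i].astype(float), ds.fs_ecg, "ECG")
        resp = SignalTrace(ds.resp[i].astype(float), ds.fs_resp, "RESP")
        try:
            feats = ecg_features(ecg, method=method, tf_band=tf_band)
        except (UnusableSegmentError, ValueError) as exc:
            logger.warning("segment %d unusable (%s); dropped", i, exc)
            continue
        feats.update(resp_features(resp))
        rows.append([feats[k] for k in ALL_FEATURES])
        keep.append(i)
    if not rows:
        return pd.DataFrame(columns=list(ALL_FEATURES)
                            + ["label", "subject", "task", "clip"])
    table = pd.DataFrame(rows, columns=list(ALL_FEATURES))
    meta = ds.meta.iloc[keep].reset_index(drop=True)
    table["label"] = ds.labels[keep]
    table["subject"] = meta["subject"].to_numpy()
    table["task"] = meta["task_index"].to_numpy()
    table["clip"] = meta["clip_index"].to_numpy()
    return table
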