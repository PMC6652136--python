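"""ECG de-noising and 50-s segmentation of task intervals.

The ECG passes through two linear-phase FIR filters — a 2000th-order 58-62 Hz
notch and a 3000th-order 1.5-150 Hz bandpass — applied causally with the
group delay compensated afterwards, so the printed order is applied exactly
once.  Respiration is deliberately left unfiltered: it is a torso
expansion signal whose motion component is not independent of breathing.

Each 5-min task interval is cut into non-overlapping half-open 50-s windows
``[k*50, (k+1)*50)``; the first clip of every task is dropped (task
initialisation time), leaving five labelled clips per task.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin

from .signal_sim import SignalTrace, SubjectRecording

logger = logging.getLogger(__name__)

WINDOW_S = 50.0


@dataclass(frozen=True)
class FilterSpec:
    kind: str       # "notch" | "bandpass"
    order: int      # number of taps - 1
    band: tuple[float, float]  # Hz
    fs: float

    def validate(self) -> None:
        if self.kind not in ("notch", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        lo, hi = self.band
        if not (0.0 < lo < hi < self.fs / 2.0):
            raise ValueError(
                f"band {self.band} must lie inside (0, fs/2)={self.fs / 2}")


def notch_spec(fs: float) -> FilterSpec:
    return FilterSpec(kind="notch", order=2000, band=(58.0, 62.0), fs=fs)


def bandpass_spec(fs: float) -> FilterSpec:
    return FilterSpec(kind="bandpass", order=3000, band=(1.5, 150.0), fs=fs)


def design_fir(spec: FilterSpec) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase FIR with ``order + 1`` taps."""
    spec.validate()
    numtaps = spec.order + 1
    pass_zero = "bandstop" if spec.kind == "notch" else "bandpass"
    return firwin(numtaps, list(spec.band), fs=spec.fs, pass_zero=pass_zero,
                  window="hamming")


def apply_filter(trace: SignalTrace, coeffs: np.ndarray) -> SignalTrace:
    """Causal FIR filtering with the linear-phase group delay removed.

    The output has the same length as the input; the shift of
    ``(len(coeffs) - 1) // 2`` samples is compensated by slicing the full
    convolution.
    """
    x = trace.samples
    if len(x) <= len(coeffs):
        raise ValueError(
            f"trace ({len(x)} samples) must be longer than the filter "
            f"({len(coeffs)} taps)")
    delay = (len(coeffs) - 1) // 2
    y = fftconvolve(x, coeffs, mode="full")[delay:delay + len(x)]
    return SignalTrace(samples=y, fs=trace.fs, channel=trace.channel)


def denoise_ecg(trace: SignalTrace) -> SignalTrace:
    """Notch then bandpass, per the preprocessing recipe."""
    trace = apply_filter(trace, design_fir(notch_spec(trace.fs)))
    trace = apply_filter(trace, design_fir(bandpass_spec(trace.fs)))
    return trace


def preprocess_recording(rec: SubjectRecording) -> SubjectRecording:
    """Filter the ECG channel; respiration passes through untouched."""
    return replace(rec, ecg=denoise_ecg(rec.ecg))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentDataset:
    """Time-aligned 50-s ECG/RESP clip pairs with labels and provenance.

    ``ground_truth`` optionally carries, per clip, the exact R-peak and
    breath-event times (seconds from clip start) inherited from the
    simulator.
    """

    ecg: np.ndarray    # (n, window_s * fs_ecg) float32
    resp: np.ndarray   # (n, window_s * fs_resp) float32
    labels: np.ndarray  # (n,) int
    meta: pd.DataFrame  # subject, task_index, task_kind, clip_index
    fs_ecg: float
    fs_resp: float
    ground_truth: dict | None = None  # keys: r_times, breath_peaks, breath_troughs

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "SegmentDataset":
        idx = np.asarray(idx)
        gt = None
        if self.ground_truth is not None:
            gt = {k: [v[i] for i in idx] for k, v in self.ground_truth.items()}
        return SegmentDataset(
            ecg=self.ecg[idx], resp=self.resp[idx], labels=self.labels[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            fs_ecg=self.fs_ecg, fs_resp=self.fs_resp, ground_truth=gt)


def _slice(trace: SignalTrace, t0: float, window_s: float) -> np.ndarray:
    i0 = int(round(t0 * trace.fs))
    n = int(round(window_s * trace.fs))
    return trace.samples[i0:i0 + n]


def segment_tasks(
    recording: SubjectRecording,
    window_s: float = WINDOW_S,
    drop_first_clips: int = 1,
) -> SegmentDataset:
    """Cut every annotated task into labelled non-overlapping clips.

    A 300-s task yields ``floor(300/50) = 6`` clips of which the first
    ``drop_first_clips`` are discarded.  Tasks shorter than one window yield
    no clips and are logged.
    """
    if not recording.annotations:
        raise ValueError("recording has no task annotations")
    n_e = int(round(window_s * recording.ecg.fs))
    n_r = int(round(window_s * recording.resp.fs))
    ecg_rows, resp_rows, labels, meta = [], [], [], []
    gt: dict[str, list] = {"r_times": [], "breath_peaks": [], "breath_troughs": []}
    events = {"r_times": recording.r_times,
              "breath_peaks": recording.breath_peaks,
              "breath_troughs": recording.breath_troughs}

    for task_index, ann in enumerate(recording.annotations):
        dur = ann.t_end - ann.t_start
        n_clips = int(np.floor(dur / window_s))
        if n_clips == 0:
            logger.warning(
                "task %d (%s) of %s is shorter than the %g-s window; skipped",
                task_index, ann.task_kind, recording.subject_id, window_s)
            continue
        for k in range(drop_first_clips, n_clips):
            t0 = ann.t_start + k * window_s
            e = _slice(recording.ecg, t0, window_s)
            r = _slice(recording.resp, t0, window_s)
            if len(e) < n_e or len(r) < n_r:
                logger.warning("clip %d of task %d truncated at recording "
                               "end; discarded", k, task_index)
                continue
            ecg_rows.append(e)
            resp_rows.append(r)
            labels.append(ann.label)
            meta.append((recording.subject_id, task_index, ann.task_kind, k))
            for key, ev in events.items():
                if ev is None:
                    gt[key].append(np.empty(0))
                else:
                    sel = ev[(ev >= t0) & (ev < t0 + window_s)]
                    gt[key].append(sel - t0)

    return SegmentDataset(
        ecg=np.asarray(ecg_rows, dtype=np.float32).reshape(-1, n_e),
        resp=np.asarray(resp_rows, dtype=np.float32).reshape(-1, n_r),
        labels=np.asarray(labels, dtype=np.int64),
        meta=pd.DataFrame(
            meta, columns=["subject", "task_index", "task_kind", "clip_index"]),
        fs_ecg=recording.ecg.fs, fs_resp=recording.resp.fs,
        ground_truth=gt)


def concat_datasets(datasets: Sequence[SegmentDataset]) -> SegmentDataset:
    first = datasets[0]
    gt = None
    if all(d.ground_truth is not None for d in datasets):
        gt = {k: sum((d.ground_truth[k] for d in datasets), [])
              for k in first.ground_truth}
    return SegmentDataset(
        ecg=np.concatenate([d.ecg for d in datasets]),
        resp=np.concatenate([d.resp for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        meta=pd.concat([d.meta for d in datasets], ignore_index=True),
        fs_ecg=first.fs_ecg, fs_resp=first.fs_resp, ground_truth=gt)


def segment_cohort(recordings: Sequence[SubjectRecording],
                   window_s: float = WINDOW_S,
                   drop_first_clips: int = 1) -> SegmentDataset:
    return concat_datasets([
        segment_tasks(r, window_s=window_s, drop_first_clips=drop_first_clips)
        for r in recordings])


# ---------------------------------------------------------------------------
# Artifact exclusion
# ---------------------------------------------------------------------------

def default_artifact_rule(clip: np.ndarray) -> bool:
    """True if the clip looks usable.

    Rejects flat-lined clips (zero variance) and clips with more than 1% of
    samples pinned at either amplitude rail.
    """
    if clip.size == 0 or float(np.std(clip)) == 0.0:
        return False
    rail_hi = np.mean(clip == clip.max())
    rail_lo = np.mean(clip == clip.min())
    return not (rail_hi > 0.01 or rail_lo > 0.01)


def exclude_artifacts(
    ds: SegmentDataset,
    rule: Callable[[np.ndarray], bool] | None = None,
) -> SegmentDataset:
    """Drop segments whose ECG clip fails the per-segment predicate."""
    rule = rule or default_artifact_rule
    keep = np.array([rule(ds.ecg[i]) for i in range(len(ds))], dtype=bool)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("excluded %d distorted segment(s) of %d", n_drop,
                       len(ds))
    if keep.sum() == 0:
        logger.warning("all segments excluded; returning empty dataset")
    return ds.subset(np.nonzero(keep)[0])
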