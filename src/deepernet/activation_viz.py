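"""First-layer activation inspection.

For a trained network and a single 50-s segment, extracts the activation
after the first ReLU of one branch (at full input resolution, before any
pooling) for a chosen filter, together with the first batch-normalization
layer's output, zero-padded to the input length if necessary.  Both arrays
are independently MinMax-normalized to [0, 1] so they can be overlaid; the
plotted patterns show which waveform features (QRS complexes and T waves in
ECG, peaks and troughs in respiration) the learned filters respond to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DeepERNet


@dataclass
class ActivationOverlay:
    bn_output: np.ndarray    # (L,) in [0, 1]
    activation: np.ndarray   # (L,) in [0, 1]
    filter_index: int
    branch: str
    degenerate: bool = False


def _minmax(x: np.ndarray) -> tuple[np.ndarray, bool]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0.0:
        return np.zeros_like(x, dtype=float), True
    return (x - lo) / (hi - lo), False


def _pad_to(x: np.ndarray, n: int) -> np.ndarray:
    if len(x) >= n:
        return x[:n]
    extra = n - len(x)
    return np.pad(x, (extra // 2, extra - extra // 2))


def _branch(model: DeepERNet, branch: str):
    if branch.lower() == "ecg":
        return model.ecg_branch
    if branch.lower() == "resp":
        return model.resp_branch
    raise ValueError(f"branch must be 'ecg' or 'resp', got {branch!r}")


def extract_overlay(model: DeepERNet, ecg: np.ndarray, resp: np.ndarray,
                    branch: str, filter_index: int) -> ActivationOverlay:
    """Overlay of the first-BN output and the post-ReLU conv1 activation of
    one filter, both MinMax-normalized to [0, 1]."""
    if not model.trained:
        raise ValueError("model has not been trained")
    br = _branch(model, branch)
    if not 0 <= filter_index < br.block.f:
        raise ValueError(f"filter index {filter_index} out of range "
                         f"[0, {br.block.f})")
    x = (ecg if branch.lower() == "ecg" else resp).reshape(1, -1)
    bn_out, act = br.first_stage(np.asarray(x, dtype=np.float32))
    L = x.shape[1]
    bn_n, deg1 = _minmax(_pad_to(bn_out[0], L))
    act_n, deg2 = _minmax(_pad_to(act[0, filter_index], L))
    return ActivationOverlay(bn_output=bn_n, activation=act_n,
                             filter_index=int(filter_index), branch=branch,
                             degenerate=bool(deg1 or deg2))


def rank_filters(model: DeepERNet, ecg: np.ndarray, resp: np.ndarray,
                 branch: str) -> np.ndarray:
    """Filters ordered by decreasing mean post-ReLU activation energy over
    the given segments; ties break towards the lower index."""
    if len(ecg) == 0:
        raise ValueError("need at least one segment")
    br = _branch(model, branch)
    x = np.asarray(ecg if branch.lower() == "ecg" else resp,
                   dtype=np.float32)
    if x.ndim == 1:
        x = x.reshape(1, -1)
    energy = np.zeros(br.block.f)
    for i in range(0, len(x), 64):
        _, act = br.first_stage(x[i:i + 64])
        energy += np.sum(act.astype(float) ** 2, axis=(0, 2))
    energy /= x.shape[0] * x.shape[1]
    order = np.lexsort((np.arange(len(energy)), -energy))
    return order


def event_overlap_fraction(overlay: ActivationOverlay, event_times: np.ndarray,
                           fs: float, window_s: float,
                           top_fraction: float = 0.1) -> float:
    """Fraction of ground-truth events with at least one top-activation
    sample within +/- ``window_s``.

    The top-activation samples are the highest ``top_fraction`` of the
    normalized activation trace.
    """
    event_times = np.asarray(event_times, dtype=float)
    if len(event_times) == 0:
        return 0.0
    act = overlay.activation
    thr = np.quantile(act, 1.0 - top_fraction)
    top_idx = np.nonzero((act >= thr) & (act > 0.0))[0]
    if len(top_idx) == 0:
        return 0.0
    top_t = top_idx / fs
    hits = 0
    for t in event_times:
        j = np.searchsorted(top_t, t)
        near = []
        if j < len(top_t):
            near.append(abs(top_t[j] - t))
        if j > 0:
            near.append(abs(top_t[j - 1] - t))
        if near and min(near) <= window_s:
            hits += 1
    return hits / len(event_times)


def activation_near_event_fraction(overlay: ActivationOverlay,
                                   event_times: np.ndarray, fs: float,
                                   window_s: float,
                                   top_fraction: float = 0.1) -> float:
    """Fraction of top-decile activation samples lying within
    +/- ``window_s`` of the nearest ground-truth event.

    The complementary direction to :func:`event_overlap_fraction`: it asks
    where the activations concentrate, rather than which events are
    covered.  Returns 0 for an all-zero activation or no events.
    """
    event_times = np.sort(np.asarray(event_times, dtype=float))
    act = overlay.activation
    thr = np.quantile(act, 1.0 - top_fraction)
    top_idx = np.nonzero((act >= thr) & (act > 0.0))[0]
    if len(top_idx) == 0 or len(event_times) == 0:
        return 0.0
    t = top_idx / fs
    j = np.searchsorted(event_times, t)
    left = event_times[np.clip(j - 1, 0, len(event_times) - 1)]
    right = event_times[np.clip(j, 0, len(event_times) - 1)]
    nearest = np.minimum(np.abs(t - left), np.abs(t - right))
    return float(np.mean(nearest <= window_s))


def overlay_to_csv(overlay: ActivationOverlay, path, fs: float) -> None:
    t = np.arange(len(overlay.bn_output)) / fs
    data = np.column_stack([t, overlay.bn_output, overlay.activation])
    np.savetxt(path, data, delimiter=",", comments="",
               header="t,bn_output,activation")


def plot_overlay(overlay: ActivationOverlay, fs: float, ax=None):
    """Overlay plot (requires matplotlib; import deferred)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    t = np.arange(len(overlay.bn_output)) / fs
    ax.plot(t, overlay.bn_output, color="tab:red", lw=0.8,
            label="batch-norm output")
    ax.plot(t, overlay.activation, color="tab:blue", lw=0.8,
            label=f"filter {overlay.filter_index} activation")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized amplitude")
    ax.legend(loc="upper right")
    return ax
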