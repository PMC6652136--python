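"""Protocol-shaped synthetic ECG and respiration generator.

Emulates a laboratory mental-stress protocol: after an initial relaxation
task, relaxation and stressor tasks (easy/hard mental arithmetic, easy/hard
Stroop) alternate in 5-min blocks, with the four stressors presented in
random order.  Each subject yields a paired single-channel ECG trace and a
respiration (RESP) trace with task annotations, a self-reported 0-10 stress
score (VAS) per task, and exact ground-truth R-peak and breath-event times.

The relax/stress contrast follows the standard autonomic picture of acute
mental stress: sympathetic dominance raises heart rate, shifts heart-rate
variability from the high-frequency (respiratory) band towards the
low-frequency band, and speeds up respiration.  Effect sizes are textbook
scale and configurable through :class:`StressParams`.

Beat morphology is a five-Gaussian P/Q/R/S/T template so that downstream
convolutional filters have genuine QRS and T shapes to respond to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

TASK_RELAX = "relax"
STRESSOR_KINDS = ("easy_math", "hard_math", "easy_stroop", "hard_stroop")
TASK_KINDS = (TASK_RELAX,) + STRESSOR_KINDS

#: Default PQRST template: (wave, offset from R in s, Gaussian width in s,
#: amplitude in mV).  The R bump dominates so the waveform argmax marks the
#: R time; T is wide and late, P precedes the QRS complex.
PQRST_TEMPLATE: tuple[tuple[str, float, float, float], ...] = (
    ("P", -0.200, 0.040, 0.15),
    ("Q", -0.030, 0.012, -0.12),
    ("R", 0.000, 0.018, 1.20),
    ("S", 0.030, 0.012, -0.25),
    ("T", 0.250, 0.060, 0.35),
)

TASK_DURATION_S = 300.0
N_TASKS = 9


@dataclass(frozen=True)
class StressParams:
    """Physiological contrast between the relaxed and stressed states.

    Rates are in beats or breaths per minute; the LF/HF amplitudes are the
    depth (in seconds) of the RR-interval modulation at ~0.1 Hz and at the
    concurrent respiratory frequency respectively.
    """

    hr_mean_relax: float = 65.0
    hr_mean_stress: float = 80.0
    lf_amp_relax: float = 0.03
    lf_amp_stress: float = 0.04
    hf_amp_relax: float = 0.04
    hf_amp_stress: float = 0.015
    resp_rate_relax: float = 14.0
    resp_rate_stress: float = 19.0
    rr_noise_sd: float = 0.01
    resp_noise_sd: float = 0.05
    powerline_amp: float = 0.0
    baseline_wander_amp: float = 0.05

    def validate(self) -> None:
        for name in ("hr_mean_relax", "hr_mean_stress",
                     "resp_rate_relax", "resp_rate_stress"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for state in ("relax", "stress"):
            hr = getattr(self, f"hr_mean_{state}")
            det = 60.0 / hr - getattr(self, f"lf_amp_{state}") \
                - getattr(self, f"hf_amp_{state}")
            if det <= 0:
                raise ValueError(
                    f"params produce non-positive RR intervals in {state} state")

    def for_state(self, stressed: bool) -> tuple[float, float, float, float]:
        """(hr_mean, lf_amp, hf_amp, resp_rate) of one state."""
        s = "stress" if stressed else "relax"
        return (getattr(self, f"hr_mean_{s}"), getattr(self, f"lf_amp_{s}"),
                getattr(self, f"hf_amp_{s}"), getattr(self, f"resp_rate_{s}"))


@dataclass(frozen=True)
class SignalTrace:
    """One uniformly sampled channel."""

    samples: np.ndarray
    fs: float
    channel: str  # "ECG" | "RESP"

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class TaskAnnotation:
    task_kind: str
    difficulty: str  # "easy" | "hard" | "" for relaxation
    t_start: float
    t_end: float
    label: int
    vas: float


@dataclass(frozen=True)
class ProtocolSchedule:
    tasks: tuple[tuple[str, float, float], ...]  # (kind, start s, duration s)
    rng_seed: int

    @property
    def total_duration(self) -> float:
        last = self.tasks[-1]
        return last[1] + last[2]

    def task_at(self, t: float) -> tuple[int, str]:
        """Index and kind of the task covering time ``t`` (half-open bins)."""
        for i, (kind, start, dur) in enumerate(self.tasks):
            if start <= t < start + dur:
                return i, kind
        # clamp to the last task for t == total duration
        return len(self.tasks) - 1, self.tasks[-1][0]


@dataclass
class SubjectRecording:
    subject_id: str
    ecg: SignalTrace
    resp: SignalTrace
    annotations: list[TaskAnnotation]
    r_times: np.ndarray          # ground-truth R-peak times, s
    breath_peaks: np.ndarray     # ground-truth inspiration peak times, s
    breath_troughs: np.ndarray   # ground-truth expiration trough times, s


def is_stressor(kind: str) -> bool:
    return kind != TASK_RELAX


def make_protocol(rng_seed: int) -> ProtocolSchedule:
    """Nine alternating 5-min tasks: relax at odd positions, the four
    stressors once each in seeded random order."""
    rng = np.random.default_rng(rng_seed)
    order = [STRESSOR_KINDS[i] for i in rng.permutation(len(STRESSOR_KINDS))]
    tasks = []
    t = 0.0
    for i in range(N_TASKS):
        kind = TASK_RELAX if i % 2 == 0 else order[i // 2]
        tasks.append((kind, t, TASK_DURATION_S))
        t += TASK_DURATION_S
    return ProtocolSchedule(tasks=tuple(tasks), rng_seed=int(rng_seed))


# ---------------------------------------------------------------------------
# Respiration phase
# ---------------------------------------------------------------------------

def _resp_phase_grid(schedule: ProtocolSchedule, params: StressParams,
                     dt: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous respiratory phase on a fine grid.

    The breathing rate is piecewise constant per task; the phase is its
    integral, so frequency steps at task boundaries keep the phase
    continuous.
    """
    total = schedule.total_duration
    t = np.arange(0.0, total + dt, dt)
    rate = np.empty_like(t)
    for kind, start, dur in schedule.tasks:
        _, _, _, rr = params.for_state(is_stressor(kind))
        rate[(t >= start) & (t < start + dur)] = rr / 60.0
    rate[t >= total] = rate[-2] if len(rate) > 1 else rate[-1]
    phase = 2.0 * np.pi * np.concatenate(([0.0], np.cumsum(
        0.5 * (rate[1:] + rate[:-1]) * np.diff(t))))
    return t, phase


# ---------------------------------------------------------------------------
# RR series
# ---------------------------------------------------------------------------

def simulate_rr_series(
    schedule: ProtocolSchedule,
    params: StressParams,
    rng_seed: int,
    resp_phase: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Beat-by-beat RR intervals over the whole protocol.

    Each interval is the state's mean RR plus a low-frequency (~0.1 Hz)
    sinusoidal modulation, a high-frequency modulation locked to the
    concurrent respiratory phase (respiratory sinus arrhythmia), and
    Gaussian jitter; intervals are clipped at 0.25 s.

    Returns ``(r_times, rr_intervals)`` with ``len(r_times) ==
    len(rr_intervals) + 1``.
    """
    params.validate()
    rng = np.random.default_rng(rng_seed)
    if resp_phase is None:
        resp_phase = _resp_phase_grid(schedule, params)
    pt, pv = resp_phase
    total = schedule.total_duration

    r_times = [0.0]
    rr = []
    t = 0.0
    while True:
        _, kind = schedule.task_at(min(t, total - 1e-9))
        hr, lf_amp, hf_amp, _ = params.for_state(is_stressor(kind))
        phase = np.interp(t, pt, pv)
        interval = (60.0 / hr
                    + lf_amp * np.sin(2.0 * np.pi * 0.1 * t)
                    + hf_amp * np.sin(phase))
        if params.rr_noise_sd > 0:
            interval += rng.normal(0.0, params.rr_noise_sd)
        interval = max(interval, 0.25)
        if t + interval > total:
            break
        t += interval
        r_times.append(t)
        rr.append(interval)
    return np.asarray(r_times), np.asarray(rr)


# ---------------------------------------------------------------------------
# ECG rendering
# ---------------------------------------------------------------------------

def render_ecg(
    r_times: np.ndarray,
    fs: float,
    params: StressParams,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
    template: Sequence[tuple[str, float, float, float]] = PQRST_TEMPLATE,
) -> SignalTrace:
    """Render an ECG trace as a train of five-Gaussian PQRST beats.

    Optional additive disturbances: a 60 Hz powerline sinusoid
    (``params.powerline_amp``) and sub-0.5 Hz baseline wander
    (``params.baseline_wander_amp``).
    """
    if fs < 300.0:
        raise ValueError(
            "fs must be >= 300 Hz (bandpass upper edge 150 Hz needs headroom "
            "below Nyquist)")
    r_times = np.asarray(r_times, dtype=float)
    if len(r_times) > 1 and np.any(np.diff(r_times) <= 0):
        raise ValueError("r_times must be strictly increasing")
    if duration is None:
        duration = float(r_times[-1]) + 1.0 if len(r_times) else 1.0
    n = int(round(duration * fs))
    x = np.zeros(n)
    if rng is None:
        rng = np.random.default_rng(0)

    for _, off, width, amp in template:
        centers = r_times + off
        half = int(np.ceil(4.0 * width * fs))
        grid = (np.round(centers * fs).astype(int)[:, None]
                + np.arange(-half, half + 1)[None, :])
        tt = grid / fs - centers[:, None]
        vals = amp * np.exp(-0.5 * (tt / width) ** 2)
        ok = (grid >= 0) & (grid < n)
        np.add.at(x, grid[ok], vals[ok])

    t = np.arange(n) / fs
    if params.baseline_wander_amp > 0:
        for f in (0.15, 0.33):
            x += (params.baseline_wander_amp / 2.0
                  * np.sin(2.0 * np.pi * f * t + rng.uniform(0, 2 * np.pi)))
    if params.powerline_amp > 0:
        x += params.powerline_amp * np.sin(
            2.0 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
    return SignalTrace(samples=x.astype(np.float64), fs=fs, channel="ECG")


# ---------------------------------------------------------------------------
# Respiration rendering
# ---------------------------------------------------------------------------

def render_resp(
    schedule: ProtocolSchedule,
    params: StressParams,
    fs: float,
    rng_seed: int,
    resp_phase: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[SignalTrace, np.ndarray, np.ndarray]:
    """Quasi-sinusoidal respiration whose instantaneous frequency is the
    state's breathing rate.

    Returns ``(trace, peak_times, trough_times)``; peak (inspiration) and
    trough (expiration) times come from the noise-free phase and are exact.
    """
    if fs < 10.0:
        raise ValueError("respiration fs must be >= 10 Hz")
    rng = np.random.default_rng(rng_seed)
    if resp_phase is None:
        resp_phase = _resp_phase_grid(schedule, params)
    pt, pv = resp_phase
    n = int(round(schedule.total_duration * fs))
    t = np.arange(n) / fs
    phase = np.interp(t, pt, pv)
    x = np.sin(phase)
    if params.resp_noise_sd > 0:
        x = x + rng.normal(0.0, params.resp_noise_sd, size=n)

    peaks = _phase_crossings(pt, pv, np.pi / 2.0)
    troughs = _phase_crossings(pt, pv, 3.0 * np.pi / 2.0)
    trace = SignalTrace(samples=x, fs=fs, channel="RESP")
    return trace, peaks, troughs


def _phase_crossings(pt: np.ndarray, pv: np.ndarray,
                     target: float) -> np.ndarray:
    """Times where the monotone phase crosses ``target`` (mod 2*pi)."""
    out = []
    k = int(np.floor((pv[0] - target) / (2 * np.pi))) + 1
    while True:
        level = target + 2 * np.pi * k
        if level > pv[-1]:
            break
        i = int(np.searchsorted(pv, level))
        if i == 0:
            t = pt[0]
        else:
            # linear interpolation inside the grid cell
            f = (level - pv[i - 1]) / (pv[i] - pv[i - 1])
            t = pt[i - 1] + f * (pt[i] - pt[i - 1])
        out.append(t)
        k += 1
    return np.asarray(out)


# ---------------------------------------------------------------------------
# VAS and cohort
# ---------------------------------------------------------------------------

#: Mean and SD of the simulated 0-10 self-report score per task kind.
VAS_MODEL = {
    TASK_RELAX: (2.0, 1.0),
    "easy_math": (5.0, 1.5),
    "easy_stroop": (5.0, 1.5),
    "hard_math": (7.0, 1.5),
    "hard_stroop": (6.0, 1.5),
}


def _difficulty(kind: str) -> str:
    if kind == TASK_RELAX:
        return ""
    return kind.split("_")[0]


def simulate_subject(
    subject_id: str,
    params: StressParams,
    rng_seed,
    fs_ecg: float = 1000.0,
    fs_resp: float = 25.0,
    jitter: bool = True,
) -> SubjectRecording:
    """One subject: seeded schedule, physiology jitter, signals, VAS."""
    rng = np.random.default_rng(rng_seed)
    schedule = make_protocol(int(rng.integers(0, 2**31 - 1)))

    p = params
    if jitter:
        dhr = rng.normal(0.0, 2.0)
        drr = rng.normal(0.0, 0.8)
        p = replace(
            params,
            hr_mean_relax=params.hr_mean_relax + dhr,
            hr_mean_stress=params.hr_mean_stress + dhr,
            resp_rate_relax=max(params.resp_rate_relax + drr, 8.0),
            resp_rate_stress=max(params.resp_rate_stress + drr, 8.0),
        )
    p.validate()

    phase = _resp_phase_grid(schedule, p)
    r_times, _ = simulate_rr_series(
        schedule, p, int(rng.integers(0, 2**31 - 1)), resp_phase=phase)
    ecg = render_ecg(r_times, fs_ecg, p, duration=schedule.total_duration,
                     rng=np.random.default_rng(int(rng.integers(0, 2**31 - 1))))
    resp, peaks, troughs = render_resp(
        schedule, p, fs_resp, int(rng.integers(0, 2**31 - 1)), resp_phase=phase)

    annotations = []
    for kind, start, dur in schedule.tasks:
        mu, sd = VAS_MODEL[kind]
        vas = float(np.clip(rng.normal(mu, sd), 0.0, 10.0))
        annotations.append(TaskAnnotation(
            task_kind=kind, difficulty=_difficulty(kind),
            t_start=start, t_end=start + dur,
            label=int(is_stressor(kind)), vas=vas))
    return SubjectRecording(
        subject_id=subject_id, ecg=ecg, resp=resp, annotations=annotations,
        r_times=r_times, breath_peaks=peaks, breath_troughs=troughs)


def simulate_cohort(
    n_subjects: int,
    params: StressParams | None = None,
    rng_seed: int = 0,
    fs_ecg: float = 1000.0,
    fs_resp: float = 25.0,
) -> list[SubjectRecording]:
    """Simulate ``n_subjects`` independent recordings.

    Child generators are spawned deterministically from ``(rng_seed,
    subject index)`` so any subject can be re-simulated in isolation.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = params or StressParams()
    out = []
    for i in range(n_subjects):
        out.append(simulate_subject(
            f"S{i:02d}", params, [int(rng_seed), i],
            fs_ecg=fs_ecg, fs_resp=fs_resp))
    logger.info("simulated cohort of %d subjects (seed %s)", n_subjects,
                rng_seed)
    return out
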