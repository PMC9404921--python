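"""Synthetic multi-subject ECG with condition-dependent heart-rate structure.

The generator emulates the structure of wearable stress-study recordings:
each subject contributes one continuous single-lead stream recorded over an
ordered schedule of condition blocks (e.g. neutral / medium / high stress).
Conditions differ in mean heart rate and in beat-to-beat variability, so the
downstream machinery (R-peak detection, HRV features, classifiers) has a
real signal to recover.  Beats are a P-Q-R-S-T sum of five Gaussians placed
at RR-interval onsets; the RR series is ``60/(baseline_hr + shift(cond))``
plus AR(1) jitter.  Baseline wander (sub-0.5 Hz sinusoids), white sensor
noise and an optional hard saturation ceiling complete the picture.

This is deliberately not a physiologically validated ECG model — see the
methods note for what it does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import EcgRecord

__all__ = ["SubjectProfile", "ConditionSchedule", "gen_ecg_record", "gen_dataset"]

# Beat morphology: (offset, width, amplitude) of each wave as fractions of the
# instantaneous RR interval (offset, width) and of the R amplitude (amplitude).
_WAVES = {
    "P": (-0.22, 0.035, 0.15),
    "Q": (-0.035, 0.012, -0.15),
    "R": (0.0, 0.014, 1.0),
    "S": (0.035, 0.012, -0.25),
    "T": (0.28, 0.060, 0.35),
}

_AR1_COEF = 0.8  # short-range RR correlation
_MIN_RR_S = 0.25  # refractory floor for the jittered RR series


@dataclass
class SubjectProfile:
    """Per-subject generator parameters.

    ``hr_shift_per_condition`` maps a condition code to a heart-rate delta in
    bpm (stress raises HR); ``rr_jitter_sd_per_condition`` maps it to the
    stationary SD (seconds) of the AR(1) RR jitter (stress lowers HRV).
    """

    subject_id: str
    baseline_hr: float = 70.0
    hr_shift_per_condition: dict[int, float] = field(default_factory=dict)
    rr_jitter_sd_per_condition: dict[int, float] = field(default_factory=dict)
    wander_amplitude: float = 0.15
    noise_sd: float = 0.05
    amplitude_gain: float = 1.0
    saturation_level: float | None = None

    def __post_init__(self) -> None:
        if not 40.0 <= self.baseline_hr <= 200.0:
            raise ValueError(f"baseline_hr {self.baseline_hr} outside [40, 200] bpm")
        if any(sd < 0 for sd in self.rr_jitter_sd_per_condition.values()):
            raise ValueError("rr_jitter_sd must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ConditionSchedule:
    """Ordered condition blocks: list of (condition_code, duration_s)."""

    blocks: list[tuple[int, float]]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("schedule must contain at least one block")
        if any(d <= 0 for _, d in self.blocks):
            raise ValueError("block durations must be positive")

    @property
    def total_s(self) -> float:
        return float(sum(d for _, d in self.blocks))

    def condition_at(self, t: float) -> int:
        """Condition code at time t (last block extends to +inf)."""
        acc = 0.0
        for code, dur in self.blocks:
            acc += dur
            if t < acc:
                return code
        return self.blocks[-1][0]

    def label_stream(self, fs: float, n_samples: int) -> np.ndarray:
        labels = np.empty(n_samples, dtype=np.int64)
        start = 0
        acc = 0.0
        for code, dur in self.blocks:
            acc += dur
            stop = min(n_samples, int(round(acc * fs)))
            labels[start:stop] = code
            start = stop
        labels[start:] = self.blocks[-1][0]
        return labels


def _beat_times(
    profile: SubjectProfile, schedule: ConditionSchedule, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """R-peak times and the RR interval that follows each, over the schedule."""
    total = schedule.total_s
    times, rrs = [], []
    t = 0.1  # first beat shortly after record start
    jitter = 0.0
    while t < total:
        cond = schedule.condition_at(t)
        hr = profile.baseline_hr + profile.hr_shift_per_condition.get(cond, 0.0)
        hr = min(max(hr, 30.0), 220.0)
        sd = profile.rr_jitter_sd_per_condition.get(cond, 0.0)
        # AR(1) with stationary SD = sd
        innov_sd = sd * np.sqrt(1.0 - _AR1_COEF**2)
        jitter = _AR1_COEF * jitter + rng.normal(0.0, innov_sd) if sd > 0 else 0.0
        rr = max(60.0 / hr + jitter, _MIN_RR_S)
        times.append(t)
        rrs.append(rr)
        t += rr
    return np.asarray(times), np.asarray(rrs)


def gen_ecg_record(
    profile: SubjectProfile,
    schedule: ConditionSchedule,
    fs: float,
    seed: int,
) -> EcgRecord:
    """Synthesize one subject's ECG stream over a condition schedule.

    The record's metadata carries the ground-truth R-peak times
    (``rpeak_times``, comma-separated seconds) so detector accuracy can be
    scored against the generator.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz; must be >= 64 so the QRS complex is rendered.
    seed : int
        Seeds all noise sources; identical inputs give bit-identical output.
    """
    if fs < 64:
        raise ValueError(f"fs={fs} too low to render QRS morphology (need >= 64 Hz)")
    rng = np.random.default_rng(seed)
    n = int(round(schedule.total_s * fs))
    t_grid = np.arange(n) / fs
    signal = np.zeros(n)

    times, rrs = _beat_times(profile, schedule, rng)
    for t_r, rr in zip(times, rrs):
        lo = max(0, int((t_r - 0.45 * rr) * fs))
        hi = min(n, int(np.ceil((t_r + 0.55 * rr) * fs)) + 1)
        if lo >= hi:
            continue
        seg_t = t_grid[lo:hi]
        beat = np.zeros(hi - lo)
        for off_f, wid_f, amp in _WAVES.values():
            c = t_r + off_f * rr
            w = wid_f * rr
            beat += amp * np.exp(-0.5 * ((seg_t - c) / w) ** 2)
        signal[lo:hi] += profile.amplitude_gain * beat

    # baseline wander: two incommensurate sub-0.5 Hz sinusoids
    if profile.wander_amplitude > 0:
        f1, f2 = rng.uniform(0.05, 0.45, size=2)
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        signal += profile.wander_amplitude * (
            np.sin(2 * np.pi * f1 * t_grid + p1)
            + 0.5 * np.sin(2 * np.pi * f2 * t_grid + p2)
        )
    if profile.noise_sd > 0:
        signal += rng.normal(0.0, profile.noise_sd, size=n)
    if profile.saturation_level is not None:
        np.clip(signal, -profile.saturation_level, profile.saturation_level, out=signal)

    labels = schedule.label_stream(fs, n)
    meta = {
        "rpeak_times": ",".join(f"{t:.6f}" for t in times),
        "seed": str(seed),
    }
    return EcgRecord(
        subject_id=profile.subject_id, fs=fs, signal=signal, labels=labels, metadata=meta
    )


def true_rpeak_times(rec: EcgRecord) -> np.ndarray:
    """Parse the generator's ground-truth R-peak times back out of a record."""
    raw = rec.metadata.get("rpeak_times", "")
    if not raw:
        return np.empty(0)
    return np.array([float(v) for v in raw.split(",")])


def default_profile(
    subject_id: str,
    conditions: list[int],
    rng: np.random.Generator,
    saturation_level: float | None = None,
) -> SubjectProfile:
    """A randomly perturbed subject with stress-ordered condition effects.

    Condition codes are treated as ordered stress levels: each step up adds
    ~10 bpm of heart rate and removes beat-to-beat variability (RR jitter SD
    50 -> 30 -> 15 ms for levels 0/1/2, scaled for deeper schedules).
    """
    base_jitter = 0.05
    shifts = {c: 10.0 * i + rng.normal(0, 1.0) for i, c in enumerate(sorted(set(conditions)))}
    jitters = {
        c: max(base_jitter * (0.55**i) * rng.uniform(0.85, 1.15), 0.004)
        for i, c in enumerate(sorted(set(conditions)))
    }
    return SubjectProfile(
        subject_id=subject_id,
        baseline_hr=rng.uniform(60.0, 80.0),
        hr_shift_per_condition=shifts,
        rr_jitter_sd_per_condition=jitters,
        wander_amplitude=rng.uniform(0.1, 0.2),
        noise_sd=rng.uniform(0.03, 0.07),
        amplitude_gain=rng.uniform(0.8, 1.2),
        saturation_level=saturation_level,
    )


def gen_dataset(
    n_subjects: int,
    schedule_template: ConditionSchedule,
    fs: float,
    class_counts: dict[int, int] | None = None,
    seed: int = 0,
    window_s: float = 5.0,
    saturation_level: float | None = None,
) -> list[EcgRecord]:
    """Generate one record per subject with perturbed profiles.

    If ``class_counts`` maps condition -> desired number of windows (of
    ``window_s`` seconds) across the whole dataset, each subject's block
    durations are set to whole multiples of the window so that subsequent
    windowing reproduces the requested class histogram (emulating the
    242:88:48-style imbalance of small stress datasets).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    conditions = [c for c, _ in schedule_template.blocks]
    records = []
    for i in range(n_subjects):
        profile = default_profile(
            f"S{i:02d}", conditions, rng, saturation_level=saturation_level
        )
        if class_counts is None:
            schedule = schedule_template
        else:
            blocks = []
            for code, _ in schedule_template.blocks:
                want = class_counts.get(code, 0)
                share = want // n_subjects + (1 if i < want % n_subjects else 0)
                if share > 0:
                    blocks.append((code, share * window_s))
            if not blocks:
                blocks = [(conditions[0], window_s)]
            schedule = ConditionSchedule(blocks)
        records.append(
            gen_ecg_record(profile, schedule, fs, seed=int(rng.integers(0, 2**31 - 1)))
        )
    return records
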