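import numpy as np
import pytest

from ecgssl.preprocess import EcgPreprocessor
from ecgssl.records import SegmentSet
from ecgssl.synthetic import ConditionSchedule, SubjectProfile, gen_dataset, gen_ecg_record


@pytest.fixture(scope="session")
def clean_record():
    """60 s, 60 bpm, zero-jitter single-condition record at 256 Hz."""
    profile = SubjectProfile(
        "clean", baseline_hr=60.0,
        rr_jitter_sd_per_condition={0: 0.0},
        wander_amplitude=0.1, noise_sd=0.03,
    )
    return gen_ecg_record(profile, ConditionSchedule([(0, 60.0)]), 256.0, seed=7)


@pytest.fixture(scope="session")
def small_segments():
    """~108 preprocessed 5 s segments from 3 subjects x 3 conditions."""
    records = gen_dataset(
        3, ConditionSchedule([(0, 60.0), (1, 60.0), (2, 60.0)]), 256.0, seed=11
    )
    return EcgPreprocessor(window_s=5.0, seed=11).transform(records)


@pytest.fixture(scope="session")
def separable_segments():
    """Two trivially separable waveform classes (n=64, L=256)."""
    rng = np.random.default_rng(3)
    t = np.arange(256) / 256.0
    rows, labels = [], []
    for i in range(64):
        cls = i % 2
        freq = 3.0 if cls == 0 else 11.0
        rows.append(np.sin(2 * np.pi * freq * t) + 0.05 * rng.normal(size=256))
        labels.append(cls)
    return SegmentSet(
        segments=np.asarray(rows), labels=np.asarray(labels),
        subject_ids=np.array([f"s{i % 4}" for i in range(64)]),
        fs=256.0, window_s=1.0,
    )
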