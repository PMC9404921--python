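"""Core data containers: per-subject ECG records and windowed segment sets.

An :class:`EcgRecord` is a continuous single-lead ECG stream for one subject,
with a per-sample condition label (the experimental block the sample was
recorded in).  A :class:`SegmentSet` is the model-ready view: fixed-length
windows cut from one or more records, each window carrying a single condition
label and the id of the subject it came from.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EcgRecord", "SegmentSet", "load_wesad_record"]


@dataclass
class EcgRecord:
    """Continuous single-lead ECG for one subject.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject the stream was recorded from.
    fs : float
        Sampling rate in Hz.
    signal : ndarray of shape (n_samples,)
        The ECG samples, in sensor units (or SD units after z-scoring).
    labels : ndarray of shape (n_samples,)
        Integer condition code of each sample.
    metadata : dict
        Free-form string annotations (e.g. generator parameters).
    """

    subject_id: str
    fs: float
    signal: np.ndarray
    labels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.signal.ndim != 1:
            raise ValueError("signal must be 1-D")
        if self.labels.shape != self.signal.shape:
            raise ValueError(
                f"labels length {self.labels.shape} != signal length {self.signal.shape}"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def to_npz(self, path: str | Path) -> None:
        np.savez(
            path,
            signal=self.signal,
            labels=self.labels,
            fs=np.float64(self.fs),
            subject_id=np.str_(self.subject_id),
            **{f"meta_{k}": np.str_(v) for k, v in self.metadata.items()},
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "EcgRecord":
        with np.load(path) as z:
            meta = {
                k[len("meta_"):]: str(z[k]) for k in z.files if k.startswith("meta_")
            }
            return cls(
                subject_id=str(z["subject_id"]),
                fs=float(z["fs"]),
                signal=z["signal"],
                labels=z["labels"],
                metadata=meta,
            )

    def to_csv(self, path: str | Path) -> None:
        """Two-column dialect: sample value, condition label."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["value", "label"])
            for v, l in zip(self.signal, self.labels):
                w.writerow([repr(float(v)), int(l)])

    @classmethod
    def from_csv(
        cls, path: str | Path, fs: float, subject_id: str = "unknown"
    ) -> "EcgRecord":
        values, labels = [], []
        with open(path, newline="") as fh:
            r = csv.reader(fh)
            next(r)  # header
            for row in r:
                values.append(float(row[0]))
                labels.append(int(row[1]))
        return cls(subject_id=subject_id, fs=fs, signal=np.array(values), labels=np.array(labels))


@dataclass
class SegmentSet:
    """Fixed-length labelled ECG windows.

    ``segments`` is an ``(n, L)`` matrix with ``L = round(fs * window_s)``;
    row ``i`` carries condition ``labels[i]`` and came from ``subject_ids[i]``.
    """

    segments: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    fs: float
    window_s: float

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.str_)
        if self.segments.ndim != 2:
            raise ValueError("segments must be a 2-D (n, L) matrix")
        n = self.segments.shape[0]
        if self.labels.shape[0] != n or self.subject_ids.shape[0] != n:
            raise ValueError("labels / subject_ids length must match segment count")
        L = int(round(self.fs * self.window_s))
        if n > 0 and self.segments.shape[1] != L:
            raise ValueError(
                f"segment length {self.segments.shape[1]} != round(fs*window_s) = {L}"
            )
        if n > 0 and not np.all(np.isfinite(self.segments)):
            raise ValueError("segments contain non-finite values")

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def segment_length(self) -> int:
        return self.segments.shape[1] if len(self) else int(round(self.fs * self.window_s))

    def subset(self, idx) -> "SegmentSet":
        idx = np.asarray(idx)
        return SegmentSet(
            segments=self.segments[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            fs=self.fs,
            window_s=self.window_s,
        )

    @staticmethod
    def concatenate(parts: list["SegmentSet"]) -> "SegmentSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        fs, ws = parts[0].fs, parts[0].window_s
        if any(p.fs != fs or p.window_s != ws for p in parts):
            raise ValueError("all parts must share fs and window_s")
        return SegmentSet(
            segments=np.concatenate([p.segments for p in parts], axis=0),
            labels=np.concatenate([p.labels for p in parts]),
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
            fs=fs,
            window_s=ws,
        )

    def to_npz(self, path: str | Path) -> None:
        np.savez(
            path,
            segments=self.segments,
            labels=self.labels,
            subject_ids=self.subject_ids,
            fs=np.float64(self.fs),
            window_s=np.float64(self.window_s),
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "SegmentSet":
        with np.load(path) as z:
            return cls(
                segments=z["segments"],
                labels=z["labels"],
                subject_ids=z["subject_ids"],
                fs=float(z["fs"]),
                window_s=float(z["window_s"]),
            )


def load_wesad_record(path: str | Path, subject_id: str | None = None,
                      fs: float = 700.0) -> EcgRecord:
    """Read one subject of a WESAD-layout pickle into an :class:`EcgRecord`.

    Expects the public wearable-stress-dataset layout: a pickled dict with
    chest-ECG samples under ``["signal"]["chest"]["ECG"]`` and per-sample
    condition codes under ``["label"]``.  Optional convenience for users
    with the real download; nothing in the package requires it.
    """
    import pickle

    with open(path, "rb") as fh:
        data = pickle.load(fh, encoding="latin1")
    signal = np.asarray(data["signal"]["chest"]["ECG"]).ravel()
    labels = np.asarray(data["label"]).ravel()[: signal.shape[0]]
    sid = subject_id or str(data.get("subject", Path(path).stem))
    return EcgRecord(subject_id=sid, fs=fs, signal=signal,
                     labels=labels.astype(int), metadata={"source": "wesad"})
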