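"""ECG preprocessing: resampling, baseline removal, normalization, windowing, SMOTE.

The canonical chain, in fixed order:

    resample -> high-pass (0.8 Hz) -> per-subject z-score -> saturation clip
             -> non-overlapping windows -> (optional) SMOTE class balancing

``EcgPreprocessor`` bundles the chain as a stateless scikit-learn style
transformer over lists of :class:`~ecgssl.records.EcgRecord`;
``SmoteBalancer`` is a ``fit_resample`` estimator over plain (X, y) arrays.
The module-level functions expose each stage individually.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .records import EcgRecord, SegmentSet

__all__ = [
    "resample_record",
    "highpass_baseline",
    "zscore_per_subject",
    "clip_saturation",
    "window_record",
    "smote_balance",
    "SmoteBalancer",
    "EcgPreprocessor",
]


def resample_record(rec: EcgRecord, fs_out: float) -> EcgRecord:
    """Polyphase rational resampling with anti-aliasing (e.g. 700 -> 256 Hz).

    Labels are carried over by nearest-neighbour so every output sample keeps
    the condition code of the input sample it came from.
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_out == rec.fs:
        return rec
    if fs_out > rec.fs:
        warnings.warn(
            f"upsampling {rec.fs} -> {fs_out} Hz adds no information", stacklevel=2
        )
    frac = Fraction(fs_out / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(rec.signal, up, down)
    n_out = out.shape[0]
    src_idx = np.clip(
        np.round(np.arange(n_out) * rec.fs / fs_out).astype(int), 0, rec.n_samples - 1
    )
    return EcgRecord(
        subject_id=rec.subject_id,
        fs=fs_out,
        signal=out,
        labels=rec.labels[src_idx],
        metadata=dict(rec.metadata),
    )


def highpass_baseline(rec: EcgRecord, passband_hz: float = 0.8) -> EcgRecord:
    """Remove baseline wander with a zero-phase Chebyshev high-pass at 0.8 Hz.

    The mean is subtracted, then a type-II design (order 4, 40 dB stop-band
    attenuation, stop-band edge at half the pass-band frequency) is applied
    forward-backward (``sosfiltfilt``) so R-peak timing is not shifted.
    """
    if rec.fs <= 2 * passband_hz:
        raise ValueError(f"passband {passband_hz} Hz at or above Nyquist ({rec.fs / 2} Hz)")
    stop_hz = passband_hz / 2.0
    sos = sps.cheby2(4, 40.0, stop_hz, btype="highpass", fs=rec.fs, output="sos")
    # remove the mean first: the type-II stop-band floor (-40 dB/pass) would
    # otherwise leave a residual of any large DC offset
    filtered = sps.sosfiltfilt(sos, rec.signal - np.mean(rec.signal))
    return EcgRecord(
        subject_id=rec.subject_id,
        fs=rec.fs,
        signal=filtered,
        labels=rec.labels.copy(),
        metadata=dict(rec.metadata),
    )


def zscore_per_subject(recs: list[EcgRecord]) -> list[EcgRecord]:
    """Standardize each record with its own mean/SD (no cross-subject pooling)."""
    out = []
    for rec in recs:
        if rec.n_samples < 2:
            raise ValueError(f"record {rec.subject_id}: need > 1 sample to z-score")
        sd = float(np.std(rec.signal))
        if sd == 0.0:
            raise ValueError(f"record {rec.subject_id}: zero variance, cannot z-score")
        out.append(
            EcgRecord(
                subject_id=rec.subject_id,
                fs=rec.fs,
                signal=(rec.signal - np.mean(rec.signal)) / sd,
                labels=rec.labels.copy(),
                metadata=dict(rec.metadata),
            )
        )
    return out


def clip_saturation(rec: EcgRecord, bound_sd: float = 10.0) -> EcgRecord:
    """Clamp z-scored amplitude to [-bound_sd, +bound_sd] (sensor saturation)."""
    if bound_sd <= 0:
        raise ValueError("bound_sd must be positive")
    return EcgRecord(
        subject_id=rec.subject_id,
        fs=rec.fs,
        signal=np.clip(rec.signal, -bound_sd, bound_sd),
        labels=rec.labels.copy(),
        metadata=dict(rec.metadata),
    )


def window_record(rec: EcgRecord, window_s: float, stride_s: float | None = None) -> SegmentSet:
    """Cut ``window_s``-second windows with uniform labels.

    Consecutive and non-overlapping by default; pass ``stride_s`` smaller
    than ``window_s`` for overlapping windows.  Windows that span a
    condition change are discarded (ambiguous supervision); the tail
    shorter than one window is discarded.
    """
    L = int(round(rec.fs * window_s))
    step = L if stride_s is None else max(1, int(round(rec.fs * stride_s)))
    n_win = (rec.n_samples - L) // step + 1 if rec.n_samples >= L else 0
    if n_win == 0:
        warnings.warn(
            f"record {rec.subject_id} shorter than one {window_s} s window", stacklevel=2
        )
        return SegmentSet(
            segments=np.empty((0, L)),
            labels=np.empty(0, dtype=int),
            subject_ids=np.empty(0, dtype=str),
            fs=rec.fs,
            window_s=window_s,
        )
    segs, labs = [], []
    for i in range(n_win):
        sl = slice(i * step, i * step + L)
        win_labels = rec.labels[sl]
        if np.all(win_labels == win_labels[0]):
            segs.append(rec.signal[sl])
            labs.append(int(win_labels[0]))
    n = len(segs)
    return SegmentSet(
        segments=np.asarray(segs).reshape(n, L),
        labels=np.asarray(labs, dtype=int),
        subject_ids=np.full(n, rec.subject_id),
        fs=rec.fs,
        window_s=window_s,
    )


class SmoteBalancer(BaseEstimator):
    """Synthetic Minority Oversampling over flat feature rows.

    Every class is oversampled to the majority count.  A synthetic row is a
    convex combination ``s_i + u * (s_j - s_i)`` with ``u ~ U(0, 1)`` of a
    minority row and one of its ``k_neighbors`` nearest minority-class
    neighbours (Euclidean).  Original rows are always preserved; if a class
    is smaller than ``k_neighbors + 1`` the neighbourhood shrinks to
    ``class size - 1``.

    Parameters
    ----------
    k_neighbors : int, default=5
        Neighbourhood size for interpolation partners.
    random_state : int, default=0
        Seeds partner and interpolation draws; resampling is deterministic.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        classes, counts = np.unique(y, return_counts=True)
        if classes.shape[0] < 2:
            warnings.warn("single-class input: nothing to balance", stacklevel=2)
            self.sample_indices_ = np.arange(len(y))
            return X, y
        n_major = int(counts.max())
        rng = np.random.default_rng(self.random_state)
        X_parts, y_parts = [X], [y]
        parents = []
        for cls, cnt in zip(classes, counts):
            need = n_major - int(cnt)
            if need == 0:
                continue
            if cnt < 2:
                raise ValueError(f"class {cls} has {cnt} member(s); SMOTE needs >= 2")
            rows = np.flatnonzero(y == cls)
            Xc = X[rows]
            k = min(self.k_neighbors, int(cnt) - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            # drop column 0 (each row's nearest neighbour is itself)
            nbrs = nn.kneighbors(Xc, return_distance=False)[:, 1:]
            base = rng.integers(0, cnt, size=need)
            partner = nbrs[base, rng.integers(0, k, size=need)]
            u = rng.uniform(0.0, 1.0, size=(need, 1))
            X_parts.append(Xc[base] + u * (Xc[partner] - Xc[base]))
            y_parts.append(np.full(need, cls, dtype=y.dtype))
            parents.append(rows[base])
        self.sample_indices_ = np.concatenate(
            [np.arange(len(y))] + parents if parents else [np.arange(len(y))]
        )
        return np.concatenate(X_parts, axis=0), np.concatenate(y_parts)


def smote_balance(segs: SegmentSet, k_neighbors: int = 5, seed: int = 0) -> SegmentSet:
    """Balance a SegmentSet's class histogram to the majority count via SMOTE.

    Synthetic segments inherit the subject id of the minority row they were
    interpolated from.  With the 242/88/48 imbalance of a small three-level
    stress corpus this yields 3 x 242 = 726 segments.
    """
    bal = SmoteBalancer(k_neighbors=k_neighbors, random_state=seed)
    X, y = bal.fit_resample(segs.segments, segs.labels)
    return SegmentSet(
        segments=X,
        labels=y,
        subject_ids=segs.subject_ids[bal.sample_indices_],
        fs=segs.fs,
        window_s=segs.window_s,
    )


class EcgPreprocessor(BaseEstimator):
    """The full record-to-segments chain as one configurable transformer.

    Stages run in fixed order: resample to ``fs_out``, high-pass at
    ``passband_hz``, per-subject z-score, clip at ``bound_sd``, window into
    ``window_s``-second segments, and (optionally) SMOTE-balance the pooled
    segments.  Stateless: ``transform`` does not fit anything across calls.
    """

    def __init__(
        self,
        fs_out: float = 256.0,
        passband_hz: float = 0.8,
        bound_sd: float = 10.0,
        window_s: float = 10.0,
        smote: bool = False,
        k_neighbors: int = 5,
        seed: int = 0,
    ):
        self.fs_out = fs_out
        self.passband_hz = passband_hz
        self.bound_sd = bound_sd
        self.window_s = window_s
        self.smote = smote
        self.k_neighbors = k_neighbors
        self.seed = seed

    def fit(self, records: list[EcgRecord], y=None) -> "EcgPreprocessor":
        return self

    def transform(self, records: list[EcgRecord]) -> SegmentSet:
        recs = [resample_record(r, self.fs_out) for r in records]
        recs = [highpass_baseline(r, self.passband_hz) for r in recs]
        recs = zscore_per_subject(recs)
        recs = [clip_saturation(r, self.bound_sd) for r in recs]
        parts = [window_record(r, self.window_s) for r in recs]
        segs = SegmentSet.concatenate(parts)
        if self.smote:
            segs = smote_balance(segs, k_neighbors=self.k_neighbors, seed=self.seed)
        return segs

    def fit_transform(self, records: list[EcgRecord], y=None) -> SegmentSet:
        return self.fit(records).transform(records)
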