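"""Comparison arms: HRV-feature SVM and the fully supervised CNN.

Heart-rate variability (HRV) summarizes the beat-to-beat RR interval series
and is the classical gold standard for ECG stress assessment.  This module
detects R peaks (Pan-Tompkins-style band-pass / derivative / square /
moving-integration with an adaptive threshold), derives the nine standard
features — HR, RMSSD, AVNN, SDNN, pNN50 and the VLF/LF/HF band powers plus
their total TP — and trains an RBF SVM on them.  The fully supervised CNN
benchmark is the downstream classifier with random initialization; it
differs from the self-supervised arm only in provenance of the encoder
weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import SimpleImputer
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .downstream import CnnClassifier
from .records import EcgRecord, SegmentSet

__all__ = [
    "HRVFeatureVector",
    "detect_rpeaks",
    "hrv_features",
    "HrvFeatureExtractor",
    "make_svm_pipeline",
    "svm_baseline",
    "supervised_baseline",
]

FEATURE_NAMES = ("HR", "RMSSD", "AVNN", "SDNN", "pNN50", "VLF", "LF", "HF", "TP")

# canonical short-term frequency bands (Hz)
_BANDS = {"VLF": (0.0033, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.4)}
_MIN_FREQ_SPAN_S = 30.0
_RR_INTERP_HZ = 4.0


@dataclass
class HRVFeatureVector:
    """The nine classical HRV features; frequency powers are ``None`` when
    the RR series is too short (< 30 s) to resolve them."""

    HR: float
    RMSSD: float
    AVNN: float
    SDNN: float
    pNN50: float
    VLF: float | None = None
    LF: float | None = None
    HF: float | None = None
    TP: float | None = None

    def to_array(self) -> np.ndarray:
        vals = [self.HR, self.RMSSD, self.AVNN, self.SDNN, self.pNN50,
                self.VLF, self.LF, self.HF, self.TP]
        return np.array([np.nan if v is None else float(v) for v in vals])


def detect_rpeaks(x, fs: float) -> np.ndarray:
    """Detect R peaks; returns strictly increasing sample indices.

    Pan-Tompkins-style chain: 5-15 Hz band-pass, derivative, squaring,
    150 ms moving integration, adaptive-threshold peak picking with a 200 ms
    refractory period, then refinement of each peak to the local maximum of
    the squared band-passed signal.
    """
    x = x.signal if isinstance(x, EcgRecord) else np.asarray(x, dtype=np.float64)
    if fs < 64:
        raise ValueError("fs must be >= 64 Hz")
    if x.shape[0] < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    sq = np.gradient(filt) ** 2
    win = max(int(0.15 * fs), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")
    refractory = int(0.2 * fs)
    cand, _ = sps.find_peaks(integ, distance=refractory)
    if cand.shape[0] == 0 or np.max(integ) <= 0:
        warnings.warn("no detectable R peaks", stacklevel=2)
        return np.empty(0, dtype=int)
    thr = 0.25 * np.percentile(integ[cand], 90)
    cand = cand[integ[cand] > thr]
    if cand.shape[0] == 0:
        warnings.warn("no detectable R peaks above threshold", stacklevel=2)
        return np.empty(0, dtype=int)
    # refine to the sharpest deflection of the band-passed signal
    half = int(0.10 * fs)
    fsq = filt**2
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(x.shape[0], c + half + 1)
        peaks.append(lo + int(np.argmax(fsq[lo:hi])))
    peaks = np.unique(peaks)
    # enforce refractory: among peaks closer than 200 ms keep the larger
    keep: list[int] = []
    for p in peaks:
        if keep and p - keep[-1] < refractory:
            if fsq[p] > fsq[keep[-1]]:
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    return np.asarray(keep, dtype=int)


def hrv_features(rpeaks: np.ndarray, fs: float) -> HRVFeatureVector:
    """Nine-feature HRV summary of an R-peak index sequence.

    Time domain needs >= 3 peaks; frequency powers additionally need a
    >= 30 s span and are reported as missing (``None``) below that.  The
    spectral path interpolates the RR series to a uniform 4 Hz grid,
    removes the linear trend, and integrates a Welch periodogram over the
    canonical VLF/LF/HF bands; TP is their sum.
    """
    rpeaks = np.asarray(rpeaks)
    if rpeaks.shape[0] < 3:
        raise ValueError("need >= 3 R peaks for HRV features")
    rr = np.diff(rpeaks) / fs * 1000.0  # ms
    avnn = float(np.mean(rr))
    sdnn = float(np.std(rr, ddof=1))
    drr = np.diff(rr)
    rmssd = float(np.sqrt(np.mean(drr**2)))
    pnn50 = float(np.mean(np.abs(drr) > 50.0)) if drr.size else 0.0
    hr = 60000.0 / avnn

    span_s = (rpeaks[-1] - rpeaks[0]) / fs
    vlf = lf = hf = tp = None
    if span_s >= _MIN_FREQ_SPAN_S:
        t_rr = rpeaks[1:] / fs  # each RR stamped at its closing beat
        t_grid = np.arange(t_rr[0], t_rr[-1], 1.0 / _RR_INTERP_HZ)
        rr_interp = np.interp(t_grid, t_rr, rr)
        rr_interp = sps.detrend(rr_interp, type="linear")
        nperseg = min(256, rr_interp.shape[0])
        freqs, psd = sps.welch(rr_interp, fs=_RR_INTERP_HZ, nperseg=nperseg)
        powers = {}
        for name, (flo, fhi) in _BANDS.items():
            m = (freqs >= flo) & (freqs < fhi)
            powers[name] = float(np.trapezoid(psd[m], freqs[m])) if np.any(m) else 0.0
        vlf, lf, hf = powers["VLF"], powers["LF"], powers["HF"]
        tp = vlf + lf + hf
    return HRVFeatureVector(HR=hr, RMSSD=rmssd, AVNN=avnn, SDNN=sdnn, pNN50=pnn50,
                            VLF=vlf, LF=lf, HF=hf, TP=tp)


class HrvFeatureExtractor(BaseEstimator, TransformerMixin):
    """Segment matrix -> (n, 9) HRV feature matrix (NaN where undefined).

    Rows where fewer than 3 R peaks are found, and frequency columns for
    windows shorter than 30 s, come out as NaN; downstream pipelines impute
    or drop them.
    """

    def __init__(self, fs: float = 256.0):
        self.fs = fs

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        if isinstance(X, SegmentSet):
            fs, rows = X.fs, X.segments
        else:
            fs, rows = self.fs, np.asarray(X, dtype=np.float64)
        out = np.full((rows.shape[0], len(FEATURE_NAMES)), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, row in enumerate(rows):
                peaks = detect_rpeaks(row, fs)
                if peaks.shape[0] >= 3:
                    out[i] = hrv_features(peaks, fs).to_array()
        return out


def make_svm_pipeline(C: float = 1.0, kernel: str = "rbf", seed: int = 0) -> Pipeline:
    """Impute -> standardize -> RBF SVM; all statistics fit on the train fold only."""
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="mean")),
            ("scale", StandardScaler()),
            ("svm", SVC(C=C, kernel=kernel, random_state=seed)),
        ]
    )


def svm_baseline(features, labels, test_ratio: float = 0.1, n_folds: int = 10,
                 seed: int = 0, C: float = 1.0, kernel: str = "rbf"):
    """10-shuffled-fold SVM on HRV feature vectors; returns a FoldReport."""
    from .evaluation import evaluate_arrays

    X = np.asarray(
        [f.to_array() if isinstance(f, HRVFeatureVector) else np.asarray(f, dtype=float)
         for f in features]
    )
    y = np.asarray(labels)
    return evaluate_arrays(
        X, y,
        make_model=lambda fold_seed: make_svm_pipeline(C=C, kernel=kernel, seed=fold_seed),
        test_ratio=test_ratio, n_folds=n_folds, base_seed=seed,
        config_echo={"pipeline": "hrv-svm", "C": C, "kernel": kernel},
    )


def supervised_baseline(segs: SegmentSet, ecfg, tcfg, test_ratio: float = 0.1,
                        n_folds: int = 10, seed: int = 0):
    """Fully supervised CNN benchmark: downstream model, random init, same protocol."""
    from .evaluation import evaluate_arrays

    def make_model(fold_seed: int) -> CnnClassifier:
        return CnnClassifier(
            init_weights=None,
            filters=ecfg.filters,
            kernels=ecfg.kernels,
            pool_size=ecfg.pool_size,
            dropout_rate=ecfg.dropout_rate,
            dense_units=ecfg.dense_units,
            l2_coeff=ecfg.l2_coeff,
            learning_rate=tcfg.learning_rate,
            batch_size=tcfg.batch_size,
            epochs=tcfg.epochs,
            random_state=fold_seed,
        )

    return evaluate_arrays(
        segs.segments, segs.labels, make_model=make_model,
        test_ratio=test_ratio, n_folds=n_folds, base_seed=seed,
        config_echo={"pipeline": "supervised", "epochs": tcfg.epochs,
                     "learning_rate": tcfg.learning_rate},
    )
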