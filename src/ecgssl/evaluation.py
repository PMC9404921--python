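"""Evaluation protocol: 10 random-shuffle splits, accuracy mean +/- SD, ablations.

"10 folds" here means ten independent random train/test splits at a fixed
test-train ratio (Monte-Carlo cross-validation), not a partition-based
k-fold — the ratio sweep from 10-90 to 90-10 requires the former.  Splits
are segment-level; an optional subject-wise mode keeps each subject's
segments on one side of the split.  Accuracy is aggregated as the mean and
SD over fold accuracies, and confusion matrices are pooled over folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .contrastive import ContrastivePretrainer
from .downstream import CnnClassifier
from .records import SegmentSet

__all__ = [
    "FoldReport",
    "shuffle_split",
    "evaluate_arrays",
    "evaluate_pipeline",
    "ratio_ablation",
    "augmentation_grid",
]

AUG_ORDER = ("scale", "negate", "hflip", "noise_snr", "timewarp", "permute")


@dataclass
class FoldReport:
    """Aggregate of one n-fold shuffled-split experiment."""

    test_ratio: float
    fold_accuracies: list[float]
    confusion: np.ndarray  # rows = true class, pooled over folds
    classes: list
    config_echo: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "test_ratio": self.test_ratio,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "confusion": np.asarray(self.confusion).tolist(),
            "classes": [int(c) for c in self.classes],
            "config_echo": self.config_echo,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def shuffle_split(
    n: int, test_ratio: float, fold_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One random disjoint-exhaustive train/test index split.

    ``|test| = round(n * test_ratio)``; the permutation is deterministic per
    fold seed.
    """
    if not 0.0 < test_ratio < 1.0:
        raise ValueError("test_ratio must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_test = int(round(n * test_ratio))
    if n_test < 1 or n_test >= n:
        raise ValueError(f"degenerate split: {n_test} test of {n}")
    perm = np.random.default_rng(fold_seed).permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def _subject_split(subject_ids, test_ratio, fold_seed):
    """Subject-exclusive variant: whole subjects go to one side."""
    subjects = np.unique(subject_ids)
    if subjects.shape[0] < 2:
        raise ValueError("subject-wise split needs >= 2 subjects")
    n_test = max(1, int(round(subjects.shape[0] * test_ratio)))
    if n_test >= subjects.shape[0]:
        n_test = subjects.shape[0] - 1
    perm = np.random.default_rng(fold_seed).permutation(subjects.shape[0])
    test_subj = set(subjects[perm[:n_test]])
    mask = np.array([s in test_subj for s in subject_ids])
    return np.flatnonzero(~mask), np.flatnonzero(mask)


def evaluate_arrays(
    X: np.ndarray,
    y: np.ndarray,
    make_model,
    test_ratio: float,
    n_folds: int = 10,
    base_seed: int = 0,
    subject_ids=None,
    subject_wise: bool = False,
    config_echo: dict | None = None,
    max_redraws: int = 5,
    train_transform=None,
) -> FoldReport:
    """Run the shuffled-split protocol for any fit/predict model factory.

    ``make_model(fold_seed)`` must return an estimator with ``fit(X, y)``
    and ``predict(X)``.  ``train_transform(X_tr, y_tr, fold_seed)``, if
    given, is applied to the training half of every fold (e.g. leakage-safe
    SMOTE); the test half is never touched.  A fold whose training half
    misses a class is redrawn (at most ``max_redraws`` times) before
    erroring out.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes = np.unique(y)
    fold_accs: list[float] = []
    conf = np.zeros((classes.shape[0], classes.shape[0]), dtype=int)
    ss = np.random.SeedSequence(base_seed)
    fold_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n_folds * (max_redraws + 1))]
    seed_iter = iter(fold_seeds)
    for _ in range(n_folds):
        for attempt in range(max_redraws + 1):
            fold_seed = next(seed_iter)
            if subject_wise:
                tr, te = _subject_split(subject_ids, test_ratio, fold_seed)
            else:
                tr, te = shuffle_split(X.shape[0], test_ratio, fold_seed)
            if np.unique(y[tr]).shape[0] == classes.shape[0]:
                break
        else:
            raise RuntimeError(
                f"could not draw a fold with all classes in train after {max_redraws} redraws"
            )
        model = make_model(fold_seed)
        X_tr, y_tr = X[tr], y[tr]
        if train_transform is not None:
            X_tr, y_tr = train_transform(X_tr, y_tr, fold_seed)
        model.fit(X_tr, y_tr)
        pred = np.asarray(model.predict(X[te]))
        fold_accs.append(float(np.mean(pred == y[te])))
        conf += confusion_matrix(y[te], pred, labels=classes)
    return FoldReport(
        test_ratio=test_ratio,
        fold_accuracies=fold_accs,
        confusion=conf,
        classes=list(classes),
        config_echo={**(config_echo or {}), "n_folds": n_folds, "base_seed": base_seed,
                     "subject_wise": subject_wise},
    )


def _ssl_factory(segs: SegmentSet, augmentation: str | None, upstream: dict, downstream: dict,
                 base_seed: int):
    """Pretrain once on the full segment set, return a per-fold classifier factory."""
    pre = ContrastivePretrainer(
        augmentation=augmentation or "timewarp+scale",
        random_state=base_seed,
        **upstream,
    ).fit(segs)  # labels never passed: upstream is label-free
    arch = {k: getattr(pre, k) for k in
            ("filters", "kernels", "pool_size", "dropout_rate", "dense_units", "l2_coeff")
            if k not in downstream}

    def make_model(fold_seed: int) -> CnnClassifier:
        return CnnClassifier(
            init_weights=pre.encoder_weights_, random_state=fold_seed, **arch, **downstream
        )

    return make_model, pre


def evaluate_pipeline(
    segs: SegmentSet,
    pipeline: str,
    test_ratio: float,
    n_folds: int = 10,
    base_seed: int = 0,
    augmentation: str | None = None,
    upstream: dict | None = None,
    downstream: dict | None = None,
    svm: dict | None = None,
    subject_wise: bool = False,
    smote_train_only: bool = False,
) -> FoldReport:
    """Evaluate one of the named pipelines under the shuffled-split protocol.

    ``pipeline`` is ``"contrastive-ssl"`` (pretrain on all segments, then
    per fold fine-tune from the pretrained encoder), ``"supervised"``
    (random init), or ``"hrv-svm"``.  ``upstream`` / ``downstream`` /
    ``svm`` override estimator hyperparameters (epochs, learning rates,
    temperature, ...).  ``smote_train_only=True`` balances classes inside
    each fold's training half only — the leakage-safe alternative to
    balancing the corpus before splitting.
    """
    upstream = dict(upstream or {})
    downstream = dict(downstream or {})
    name = pipeline.lower().replace("_", "-")
    echo = {"pipeline": name, "augmentation": augmentation,
            "upstream": upstream, "downstream": downstream}
    if name == "contrastive-ssl":
        make_model, _ = _ssl_factory(segs, augmentation, upstream, downstream, base_seed)
        X, y = segs.segments, segs.labels
    elif name == "supervised":
        def make_model(fold_seed: int) -> CnnClassifier:
            return CnnClassifier(init_weights=None, random_state=fold_seed, **downstream)
        X, y = segs.segments, segs.labels
    elif name == "hrv-svm":
        from .baselines import HrvFeatureExtractor, make_svm_pipeline

        X = HrvFeatureExtractor(fs=segs.fs).transform(segs)
        y = segs.labels
        svm = dict(svm or {})

        def make_model(fold_seed: int):
            return make_svm_pipeline(seed=fold_seed, **svm)
    else:
        raise ValueError(f"unknown pipeline {pipeline!r}")
    train_transform = None
    if smote_train_only:
        from .preprocess import SmoteBalancer

        def train_transform(X_tr, y_tr, fold_seed):
            return SmoteBalancer(random_state=fold_seed).fit_resample(X_tr, y_tr)

        echo["smote_train_only"] = True
    return evaluate_arrays(
        X, y, make_model, test_ratio, n_folds=n_folds, base_seed=base_seed,
        subject_ids=segs.subject_ids, subject_wise=subject_wise, config_echo=echo,
        train_transform=train_transform,
    )


def ratio_ablation(
    segs: SegmentSet,
    augmentations: tuple[str, ...] = AUG_ORDER,
    ratios: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    n_folds: int = 10,
    base_seed: int = 0,
    upstream: dict | None = None,
    downstream: dict | None = None,
) -> pd.DataFrame:
    """Mean accuracy for every (test ratio, primary augmentation) cell.

    Rows are test-train ratios; the first column is the no-augmentation
    control (the downstream model from random init), the rest are single
    augmentations used for pretraining.
    """
    table = pd.DataFrame(index=[f"{r:.1f}" for r in ratios],
                         columns=("no_augmentation",) + tuple(augmentations), dtype=float)
    ds = dict(downstream or {})
    for ratio in ratios:
        rep = evaluate_pipeline(segs, "supervised", ratio, n_folds=n_folds,
                                base_seed=base_seed, downstream=ds)
        table.loc[f"{ratio:.1f}", "no_augmentation"] = rep.mean_accuracy
    for aug in augmentations:
        make_model, _ = _ssl_factory(segs, aug, dict(upstream or {}), ds, base_seed)
        for ratio in ratios:
            rep = evaluate_arrays(segs.segments, segs.labels, make_model, ratio,
                                  n_folds=n_folds, base_seed=base_seed,
                                  config_echo={"augmentation": aug})
            table.loc[f"{ratio:.1f}", aug] = rep.mean_accuracy
    return table


def augmentation_grid(
    segs: SegmentSet,
    aug_names: tuple[str, ...] = AUG_ORDER,
    test_ratio: float = 0.3,
    n_folds: int = 10,
    base_seed: int = 0,
    upstream: dict | None = None,
    downstream: dict | None = None,
) -> pd.DataFrame:
    """Accuracy matrix over ordered augmentation pairs at one split.

    Cell (i, j) pretrains with augmentation i followed by j; the diagonal
    is the single augmentation.  Order matters, so the matrix is not
    symmetric in general.
    """
    grid = pd.DataFrame(index=aug_names, columns=aug_names, dtype=float)
    for first in aug_names:
        for second in aug_names:
            name = first if first == second else f"{first}+{second}"
            rep = evaluate_pipeline(
                segs, "contrastive-ssl", test_ratio, n_folds=n_folds,
                base_seed=base_seed, augmentation=name,
                upstream=upstream, downstream=downstream,
            )
            grid.loc[first, second] = rep.mean_accuracy
    return grid
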