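"""Canned study-scale experiments on synthetic ECG.

These bundle the package's end-to-end claims into single calls so the test
suite and the reproduction script exercise exactly the same conditions.
Problem sizes are scaled to a laptop-class single core: six subjects with
three 110-second stress blocks each at 256 Hz, 5-second windows
(~396 segments of 1280 samples), the full 20 upstream epochs of the
standard protocol, and 40 downstream epochs (scaled down from the
full-size 150-250; the downstream count affects both comparison arms
equally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contrastive import ContrastivePretrainer
from .downstream import CnnClassifier
from .evaluation import shuffle_split
from .preprocess import EcgPreprocessor
from .records import SegmentSet
from .synthetic import ConditionSchedule, gen_dataset

__all__ = ["make_study_segments", "pretraining_benefit", "BenefitResult"]

STUDY = {
    "n_subjects": 6,
    "fs": 256.0,
    "block_s": 110.0,
    "n_conditions": 3,
    "window_s": 5.0,
    "upstream_epochs": 20,
    "downstream_epochs": 40,
}


def make_study_segments(seed: int, n_subjects: int | None = None,
                        block_s: float | None = None) -> SegmentSet:
    """Generate and preprocess the standard synthetic study corpus."""
    n_subjects = n_subjects or STUDY["n_subjects"]
    block_s = block_s or STUDY["block_s"]
    schedule = ConditionSchedule([(c, block_s) for c in range(STUDY["n_conditions"])])
    records = gen_dataset(n_subjects, schedule, STUDY["fs"], seed=seed)
    return EcgPreprocessor(window_s=STUDY["window_s"], seed=seed).transform(records)


@dataclass
class BenefitResult:
    """Accuracies of the two arms of one pretraining-benefit contrast."""

    seed: int
    ssl_accuracy: float
    supervised_accuracy: float
    n_train: int
    n_test: int

    @property
    def gain(self) -> float:
        return self.ssl_accuracy - self.supervised_accuracy


def pretraining_benefit(
    seed: int,
    test_ratio: float = 0.7,
    augmentation: str = "timewarp+scale",
    upstream_epochs: int | None = None,
    downstream_epochs: int | None = None,
    segs: SegmentSet | None = None,
) -> BenefitResult:
    """One matched contrast: SSL-pretrained vs random-init classifier.

    Both arms share the data, the split (default 70-30 test-train, the
    regime where pretraining helps most), the architecture, and every
    training hyperparameter; they differ only in encoder initialization.
    """
    up = upstream_epochs if upstream_epochs is not None else STUDY["upstream_epochs"]
    down = downstream_epochs if downstream_epochs is not None else STUDY["downstream_epochs"]
    if segs is None:
        segs = make_study_segments(seed)
    pre = ContrastivePretrainer(
        augmentation=augmentation, epochs=up, random_state=seed
    ).fit(segs)  # unlabeled: the whole corpus, no labels touched
    tr, te = shuffle_split(len(segs), test_ratio, fold_seed=seed)
    train, test = segs.subset(tr), segs.subset(te)
    common = dict(epochs=down, random_state=seed)
    ssl_clf = CnnClassifier(init_weights=pre.encoder_weights_, **common).fit(train)
    sup_clf = CnnClassifier(init_weights=None, **common).fit(train)
    return BenefitResult(
        seed=seed,
        ssl_accuracy=float(np.mean(ssl_clf.predict(test.segments) == test.labels)),
        supervised_accuracy=float(np.mean(sup_clf.predict(test.segments) == test.labels)),
        n_train=len(tr),
        n_test=len(te),
    )
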