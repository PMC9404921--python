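"""Downstream stress classification: the fine-tuned 1-D CNN.

The classifier reuses the encoder architecture of the pretext task exactly
(same conv blocks, same 80-unit dense, same flatten) and adds a softmax
head with one unit per class.  When pretrained encoder weights are given
they initialize the encoder; the head is always freshly initialized; all
layers are trainable (full fine-tuning).  Without pretrained weights this
is the fully supervised benchmark — the architectures differ only in
initialization provenance.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .contrastive import EncoderConfig, build_encoder, encoder_forward
from .nn import Adam, Dense, Sequential, softmax
from .records import SegmentSet

__all__ = ["CnnClassifier", "build_classifier", "finetune", "predict"]


def _as_xy(X, y):
    if isinstance(X, SegmentSet):
        Xarr = X.segments
        if y is None:
            y = X.labels
    else:
        Xarr = np.asarray(X, dtype=np.float64)
    if y is None:
        raise ValueError("labels are required")
    return Xarr, np.asarray(y)


class CnnClassifier(BaseEstimator, ClassifierMixin):
    """1-D CNN stress classifier with optional contrastively pretrained init.

    Parameters
    ----------
    init_weights : dict[str, ndarray] or None, default=None
        Encoder weights from a :class:`~ecgssl.contrastive.ContrastivePretrainer`
        (``encoder_weights_``).  ``None`` means random initialization (the
        fully supervised benchmark).
    filters, kernels, pool_size, dropout_rate, dense_units, l2_coeff
        Encoder architecture; must match the pretrained weights if given.
    learning_rate : float, default=1e-3
    batch_size : int, default=128
    epochs : int, default=250
    random_state : int, default=0

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in fit.
    loss_history_ : list[float]
        Mean cross-entropy (plus L2 penalty) per epoch.
    provenance_ : {"pretrained", "random-init"}
    """

    def __init__(
        self,
        init_weights: dict | None = None,
        filters: tuple = (32, 64, 128),
        kernels: tuple = (32, 16, 8),
        pool_size: int = 4,
        dropout_rate: float = 0.1,
        dense_units: int = 80,
        l2_coeff: float = 3.0,
        learning_rate: float = 1e-3,
        batch_size: int = 128,
        epochs: int = 250,
        random_state: int = 0,
    ):
        self.init_weights = init_weights
        self.filters = filters
        self.kernels = kernels
        self.pool_size = pool_size
        self.dropout_rate = dropout_rate
        self.dense_units = dense_units
        self.l2_coeff = l2_coeff
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    def _encoder_config(self, L: int) -> EncoderConfig:
        return EncoderConfig(
            input_length=L,
            filters=tuple(self.filters),
            kernels=tuple(self.kernels),
            pool_size=self.pool_size,
            dropout_rate=self.dropout_rate,
            dense_units=self.dense_units,
            l2_coeff=self.l2_coeff,
        )

    def initialize(self, input_length: int, classes) -> "CnnClassifier":
        """Build encoder + head without training (weights in initial state).

        Exposed so the weight-transfer contract — pre-finetune encoder
        forward pass identical to the upstream encoder's — can be exercised
        directly; ``fit`` calls this internally.
        """
        self.classes_ = np.asarray(sorted(set(np.asarray(classes).tolist())))
        if self.classes_.shape[0] < 2:
            raise ValueError("need at least two classes")
        cfg = self._encoder_config(input_length)
        ss = np.random.SeedSequence(self.random_state)
        s_enc, s_head, s_shuf, s_drop = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
        self._encoder = build_encoder(cfg, seed=s_enc)
        if self.init_weights is not None:
            self._encoder.set_weights(self.init_weights)
            self.provenance_ = "pretrained"
        else:
            self.provenance_ = "random-init"
        rng = np.random.default_rng(s_head)
        self._head = Sequential(
            [Dense(cfg.output_width, self.classes_.shape[0], rng, name="head")]
        )
        self._shuf_seed, self._drop_seed = s_shuf, s_drop
        self.n_features_in_ = input_length
        self.encoder_config_ = cfg
        return self

    def encoder_representation(self, X) -> np.ndarray:
        """The encoder's flat representation h (eval mode)."""
        Xarr = X.segments if isinstance(X, SegmentSet) else np.asarray(X, dtype=np.float64)
        return encoder_forward(self._encoder, Xarr, train_mode=False)

    def fit(self, X, y=None) -> "CnnClassifier":
        Xarr, y = _as_xy(X, y)
        if Xarr.shape[0] == 0:
            raise ValueError("empty training set")
        if np.unique(y).shape[0] < 2:
            raise ValueError("training labels cover a single class")
        self.initialize(Xarr.shape[1], y)
        y_idx = np.searchsorted(self.classes_, y)
        n = Xarr.shape[0]
        Y = np.eye(self.classes_.shape[0])[y_idx]

        opt = Adam([self._encoder, self._head], lr=self.learning_rate)
        shuf_rng = np.random.default_rng(self._shuf_seed)
        drop_rng = np.random.default_rng(self._drop_seed)
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = shuf_rng.permutation(n)
            losses, weights = [], []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xarr[idx], Y[idx]
                h = self._encoder.forward(xb[:, :, None], train=True, rng=drop_rng)
                logits = self._head.forward(h, train=True, rng=drop_rng)
                P = softmax(logits)
                ce = -float(np.mean(np.log(np.clip(P[np.arange(len(idx)), y_idx[idx]], 1e-300, None))))
                # gradient of mean CE wrt logits
                dlogits = ((P - yb) / len(idx)).astype(np.float32)
                self._encoder.backward(self._head.backward(dlogits))
                opt.step()
                losses.append(ce + self._encoder.l2_penalty() + self._head.l2_penalty())
                weights.append(len(idx))
            self.loss_history_.append(float(np.average(losses, weights=weights)))
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "_head"):
            raise RuntimeError("CnnClassifier is not fitted")
        Xarr = X.segments if isinstance(X, SegmentSet) else np.asarray(X, dtype=np.float64)
        if Xarr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"segment length {Xarr.shape[1]} != model input {self.n_features_in_}"
            )
        h = self._encoder.forward(Xarr[:, :, None], train=False)
        return softmax(self._head.forward(h, train=False))

    def predict(self, X) -> np.ndarray:
        P = self.predict_proba(X)
        return self.classes_[np.argmax(P, axis=1)]  # argmax takes lowest index on ties

    def score(self, X, y=None) -> float:
        Xarr, y = _as_xy(X, y)
        return float(np.mean(self.predict(Xarr) == y))


def build_classifier(
    ecfg: EncoderConfig, n_classes: int, init: dict | None = None, seed: int = 0
) -> CnnClassifier:
    """Functional wrapper: an initialized (untrained) classifier."""
    clf = CnnClassifier(
        init_weights=init,
        filters=ecfg.filters,
        kernels=ecfg.kernels,
        pool_size=ecfg.pool_size,
        dropout_rate=ecfg.dropout_rate,
        dense_units=ecfg.dense_units,
        l2_coeff=ecfg.l2_coeff,
        random_state=seed,
    )
    return clf.initialize(ecfg.input_length, np.arange(n_classes))


def finetune(model: CnnClassifier, train: SegmentSet, tcfg) -> tuple[CnnClassifier, list[float]]:
    """Fine-tune an (initialized or fresh) classifier on labeled segments."""
    model.set_params(
        learning_rate=tcfg.learning_rate,
        batch_size=tcfg.batch_size,
        epochs=tcfg.epochs,
        random_state=tcfg.seed,
    )
    model.fit(train)
    return model, model.loss_history_


def predict(model: CnnClassifier, segs: SegmentSet) -> tuple[np.ndarray, np.ndarray]:
    """(probability matrix, argmax labels) for a segment set."""
    P = model.predict_proba(segs)
    return P, model.classes_[np.argmax(P, axis=1)]
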