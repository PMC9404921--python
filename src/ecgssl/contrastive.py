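"""Contrastive pretraining: encoder f(.), projection head g(.), NT-Xent loss.

The upstream pretext task trains a siamese pair of weight-shared networks to
embed a segment x and its augmented view x' close together while pushing
apart every other segment in the minibatch.  Similarity is cosine; the
objective is the normalized temperature-scaled cross-entropy (NT-Xent)

    l(x, x') = -log [ exp(sim(z_x, z_x') / tau)
                      / sum_{y != x}^{2N} exp(sim(z_x, z_y) / tau) ]

averaged over all 2N anchors of a batch of N segments (each anchor sees one
positive and 2(N-1) negatives).  No ground-truth labels are used anywhere
upstream; only the encoder's weights transfer to the downstream classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .augment import AugmentationSpec, AUGMENTATIONS
from .nn import Adam, Conv1D, Dense, Dropout, Flatten, MaxPool1D, ReLU, Sequential, TimeDense, softmax
from .records import SegmentSet

__all__ = [
    "EncoderConfig",
    "ProjectionConfig",
    "TrainConfig",
    "ContrastiveBatchEmbedding",
    "build_encoder",
    "encoder_forward",
    "projection_forward",
    "cosine_sim",
    "nt_xent_loss",
    "ContrastivePretrainer",
    "pretrain",
    "save_weights",
    "load_weights",
]


@dataclass
class EncoderConfig:
    """Architecture of the 1-D CNN encoder f(.).

    Three convolutional blocks (one conv layer each, ReLU, max-pool,
    dropout) with filters widening 32 -> 64 -> 128 while kernels narrow
    32 -> 16 -> 8, then a dense layer of 80 units applied per time position
    (with an L2 weight penalty) and a flatten.
    """

    input_length: int
    filters: tuple[int, ...] = (32, 64, 128)
    kernels: tuple[int, ...] = (32, 16, 8)
    pool_size: int = 4
    dropout_rate: float = 0.1
    dense_units: int = 80
    l2_coeff: float = 3.0

    def __post_init__(self) -> None:
        if len(self.filters) != len(self.kernels):
            raise ValueError("filters and kernels must have equal length")
        if any(b >= a for a, b in zip(self.kernels, self.kernels[1:])):
            raise ValueError("kernel sizes must be strictly decreasing")
        if self.dense_units <= 0:
            raise ValueError("dense_units must be positive")
        L = self.input_length
        for i in range(self.n_blocks):
            L = L // self.pool_size
            if L < 1:
                raise ValueError(
                    f"input_length {self.input_length} too short: block {i + 1} "
                    f"pool reduces the sequence below one position"
                )

    @property
    def n_blocks(self) -> int:
        return len(self.filters)

    @property
    def output_positions(self) -> int:
        L = self.input_length
        for _ in range(self.n_blocks):
            L //= self.pool_size
        return L

    @property
    def output_width(self) -> int:
        """Width h of the flattened representation."""
        return self.output_positions * self.dense_units


@dataclass
class ProjectionConfig:
    """The projection head g(.): one dense layer of 256 units.

    ``activation`` is "linear" (default) or "softmax".  The softmax variant
    maps z onto the probability simplex, which compresses cosine
    similarities toward 1 and starves the contrastive objective; it is kept
    as a config switch for comparison runs.
    """

    units: int = 256
    activation: str = "linear"

    def __post_init__(self) -> None:
        if self.units <= 0:
            raise ValueError("units must be positive")
        if self.activation not in ("softmax", "linear"):
            raise ValueError("activation must be 'softmax' or 'linear'")


@dataclass
class TrainConfig:
    """Adam optimizer settings and the NT-Xent temperature."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 20
    temperature: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class ContrastiveBatchEmbedding:
    """2N projected vectors; rows (2k, 2k+1) are the positive pair of sample k."""

    Z: np.ndarray
    N: int = field(init=False)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if self.Z.ndim != 2 or self.Z.shape[0] % 2 != 0:
            raise ValueError("Z must be a 2-D matrix with an even row count")
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("embeddings must be finite")
        self.N = self.Z.shape[0] // 2


def build_encoder(cfg: EncoderConfig, seed: int = 0) -> Sequential:
    """Instantiate f(.) with deterministic Glorot-uniform weights."""
    rng = np.random.default_rng(seed)
    layers = []
    in_ch = 1
    for i, (f, k) in enumerate(zip(cfg.filters, cfg.kernels), start=1):
        layers.append(Conv1D(in_ch, f, k, rng, name=f"block{i}_conv"))
        layers.append(ReLU())
        layers.append(MaxPool1D(cfg.pool_size, name=f"block{i}_pool"))
        layers.append(Dropout(cfg.dropout_rate, name=f"block{i}_dropout"))
        in_ch = f
    layers.append(
        TimeDense(in_ch, cfg.dense_units, rng, l2=cfg.l2_coeff, name="dense80")
    )
    layers.append(ReLU())
    layers.append(Flatten())
    model = Sequential(layers)
    model.input_length = cfg.input_length
    return model


def build_projection(pcfg: ProjectionConfig, h_width: int, seed: int = 0) -> Sequential:
    rng = np.random.default_rng(seed)
    return Sequential([Dense(h_width, pcfg.units, rng, name="projection")])


def _as_batch(X) -> np.ndarray:
    """(n, L) segments -> (n, L, 1) channels-last network input."""
    X = X.segments if isinstance(X, SegmentSet) else np.asarray(X, dtype=np.float64)
    return X[:, :, None]


def encoder_forward(encoder: Sequential, X, train_mode: bool = False, rng=None) -> np.ndarray:
    """Representation h for each segment row; deterministic in eval mode."""
    batch = _as_batch(X)
    expected = getattr(encoder, "input_length", None)
    if expected is not None and batch.shape[1] != expected:
        raise ValueError(f"segment length {batch.shape[1]} != encoder input {expected}")
    return encoder.forward(batch, train=train_mode, rng=rng)


def projection_forward(
    projection: Sequential, h: np.ndarray, activation: str = "linear"
) -> ContrastiveBatchEmbedding:
    logits = projection.forward(h, train=False)
    Z = softmax(logits) if activation == "softmax" else logits
    return ContrastiveBatchEmbedding(Z=Z)


def cosine_sim(z1: np.ndarray, z2: np.ndarray) -> float:
    """Cosine similarity z1.z2 / (|z1| |z2|), in [-1, 1]."""
    z1 = np.asarray(z1, dtype=np.float64)
    z2 = np.asarray(z2, dtype=np.float64)
    n1, n2 = np.linalg.norm(z1), np.linalg.norm(z2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(z1, z2) / (n1 * n2))


def nt_xent_loss(batch, tau: float = 0.1, return_grad: bool = False):
    """Mean NT-Xent loss over all 2N anchors of a paired embedding batch.

    Each anchor's denominator runs over the other 2N - 1 rows (its positive
    plus 2(N - 1) negatives); the anchor's similarity with itself is
    excluded.  With N = 1 the denominator equals the numerator and the loss
    is exactly zero.

    Parameters
    ----------
    batch : ContrastiveBatchEmbedding or (2N, d) array
        Rows (2k, 2k+1) are the positive pair for sample k.
    tau : float
        Temperature; must be positive.
    return_grad : bool
        Also return d(loss)/dZ (used by the training loop).
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    Z = batch.Z if isinstance(batch, ContrastiveBatchEmbedding) else np.asarray(batch, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] % 2 != 0:
        raise ValueError("batch must have an even number of rows")
    M = Z.shape[0]
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero rows have no cosine similarity")
    U = Z / norms
    S = U @ U.T
    logits = S / tau
    np.fill_diagonal(logits, -np.inf)
    P = softmax(logits, axis=1)  # row-wise over the 2N-1 valid entries
    pos = np.arange(M) ^ 1  # partner index: 2k <-> 2k+1
    logprob = logits - (np.max(logits, axis=1, keepdims=True)
                        + np.log(np.sum(np.exp(logits - np.max(logits, axis=1, keepdims=True)),
                                        axis=1, keepdims=True)))
    loss = float(-np.mean(logprob[np.arange(M), pos]))
    if not return_grad:
        return loss
    dS = P.copy()
    dS[np.arange(M), pos] -= 1.0
    np.fill_diagonal(dS, 0.0)
    dS /= M * tau
    dU = (dS + dS.T) @ U
    dZ = (dU - U * np.sum(U * dU, axis=1, keepdims=True)) / norms
    return loss, dZ


class ContrastivePretrainer(BaseEstimator, TransformerMixin):
    """Self-supervised ECG representation learner (SimCLR-style pretext).

    ``fit`` trains encoder + projection head with NT-Xent on unlabeled
    segments: branch one of the siamese pair sees the segment as-is, branch
    two sees a freshly augmented view drawn per segment per epoch.
    ``transform`` returns the learned representation h (the projection head
    is discarded downstream).

    Parameters
    ----------
    augmentation : str, default="timewarp+scale"
        One or two operator names joined by '+', applied sequentially.
    filters, kernels, pool_size, dropout_rate, dense_units, l2_coeff
        Encoder architecture (see :class:`EncoderConfig`).
    projection_units : int, default=256
    projection_activation : {"linear", "softmax"}, default="linear"
        Activation of the contrast head.  The linear head is the default:
        a softmax head confines z to the probability simplex, where cosine
        similarities are compressed near 1 and the NT-Xent objective cannot
        separate positives from negatives (kept available for comparison).
    temperature : float, default=0.1
        NT-Xent temperature tau.
    learning_rate : float, default=1e-4
    batch_size : int, default=32
        Must be >= 2: a single sample has no negatives.
    epochs : int, default=20
    random_state : int, default=0

    Attributes
    ----------
    encoder_weights_ : dict[str, ndarray]
        Transferable weights of f(.) after pretraining.
    loss_history_ : list[float]
        Mean NT-Xent loss (plus L2 penalty) per epoch.
    n_features_in_ : int
        Segment length L seen during fit.
    """

    def __init__(
        self,
        augmentation: str = "timewarp+scale",
        filters: tuple = (32, 64, 128),
        kernels: tuple = (32, 16, 8),
        pool_size: int = 4,
        dropout_rate: float = 0.1,
        dense_units: int = 80,
        l2_coeff: float = 3.0,
        projection_units: int = 256,
        projection_activation: str = "linear",
        temperature: float = 0.1,
        learning_rate: float = 1e-4,
        batch_size: int = 32,
        epochs: int = 20,
        random_state: int = 0,
    ):
        self.augmentation = augmentation
        self.filters = filters
        self.kernels = kernels
        self.pool_size = pool_size
        self.dropout_rate = dropout_rate
        self.dense_units = dense_units
        self.l2_coeff = l2_coeff
        self.projection_units = projection_units
        self.projection_activation = projection_activation
        self.temperature = temperature
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

    def fit(self, X, y=None) -> "ContrastivePretrainer":
        """Pretrain on segments; ``y`` is accepted and ignored (no labels upstream)."""
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 for contrastive training")
        Xarr = X.segments if isinstance(X, SegmentSet) else np.asarray(X, dtype=np.float64)
        if Xarr.ndim != 2 or Xarr.shape[0] == 0:
            raise ValueError("X must be a non-empty (n, L) segment matrix")
        n, L = Xarr.shape
        self.n_features_in_ = L
        cfg = self._encoder_config(L)
        pcfg = ProjectionConfig(units=self.projection_units, activation=self.projection_activation)
        spec = AugmentationSpec.parse(self.augmentation, seed=self.random_state)

        ss = np.random.SeedSequence(self.random_state)
        s_enc, s_proj, s_shuf, s_aug, s_drop = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(5)]
        encoder = build_encoder(cfg, seed=s_enc)
        projection = build_projection(pcfg, cfg.output_width, seed=s_proj)
        opt = Adam([encoder, projection], lr=self.learning_rate)
        shuf_rng = np.random.default_rng(s_shuf)
        aug_rng = np.random.default_rng(s_aug)
        drop_rng = np.random.default_rng(s_drop)

        self.loss_history_ = []
        for _ in range(self.epochs):
            order = shuf_rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                if idx.shape[0] < 2:
                    continue  # a lone sample has no negatives
                xb = Xarr[idx]
                xb_aug = np.empty_like(xb)
                for i in range(xb.shape[0]):
                    row = xb[i]
                    for name, params in spec.ops:
                        row = AUGMENTATIONS[name](row, seed=aug_rng, **params)
                    xb_aug[i] = row
                # interleave: rows (2k, 2k+1) = (x_k, x'_k)
                pair = np.empty((2 * xb.shape[0], L))
                pair[0::2] = xb
                pair[1::2] = xb_aug
                h = encoder.forward(pair[:, :, None], train=True, rng=drop_rng)
                logits = projection.forward(h, train=True, rng=drop_rng)
                if pcfg.activation == "softmax":
                    Zb = softmax(logits)
                else:
                    Zb = logits
                loss, dZ = nt_xent_loss(Zb, tau=self.temperature, return_grad=True)
                if pcfg.activation == "softmax":
                    dlogits = Zb * (dZ - np.sum(dZ * Zb, axis=1, keepdims=True))
                else:
                    dlogits = dZ
                dlogits = dlogits.astype(np.float32)
                encoder.backward(projection.backward(dlogits))
                opt.step()
                epoch_losses.append(loss + encoder.l2_penalty() + projection.l2_penalty())
            self.loss_history_.append(float(np.mean(epoch_losses)))

        self._encoder = encoder
        self._projection = projection
        self.encoder_config_ = cfg
        self.encoder_weights_ = encoder.get_weights()
        self.projection_weights_ = projection.get_weights()
        return self

    def transform(self, X) -> np.ndarray:
        """Learned representation h for each segment (eval mode, deterministic)."""
        if not hasattr(self, "_encoder"):
            raise RuntimeError("ContrastivePretrainer is not fitted")
        Xarr = X.segments if isinstance(X, SegmentSet) else np.asarray(X, dtype=np.float64)
        if Xarr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"segment length {Xarr.shape[1]} != fitted length {self.n_features_in_}"
            )
        return encoder_forward(self._encoder, Xarr, train_mode=False)

    def project(self, X) -> ContrastiveBatchEmbedding:
        """Map segments through f then g into the contrast space z."""
        h = self.transform(X)
        return projection_forward(self._projection, h, activation=self.projection_activation)


def pretrain(
    segs: SegmentSet,
    spec: AugmentationSpec,
    ecfg: EncoderConfig,
    pcfg: ProjectionConfig,
    tcfg: TrainConfig,
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Functional wrapper: returns (encoder weights, per-epoch loss history)."""
    est = ContrastivePretrainer(
        augmentation=spec.name(),
        filters=ecfg.filters,
        kernels=ecfg.kernels,
        pool_size=ecfg.pool_size,
        dropout_rate=ecfg.dropout_rate,
        dense_units=ecfg.dense_units,
        l2_coeff=ecfg.l2_coeff,
        projection_units=pcfg.units,
        projection_activation=pcfg.activation,
        temperature=tcfg.temperature,
        learning_rate=tcfg.learning_rate,
        batch_size=tcfg.batch_size,
        epochs=tcfg.epochs,
        random_state=tcfg.seed,
    ).fit(segs)
    return est.encoder_weights_, est.loss_history_


def save_weights(weights: dict[str, np.ndarray], path: str | Path) -> None:
    """NPZ archive of named arrays plus a JSON shape manifest."""
    manifest = json.dumps({k: list(v.shape) for k, v in weights.items()})
    np.savez(path, __manifest__=np.str_(manifest), **weights)


def load_weights(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as z:
        manifest = json.loads(str(z["__manifest__"]))
        out = {}
        for k, shape in manifest.items():
            arr = z[k]
            if list(arr.shape) != shape:
                raise ValueError(f"manifest mismatch for {k}")
            out[k] = arr
        return out
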