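"""Label-free stochastic ECG segment transformations and their composition.

Six operators create the altered view x' of a segment x for contrastive
pretraining: amplitude scaling, negation, horizontal (time) flipping,
additive Gaussian noise at a target SNR, chunk permutation, and smooth time
warping.  An :class:`AugmentationSpec` names one or two operators applied
sequentially (order matters); `timewarp+scale` is the composition that works
best for multi-condition affect data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .records import SegmentSet

__all__ = [
    "scale",
    "negate",
    "hflip",
    "noise_snr",
    "permute",
    "timewarp",
    "AugmentationSpec",
    "apply_spec",
    "AUGMENTATIONS",
]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def scale(x: np.ndarray, factor_range=(0.5, 2.0), seed=0) -> np.ndarray:
    """Multiply the segment by a random factor c ~ U(lo, hi)."""
    lo, hi = factor_range
    if lo <= 0 or hi < lo:
        raise ValueError(f"invalid factor_range {factor_range}: need 0 < lo <= hi")
    c = _as_rng(seed).uniform(lo, hi)
    return np.asarray(x, dtype=np.float64) * c


def negate(x: np.ndarray, seed=None) -> np.ndarray:
    """Sign inversion (vertical flip)."""
    return -np.asarray(x, dtype=np.float64)


def hflip(x: np.ndarray, seed=None) -> np.ndarray:
    """Time reversal: out[i] = x[L-1-i]."""
    return np.asarray(x, dtype=np.float64)[::-1].copy()


def noise_snr(x: np.ndarray, snr_db: float = 15.0, seed=0) -> np.ndarray:
    """Add Gaussian white noise at a target signal-to-noise ratio in dB."""
    x = np.asarray(x, dtype=np.float64)
    p_sig = float(np.mean(x**2))
    if p_sig == 0.0:
        raise ValueError("zero-power segment: SNR is undefined")
    noise_sd = np.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
    return x + _as_rng(seed).normal(0.0, noise_sd, size=x.shape)


def permute(x: np.ndarray, n_segments: int = 20, seed=0) -> np.ndarray:
    """Split into contiguous near-equal chunks and shuffle their order."""
    x = np.asarray(x, dtype=np.float64)
    if n_segments == 1:  # degenerate identity, allowed via config
        return x.copy()
    if n_segments < 1 or n_segments > x.shape[0]:
        raise ValueError(f"n_segments={n_segments} invalid for length {x.shape[0]}")
    chunks = np.array_split(x, n_segments)
    order = _as_rng(seed).permutation(n_segments)
    return np.concatenate([chunks[i] for i in order])


def timewarp(x: np.ndarray, n_knots: int = 4, warp_sd: float = 0.2, seed=0) -> np.ndarray:
    """Resample along a smooth random monotone time map.

    Local playback speeds ~ N(1, warp_sd^2) (clipped positive) are drawn at
    ``n_knots`` interior knots plus the endpoints, interpolated with a cubic
    spline, and integrated into a monotone map; the segment is linearly
    re-interpolated along it back to its original length.  ``warp_sd = 0``
    is the identity.
    """
    if warp_sd < 0:
        raise ValueError("warp_sd must be >= 0")
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    L = x.shape[0]
    rng = _as_rng(seed)
    knot_pos = np.linspace(0.0, 1.0, n_knots + 2)
    speeds = np.clip(rng.normal(1.0, warp_sd, size=n_knots + 2), 0.05, None)
    speed_curve = np.clip(CubicSpline(knot_pos, speeds)(np.linspace(0, 1, L)), 0.05, None)
    tau = np.concatenate([[0.0], np.cumsum(speed_curve[:-1])])
    tau *= (L - 1) / tau[-1]
    return np.interp(tau, np.arange(L), x)


AUGMENTATIONS = {
    "scale": scale,
    "negate": negate,
    "hflip": hflip,
    "noise_snr": noise_snr,
    "timewarp": timewarp,
    "permute": permute,
}


@dataclass
class AugmentationSpec:
    """One or two named operators applied sequentially, with parameters.

    ``ops`` is an ordered list of ``(name, params)`` pairs, e.g.
    ``[("timewarp", {}), ("scale", {})]``.  ``seed`` drives the random draws
    when no external generator is supplied.
    """

    ops: list[tuple[str, dict]] = field(default_factory=lambda: [("timewarp", {}), ("scale", {})])
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.ops) <= 2:
            raise ValueError("spec must name one or two operators")
        for name, params in self.ops:
            if name not in AUGMENTATIONS:
                raise ValueError(f"unknown augmentation {name!r}; choose from {sorted(AUGMENTATIONS)}")
            if not isinstance(params, dict):
                raise ValueError("params must be a dict")

    @classmethod
    def parse(cls, value, seed: int = 0) -> "AugmentationSpec":
        """Build a spec from the CLI shorthand 'timewarp+scale', a YAML-style
        list of {name, params} mappings, or a list of (name, params) pairs."""
        if isinstance(value, AugmentationSpec):
            return value
        if isinstance(value, str):
            return cls(ops=[(name.strip(), {}) for name in value.split("+")], seed=seed)
        ops = []
        for item in value:
            if isinstance(item, dict):
                ops.append((item["name"], dict(item.get("params") or {})))
            else:
                name, params = item
                ops.append((name, dict(params or {})))
        return cls(ops=ops, seed=seed)

    def name(self) -> str:
        return "+".join(n for n, _ in self.ops)


def apply_spec(
    spec: AugmentationSpec, segs: SegmentSet, rng: np.random.Generator | None = None
) -> SegmentSet:
    """Produce the altered view x' of every segment, row-aligned with input.

    Each row gets fresh random draws for every operator; labels and subject
    ids are carried through unchanged.  Pass ``rng`` to draw from an ongoing
    stream (fresh views each epoch); otherwise ``spec.seed`` makes the call
    deterministic.
    """
    rng = _as_rng(spec.seed if rng is None else rng)
    out = np.empty_like(segs.segments)
    for i in range(len(segs)):
        row = segs.segments[i]
        for name, params in spec.ops:
            row = AUGMENTATIONS[name](row, seed=rng, **params)
        out[i] = row
    return SegmentSet(
        segments=out,
        labels=segs.labels.copy(),
        subject_ids=segs.subject_ids.copy(),
        fs=segs.fs,
        window_s=segs.window_s,
    )
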