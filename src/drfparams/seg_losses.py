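"""Segmentation loss primitives: cross-entropy, focal, Dice.

Pure numeric implementations for unit-level verification; no gradients
or training machinery.  All losses are reported as means over elements
and are finite under the log-clipping contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Clip floor applied to probabilities before taking logs.
LOG_CLIP = 1e-12
#: Default Dice smoothing term.
DICE_EPS = 1e-6


def _check_pair(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
        raise ValueError("probabilities must lie in [0, 1]")
    return p, y


def cross_entropy(p: np.ndarray, y: np.ndarray, eps_clip: float = LOG_CLIP) -> float:
    """Mean over elements of -sum_i y_i log p_i.

    ``p`` holds per-class predicted probabilities along the last axis,
    ``y`` the matching one-hot labels.  Probabilities are clipped to
    ``[eps_clip, 1]`` so a zero true-class probability yields a large
    finite value instead of infinity.
    """
    p, y = _check_pair(p, y)
    pc = np.clip(p, eps_clip, 1.0)
    per_element = -(y * np.log(pc)).sum(axis=-1)
    return float(per_element.mean())


def focal_loss(p_t, alpha_t: float = 1.0, gamma: float = 2.0,
               eps_clip: float = LOG_CLIP) -> float:
    """-alpha_t * (1 - p_t)**gamma * log(p_t), averaged over elements.

    ``gamma`` is the focusing exponent that down-weights well-classified
    samples; at gamma = 0 this reduces to weighted cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if alpha_t < 0:
        raise ValueError("alpha_t must be >= 0")
    pt = np.clip(np.asarray(p_t, dtype=float), eps_clip, 1.0)
    val = -alpha_t * (1.0 - pt) ** gamma * np.log(pt)
    return float(np.mean(val))


def dice_coefficient(x: np.ndarray, y: np.ndarray, epsilon: float = DICE_EPS) -> float:
    """(2|X.Y| + eps) / (|X| + |Y| + eps) with the elementwise-product overlap."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: X {x.shape} vs Y {y.shape}")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    inter = float((x * y).sum())
    return (2.0 * inter + epsilon) / (float(x.sum()) + float(y.sum()) + epsilon)


def dice_loss(x: np.ndarray, y: np.ndarray, epsilon: float = DICE_EPS) -> float:
    return 1.0 - dice_coefficient(x, y, epsilon)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN tallies plus the delta/epsilon knobs of the general Dice loss."""

    tp: int
    fp: int
    fn: int
    tn: int = 0
    delta: float = 1.0
    epsilon: float = DICE_EPS

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def dice_loss_generalized(counts: ConfusionCounts) -> float:
    """1 - ((1+d^2)TP + eps) / ((1+d^2)TP + d^2 FN + FP + eps).

    At delta = 1 this equals 1 - (2TP+eps)/(2TP+FN+FP+eps), i.e. the
    plain Dice loss with X = TP+FN and Y = TP+FP.
    """
    d2 = counts.delta ** 2
    num = (1.0 + d2) * counts.tp + counts.epsilon
    den = (1.0 + d2) * counts.tp + d2 * counts.fn + counts.fp + counts.epsilon
    return 1.0 - num / den
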