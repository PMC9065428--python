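"""Training objectives: weighted Soft Dice, Soft Dice + cross-entropy, and
the Exponential Logarithmic Loss, with inverse-frequency class weighting.

Conventions pinned here and used repo-wide:

* The smoothed per-class soft Dice is ``(2 * sum(y*p) + 1) / (sum(y) +
  sum(p) + 1)``; the +1 smoothing makes empty classes contribute a perfect
  score instead of 0/0.
* Class weights are the normalised inverse relative label frequencies,
  ``w_l = f_l**(-alpha) / sum_k f_k**(-alpha)``, computed over all classes
  including background.  The Soft Dice losses use ``alpha = 1/3``; the
  Exponential Logarithmic Loss uses ``alpha = 0.5``.
* The Exponential Logarithmic Loss is ``mean_l (-ln Dice_l)**0.3 +
  mean_x w_{l(x)} (-ln p_{l(x)})**0.3`` with both exponents fixed at 0.3.
* Probabilities are clamped to ``[eps, 1]`` with ``eps = 1e-7`` before any
  logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .volume import GeometryError, LabelMap

EPSILON = 1e-7
#: Exponent of both terms of the Exponential Logarithmic Loss.
EXP_LOG_GAMMA = 0.3
#: Derivative of x**gamma diverges at x=0; cap it below this x for stability.
_GRAD_FLOOR = 1e-6


class WeightError(ValueError):
    """Class weights cannot be computed (e.g. an absent class)."""


@dataclass(frozen=True)
class ClassWeights:
    """Per-class non-negative weights summing to one."""

    weights: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        if np.any(w < 0):
            raise WeightError("class weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise WeightError(f"class weights must sum to 1, got {w.sum()}")

    @property
    def num_classes(self) -> int:
        return self.weights.size

    @staticmethod
    def uniform(num_classes: int) -> "ClassWeights":
        return ClassWeights(np.full(num_classes, 1.0 / num_classes), alpha=0.0)


@dataclass
class LossValue:
    """A differentiable scalar loss with a per-term breakdown."""

    total: Tensor
    per_class: np.ndarray | None = None
    components: dict | None = None

    @property
    def value(self) -> float:
        return float(self.total.data)


def inverse_frequency_weights(
    targets, alpha: float, num_classes: int | None = None
) -> ClassWeights:
    """Normalised inverse-frequency weights over a collection of label maps.

    ``w_l = f_l**(-alpha) / sum_k f_k**(-alpha)`` where ``f_l`` is the voxel
    frequency of label ``l`` pooled over the collection (background
    included).  Every class must occur at least once.
    """
    if isinstance(targets, (LabelMap, np.ndarray)):
        targets = [targets]
    arrays = [t.labels if isinstance(t, LabelMap) else np.asarray(t) for t in targets]
    if num_classes is None:
        num_classes = int(max(a.max() for a in arrays)) + 1
    counts = np.zeros(num_classes, dtype=np.int64)
    for a in arrays:
        counts += np.bincount(a.ravel(), minlength=num_classes)[:num_classes]
    if np.any(counts == 0):
        missing = np.flatnonzero(counts == 0).tolist()
        raise WeightError(
            f"classes {missing} are absent from the targets; "
            "inverse-frequency weights are undefined for frequency zero"
        )
    freq = counts / counts.sum()
    raw = freq ** (-float(alpha))
    return ClassWeights(weights=raw / raw.sum(), alpha=float(alpha))


def one_hot(labels, num_classes: int) -> np.ndarray:
    """(X, Y, Z) integer labels -> (C, X, Y, Z) float32 indicators."""
    lab = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    if lab.min() < 0 or lab.max() >= num_classes:
        raise ValueError(f"labels outside [0, {num_classes})")
    out = np.zeros((num_classes,) + lab.shape, dtype=np.float32)
    flat = out.reshape(num_classes, -1)
    flat[lab.ravel(), np.arange(lab.size)] = 1.0
    return out


def _check_geometry(pred: Tensor, target: np.ndarray, weights: ClassWeights) -> None:
    if pred.shape != target.shape:
        raise GeometryError(f"prediction {pred.shape} vs target {target.shape}")
    if pred.shape[0] != weights.num_classes:
        raise GeometryError(
            f"{pred.shape[0]} classes in prediction, {weights.num_classes} weights"
        )


def _as_tensor(pred) -> Tensor:
    return pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred))


def _smoothed_dice(pred: Tensor, target: np.ndarray) -> Tensor:
    """Per-class smoothed soft Dice, shape (C,)."""
    axes = (1, 2, 3)
    inter = (pred * target).sum(axis=axes)
    sums = pred.sum(axis=axes) + target.sum(axis=axes)
    return (2.0 * inter + 1.0) / (sums + 1.0)


def weighted_soft_dice_loss(pred, target: np.ndarray, weights: ClassWeights) -> LossValue:
    """``sum_l w_l * (1 - smoothed Dice_l)``; zero at a perfect binary match."""
    pred = _as_tensor(pred)
    _check_geometry(pred, target, weights)
    dice = _smoothed_dice(pred, target)
    per_class_t = (1.0 - dice) * weights.weights
    total = per_class_t.sum()
    return LossValue(
        total=total,
        per_class=per_class_t.data.copy(),
        components={"wsd": float(total.data)},
    )


def weighted_cross_entropy(pred, target: np.ndarray, weights: ClassWeights) -> LossValue:
    """Mean over voxels of ``w_{l(x)} * (-ln p_{l(x)})``."""
    pred = _as_tensor(pred)
    _check_geometry(pred, target, weights)
    w_map = (weights.weights[:, None, None, None] * target).sum(axis=0)
    p_true = (pred * target).sum(axis=0).clip(EPSILON, 1.0)
    total = (-(p_true.log()) * w_map).mean()
    return LossValue(total=total, components={"xe": float(total.data)})


def wsd_plus_xe_loss(
    pred,
    target: np.ndarray,
    weights: ClassWeights,
    wsd_coefficient: float = 1.0,
    xe_coefficient: float = 1.0,
) -> LossValue:
    """Linear combination of weighted Soft Dice and weighted cross-entropy."""
    pred = _as_tensor(pred)
    wsd = weighted_soft_dice_loss(pred, target, weights)
    xe = weighted_cross_entropy(pred, target, weights)
    total = wsd_coefficient * wsd.total + xe_coefficient * xe.total
    return LossValue(
        total=total,
        per_class=wsd.per_class,
        components={
            "wsd": wsd_coefficient * wsd.value,
            "xe": xe_coefficient * xe.value,
        },
    )


def _safe_pow_gamma(x: Tensor, gamma: float) -> Tensor:
    """``x**gamma`` for x >= 0, exact in value, with the (divergent) derivative
    at x -> 0 capped at its value at ``_GRAD_FLOOR``."""
    out = Tensor(x.data**gamma, parents=(x,))

    def bwd(g):
        xs = np.maximum(x.data, _GRAD_FLOOR)
        x._accum(g * gamma * xs ** (gamma - 1.0))

    out._backward = bwd
    return out


def exp_log_loss(pred, target: np.ndarray, weights: ClassWeights) -> LossValue:
    """Exponential Logarithmic Loss (Dice term + weighted NLL term, both ^0.3)."""
    pred = _as_tensor(pred)
    _check_geometry(pred, target, weights)
    dice = _smoothed_dice(pred, target).clip(EPSILON, 1.0)
    dice_term = _safe_pow_gamma(-(dice.log()), EXP_LOG_GAMMA).mean()

    w_map = (weights.weights[:, None, None, None] * target).sum(axis=0)
    p_true = (pred * target).sum(axis=0).clip(EPSILON, 1.0)
    xe_term = (_safe_pow_gamma(-(p_true.log()), EXP_LOG_GAMMA) * w_map).mean()

    total = dice_term + xe_term
    return LossValue(
        total=total,
        components={"dice_term": float(dice_term.data), "xe_term": float(xe_term.data)},
    )


def deep_supervision_aggregate(
    main: LossValue, auxiliaries: list[LossValue], level_weights=None
) -> LossValue:
    """Weighted sum of the main and auxiliary losses, weights normalised to 1.

    With no auxiliaries the main loss is returned unchanged.  Default
    weights are equal across all outputs.
    """
    if not auxiliaries:
        return main
    n = 1 + len(auxiliaries)
    if level_weights is None:
        level_weights = np.full(n, 1.0 / n)
    level_weights = np.asarray(level_weights, dtype=np.float64)
    if level_weights.size != n:
        raise ValueError(f"need {n} level weights, got {level_weights.size}")
    level_weights = level_weights / level_weights.sum()
    total = level_weights[0] * main.total
    for w, aux in zip(level_weights[1:], auxiliaries):
        total = total + w * aux.total
    return LossValue(
        total=total,
        per_class=main.per_class,
        components={"main": main.value, "aux": [a.value for a in auxiliaries]},
    )


#: Loss registry used by config / CLI.
LOSS_KINDS = ("wsd", "wsd_xe", "explog")
#: Inverse-frequency exponent per loss kind.
DEFAULT_ALPHA = {"wsd": 1.0 / 3.0, "wsd_xe": 1.0 / 3.0, "explog": 0.5}


def make_loss(kind: str, xe_coefficient: float = 1.0):
    """Return ``f(pred, target_onehot, weights) -> LossValue`` for a kind."""
    if kind == "wsd":
        return weighted_soft_dice_loss
    if kind == "wsd_xe":
        return lambda p, t, w: wsd_plus_xe_loss(p, t, w, xe_coefficient=xe_coefficient)
    if kind == "explog":
        return exp_log_loss
    raise ValueError(f"unknown loss kind {kind!r}; choose from {LOSS_KINDS}")
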