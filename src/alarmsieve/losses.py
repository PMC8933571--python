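"""Pair-wise discriminative constraint, weighted BCE and the combined loss.

For a false alarm the alarm-window feature and the baseline feature of the
same record should be similar, for a true alarm dissimilar; similarity is the
raw dot product squashed through a sigmoid:

    C_false = -log sigmoid( f_A . f_R )
    C_true  = -log sigmoid(-f_A . f_R )

The batch constraint averages the two classes separately; a class absent from
the mini-batch contributes nothing. The classification loss is binary cross
entropy with a configurable weight on the positive (true-alarm) class, and
the training objective is ``L = L_BCE + w * C``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "LossConfig",
    "constraint_false",
    "constraint_true",
    "batch_constraint",
    "batch_constraint_grad",
    "weighted_bce",
    "bce_with_logits_grad",
    "total_loss",
]

EPS_DEFAULT = 1e-12


@dataclass
class LossConfig:
    constraint_weight: float = 1.5
    positive_class_weight: float = 1.5
    eps: float = EPS_DEFAULT

    def __post_init__(self) -> None:
        if self.constraint_weight < 0:
            raise ValidationError("constraint_weight must be >= 0")
        if self.positive_class_weight <= 0:
            raise ValidationError("positive_class_weight must be > 0")
        if not 0.0 < self.eps <= 1e-4:
            raise ValidationError(f"eps must lie in (0, 1e-4], got {self.eps}")


def _log_sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable ``log(sigmoid(z)) = -softplus(-z)``."""
    z = np.asarray(z, dtype=np.float64)
    return -(np.logaddexp(0.0, -z))


def _pair_dot(f_a, f_r) -> float:
    f_a = np.asarray(f_a, dtype=np.float64).reshape(-1)
    f_r = np.asarray(f_r, dtype=np.float64).reshape(-1)
    if f_a.shape != f_r.shape:
        raise ValidationError(
            f"feature lengths differ: {f_a.shape[0]} vs {f_r.shape[0]}"
        )
    return float(f_a @ f_r)


def constraint_false(f_a, f_r) -> float:
    """``-log sigmoid(f_A . f_R)`` — penalizes dissimilar pairs."""
    return float(-_log_sigmoid(_pair_dot(f_a, f_r)))


def constraint_true(f_a, f_r) -> float:
    """``-log sigmoid(-(f_A . f_R))`` — penalizes similar pairs.

    Identically ``constraint_false(f_a, -f_r)``.
    """
    return float(-_log_sigmoid(-_pair_dot(f_a, f_r)))


def batch_constraint(features) -> float:
    """Mini-batch constraint over ``(f_A, f_R, label)`` triples.

    ``label`` is ``"true_alarm"``/``"false_alarm"`` (or 1/0). Each class is
    averaged separately; an absent class's term is omitted.
    """
    features = list(features)
    if not features:
        raise ValidationError("batch_constraint requires a non-empty batch")
    c_false, c_true = [], []
    for f_a, f_r, label in features:
        is_true = label in (1, True, "true_alarm")
        if not is_true and label not in (0, False, "false_alarm"):
            raise ValidationError(f"unknown pair label: {label!r}")
        (c_true if is_true else c_false).append(
            constraint_true(f_a, f_r) if is_true else constraint_false(f_a, f_r)
        )
    total = 0.0
    if c_false:
        total += float(np.mean(c_false))
    if c_true:
        total += float(np.mean(c_true))
    return total


def batch_constraint_grad(f_a: np.ndarray, f_r: np.ndarray, y: np.ndarray):
    """Vectorized batch constraint and its gradients.

    ``f_a``/``f_r``: (N, S) float arrays; ``y``: (N,) in {0,1} with 1 = true
    alarm. Returns ``(C, dC/df_a, dC/df_r)``.
    """
    f_a = np.asarray(f_a, dtype=np.float64)
    f_r = np.asarray(f_r, dtype=np.float64)
    y = np.asarray(y)
    if f_a.shape != f_r.shape or f_a.ndim != 2 or len(y) != f_a.shape[0]:
        raise ValidationError("batch_constraint_grad: shape mismatch")
    if len(y) == 0:
        raise ValidationError("empty batch")
    dots = np.einsum("ns,ns->n", f_a, f_r)
    sign = np.where(y == 1, -1.0, 1.0)          # C = -log sigmoid(sign * dot)
    losses = -_log_sigmoid(sign * dots)
    n_true = int(np.sum(y == 1))
    n_false = len(y) - n_true
    scale = np.where(y == 1,
                     1.0 / n_true if n_true else 0.0,
                     1.0 / n_false if n_false else 0.0)
    c = float(np.sum(losses * scale))
    # d/d(dot) [-log sigmoid(sign*dot)] = -sign * (1 - sigmoid(sign*dot))
    sig = 1.0 / (1.0 + np.exp(-np.clip(sign * dots, -500, 500)))
    ddot = -sign * (1.0 - sig) * scale
    return c, ddot[:, None] * f_r, ddot[:, None] * f_a


def weighted_bce(labels, probabilities, positive_class_weight=1.5,
                 eps=EPS_DEFAULT) -> float:
    """Mean of ``-w+ y log p - (1-y) log(1-p)`` with probabilities clamped to
    ``[eps, 1-eps]``."""
    y = np.asarray(labels, dtype=np.float64)
    p = np.asarray(probabilities, dtype=np.float64)
    if y.shape != p.shape:
        raise ValidationError("labels and probabilities must align")
    if y.size == 0:
        raise ValidationError("empty batch")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("labels must be 0 or 1")
    if positive_class_weight <= 0:
        raise ValidationError("positive_class_weight must be > 0")
    p = np.clip(p, eps, 1.0 - eps)
    terms = -positive_class_weight * y * np.log(p) - (1.0 - y) * np.log(1.0 - p)
    return float(np.mean(terms))


def bce_with_logits_grad(labels, logits, positive_class_weight=1.5):
    """Stable weighted BCE from logits plus its gradient w.r.t. the logits.

    Matches :func:`weighted_bce` applied to ``sigmoid(logits)`` (up to the
    eps clamp). Returns ``(loss, dloss/dlogits)``.
    """
    y = np.asarray(labels, dtype=np.float64)
    z = np.asarray(logits, dtype=np.float64)
    if y.shape != z.shape or y.size == 0:
        raise ValidationError("labels and logits must align and be non-empty")
    w = positive_class_weight
    softplus = np.logaddexp(0.0, z)
    # y=1: w * softplus(-z); y=0: softplus(z)
    per = np.where(y == 1.0, w * np.logaddexp(0.0, -z), softplus)
    loss = float(np.mean(per))
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    dz = np.where(y == 1.0, w * (sig - 1.0), sig) / y.size
    return loss, dz


def total_loss(l_bce: float, c: float, w: float) -> float:
    """Combined objective ``L = L_BCE + w * C``."""
    for name, value in (("l_bce", l_bce), ("c", c), ("w", w)):
        if not np.isfinite(value):
            raise ValidationError(f"{name} must be finite, got {value}")
    return float(l_bce + w * c)
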