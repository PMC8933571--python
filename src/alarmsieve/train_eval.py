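"""Training loop, cross-validation, ablation grid and evaluation metrics.

Training minimizes ``L = L_BCE + w * C`` with Adam. The alarm segment of each
record is fixed; the baseline segment is freshly sampled every epoch from a
seeded, epoch-keyed stream, which acts as data augmentation. All randomness
(ordering, baselines, dropout, initialization, folds) derives from one seed
through named substreams, so runs are exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from . import losses, nn
from .data_io import (
    SEGMENT_SECONDS,
    WaveformRecord,
    alarm_onehot,
    make_folds,
    preprocess,
)
from .errors import ValidationError
from .model import ALL_COMPONENTS, AlarmModel, ModelConfig
from .seeding import substream

__all__ = [
    "TrainConfig",
    "ConfusionCounts",
    "challenge_score",
    "tpr_tnr_acc",
    "confusion_from_labels",
    "train",
    "predict",
    "cross_validate",
    "ablate",
    "ABLATION_GRID",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference setup)."""

    max_epochs: int = 1000
    batch_size: int = 256
    learning_rate: float = 0.001
    l2_lambda: float = 0.0005
    dropout: float = 0.8
    constraint_weight: float = 1.5
    positive_class_weight: float = 1.5
    decision_threshold: float = 0.5
    folds: int = 5
    rng_seed: int = 0
    components: tuple = ALL_COMPONENTS

    def validate(self) -> None:
        for name in ("max_epochs", "batch_size", "folds"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("learning_rate", "l2_lambda", "dropout",
                     "constraint_weight", "positive_class_weight"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValidationError("decision_threshold must lie in (0,1)")
        unknown = set(self.components) - set(ALL_COMPONENTS)
        if unknown:
            raise ValidationError(f"unknown components: {sorted(unknown)}")


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN,
            self.FP + other.FP, self.FN + other.FN,
        )


def challenge_score(cc: ConfusionCounts) -> float:
    """``(TP+TN) / (TP+TN+FP+5*FN)`` — missed true alarms cost five-fold."""
    if cc.total == 0:
        raise ValidationError("all confusion counts are zero")
    return (cc.TP + cc.TN) / (cc.TP + cc.TN + cc.FP + 5 * cc.FN)


def tpr_tnr_acc(cc: ConfusionCounts):
    """Sensitivity, specificity and accuracy; undefined rates come back as
    ``None`` rather than NaN."""
    if cc.total == 0:
        raise ValidationError("all confusion counts are zero")
    tpr = cc.TP / (cc.TP + cc.FN) if cc.TP + cc.FN > 0 else None
    tnr = cc.TN / (cc.TN + cc.FP) if cc.TN + cc.FP > 0 else None
    acc = (cc.TP + cc.TN) / cc.total
    return tpr, tnr, acc


def confusion_from_labels(truth, predicted) -> ConfusionCounts:
    """Counts with ``true_alarm`` as the positive class."""
    cc = ConfusionCounts()
    for t, p in zip(truth, predicted, strict=True):
        t_pos = t in (1, True, "true_alarm")
        p_pos = p in (1, True, "true_alarm")
        if t_pos and p_pos:
            cc.TP += 1
        elif t_pos:
            cc.FN += 1
        elif p_pos:
            cc.FP += 1
        else:
            cc.TN += 1
    return cc


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _prepare(records, rule_scores):
    """Preprocess records once; build fixed alarm segments and metadata."""
    prepped = []
    for rec in records:
        pre = preprocess(rec)
        t_seg = int(round(pre.fs * SEGMENT_SECONDS))
        if pre.onset < 2 * t_seg:
            raise ValidationError(
                f"record {rec.record_id} too short for a baseline window"
            )
        if callable(rule_scores):
            r = float(rule_scores(pre))
        elif rule_scores is None:
            r = 0.5
        else:
            r = float(rule_scores[rec.record_id])
        prepped.append(
            {
                "id": rec.record_id,
                "matrix": pre.matrix.astype(nn.DTYPE),
                "t_seg": t_seg,
                "onset": pre.onset,
                "onehot": alarm_onehot(pre.alarm_type),
                "rule": r,
                "y": 1.0 if pre.label == "true_alarm" else 0.0,
                "label": pre.label,
            }
        )
    return prepped


def _l2_keys(params) -> list[str]:
    """Convolution and linear weights only — no biases, no batch-norm."""
    return [k for k in params if k.endswith(".W") or k in ("W_a", "W_r", "W_c")]


def train(
    records: list[WaveformRecord],
    rule_scores,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
):
    """Fit the model; returns ``(model, history)``.

    ``rule_scores`` may be a callable applied to each preprocessed record, a
    mapping from record id to score, or ``None`` (neutral 0.5).
    ``history`` is a DataFrame with per-epoch ``bce``, ``constraint`` and
    ``total`` columns. Fully seeded via ``config.rng_seed``.
    """
    config.validate()
    if not records:
        raise ValidationError("empty training set")
    for rec in records:
        if rec.label == "unknown":
            raise ValidationError(f"record {rec.record_id} has no label")

    if "rule_embedding" not in config.components:
        rule_scores = None   # the rule branch is removed entirely when disabled
    data = _prepare(records, rule_scores)
    ys = np.array([d["y"] for d in data])
    if len(np.unique(ys)) < 2:
        warnings.warn(
            "training set contains a single label; the discriminative "
            "constraint degenerates to one term",
            stacklevel=2,
        )

    if model_config is None:
        model_config = ModelConfig()
    model_config = dc_replace(
        model_config, dropout=config.dropout, components=tuple(config.components)
    )
    model = AlarmModel(model_config, seed=config.rng_seed)
    optimizer = nn.Adam(model.params, lr=config.learning_rate)
    use_constraint = (
        "constraint" in config.components and config.constraint_weight > 0
    )

    n = len(data)
    history = []
    for epoch in range(config.max_epochs):
        order_rng = substream(config.rng_seed, "order", epoch)
        order = order_rng.permutation(n)
        base_rng = substream(config.rng_seed, "baseline", epoch)
        starts = np.array(
            [base_rng.integers(0, d["onset"] - 2 * d["t_seg"] + 1) for d in data]
        )
        drop_rng = substream(config.rng_seed, "dropout", epoch)

        sums = {"bce": 0.0, "constraint": 0.0, "total": 0.0}
        seen = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            batch = [data[i] for i in idx]
            x_alarm = np.stack(
                [d["matrix"][:, d["onset"] - d["t_seg"] : d["onset"]] for d in batch]
            )
            onehots = np.stack([d["onehot"] for d in batch])
            rules = np.array([d["rule"] for d in batch])
            y = np.array([d["y"] for d in batch])

            grads: dict[str, np.ndarray] = {}
            f_a, cache_a = model.encode(x_alarm, training=True, rng=drop_rng)
            probs, logits, e = model.head_forward(f_a, onehots, rules)
            l_bce, dlogits = losses.bce_with_logits_grad(
                y, logits, config.positive_class_weight
            )
            df_a = model.head_backward(dlogits, e, onehots, rules, grads)

            c_val = 0.0
            if use_constraint:
                x_base = np.stack(
                    [
                        d["matrix"][:, s : s + d["t_seg"]]
                        for d, s in zip(batch, starts[idx])
                    ]
                )
                f_r, cache_r = model.encode(x_base, training=True, rng=drop_rng)
                c_val, dca, dcr = losses.batch_constraint_grad(f_a, f_r, y)
                df_a = df_a + config.constraint_weight * dca
                model.encode_backward(
                    cache_r, config.constraint_weight * dcr, grads
                )
            model.encode_backward(cache_a, df_a, grads)

            if config.l2_lambda > 0:
                for key in _l2_keys(model.params):
                    base = grads.get(key, 0.0)
                    grads[key] = base + config.l2_lambda * model.params[key]
            optimizer.step(grads)

            l_total = losses.total_loss(l_bce, c_val, config.constraint_weight)
            b = len(idx)
            sums["bce"] += l_bce * b
            sums["constraint"] += c_val * b
            sums["total"] += l_total * b
            seen += b
        history.append(
            {
                "epoch": epoch,
                "bce": sums["bce"] / seen,
                "constraint": sums["constraint"] / seen,
                "total": sums["total"] / seen,
            }
        )
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# Prediction and evaluation
# ---------------------------------------------------------------------------

def predict(
    records: list[WaveformRecord],
    model: AlarmModel,
    rule_scorer=None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Classify records; returns a DataFrame with probabilities and labels.

    Records are preprocessed internally, so only pre-onset samples can affect
    the output (the real-time contract). A probability at or above the
    threshold maps to ``true_alarm``.
    """
    if not records:
        raise ValidationError("no records to predict")
    rows = []
    batch_size = 64
    prepped = [preprocess(rec) for rec in records]
    for lo in range(0, len(prepped), batch_size):
        chunk = prepped[lo : lo + batch_size]
        x = np.stack(
            [
                p.matrix[:, p.onset - int(round(p.fs * SEGMENT_SECONDS)) : p.onset]
                for p in chunk
            ]
        ).astype(nn.DTYPE)
        onehots = np.stack([alarm_onehot(p.alarm_type) for p in chunk])
        if callable(rule_scorer):
            rules = np.array([float(rule_scorer(p)) for p in chunk])
        else:
            rules = np.full(len(chunk), 0.5)
        probs = model.predict_proba(x, onehots, rules)
        for p, prob in zip(chunk, np.atleast_1d(probs)):
            rows.append(
                {
                    "record_id": p.record_id,
                    "alarm_type": p.alarm_type,
                    "probability": float(prob),
                    "predicted": "true_alarm" if prob >= threshold else "false_alarm",
                    "label": p.label,
                }
            )
    return pd.DataFrame(rows)


def _metrics_block(frame: pd.DataFrame) -> dict:
    cc = confusion_from_labels(frame["label"], frame["predicted"])
    tpr, tnr, acc = tpr_tnr_acc(cc)
    return {
        "score": challenge_score(cc),
        "tpr": tpr,
        "tnr": tnr,
        "acc": acc,
        "confusion": {"TP": cc.TP, "TN": cc.TN, "FP": cc.FP, "FN": cc.FN},
    }


def cross_validate(
    records: list[WaveformRecord],
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    rule_scorer=None,
) -> dict:
    """K-fold cross-validation with stratified, seeded folds.

    Returns per-fold metrics, their mean +- sd, and per-alarm-type scores
    pooled over the held-out predictions of all folds.
    """
    config.validate()
    if len(records) < config.folds:
        raise ValidationError("fewer records than folds")
    by_id = {r.record_id: r for r in records}
    folds = make_folds(
        [r.record_id for r in records],
        [r.label for r in records],
        [r.alarm_type for r in records],
        config.folds,
        config.rng_seed,
    )

    if "rule_embedding" not in config.components:
        rule_scorer = None
    fold_metrics = []
    all_preds = []
    for i, held_out in enumerate(folds):
        held = set(held_out)
        train_recs = [r for r in records if r.record_id not in held]
        test_recs = [by_id[rid] for rid in held_out]
        model, _ = train(train_recs, rule_scorer, config, model_config)
        preds = predict(
            test_recs, model, rule_scorer, threshold=config.decision_threshold
        )
        preds["fold"] = i
        all_preds.append(preds)
        fold_metrics.append(_metrics_block(preds))

    pooled = pd.concat(all_preds, ignore_index=True)
    scores = np.array([m["score"] for m in fold_metrics])
    per_type = {
        typ: _metrics_block(group)["score"]
        for typ, group in pooled.groupby("alarm_type")
    }
    return {
        "folds": fold_metrics,
        "mean_score": float(scores.mean()),
        "sd_score": float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
        "per_type_score": per_type,
        "pooled": _metrics_block(pooled),
        "predictions": pooled,
    }


#: Component grid of the ablation table, in presentation order.
ABLATION_GRID = {
    "basic": ("alarm_embedding",),
    "basic+constraint": ("alarm_embedding", "constraint"),
    "basic+rule": ("alarm_embedding", "rule_embedding"),
    "full": ALL_COMPONENTS,
}


def ablate(
    records: list[WaveformRecord],
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    rule_scorer=None,
) -> dict:
    """Run the four-configuration ablation grid with shared folds and seeds."""
    results = {}
    for name, components in ABLATION_GRID.items():
        cfg = dc_replace(config, components=components)
        cv = cross_validate(records, cfg, model_config, rule_scorer)
        results[name] = {
            "components": list(components),
            "mean_score": cv["mean_score"],
            "sd_score": cv["sd_score"],
            "per_type_score": cv["per_type_score"],
            "pooled": cv["pooled"],
        }
    return results
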