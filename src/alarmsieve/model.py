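"""Signal encoder, embedding layers and sigmoid classifier.

The encoder runs four parallel convolution blocks over the ``(M, T)`` input
segment. Each block applies (optionally) dropout to the raw segment, then two
[conv -> batch-norm -> ReLU] stages with a shared kernel size and stride 5,
and finally a global max pool over time, yielding ``filters`` values per
block; block outputs are concatenated. With the default 4 blocks x 64
filters, the encoder output has length 256.

The Siamese property is structural: there is exactly one parameter store, and
both the alarm and the baseline segment are encoded through it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .data_io import ALARM_TYPES, ROLES, SegmentPair
from .errors import ValidationError
from .seeding import substream

__all__ = [
    "ModelConfig",
    "AlarmModel",
    "embed_alarm",
    "embed_rule",
    "fuse_and_classify",
    "save_checkpoint",
    "load_checkpoint",
]

ALL_COMPONENTS = ("constraint", "rule_embedding", "alarm_embedding")


@dataclass
class ModelConfig:
    """Structural hyperparameters of the network."""

    channels: int = len(ROLES)
    kernel_sizes: tuple = (50, 100, 200, 400)
    filters: int = 64
    stride: int = 5
    dropout: float = 0.8
    alarm_dim: int = 64
    rule_dim: int = 64
    components: tuple = ALL_COMPONENTS

    def validate(self) -> None:
        if len(self.kernel_sizes) < 1 or any(k < 1 for k in self.kernel_sizes):
            raise ValidationError(f"bad kernel sizes: {self.kernel_sizes}")
        if self.filters < 1 or self.stride < 1:
            raise ValidationError("filters and stride must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError(f"dropout must be in [0,1), got {self.dropout}")
        unknown = set(self.components) - set(ALL_COMPONENTS)
        if unknown:
            raise ValidationError(f"unknown components: {sorted(unknown)}")

    @property
    def encoder_dim(self) -> int:
        return len(self.kernel_sizes) * self.filters

    @property
    def classifier_dim(self) -> int:
        dim = self.encoder_dim
        if "alarm_embedding" in self.components:
            dim += self.alarm_dim
        if "rule_embedding" in self.components:
            dim += self.rule_dim
        return dim


# ---------------------------------------------------------------------------
# Functional layer contracts
# ---------------------------------------------------------------------------

def _as_batch(x, width):
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        return x[None, :], True
    if x.ndim == 2 and x.shape[1] == width:
        return x, False
    raise ValidationError(f"expected vectors of width {width}, got shape {x.shape}")


def embed_alarm(a, w_a):
    """``E_a = A W_a`` — selects the alarm type's row of ``W_a``.

    ``a`` must be one-hot (single vector or a batch of them).
    """
    w_a = np.asarray(w_a)
    batch, squeeze = _as_batch(a, w_a.shape[0])
    if not np.all(np.isin(batch, (0.0, 1.0))) or not np.all(batch.sum(axis=1) == 1.0):
        raise ValidationError("alarm indicator must be one-hot")
    out = batch @ w_a
    return out[0] if squeeze else out


def embed_rule(r, w_r):
    """``E_r = R W_r`` — the rule score scales a learned vector."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0.0) or np.any(r > 1.0):
        raise ValidationError(f"rule score outside [0,1]: {r}")
    w_r = np.asarray(w_r)
    if r.ndim == 0:
        return float(r) * w_r
    return r[:, None] * w_r[None, :]


def fuse_and_classify(e_e, e_a, e_r, w_c, bias=0.0):
    """``O = sigmoid(concat(E_e, E_a, E_r) . W_c + bias)``.

    Components passed as ``None`` are omitted from the concatenation (used by
    ablation configurations).
    """
    parts = [np.atleast_2d(np.asarray(p, dtype=np.float64))
             for p in (e_e, e_a, e_r) if p is not None]
    e = np.concatenate(parts, axis=1)
    w_c = np.asarray(w_c, dtype=np.float64).reshape(-1)
    if e.shape[1] != w_c.shape[0]:
        raise ValidationError(
            f"classifier expects width {w_c.shape[0]}, got {e.shape[1]}"
        )
    logits = e @ w_c + bias
    probs = nn.sigmoid(logits)
    if probs.shape[0] == 1 and all(
        np.asarray(p).ndim == 1 for p in (e_e, e_a, e_r) if p is not None
    ):
        return float(probs[0])
    return probs


# ---------------------------------------------------------------------------
# The trainable model
# ---------------------------------------------------------------------------

class AlarmModel:
    """Encoder + embeddings + classifier with one shared parameter store."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        rng = substream(seed, "init")
        c, f = config.channels, config.filters

        def uniform(shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape).astype(nn.DTYPE)

        for bi, d in enumerate(config.kernel_sizes):
            for li, c_in in enumerate((c, f)):
                pre = f"block{bi}.conv{li}"
                self.params[f"{pre}.W"] = uniform((c_in, d, f), c_in * d)
                self.params[f"{pre}.b"] = uniform((f,), c_in * d)
                self.params[f"block{bi}.bn{li}.gamma"] = np.ones(f, dtype=nn.DTYPE)
                self.params[f"block{bi}.bn{li}.beta"] = np.zeros(f, dtype=nn.DTYPE)
                self.buffers[f"block{bi}.bn{li}.mean"] = np.zeros(f)
                self.buffers[f"block{bi}.bn{li}.var"] = np.ones(f)

        if "alarm_embedding" in config.components:
            self.params["W_a"] = uniform(
                (len(ALARM_TYPES), config.alarm_dim), len(ALARM_TYPES)
            )
        if "rule_embedding" in config.components:
            self.params["W_r"] = uniform((config.rule_dim,), 1)
        dim = config.classifier_dim
        self.params["W_c"] = uniform((dim,), dim)
        self.params["b_c"] = np.zeros(1, dtype=nn.DTYPE)

    # -- encoder ------------------------------------------------------------

    def encode(self, x, training: bool = False, rng=None):
        """Encode ``(N, M, T)`` (or ``(M, T)``) segments to ``(N, S_e)``."""
        x = np.asarray(x, dtype=nn.DTYPE)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.config.channels:
            raise ValidationError(
                f"expected (N, {self.config.channels}, T) input, got {x.shape}"
            )
        if x.shape[2] < 1:
            raise ValidationError("segment must have at least one time step")
        if training and self.config.dropout > 0 and rng is None:
            raise ValidationError("training-mode encode requires an rng for dropout")

        feats, caches = [], []
        for bi, d in enumerate(self.config.kernel_sizes):
            h, drop_cache = nn.dropout_forward(x, self.config.dropout, training, rng)
            layer_caches = [drop_cache]
            for li in range(2):
                pre = f"block{bi}"
                h, conv_cache = nn.conv1d_forward(
                    h, self.params[f"{pre}.conv{li}.W"],
                    self.params[f"{pre}.conv{li}.b"], self.config.stride,
                )
                h, bn_cache = nn.batchnorm_forward(
                    h,
                    self.params[f"{pre}.bn{li}.gamma"],
                    self.params[f"{pre}.bn{li}.beta"],
                    self.buffers[f"{pre}.bn{li}.mean"],
                    self.buffers[f"{pre}.bn{li}.var"],
                    training,
                )
                h, relu_mask = nn.relu_forward(h)
                layer_caches.append((conv_cache, bn_cache, relu_mask))
            pooled, pool_cache = nn.global_maxpool_forward(h)
            layer_caches.append(pool_cache)
            feats.append(pooled)
            caches.append(layer_caches)
        out = np.concatenate(feats, axis=1)
        return (out[0], caches) if squeeze else (out, caches)

    def encode_backward(self, caches, dfeat, grads: dict) -> None:
        """Accumulate encoder parameter gradients for one encode pass."""
        dfeat = np.atleast_2d(np.asarray(dfeat, dtype=nn.DTYPE))
        f = self.config.filters
        for bi in range(len(self.config.kernel_sizes)):
            drop_cache, stage0, stage1, pool_cache = caches[bi]
            dpool = dfeat[:, bi * f : (bi + 1) * f]
            dh = nn.global_maxpool_backward(dpool, pool_cache)
            for li, stage in ((1, stage1), (0, stage0)):
                conv_cache, bn_cache, relu_mask = stage
                dh = nn.relu_backward(dh, relu_mask)
                dh, dgamma, dbeta = nn.batchnorm_backward(dh, bn_cache)
                pre = f"block{bi}"
                dh, dw, db = nn.conv1d_backward(dh, conv_cache, need_dx=(li == 1))
                _acc(grads, f"{pre}.conv{li}.W", dw)
                _acc(grads, f"{pre}.conv{li}.b", db)
                _acc(grads, f"{pre}.bn{li}.gamma", dgamma)
                _acc(grads, f"{pre}.bn{li}.beta", dbeta)

    # -- full forward -------------------------------------------------------

    def head_forward(self, f_a, alarm_onehot, rule_scores):
        """Fuse encoder features with the enabled embeddings; returns
        (probabilities, logits, concatenated input)."""
        f_a = np.atleast_2d(f_a)
        parts = [f_a]
        if "alarm_embedding" in self.config.components:
            parts.append(np.atleast_2d(alarm_onehot) @ self.params["W_a"])
        if "rule_embedding" in self.config.components:
            r = np.atleast_1d(np.asarray(rule_scores, dtype=np.float64))
            if np.any((r < 0) | (r > 1)):
                raise ValidationError("rule scores must lie in [0,1]")
            parts.append(r[:, None] * self.params["W_r"][None, :])
        e = np.concatenate(parts, axis=1)
        logits = e @ self.params["W_c"].astype(np.float64) + float(self.params["b_c"][0])
        return nn.sigmoid(logits), logits, e

    def head_backward(self, dlogits, e, alarm_onehot, rule_scores, grads) -> np.ndarray:
        """Backprop through the head; returns gradient w.r.t. f_A."""
        dlogits = np.asarray(dlogits, dtype=np.float64)
        _acc(grads, "W_c", e.T @ dlogits)
        _acc(grads, "b_c", np.array([dlogits.sum()]))
        de = dlogits[:, None] * self.params["W_c"][None, :].astype(np.float64)
        s_e = self.config.encoder_dim
        df_a = de[:, :s_e]
        offset = s_e
        if "alarm_embedding" in self.config.components:
            d_ea = de[:, offset : offset + self.config.alarm_dim]
            _acc(grads, "W_a", np.atleast_2d(alarm_onehot).T @ d_ea)
            offset += self.config.alarm_dim
        if "rule_embedding" in self.config.components:
            d_er = de[:, offset : offset + self.config.rule_dim]
            r = np.atleast_1d(np.asarray(rule_scores, dtype=np.float64))
            _acc(grads, "W_r", (r[:, None] * d_er).sum(axis=0))
        return df_a

    def predict_proba(self, segments, alarm_onehot, rule_scores):
        """Inference-mode probabilities for ``(N, M, T)`` alarm segments."""
        feats, _ = self.encode(segments, training=False)
        probs, _, _ = self.head_forward(np.atleast_2d(feats), alarm_onehot, rule_scores)
        return probs

    def forward_pair(self, pair: SegmentPair):
        """Siamese inference on one pair: returns ``(O, f_A, f_R)``.

        Both segments pass through the single shared parameter store; the
        classification output depends on the alarm segment only.
        """
        f_a, _ = self.encode(pair.alarm_segment, training=False)
        f_r, _ = self.encode(pair.baseline_segment, training=False)
        probs, _, _ = self.head_forward(
            f_a[None, :], pair.alarm_onehot[None, :], [pair.rule_score]
        )
        return float(probs[0]), f_a, f_r


def _acc(grads: dict, key: str, value: np.ndarray) -> None:
    if key in grads:
        grads[key] = grads[key] + value
    else:
        grads[key] = value


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: AlarmModel, prefix: str) -> None:
    """Write ``prefix.npz`` (tensors) and ``prefix.json`` (hyperparameters)."""
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    arrays = {f"param::{k}": v for k, v in model.params.items()}
    arrays.update({f"buffer::{k}": v for k, v in model.buffers.items()})
    np.savez(prefix + ".npz", **arrays)
    cfg = asdict(model.config)
    cfg["kernel_sizes"] = list(cfg["kernel_sizes"])
    cfg["components"] = list(cfg["components"])
    with open(prefix + ".json", "w") as fh:
        json.dump(cfg, fh, indent=1)


def load_checkpoint(prefix: str) -> AlarmModel:
    with open(prefix + ".json") as fh:
        cfg = json.load(fh)
    cfg["kernel_sizes"] = tuple(cfg["kernel_sizes"])
    cfg["components"] = tuple(cfg["components"])
    model = AlarmModel(ModelConfig(**cfg), seed=0)
    with np.load(prefix + ".npz") as data:
        for key in data.files:
            kind, name = key.split("::", 1)
            target = model.params if kind == "param" else model.buffers
            if name not in target:
                raise ValidationError(f"checkpoint has unexpected tensor {name!r}")
            if target[name].shape != data[key].shape:
                raise ValidationError(
                    f"checkpoint tensor {name!r} has shape {data[key].shape}, "
                    f"expected {target[name].shape}"
                )
            target[name] = data[key]
    return model
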