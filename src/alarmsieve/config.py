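"""YAML configuration parsing and run manifests.

A config file has up to three sections::

    train:      # TrainConfig fields
      batch_size: 256
    synthetic:  # SyntheticSpec fields
      n_records: 100
    model:      # ModelConfig fields
      filters: 64
    paths:
      data_dir: ...
      out_dir: ...

Omitted keys fall back to the package defaults; unknown keys are rejected by
name. Every artifact-producing CLI command writes a ``run_manifest.json``
capturing the config snapshot, seed, package version, input digest and
output paths — enough to re-run the command.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import os

import yaml

from .errors import ValidationError
from .model import ModelConfig
from .synthetic_data import SyntheticSpec
from .train_eval import TrainConfig

__all__ = ["parse_config", "RunManifest", "write_run_manifest"]

_SECTIONS = {"train": TrainConfig, "synthetic": SyntheticSpec, "model": ModelConfig}
_PATH_KEYS = {"data_dir", "out_dir", "checkpoint", "rule_scorer"}


def _build_section(cls, mapping: dict, section: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(fields)
    if unknown:
        raise ValidationError(
            f"unknown key(s) in section {section!r}: {', '.join(sorted(unknown))}"
        )
    coerced = {}
    for key, value in mapping.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    obj = cls(**coerced)
    if hasattr(obj, "validate"):
        obj.validate()
    return obj


def parse_config(path: str | None):
    """Parse a YAML config into ``(TrainConfig, SyntheticSpec, ModelConfig, paths)``.

    ``path=None`` yields all defaults.
    """
    raw = {}
    if path is not None:
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            where = f" (line {mark.line + 1})" if mark else ""
            raise ValidationError(f"malformed config {path}{where}: {exc}") from exc
        except OSError as exc:
            raise ValidationError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError(f"config root must be a mapping, got {type(raw).__name__}")

    unknown = set(raw) - set(_SECTIONS) - {"paths"}
    if unknown:
        raise ValidationError(f"unknown config section(s): {', '.join(sorted(unknown))}")

    out = {}
    for section, cls in _SECTIONS.items():
        mapping = raw.get(section) or {}
        if not isinstance(mapping, dict):
            raise ValidationError(f"config section {section!r} must be a mapping")
        out[section] = _build_section(cls, mapping, section)

    paths = raw.get("paths") or {}
    if not isinstance(paths, dict) or set(paths) - _PATH_KEYS:
        raise ValidationError(f"paths section accepts only {sorted(_PATH_KEYS)}")
    return out["train"], out["synthetic"], out["model"], paths


@dataclasses.dataclass
class RunManifest:
    command: str
    seed: int
    config: dict
    inputs: dict
    outputs: list[str]
    package_version: str
    timestamp: str


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def write_run_manifest(
    out_dir: str,
    command: str,
    seed: int,
    config_snapshot: dict,
    input_files: list[str],
    outputs: list[str],
) -> str:
    from . import __version__

    manifest = RunManifest(
        command=command,
        seed=seed,
        config=config_snapshot,
        inputs={p: _digest(p) for p in input_files if os.path.exists(p)},
        outputs=outputs,
        package_version=__version__,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "run_manifest.json")
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=1, default=str)
    return path
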