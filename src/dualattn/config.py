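"""Configuration files and the reproducibility manifest.

A run is configured by a YAML file with up to three sections — ``model``,
``train`` and ``data`` — whose keys map one-to-one onto
:class:`~dualattn.model.ModelConfig`, :class:`~dualattn.train.TrainConfig`
and :class:`~dualattn.synth.SyntheticTaskSpec`.  Unknown sections or keys
are rejected with a single aggregated error report; omitted keys take the
documented defaults.  A resolved config can be emitted and re-parsed to
an identical record.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .model import ModelConfig
from .synth import SyntheticTaskSpec
from .train import TrainConfig

__all__ = ["ConfigError", "ResolvedConfig", "parse_config", "RunManifest"]


class ConfigError(ValueError):
    """All schema violations of a config file, aggregated."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


_SECTIONS = {"model": ModelConfig, "train": TrainConfig, "data": SyntheticTaskSpec}


@dataclass(frozen=True)
class ResolvedConfig:
    model: ModelConfig
    train: TrainConfig
    data: SyntheticTaskSpec

    def to_dict(self) -> dict:
        return {
            "model": dataclasses.asdict(self.model),
            "train": dataclasses.asdict(self.train),
            "data": dataclasses.asdict(self.data),
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def _coerce(value, typ):
    # YAML gives lists where the dataclasses want tuples
    if isinstance(value, list):
        return tuple(value)
    return value


def parse_config(source=None, overrides: dict | None = None) -> ResolvedConfig:
    """Parse a YAML file (path or text), validate, and fill defaults.

    ``source`` may be None (all defaults), a path to a YAML file, or a
    mapping.  ``overrides`` is a {section: {key: value}} mapping applied
    on top.  Raises :class:`ConfigError` listing every offending key.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError([f"config file not found: {path}"])
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError([f"config root must be a mapping, got {type(raw).__name__}"])
    if overrides:
        for section, kv in overrides.items():
            raw.setdefault(section, {})
            raw[section] = {**(raw[section] or {}), **kv}

    errors: list[str] = []
    parsed = {}
    for section in raw:
        if section not in _SECTIONS:
            errors.append(f"unknown section {section!r} (expected one of {sorted(_SECTIONS)})")
    for section, cls in _SECTIONS.items():
        entries = raw.get(section) or {}
        if not isinstance(entries, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in entries.items():
            if key not in known:
                errors.append(f"unknown key {section}.{key!r}")
                continue
            kwargs[key] = _coerce(value, known[key].type)
        if section == "data" and "n_samples" not in kwargs:
            kwargs["n_samples"] = 120
        try:
            parsed[section] = cls(**kwargs)
        except (TypeError, ValueError) as exc:
            errors.append(f"section {section!r}: {exc}")
    if errors:
        raise ConfigError(errors)
    return ResolvedConfig(model=parsed["model"], train=parsed["train"], data=parsed["data"])


@dataclass
class RunManifest:
    """Everything needed to re-launch an identical run, written before
    any computation starts."""

    command: str
    seed: int
    config: dict
    outputs: list
    code_version: str = __version__
    platform_fingerprint: str = ""
    created_unix: float = 0.0

    def __post_init__(self):
        if not self.platform_fingerprint:
            self.platform_fingerprint = (
                f"python {sys.version.split()[0]}; numpy {np.__version__}; "
                f"{platform.system()} {platform.machine()}"
            )
        if not self.created_unix:
            self.created_unix = time.time()

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path
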