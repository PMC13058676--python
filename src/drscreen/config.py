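"""Structured configuration files and provenance sidecars.

Generator parameters, threshold sets and referral policies serialize to a
single YAML document so that a calibration run can write its derived
thresholds back into the same format an evaluation run consumes bit-exactly.
Every pipeline output gets a JSON provenance sidecar (config hash, seed,
package version) sufficient to re-run it identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .errors import ConfigError
from .simulate import GeneratorConfig, config_hash
from .thresholds import ReferralPolicy, ThresholdSet

__all__ = [
    "load_generator_config",
    "save_generator_config",
    "load_thresholds",
    "save_thresholds",
    "load_policy",
    "write_provenance",
]


def load_generator_config(path) -> GeneratorConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    section = data.get("generator", data)
    try:
        cfg = GeneratorConfig.from_dict(section)
    except (TypeError, ValueError, KeyError) as exc:
        raise ConfigError(f"bad generator config: {exc}") from exc
    cfg.validate()
    return cfg


def save_generator_config(config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"generator": config.to_dict()}, fh, sort_keys=True)


def load_thresholds(path) -> ThresholdSet:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    section = data.get("thresholds", data)
    if isinstance(section, dict):
        cutpoints = section.get("cutpoints")
    else:
        cutpoints = section
    if not cutpoints:
        raise ConfigError(f"no cutpoints found in {path}")
    return ThresholdSet(tuple(float(c) for c in cutpoints))


def save_thresholds(thresholds: ThresholdSet, path, extra: dict | None = None) -> None:
    doc: dict = {"thresholds": {"cutpoints": list(thresholds.cutpoints)}}
    if extra:
        doc["thresholds"].update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_policy(data: dict) -> ReferralPolicy:
    return ReferralPolicy(
        mode=data.get("mode", "stage_based"),
        cutoff=float(data.get("cutoff", 0.1)),
    )


def write_provenance(path, config: GeneratorConfig, seed: int) -> None:
    from . import __version__

    record = {
        "config_hash": config_hash(config),
        "seed": int(seed),
        "n_patients": config.n_patients,
        "package_version": __version__,
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
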