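"""YAML configuration round-tripping for spaces, conditions and runs.

The shared config format is a plain key-value tree::

    space:
      prior: {mostly_red: 0.5, mostly_yellow: 0.5}   # optional, default uniform
      jars:
        - label: mostly_red
          composition: {red: 5, yellow: 1, white: 1}
        - label: mostly_yellow
          composition: {yellow: 5, red: 1, green: 1}
    conditions:
      - experiment: 1
        cell_id: exp1_independent_informant
        majority_size: 2
        evidence_structure: independent
        dissent_source: informant
        majority_jar: mostly_red
        majority_colour: red
        dissent_colour: yellow

Every output file written by the CLI carries a sidecar ``*.meta.json`` with
the echoed settings, a config hash and the seed, so identical settings
yield identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .experiments import ConditionSpec
from .space import HypothesisSpace, Jar

__all__ = [
    "load_config",
    "space_from_config",
    "conditions_from_config",
    "space_to_config",
    "conditions_to_config",
    "config_hash",
    "write_with_metadata",
]


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} must contain a mapping at top level")
    return dict(data)


def space_from_config(node: Mapping[str, Any]) -> HypothesisSpace:
    jars = [Jar(j["label"], dict(j["composition"])) for j in node["jars"]]
    return HypothesisSpace(jars, node.get("prior"))


def space_to_config(space: HypothesisSpace) -> dict[str, Any]:
    return {
        "prior": dict(space.prior),
        "jars": [
            {"label": j.label, "composition": dict(j.composition)} for j in space.jars
        ],
    }


_CONDITION_KEYS = {f.name for f in dataclasses.fields(ConditionSpec)}


def conditions_from_config(nodes: Sequence[Mapping[str, Any]]) -> list[ConditionSpec]:
    out = []
    for node in nodes:
        unknown = set(node) - _CONDITION_KEYS
        if unknown:
            raise ValueError(f"unknown condition key(s): {sorted(unknown)}")
        kwargs = dict(node)
        if "observed_sample" in kwargs and kwargs["observed_sample"] is not None:
            kwargs["observed_sample"] = tuple(kwargs["observed_sample"])
        out.append(ConditionSpec(**kwargs))
    return out


def conditions_to_config(conditions: Sequence[ConditionSpec]) -> list[dict[str, Any]]:
    out = []
    for c in conditions:
        d = dataclasses.asdict(c)
        if d["observed_sample"] is not None:
            d["observed_sample"] = list(d["observed_sample"])
        out.append(d)
    return out


def config_hash(settings: Mapping[str, Any]) -> str:
    """Stable short hash of a settings mapping (sorted-key JSON, sha256)."""
    payload = json.dumps(settings, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:16]


def write_with_metadata(path: str | Path, settings: Mapping[str, Any]) -> Path:
    """Write ``<path>.meta.json`` echoing settings plus their hash."""
    path = Path(path)
    meta = {"settings": dict(settings), "config_hash": config_hash(settings)}
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return meta_path
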