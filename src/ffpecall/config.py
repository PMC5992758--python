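"""Run configuration: defaults from the dataclasses in each caller module,
overridable from a YAML or ``key=value`` file.  Unknown keys are rejected so
typos never silently fall back to defaults; the resolved configuration is
echoed into logs/output headers by the CLI."""

from __future__ import annotations

import dataclasses
from typing import Optional, Type, TypeVar

import yaml

T = TypeVar("T")


class UnknownConfigKeyError(KeyError):
    pass


def _parse_file(path: str) -> dict:
    with open(path) as fh:
        text = fh.read()
    if "=" in text.splitlines()[0] if text.strip() else False:
        out = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            out[key.strip()] = yaml.safe_load(val.strip())
        return out
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of parameter names to values")
    return data


def build_config(cls: Type[T], path: Optional[str] = None, **overrides) -> T:
    """Instantiate a config dataclass from defaults + file + overrides."""
    values: dict = {}
    if path:
        values.update(_parse_file(path))
    values.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - valid
    if unknown:
        raise UnknownConfigKeyError(
            f"unknown configuration keys for {cls.__name__}: {sorted(unknown)}"
        )
    for f in dataclasses.fields(cls):
        if f.name in values and isinstance(values[f.name], list):
            values[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in values[f.name]
            )
    return cls(**values)


def echo_config(cfg) -> str:
    return " ".join(f"{f.name}={getattr(cfg, f.name)!r}" for f in dataclasses.fields(cfg))
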