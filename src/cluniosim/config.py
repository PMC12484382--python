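"""Structured-text (YAML) round-tripping of model parameters."""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .demography import ModelParams

_TUPLE_FIELDS = {"maturation", "fecundity", "daily_split"}


def params_to_dict(params: ModelParams) -> dict:
    d = asdict(params)
    for key in _TUPLE_FIELDS:
        d[key] = list(d[key])
    return d


def params_from_dict(d: dict) -> ModelParams:
    known = {f.name for f in fields(ModelParams)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    kwargs = dict(d)
    for key in _TUPLE_FIELDS & set(kwargs):
        kwargs[key] = tuple(kwargs[key])
    return ModelParams(**kwargs)


def save_params(params: ModelParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=True))


def load_params(path: str | Path) -> ModelParams:
    return params_from_dict(yaml.safe_load(Path(path).read_text()))
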