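"""Flat key-value configuration with fail-fast unknown-key handling.

The config file is a flat YAML mapping whose keys are the
:class:`~genesift.models.ScoringParams` field names (snake_case) plus
``seed``.  Unknown keys are fatal, so a typo in a threshold name cannot
silently fall back to a default.  A config round-trips losslessly
through :func:`save_config` / :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .models import ScoringParams

__all__ = ["ConfigError", "load_config", "save_config", "params_to_dict"]

_PARAM_FIELDS = {f.name: f for f in dataclasses.fields(ScoringParams)}
_EXTRA_KEYS = {"seed"}


class ConfigError(ValueError):
    pass


def params_to_dict(params: ScoringParams) -> dict:
    d = dataclasses.asdict(params)
    d["acceptable_donor_acceptor"] = sorted(d["acceptable_donor_acceptor"])
    d["exon_depth_range"] = list(d["exon_depth_range"])
    return d


def save_config(params: ScoringParams, path, seed: int | None = None) -> None:
    d = params_to_dict(params)
    if seed is not None:
        d["seed"] = seed
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True, default_flow_style=False)


def load_config(path) -> tuple[ScoringParams, dict]:
    """Read a config file; returns (params, extras) where extras holds
    non-ScoringParams keys such as ``seed``."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return ScoringParams(), {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat key-value mapping")
    unknown = set(raw) - set(_PARAM_FIELDS) - _EXTRA_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _EXTRA_KEYS:
            continue
        if key == "acceptable_donor_acceptor":
            value = frozenset(value)
        elif key == "exon_depth_range":
            value = tuple(value)
        kwargs[key] = value
    try:
        params = ScoringParams(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    extras = {k: raw[k] for k in _EXTRA_KEYS if k in raw}
    return params, extras
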