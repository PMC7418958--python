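"""YAML configuration loading with validated defaults.

An empty config file yields the full default study conditions: N = 40,
equal groups, delta = 0.2, k = 3, same-group mixing probability 0.5,
sigma_S = 0.1 with sigma_L = 1.5 sigma_S.  Unknown keys are rejected with
an error naming the key, so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .experiments import SweepConfig, sigma_relation
from .params import ModelParams

_MODEL_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}
_SWEEP_FIELDS = {f.name for f in dataclasses.fields(SweepConfig)}
_EXTRA_KEYS = {"sigma_relation_rule"}  # derive sigma_large from sigma_small


class ConfigError(ValueError):
    pass


def default_model_params(**overrides) -> ModelParams:
    return ModelParams(**overrides)


def default_sweep_config(**overrides) -> SweepConfig:
    return SweepConfig(**overrides)


def load_config(path: str | Path, **overrides) -> tuple[ModelParams, SweepConfig]:
    """Parse a YAML config into (ModelParams, SweepConfig).

    Keys matching ModelParams fields configure the single-run model; keys
    matching SweepConfig fields configure the batch designs.  The special
    key ``sigma_relation_rule: f1|f2`` derives sigma_large from
    sigma_small.  ``overrides`` (e.g. from CLI flags) take precedence over
    the file; ``None`` overrides are ignored.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping of keys to values")

    for key, value in overrides.items():
        if value is not None:
            raw[key] = value

    unknown = set(raw) - _MODEL_FIELDS - _SWEEP_FIELDS - _EXTRA_KEYS
    if unknown:
        raise ConfigError(
            f"unknown config key(s): {', '.join(sorted(unknown))}"
        )

    model_kwargs = {k: v for k, v in raw.items() if k in _MODEL_FIELDS}
    sweep_kwargs = {k: v for k, v in raw.items() if k in _SWEEP_FIELDS}

    # fill in the group partition when only part of it is specified
    n_agents = model_kwargs.get("n_agents", 40)
    if "n_small" in model_kwargs and "n_large" not in model_kwargs:
        model_kwargs["n_large"] = n_agents - model_kwargs["n_small"]
    elif "n_large" in model_kwargs and "n_small" not in model_kwargs:
        model_kwargs["n_small"] = n_agents - model_kwargs["n_large"]
    elif "n_agents" in model_kwargs and "n_small" not in model_kwargs:
        model_kwargs["n_small"] = n_agents // 2
        model_kwargs["n_large"] = n_agents - n_agents // 2

    rule = raw.get("sigma_relation_rule")
    if rule is None and "sigma_small" in model_kwargs and "sigma_large" not in model_kwargs:
        rule = "f1"
    if rule is not None:
        if "sigma_large" in model_kwargs:
            raise ConfigError(
                "give either sigma_large or sigma_relation_rule, not both"
            )
        try:
            model_kwargs["sigma_large"] = sigma_relation(
                model_kwargs.get("sigma_small", 0.1), rule
            )
        except ValueError as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc

    # grids arrive as YAML lists; the dataclasses expect tuples
    for key in ("sigma_small_grid", "n_small_grid", "gossip_grid"):
        if key in sweep_kwargs:
            sweep_kwargs[key] = tuple(sweep_kwargs[key])
    if "esteem_bounds" in model_kwargs:
        model_kwargs["esteem_bounds"] = tuple(model_kwargs["esteem_bounds"])

    try:
        params = ModelParams(**model_kwargs)
        sweep = SweepConfig(**sweep_kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    return params, sweep
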