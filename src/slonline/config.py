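"""YAML configuration loading for designs, observers and filters."""

from __future__ import annotations

import yaml

from .designs import DesignSpec, get_preset
from .errors import ConfigurationError
from .observer import ObserverParams
from .preprocess import FilterConfig


def _load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return data


def design_from_mapping(data: dict) -> DesignSpec:
    """Build a DesignSpec from a mapping; ``preset`` names a starting point
    whose fields the remaining keys override."""
    data = dict(data)
    preset = data.pop("preset", None)
    if preset is not None and not data:
        return get_preset(preset)
    base = get_preset(preset).__dict__ if preset is not None else {}
    merged = {**base, **data}
    if "pair_templates" in merged:
        merged["pair_templates"] = tuple(
            tuple(t) for t in merged["pair_templates"]
        )
    if "iti_ms" in merged:
        merged["iti_ms"] = tuple(merged["iti_ms"])
    if "categories" in merged:
        merged["categories"] = tuple(merged["categories"])
    merged.setdefault("name", preset or "custom")
    try:
        return DesignSpec(**merged)
    except TypeError as err:
        raise ConfigurationError(f"bad design config: {err}") from err


def load_design(path) -> DesignSpec:
    return design_from_mapping(_load_yaml(path))


def load_observer_params(path) -> ObserverParams:
    data = _load_yaml(path)
    if "nvar_effects" in data:
        data["nvar_effects"] = tuple(data["nvar_effects"])
    try:
        return ObserverParams(**data)
    except TypeError as err:
        raise ConfigurationError(f"bad observer params: {err}") from err


def load_filters(path) -> FilterConfig:
    data = _load_yaml(path)
    try:
        return FilterConfig(**data)
    except TypeError as err:
        raise ConfigurationError(f"bad filter config: {err}") from err
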