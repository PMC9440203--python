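"""Loading and validation of BTC model configurations.

A configuration is one hierarchical YAML document with sections
``populations``, ``connectivity``, ``sigmoid``, ``noise``, ``simulation``
and ``experiments``.  Connectivity entries use the symbolic edge names
(``C_tde``, ``C_idi``, ``C_ndi``, ``C_dpe``, ...) so that experiment specs
can address individual weights by name.

The packaged default, :func:`default_config`, is the model's reference
parameter set; see the YAML file itself and ``docs/methods.md`` for the
provenance of each value.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .model_core import BTCModel, build_btc_model

__all__ = ["default_config", "load_config", "model_from_config", "dump_config"]

_DEFAULT_RESOURCE = "default.yaml"


def default_config() -> dict[str, Any]:
    """Return a deep copy of the packaged default configuration."""
    text = resources.files("btcmodel.data").joinpath(_DEFAULT_RESOURCE).read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a configuration file, or the packaged default when ``path`` is None.

    User files may be partial: any section or key they omit is filled in
    from the default, so a file containing only ``connectivity: {C_tde: 80}``
    is a valid way to run a perturbed model.
    """
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(cfg, user)


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def model_from_config(config: Mapping | None = None) -> BTCModel:
    """Build a validated :class:`~btcmodel.model_core.BTCModel`."""
    return build_btc_model(config if config is not None else default_config())


def dump_config(config: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=False)
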