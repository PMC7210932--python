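"""Config-file parsing, validation and packaged process presets.

Process definitions are structured YAML mirroring :class:`SMBConfig`
(see ``presets/sugar.yaml`` for the schema).  Units are fixed — cm, min,
mL/min, g/L, cm^2/min — and match the preset files verbatim; there is
no unit-conversion layer.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .isotherms import IsothermSpec
from .smb import SMBConfig

__all__ = ["load_config", "validate_config", "load_preset", "preset_names"]

_PRESETS = {"sugar": "sugar.yaml", "binaphthol": "binaphthol.yaml"}


def preset_names() -> tuple[str, ...]:
    return tuple(_PRESETS)


def _require(raw: dict, key: str) -> Any:
    if key not in raw:
        raise ValueError(f"config is missing required field {key!r}")
    return raw[key]


def _component_pair(raw: Any, field: str) -> tuple[float, float]:
    if not isinstance(raw, dict) or set(raw) != {"A", "B"}:
        raise ValueError(f"{field}: expected a mapping with keys A and B")
    return float(raw["A"]), float(raw["B"])


def validate_config(raw: dict) -> SMBConfig:
    """Build a validated :class:`SMBConfig` from parsed structured text.

    Every violated invariant is reported with its field name; derived
    quantities (port flows, interstitial velocities, zone Peclet numbers)
    are available on the returned object.
    """
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    column = _require(raw, "column")
    iso_raw = _require(raw, "isotherm")
    try:
        isotherm = IsothermSpec(_require(iso_raw, "kind"), _require(iso_raw, "coefficients"))
    except ValueError as exc:
        raise ValueError(f"isotherm: {exc}") from exc
    cfg = SMBConfig(
        column_length=float(_require(column, "length_cm")),
        inner_diameter=float(_require(column, "inner_diameter_cm")),
        eps_b=float(_require(raw, "bed_porosity")),
        switching_time=float(_require(raw, "switching_time_min")),
        zone_flows=tuple(_require(raw, "zone_flow_mL_per_min")),
        zone_dispersion=tuple(_require(raw, "zone_dispersion_cm2_per_min")),
        feed_conc=_component_pair(
            _require(raw, "feed_concentration_g_per_L"), "feed_concentration_g_per_L"
        ),
        ke=_component_pair(
            _require(raw, "mass_transfer_coefficient_per_min"),
            "mass_transfer_coefficient_per_min",
        ),
        isotherm=isotherm,
        columns_per_zone=tuple(raw.get("columns_per_zone", (2, 2, 2, 2))),
        grid_points_per_column=int(raw.get("grid_points_per_column", 65)),
        boundary_method=raw.get("boundary_method", "pseudo"),
        css_rel_tol=float(raw.get("css_rel_tol", 1e-4)),
        theta=float(raw.get("theta", 0.0)),
        max_switches=int(raw.get("max_switches", 300)),
        rtol=float(raw.get("rtol", 1e-8)),
        atol=float(raw.get("atol", 1e-8)),
        name=str(raw.get("name", "")),
    )
    return cfg


def load_config(path: str | Path) -> SMBConfig:
    """Load and validate a process configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


def load_preset(name: str) -> SMBConfig:
    """Load one of the packaged case studies (``sugar`` or ``binaphthol``)."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    text = resources.files("smbcfd").joinpath("presets", _PRESETS[name]).read_text()
    return validate_config(yaml.safe_load(text))
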