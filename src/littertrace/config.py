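"""TOML configuration loading for the command-line tools.

A single config file may carry an ``[isotope]`` block (standard ratio,
default control signature, clamp tolerance), a ``[respiration]`` block
(headspace volume, molar volume, bulk C, end members), a ``[markers]``
table overriding the PLFA marker map, and a ``[nanosims]`` block
(dwell, dead time, field of view). Absent blocks fall back to the
package defaults.
"""

from __future__ import annotations

import sys
from pathlib import Path

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

from .isotope import CLAMP_TOLERANCE_DEFAULT, DELTA_CONTROL_DEFAULT, R13_VPDB
from .nanosims import DEAD_TIME_DEFAULT, DWELL_DEFAULT
from .respiration import RespirationConfig

__all__ = ["load_config", "respiration_config_from_toml", "marker_map_from_toml"]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def respiration_config_from_toml(raw: dict) -> RespirationConfig:
    iso = raw.get("isotope", {})
    resp = raw.get("respiration", {})
    return RespirationConfig(
        v_headspace_ml=resp.get("v_headspace_ml", 377.0),
        molar_volume_ml_mmol=resp.get("molar_volume_ml_mmol", 24.1),
        c_bulk_mass_g=resp.get("c_bulk_mass_g", 1.0),
        delta_litter=resp.get("delta_litter", 2129.0),
        delta_control=iso.get("delta_control_default", resp.get("delta_control", DELTA_CONTROL_DEFAULT)),
        clamp_tolerance=iso.get("clamp_tolerance", CLAMP_TOLERANCE_DEFAULT),
    )


def isotope_params_from_toml(raw: dict) -> dict:
    iso = raw.get("isotope", {})
    return {
        "r13_vpdb": iso.get("r13_vpdb", R13_VPDB),
        "delta_control_default": iso.get("delta_control_default", DELTA_CONTROL_DEFAULT),
        "clamp_tolerance": iso.get("clamp_tolerance", CLAMP_TOLERANCE_DEFAULT),
    }


def marker_map_from_toml(raw: dict) -> dict | None:
    """User marker map: ``[markers]`` table of fa_name -> group."""
    return raw.get("markers")


def nanosims_params_from_toml(raw: dict) -> dict:
    blk = raw.get("nanosims", {})
    return {
        "dwell_s": blk.get("dwell_s", DWELL_DEFAULT),
        "dead_time_s": blk.get("dead_time_s", DEAD_TIME_DEFAULT),
        "field_of_view_um": blk.get("field_of_view_um", 25.0),
    }
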