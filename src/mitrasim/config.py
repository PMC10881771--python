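"""Rig configuration for the pulse-duplicator digital twin.

A :class:`RigConfig` fully parameterizes one bench run: the piston pump
(rate, stroke, ejection fraction of the cycle), the ventricular compliance
chamber (an air pocket of ``cv_ml`` millilitres), the two valves as
effective orifice areas, the Windkessel afterload, the working fluid and
the pressure/flow sensors.  Configurations are plain data — the physics
lives in :mod:`mitrasim.twin`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class RigConfig(BaseModel):
    """Complete parameterization of the digital twin.

    Pressures are handled on an absolute scale internally (sensors report
    absolute pressure, offset ``p_atm_mmhg``); areas are effective orifice
    areas in cm².  ``mv_ero_cm2 = 0`` models a fully competent mitral valve.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    hr_bpm: float = 80.0
    sv_pump_ml: float = 70.0
    systolic_fraction: float = 0.35
    cv_ml: float = 130.0
    p_atm_mmhg: float = 760.0
    mv_forward_area_cm2: float = 2.4
    mv_ero_cm2: float = 0.0
    av_area_cm2: float = 0.96
    av_leak_area_cm2: float = 0.0
    c_reservoir_ml_per_mmhg: float = 1.5
    r_peripheral_mmhg_s_per_ml: float = 0.48
    p_la_baseline_mmhg: float = 20.0
    rho_kg_m3: float = 1060.0
    fs_hz: float = 150.0
    noise_sd_mmhg: float = 0.5
    noise_sd_ml_s: float = 2.0
    duration_s: float = 30.0
    seed: int = 0
    dt_s: float = 2.0e-4

    @model_validator(mode="after")
    def _check_invariants(self) -> "RigConfig":
        if self.hr_bpm <= 0:
            raise ValueError("hr_bpm must be positive")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic_fraction must lie in (0, 1)")
        if self.cv_ml < 0:
            raise ValueError("cv_ml must be non-negative")
        for name in ("mv_forward_area_cm2", "mv_ero_cm2", "av_area_cm2",
                     "av_leak_area_cm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.dt_s > 1.0 / self.fs_hz:
            raise ValueError("dt_s must not exceed the sensor sampling interval")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.p_atm_mmhg <= 0 or self.rho_kg_m3 <= 0:
            raise ValueError("p_atm_mmhg and rho_kg_m3 must be positive")
        return self

    @property
    def period_s(self) -> float:
        return 60.0 / self.hr_bpm

    def replace(self, **updates: Any) -> "RigConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return RigConfig(**{**self.model_dump(), **updates})


def load_config(path: str | Path) -> RigConfig:
    """Read a :class:`RigConfig` from a YAML or JSON file.

    Unknown keys are rejected so that typos in rig files fail loudly.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of RigConfig fields")
    return RigConfig(**data)


def dump_config(config: RigConfig, path: str | Path) -> None:
    """Write a config as YAML (JSON if the suffix is ``.json``)."""
    path = Path(path)
    data = config.model_dump()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Named valve presets.
#
# Each preset mirrors one column of the bench validation campaign: the
# compliance-chamber volume is the documented rig setting, the peripheral
# resistance is the value obtained by calibrating the competent rig at that
# compliance volume to the documented systolic pressure, and the mitral
# effective regurgitant orifice is a tuned fixture constant chosen so that
# the full pipeline lands near the documented regurgitant volume for that
# valve/condition.  The EROs are properties of the presets, not measured
# quantities.
# ---------------------------------------------------------------------------

_PRESET_FIELDS: dict[str, dict[str, float]] = {
    # name: cv_ml, r_peripheral, mv_ero, mv_forward_area
    "biological":       dict(cv_ml=130.0, r_peripheral_mmhg_s_per_ml=0.5116, mv_ero_cm2=0.0171, mv_forward_area_cm2=2.4),
    "mechanical":       dict(cv_ml=130.0, r_peripheral_mmhg_s_per_ml=0.5504, mv_ero_cm2=0.0250, mv_forward_area_cm2=1.7),
    "exvivo_a_physio":  dict(cv_ml=100.0, r_peripheral_mmhg_s_per_ml=0.2902, mv_ero_cm2=0.0965, mv_forward_area_cm2=3.2),
    "exvivo_a_patho":   dict(cv_ml=100.0, r_peripheral_mmhg_s_per_ml=0.2902, mv_ero_cm2=0.3419, mv_forward_area_cm2=3.2),
    "exvivo_a_repaired": dict(cv_ml=100.0, r_peripheral_mmhg_s_per_ml=0.2902, mv_ero_cm2=0.0901, mv_forward_area_cm2=3.2),
    "exvivo_b_patho":   dict(cv_ml=40.0,  r_peripheral_mmhg_s_per_ml=0.2589, mv_ero_cm2=0.3347, mv_forward_area_cm2=3.0),
    "exvivo_b_repaired": dict(cv_ml=40.0, r_peripheral_mmhg_s_per_ml=0.2589, mv_ero_cm2=0.1257, mv_forward_area_cm2=3.0),
    "invitro_patho":    dict(cv_ml=0.0,   r_peripheral_mmhg_s_per_ml=0.1760, mv_ero_cm2=0.5373, mv_forward_area_cm2=1.3),
    "invitro_repaired": dict(cv_ml=0.0,   r_peripheral_mmhg_s_per_ml=0.1760, mv_ero_cm2=0.2330, mv_forward_area_cm2=1.3),
}

#: Condition label of every preset (used when assembling condition summaries).
PRESET_CONDITIONS: dict[str, str] = {
    "biological": "physiological",
    "mechanical": "physiological",
    "exvivo_a_physio": "physiological",
    "exvivo_a_patho": "pathological",
    "exvivo_a_repaired": "repaired",
    "exvivo_b_patho": "pathological",
    "exvivo_b_repaired": "repaired",
    "invitro_patho": "pathological",
    "invitro_repaired": "repaired",
}

#: Pathological preset -> its repaired counterpart (same physical valve).
REPAIR_PAIRS: dict[str, str] = {
    "exvivo_a_patho": "exvivo_a_repaired",
    "exvivo_b_patho": "exvivo_b_repaired",
    "invitro_patho": "invitro_repaired",
}

PRESET_NAMES: tuple[str, ...] = tuple(_PRESET_FIELDS)


def preset(name: str, **overrides: Any) -> RigConfig:
    """Return the named valve preset, optionally overriding fields."""
    try:
        fields = _PRESET_FIELDS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    return RigConfig(**{**fields, **overrides})
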