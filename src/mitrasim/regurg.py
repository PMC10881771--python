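"""Regurgitant volume and fraction with ideal-gas compliance correction.

The rig cannot measure mitral backflow directly; it is inferred from a
volume balance.  Per beat, the piston ejects ``SV_Pump`` millilitres; part
of that stroke is taken up by the isothermal compression of the
compliance-chamber air volume ``CV`` between end diastole (absolute
pressure ``P_LVED``) and systole (mean absolute systolic pressure
``P_LVMS``); the rest leaves through the aortic valve (``SV_aortic``) or
leaks back through the mitral valve:

    RVol = SV_Pump − CV·(1 − P_LVED/P_LVMS) − SV_aortic

The regurgitant fraction relates the backflow to the effective forward
stroke delivered through the mitral valve:

    RF = RVol / (SV_Pump − CV·(1 − P_LVED/P_LVMS)) × 100

Reported values are rounded half-up to integer millilitres / percent, the
convention of the bench protocol; the raw values are preserved (a raw RVol
can be slightly negative through measurement rounding — only the rounded
display is floored at zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero upward."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class RegurgInputs:
    """The five measured quantities the volume balance consumes."""

    sv_pump: float      # piston stroke volume, ml
    cv: float           # compliance-chamber air volume, ml
    p_lved_abs: float   # absolute LV end-diastolic pressure, mmHg
    p_lvms_abs: float   # mean absolute LV systolic pressure, mmHg
    sv_aortic: float    # net aortic stroke volume, ml

    def __post_init__(self) -> None:
        if self.sv_pump <= 0:
            raise ValueError("sv_pump must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if not 0 < self.p_lved_abs <= self.p_lvms_abs:
            raise ValueError("require 0 < p_lved_abs <= p_lvms_abs")
        if self.sv_aortic < 0:
            raise ValueError("sv_aortic must be non-negative")


@dataclass(frozen=True)
class RegurgResult:
    compression: float   # ml absorbed by the air pocket
    rvol: float          # ml, raw
    rf: float            # percent, raw
    rounded_rvol: int    # display value, floored at 0
    rounded_rf: int      # display value, floored at 0


def compliance_compression(inputs: RegurgInputs) -> float:
    """Isothermal pocket compression ``CV (1 − P_LVED/P_LVMS)`` in ml."""
    if inputs.p_lvms_abs <= 0:
        raise ValueError("p_lvms_abs must be positive")
    return inputs.cv * (1.0 - inputs.p_lved_abs / inputs.p_lvms_abs)


def regurgitant_volume(inputs: RegurgInputs) -> float:
    """Raw regurgitant volume (ml) from the per-beat volume balance."""
    return inputs.sv_pump - compliance_compression(inputs) - inputs.sv_aortic


def regurgitant_fraction(inputs: RegurgInputs) -> float:
    """Raw regurgitant fraction (%) relative to the effective forward stroke."""
    denom = inputs.sv_pump - compliance_compression(inputs)
    if denom <= 0:
        raise ValueError(
            "effective forward stroke (sv_pump - compression) must be positive"
        )
    return 100.0 * regurgitant_volume(inputs) / denom


def assess_regurgitation(inputs: RegurgInputs) -> RegurgResult:
    """Evaluate compression, RVol and RF with display rounding."""
    compression = compliance_compression(inputs)
    rvol = regurgitant_volume(inputs)
    rf = regurgitant_fraction(inputs)
    return RegurgResult(
        compression=compression,
        rvol=rvol,
        rf=rf,
        rounded_rvol=max(0, round_half_up(rvol)),
        rounded_rf=max(0, round_half_up(rf)),
    )
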