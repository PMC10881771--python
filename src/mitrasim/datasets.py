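"""Bundled bench measurements from the five-valve validation campaign.

Nine valve/condition runs (two prosthetic valves, one excised porcine
valve in physiological / post-chordae-rupture / repaired states, one
dilated excised valve before and after edge-to-edge repair, and one
patient-specific silicone valve before and after surgical repair) at
80 bpm and a 70 ml pump stroke.  These printed measurement rows serve as
the reference inputs for the regurgitation equations and the condition
summaries; pressures are absolute (mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass

from .regurg import RegurgInputs

PUMP_STROKE_ML = 70.0
HEART_RATE_BPM = 80.0


@dataclass(frozen=True)
class BenchMeasurement:
    """One measured valve/condition column of the validation campaign."""

    valve_id: str
    condition: str          # physiological | pathological | repaired
    cv_ml: float
    sbp_mmhg: float
    tmg_mmhg: float
    sv_aortic_ml: float
    co_l_min: float
    rvol_ml: int            # reported (rounded) regurgitant volume
    rf_pct: int             # reported (rounded) regurgitant fraction
    grade: str              # reported grade ("2.3" = between grades 2 and 3)
    p_lvms_abs_mmhg: float
    p_lved_abs_mmhg: float

    @property
    def regurg_inputs(self) -> RegurgInputs:
        return RegurgInputs(
            sv_pump=PUMP_STROKE_ML,
            cv=self.cv_ml,
            p_lved_abs=self.p_lved_abs_mmhg,
            p_lvms_abs=self.p_lvms_abs_mmhg,
            sv_aortic=self.sv_aortic_ml,
        )


REFERENCE_MEASUREMENTS: dict[str, BenchMeasurement] = {
    m.valve_id: m
    for m in (
        BenchMeasurement("biological", "physiological", 130, 118, 3.21, 61, 4.88, 3, 5, "0", 819, 782),
        BenchMeasurement("mechanical", "physiological", 130, 119, 6.69, 61, 4.90, 4, 6, "0", 814, 783),
        BenchMeasurement("exvivo_a_physio", "physiological", 100, 120, 0.72, 57, 4.55, 9, 14, "0", 821, 788),
        BenchMeasurement("exvivo_a_patho", "pathological", 100, 85, 0.72, 44, 3.49, 24, 35, "2", 809, 789),
        BenchMeasurement("exvivo_a_repaired", "repaired", 100, 117, 1.49, 58, 4.67, 8, 12, "0", 824, 795),
        BenchMeasurement("exvivo_b_patho", "pathological", 40, 99, 2.32, 45, 3.56, 24, 35, "2", 813, 788),
        BenchMeasurement("exvivo_b_repaired", "repaired", 40, 106, 2.51, 54, 4.30, 15, 22, "1", 812, 789),
        BenchMeasurement("invitro_patho", "pathological", 0, 79, 6.86, 37, 2.98, 32, 47, "2.3", 803, 781),
        BenchMeasurement("invitro_repaired", "repaired", 0, 115, 13.5, 48, 3.83, 22, 32, "1", 814, 782),
    )
}

#: Pathological measurement -> its repaired counterpart (same valve).
REPAIR_PAIRS: dict[str, str] = {
    "exvivo_a_patho": "exvivo_a_repaired",
    "exvivo_b_patho": "exvivo_b_repaired",
    "invitro_patho": "invitro_repaired",
}
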