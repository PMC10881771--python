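"""Per-valve records and per-condition summary tables.

``ValveRecord`` mirrors one measured column of the bench campaign (one
valve in one condition); ``ConditionSummary`` aggregates records of a
condition as mean ± SD.  The SD convention is the population SD (divisor
``n``), which is what the bench protocol's summary table uses.  Display
rounding is half-up: integers for pressures, volumes and percentages, two
decimals for cardiac output and the transmitral gradient.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beats import HemoSummary
from .grading import MRAssessment
from .regurg import RegurgResult, round_half_up

SUMMARY_METRICS = ("sbp", "co", "sv_aortic", "rvol", "rf")

_DISPLAY_2DP = {"co", "tmg"}


def _round2(x: float) -> float:
    return round_half_up(100.0 * x) / 100.0


@dataclass(frozen=True)
class ValveRecord:
    """One valve/condition run, with display-rounded fields."""

    valve_id: str
    condition: str
    cv: float
    sbp: float
    tmg: float
    sv_aortic: float
    co: float
    rvol: float
    rf: float
    grade_rvol: int
    grade_rf: int
    p_lvms_abs: float
    p_lved_abs: float

    @property
    def combined_grade(self) -> int | tuple[int, int]:
        if self.grade_rvol == self.grade_rf:
            return self.grade_rvol
        lo, hi = sorted((self.grade_rvol, self.grade_rf))
        return (lo, hi)

    def display(self) -> dict:
        """The record with the bench table's rounding conventions applied."""
        out = {}
        for key, value in asdict(self).items():
            if isinstance(value, float):
                out[key] = _round2(value) if key in _DISPLAY_2DP else round_half_up(value)
            else:
                out[key] = value
        grade = self.combined_grade
        out["grade"] = f"{grade[0]}.{grade[1]}" if isinstance(grade, tuple) else str(grade)
        return out


@dataclass(frozen=True)
class ConditionSummary:
    """Mean ± population SD of each metric over one condition's records."""

    condition: str
    n: int
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def display(self) -> dict[str, str]:
        out = {"condition": self.condition, "n": str(self.n)}
        for metric in SUMMARY_METRICS:
            m, s = self.mean[metric], self.sd[metric]
            if metric in _DISPLAY_2DP:
                out[metric] = f"{_round2(m):.2f} ± {_round2(s):.2f}"
            else:
                out[metric] = f"{round_half_up(m)} ± {round_half_up(s)}"
        return out


def build_valve_record(
    summary: HemoSummary,
    regurg: RegurgResult,
    assessment: MRAssessment,
    valve_id: str,
    condition: str,
    cv_ml: float,
) -> ValveRecord:
    """Assemble the per-valve row from one pipeline run's outputs."""
    return ValveRecord(
        valve_id=valve_id,
        condition=condition,
        cv=cv_ml,
        sbp=summary.sbp,
        tmg=summary.tmg,
        sv_aortic=summary.sv_aortic,
        co=summary.co,
        rvol=regurg.rvol,
        rf=regurg.rf,
        grade_rvol=assessment.grade_rvol,
        grade_rf=assessment.grade_rf,
        p_lvms_abs=summary.p_lvms_abs,
        p_lved_abs=summary.p_lved_abs,
    )


def _pop_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=0))


def condition_summary(records: list[ValveRecord], condition: str) -> ConditionSummary:
    """Mean and population SD of the unrounded metrics for one condition."""
    rows = [r for r in records if r.condition == condition]
    if not rows:
        raise ValueError(f"no records with condition {condition!r}")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for metric in SUMMARY_METRICS:
        values = np.array([getattr(r, metric) for r in rows], dtype=float)
        mean[metric] = float(values.mean())
        sd[metric] = _pop_sd(values)
    return ConditionSummary(condition=condition, n=len(rows), mean=mean, sd=sd)


def repair_deltas(
    patho: list[ValveRecord],
    repaired: list[ValveRecord],
    pairs: dict[str, str],
) -> dict[str, tuple[float, float]]:
    """Mean ± population SD of per-valve (patho − repaired) RVol/RF drops.

    ``pairs`` maps each pathological record's valve_id to its repaired
    counterpart's; every pathological record must find its partner.
    """
    repaired_by_id = {r.valve_id: r for r in repaired}
    missing = [
        p.valve_id
        for p in patho
        if pairs.get(p.valve_id) not in repaired_by_id
    ]
    if missing:
        raise ValueError(f"unpaired pathological valves: {missing}")
    out: dict[str, tuple[float, float]] = {}
    for metric in ("rvol", "rf"):
        drops = np.array(
            [
                getattr(p, metric) - getattr(repaired_by_id[pairs[p.valve_id]], metric)
                for p in patho
            ],
            dtype=float,
        )
        out[metric] = (float(drops.mean()), _pop_sd(drops))
    return out


def records_to_table(records: list[ValveRecord]) -> pd.DataFrame:
    """Bench-style per-valve table (columns = valves, rows = parameters)."""
    rows = {
        "Compliance volume (ml)": "cv",
        "Systolic blood pressure (mmHg)": "sbp",
        "Trans mitral gradient (mmHg)": "tmg",
        "Stroke volume (ml)": "sv_aortic",
        "Cardiac output (l/min)": "co",
        "Regurgitation volume (ml)": "rvol",
        "Regurgitation fraction (%)": "rf",
        "Mitral regurgitation grade": "grade",
        "P_LVMS (mmHg)": "p_lvms_abs",
        "P_LVED (mmHg)": "p_lved_abs",
    }
    data = {}
    for record in records:
        disp = record.display()
        data[record.valve_id] = [disp[key] for key in rows.values()]
    return pd.DataFrame(data, index=list(rows))


def summaries_to_table(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Per-condition mean ± SD table."""
    labels = {
        "sbp": "Systolic blood pressure (mmHg)",
        "co": "Cardiac output (l/min)",
        "sv_aortic": "Stroke volume (ml)",
        "rvol": "Regurgitation volume (ml)",
        "rf": "Regurgitation fraction (%)",
    }
    data = {
        s.condition: [s.display()[metric] for metric in labels] for s in summaries
    }
    return pd.DataFrame(data, index=list(labels.values()))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index_label="parameter")
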