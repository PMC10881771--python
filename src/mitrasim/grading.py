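"""Mitral-regurgitation severity grading and condition classification.

Severity follows a Dujardin-style scheme extended downward with a grade 0
for trivial regurgitation: grade 0 is RVol < 12 ml and RF < 19 %, grade 1
RVol < 30 ml and RF < 30 %, grade 2 30–44 ml and 30–39 %, grade 3 45–59 ml
and 40–49 %, grade 4 anything larger.  The printed integer gaps (44→45,
39→40, 49→50) are closed with half-open intervals so every non-negative
value is gradable.  RVol and RF are graded separately; when the two
parameters disagree the combined grade is reported as the ordered range
``(min, max)`` rather than invented by a tie-break.

A valve/condition is *physiological* when SBP lies in 90–120 mmHg
(inclusive), CO in 4.5–5 l/min and the MR grade is 0; any MR grade above 0
is *pathological*; a repair is *successful* when it lowers the MR grade —
conservatively, when the repaired grade range lies entirely below the
pre-repair range.

The thresholds live in a packaged JSON file (``thresholds.json``) so an
alternative guideline scheme can be swapped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .beats import HemoSummary


@dataclass(frozen=True)
class GradeThresholds:
    """Per-grade half-open ``[lo, hi)`` intervals for RVol (ml) and RF (%)."""

    rvol_ml: tuple[tuple[float, float], ...]
    rf_pct: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for name, intervals in (("rvol_ml", self.rvol_ml), ("rf_pct", self.rf_pct)):
            if intervals[0][0] != 0.0 or intervals[-1][1] != float("inf"):
                raise ValueError(f"{name} intervals must cover [0, inf)")
            for (lo1, hi1), (lo2, _) in zip(intervals[:-1], intervals[1:]):
                if hi1 != lo2 or lo2 <= lo1:
                    raise ValueError(
                        f"{name} intervals must partition [0, inf) with "
                        "strictly increasing bounds"
                    )

    @classmethod
    def from_file(cls, path: str | Path | None = None) -> "GradeThresholds":
        if path is None:
            text = (
                resources.files("mitrasim").joinpath("thresholds.json").read_text()
            )
        else:
            text = Path(path).read_text()
        spec = json.loads(text)
        inf = float("inf")

        def iv(pair: list) -> tuple[float, float]:
            lo, hi = pair
            return (float(lo), inf if hi is None else float(hi))

        rows = sorted(spec["grades"], key=lambda g: g["grade"])
        return cls(
            rvol_ml=tuple(iv(g["rvol_ml"]) for g in rows),
            rf_pct=tuple(iv(g["rf_pct"]) for g in rows),
        )


DEFAULT_THRESHOLDS = GradeThresholds.from_file()


@dataclass(frozen=True)
class MRAssessment:
    """Per-parameter grades and the combined grade (integer or range)."""

    rvol: float
    rf: float
    grade_rvol: int
    grade_rf: int

    @property
    def combined(self) -> int | tuple[int, int]:
        if self.grade_rvol == self.grade_rf:
            return self.grade_rvol
        lo, hi = sorted((self.grade_rvol, self.grade_rf))
        return (lo, hi)

    @property
    def grade_min(self) -> int:
        return min(self.grade_rvol, self.grade_rf)

    @property
    def grade_max(self) -> int:
        return max(self.grade_rvol, self.grade_rf)


def _lookup(value: float, intervals: tuple[tuple[float, float], ...]) -> int:
    v = max(0.0, value)  # negative raw values grade as no regurgitation
    for grade, (lo, hi) in enumerate(intervals):
        if lo <= v < hi:
            return grade
    raise AssertionError("intervals partition [0, inf)")  # pragma: no cover


def grade_from_rvol(
    rvol_ml: float, thresholds: GradeThresholds = DEFAULT_THRESHOLDS
) -> int:
    """Severity grade 0–4 from regurgitant volume alone."""
    return _lookup(rvol_ml, thresholds.rvol_ml)


def grade_from_rf(rf_pct: float, thresholds: GradeThresholds = DEFAULT_THRESHOLDS) -> int:
    """Severity grade 0–4 from regurgitant fraction alone."""
    return _lookup(rf_pct, thresholds.rf_pct)


def assess(
    rvol_ml: float, rf_pct: float, thresholds: GradeThresholds = DEFAULT_THRESHOLDS
) -> MRAssessment:
    """Grade both parameters; disagreements surface as a grade range."""
    return MRAssessment(
        rvol=rvol_ml,
        rf=rf_pct,
        grade_rvol=grade_from_rvol(rvol_ml, thresholds),
        grade_rf=grade_from_rf(rf_pct, thresholds),
    )


def classify_condition(summary: HemoSummary, assessment: MRAssessment) -> str:
    """Classify a run as ``physiological``, ``pathological`` or ``indeterminate``.

    Physiological requires SBP in [90, 120] mmHg, CO in [4.5, 5] l/min and
    MR grade 0 on both parameters.  Any grade above 0 (the lower end of a
    range, for discordant grades) is pathological.  A competent valve that
    misses a hemodynamic bound is neither, and flagged indeterminate.
    """
    if (
        90.0 <= summary.sbp <= 120.0
        and 4.5 <= summary.co <= 5.0
        and assessment.grade_max == 0
    ):
        return "physiological"
    if assessment.grade_min > 0:
        return "pathological"
    return "indeterminate"


def repair_success(before: MRAssessment, after: MRAssessment) -> bool:
    """Whether an intervention lowered the MR grade.

    Conservative over grade ranges: the repaired range must lie entirely
    below the pre-repair range (``after.max < before.min``).
    """
    return after.grade_max < before.grade_min
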