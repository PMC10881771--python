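"""End-to-end evaluation: sensor stream → indices → RVol/RF → grade.

Chains the beat pipeline, the volume-balance regurgitation equations and
the severity grading exactly as the bench protocol applies them, for both
twin-generated and externally recorded streams.
"""

from __future__ import annotations

from dataclasses import dataclass

from .beats import BeatIndices, HemoSummary, analyze_stream
from .config import PRESET_CONDITIONS, RigConfig, preset
from .grading import MRAssessment, assess, classify_condition
from .regurg import RegurgInputs, RegurgResult, assess_regurgitation
from .reporting import ValveRecord, build_valve_record
from .twin import GroundTruth, SensorStream, simulate


@dataclass(frozen=True)
class StreamEvaluation:
    """Everything the pipeline derives from one recording."""

    beats: list[BeatIndices]
    summary: HemoSummary
    regurg: RegurgResult
    assessment: MRAssessment
    condition_class: str


def evaluate_stream(
    stream: SensorStream,
    sv_pump_ml: float,
    cv_ml: float,
    p_atm_mmhg: float = 760.0,
    expected_hr: float | None = None,
    window_s: float | None = 30.0,
) -> StreamEvaluation:
    """Run the full evaluation chain on a sensor stream."""
    beats, summary = analyze_stream(
        stream, p_atm=p_atm_mmhg, expected_hr=expected_hr, window_s=window_s
    )
    regurg = assess_regurgitation(
        RegurgInputs(
            sv_pump=sv_pump_ml,
            cv=cv_ml,
            p_lved_abs=summary.p_lved_abs,
            p_lvms_abs=summary.p_lvms_abs,
            sv_aortic=max(0.0, summary.sv_aortic),
        )
    )
    assessment = assess(regurg.rvol, regurg.rf)
    return StreamEvaluation(
        beats=beats,
        summary=summary,
        regurg=regurg,
        assessment=assessment,
        condition_class=classify_condition(summary, assessment),
    )


def evaluate_config(
    config: RigConfig, window_s: float | None = 30.0
) -> tuple[StreamEvaluation, GroundTruth]:
    """Simulate a configuration and evaluate its stream."""
    stream, truth = simulate(config)
    evaluation = evaluate_stream(
        stream,
        sv_pump_ml=config.sv_pump_ml,
        cv_ml=config.cv_ml,
        p_atm_mmhg=config.p_atm_mmhg,
        expected_hr=config.hr_bpm,
        window_s=window_s,
    )
    return evaluation, truth


def run_preset(
    name: str,
    seed: int = 0,
    duration_s: float = 30.0,
    **overrides,
) -> tuple[ValveRecord, StreamEvaluation, GroundTruth]:
    """Simulate a named valve preset and assemble its per-valve record."""
    config = preset(name, seed=seed, duration_s=duration_s, **overrides)
    evaluation, truth = evaluate_config(config, window_s=duration_s)
    record = build_valve_record(
        evaluation.summary,
        evaluation.regurg,
        evaluation.assessment,
        valve_id=name,
        condition=PRESET_CONDITIONS[name],
        cv_ml=config.cv_ml,
    )
    return record, evaluation, truth
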