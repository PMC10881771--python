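"""Per-beat hemodynamic indices from a pressure/flow sensor stream.

Beats are delimited by systole onset, defined operationally as the
ascending crossing of LV pressure above LA pressure.  Within a beat,
systole runs from the onset to the first sustained return of LV below LA
pressure; the remainder is diastole.  Detection runs on lightly smoothed
signals (short moving average) so that sensor noise near the small
diastolic transmitral gradient cannot split a beat; all reported indices
are computed from the raw samples.

Reported per beat: peak systolic gauge pressure (SBP), mean absolute LV
pressure over systole (P_LVMS), absolute LV pressure at end diastole
(P_LVED, the last sample before onset), net aortic volume by trapezoidal
integration (SV_aortic), and the mean diastolic transmitral gradient.
Window summaries are plain means over complete beats, with cardiac output
``CO = SV_aortic_mean * HR / 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .twin import SensorStream

_SMOOTH_SAMPLES = 5  # detection-only moving average (~33 ms at 150 Hz)

#: A crossing only counts as a systole onset when the smoothed LV-LA
#: difference subsequently exceeds this excursion (mmHg); guards against
#: sensor noise faking a crossing while the diastolic gradient is near zero.
_ONSET_EXCURSION_MMHG = 1.5


class SegmentationError(ValueError):
    """Raised when no complete beat can be delimited."""


@dataclass(frozen=True)
class BeatIndices:
    """Hemodynamic indices of one complete beat."""

    beat_index: int
    sbp: float          # peak systolic gauge pressure, mmHg
    p_lvms_abs: float   # mean absolute LV pressure over systole, mmHg
    p_lved_abs: float   # absolute LV pressure at end diastole, mmHg
    sv_aortic: float    # net aortic volume, ml
    tmg: float          # mean diastolic transmitral gradient, mmHg
    tmg_peak: float     # peak diastolic transmitral gradient, mmHg
    period_s: float


@dataclass(frozen=True)
class HemoSummary:
    """Across-beat means over an analysis window."""

    sbp: float
    p_lvms_abs: float
    p_lved_abs: float
    sv_aortic: float
    tmg: float
    co: float           # cardiac output, l/min
    hr_bpm: float
    n_beats: int
    window_s: float


def _smooth(x: np.ndarray, width: int = _SMOOTH_SAMPLES) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def _onsets(stream: SensorStream, expected_hr: float | None) -> np.ndarray:
    diff = _smooth(stream.p_lv_abs - stream.p_la_abs)
    high = np.flatnonzero(diff > _ONSET_EXCURSION_MMHG)
    if len(high) == 0:
        raise SegmentationError("no beats: LV pressure never rises above LA pressure")
    # Starts of the supra-threshold runs, walked back to the ascending zero
    # crossing that precedes each run (the actual systole onset).
    run_starts = high[np.flatnonzero(np.diff(high, prepend=-2) > 1)]
    onsets = []
    for rs in run_starts:
        i = int(rs)
        while i > 0 and diff[i - 1] > 0.0:
            i -= 1
        onsets.append(i)
    if expected_hr is not None:
        min_gap = 0.7 * (60.0 / expected_hr) * stream.fs_hz
    elif len(onsets) > 2:
        min_gap = 0.7 * float(np.median(np.diff(onsets)))
    else:
        min_gap = 0.0
    kept = [onsets[0]]
    for idx in onsets[1:]:
        if idx - kept[-1] >= min_gap:
            kept.append(idx)
    return np.asarray(kept)


def segment_beats(
    stream: SensorStream, expected_hr: float | None = None
) -> list[tuple[int, int]]:
    """Delimit complete beats as ``(start, end)`` sample-index windows.

    Systole onsets are ascending crossings of (smoothed) P_LV above P_LA
    followed by a sustained systolic excursion; consecutive onsets closer
    than 0.7 expected periods are merged.  The leading partial beat before
    the first onset and the trailing partial beat after the last onset are
    discarded; when ``expected_hr`` is given and a full expected period of
    samples follows the final onset, that final beat is kept.
    """
    onsets = _onsets(stream, expected_hr)
    windows = [(int(a), int(b)) for a, b in zip(onsets[:-1], onsets[1:])]
    if expected_hr is not None:
        tail_end = int(onsets[-1]) + int(round(stream.fs_hz * 60.0 / expected_hr))
        if tail_end < len(stream):
            windows.append((int(onsets[-1]), tail_end))
    if not windows:
        raise SegmentationError(
            "fewer than one complete beat in the stream "
            f"({len(onsets)} onset(s) found)"
        )
    return windows


def beat_indices(
    stream: SensorStream,
    window: tuple[int, int],
    p_atm: float = 760.0,
    beat_index: int = 0,
) -> BeatIndices:
    """Compute the per-beat indices over one segmented window."""
    start, end = window
    if not 0 <= start < end <= len(stream):
        raise ValueError(f"invalid beat window {window}")
    p_lv = stream.p_lv_abs
    p_la = stream.p_la_abs
    diff = _smooth(p_lv - p_la)

    below = np.flatnonzero(diff[start:end] <= 0.0)
    end_sys = start + int(below[0]) if len(below) else end
    if end_sys == start:
        raise ValueError("empty systole in beat window")
    if end_sys == end:
        raise ValueError("empty diastole in beat window")

    sys_slice = slice(start, end_sys)
    dia_slice = slice(end_sys, end)

    gradient = p_la[dia_slice] - p_lv[dia_slice]
    gradient = gradient[gradient > 0.0]
    if len(gradient) == 0:
        raise ValueError("no diastolic samples with LA above LV pressure")

    dt = 1.0 / stream.fs_hz
    stop = min(end + 1, len(stream))  # include shared boundary sample
    return BeatIndices(
        beat_index=beat_index,
        sbp=float(p_lv[sys_slice].max() - p_atm),
        p_lvms_abs=float(p_lv[sys_slice].mean()),
        p_lved_abs=float(p_lv[start - 1] if start > 0 else p_lv[start]),
        sv_aortic=float(np.trapezoid(stream.q_aortic[start:stop], dx=dt)),
        tmg=float(gradient.mean()),
        tmg_peak=float(gradient.max()),
        period_s=(end - start) * dt,
    )


def cardiac_output(sv_aortic_mean_ml: float, hr_bpm: float) -> float:
    """Cardiac output in l/min from mean aortic stroke volume and rate."""
    if sv_aortic_mean_ml < 0 or hr_bpm < 0:
        raise ValueError("stroke volume and heart rate must be non-negative")
    return sv_aortic_mean_ml * hr_bpm / 1000.0


def summarize_window(beats: list[BeatIndices], window_s: float) -> HemoSummary:
    """Arithmetic means of the per-beat indices over an analysis window."""
    if not beats:
        raise ValueError("cannot summarize an empty beat list")
    total_time = sum(b.period_s for b in beats)
    hr = 60.0 * len(beats) / total_time
    sv = float(np.mean([b.sv_aortic for b in beats]))
    return HemoSummary(
        sbp=float(np.mean([b.sbp for b in beats])),
        p_lvms_abs=float(np.mean([b.p_lvms_abs for b in beats])),
        p_lved_abs=float(np.mean([b.p_lved_abs for b in beats])),
        sv_aortic=sv,
        tmg=float(np.mean([b.tmg for b in beats])),
        co=cardiac_output(sv, hr),
        hr_bpm=hr,
        n_beats=len(beats),
        window_s=window_s,
    )


def analyze_stream(
    stream: SensorStream,
    p_atm: float = 760.0,
    expected_hr: float | None = None,
    window_s: float | None = None,
) -> tuple[list[BeatIndices], HemoSummary]:
    """Segment, index and summarize a stream over its analysis window.

    ``window_s`` truncates the stream (complete beats whose onset falls
    inside the window); by default the whole stream is used.
    """
    windows = segment_beats(stream, expected_hr)
    if window_s is not None:
        limit = int(window_s * stream.fs_hz)
        windows = [w for w in windows if w[0] < limit] or windows[:1]
    beats = [
        beat_indices(stream, w, p_atm=p_atm, beat_index=i)
        for i, w in enumerate(windows)
    ]
    span = window_s if window_s is not None else len(stream) / stream.fs_hz
    return beats, summarize_window(beats, span)


def measure_sbp(
    stream: SensorStream, p_atm: float = 760.0, expected_hr: float | None = None
) -> float:
    """Mean per-beat systolic gauge pressure of a stream (calibration probe)."""
    _, summary = analyze_stream(stream, p_atm=p_atm, expected_hr=expected_hr)
    return summary.sbp
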