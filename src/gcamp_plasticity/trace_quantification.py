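"""Trace-level measurements: ΔF/F₀, T₅₀, response detection, transient
counting, percent change, positivity calls, conduction velocity.

ΔF/F₀ follows the standard definition: F₀ is the mean
background-subtracted fluorescence over a baseline window preceding the
stimulus, F the background-subtracted peak in the response window, and
ΔF/F₀ [%] = 100·(F − F₀)/F₀.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .imaging_io import (
    FluorescenceTrace,
    ImageStack,
    ROI,
    StimulusProtocol,
    control_for,
    estimate_background,
    extract_trace,
)

log = logging.getLogger(__name__)


class DegenerateBaselineError(ValueError):
    """Baseline fluorescence non-positive; cell must be excluded."""


class ZeroBaselineResponseError(ValueError):
    """Percent change undefined for a zero baseline response."""


@dataclass(frozen=True)
class QuantConfig:
    """Quantification knobs.

    ``baseline_window_s`` seconds of trace immediately before stimulus
    onset define F₀; the response window runs from onset to offset plus
    ``response_extra_s``.  ``k_sd`` scales the baseline-noise detection
    threshold and ``min_peak_dff_pct`` is an absolute ΔF/F₀ floor below
    which a peak is never called a response (guards against
    max-statistics false positives over long windows).
    ``normalization`` selects the adjacent-ROI dialect (``subtract`` or
    ``ratio``).  ``smooth_boxcar`` (frames) optionally smooths noisy
    real data before peak picking; 0 disables it.
    """

    baseline_window_s: float = 2.0
    response_extra_s: float = 2.0
    k_sd: float = 3.0
    min_peak_dff_pct: float = 5.0
    normalization: str = "subtract"
    smooth_boxcar: int = 0
    prominence_fraction: float = 0.1


DEFAULT_QUANT = QuantConfig()


@dataclass(frozen=True)
class ResponseMeasure:
    """One stimulus-evoked response for one ROI."""

    peak_dff_pct: float
    peak_time_s: float
    baseline_sd_dff: float
    t50_s: float | None = None
    responded: bool = False
    contaminated: bool = False


# ---------------------------------------------------------------------------
# core measures


def _window_slice(times: np.ndarray, start: float, stop: float) -> np.ndarray:
    idx = np.nonzero((times >= start) & (times < stop))[0]
    return idx


def _smoothed(values: np.ndarray, boxcar: int) -> np.ndarray:
    if boxcar and boxcar > 1:
        kernel = np.ones(boxcar) / boxcar
        return np.convolve(values, kernel, mode="same")
    return values


def compute_dff(trace: FluorescenceTrace,
                baseline_window: tuple[float, float],
                response_window: tuple[float, float],
                config: QuantConfig = DEFAULT_QUANT) -> ResponseMeasure:
    """Peak ΔF/F₀ (%) of a trace for one stimulus.

    Raises :class:`DegenerateBaselineError` when F₀ ≤ 0 — such cells are
    excluded from analysis and logged by callers.
    """
    if baseline_window[1] > response_window[0]:
        raise ValueError("baseline window must precede response window")
    times = trace.times()
    values = _smoothed(trace.values - trace.background, config.smooth_boxcar)
    b = _window_slice(times, *baseline_window)
    r = _window_slice(times, *response_window)
    if len(b) == 0 or len(r) == 0:
        raise ValueError("analysis windows fall outside the trace")
    f0 = float(values[b].mean())
    if f0 <= 0:
        raise DegenerateBaselineError(
            f"baseline fluorescence {f0:.3g} is non-positive")
    peak_idx = r[np.argmax(values[r])]
    peak = float(values[peak_idx])
    peak_dff = 100.0 * (peak - f0) / f0
    baseline_sd = float(np.std(100.0 * (values[b] - f0) / f0))
    return ResponseMeasure(peak_dff_pct=peak_dff,
                           peak_time_s=float(times[peak_idx]),
                           baseline_sd_dff=baseline_sd)


def compute_t50(trace: FluorescenceTrace, peak_time_s: float,
                baseline_f: float,
                window_end_s: float | None = None) -> float | None:
    """Decay time from the peak to 50% of peak-minus-baseline amplitude.

    Linearly interpolated between frames; ``None`` when the trace never
    recrosses the half-amplitude level inside the window (cells that do
    not return toward baseline are flagged rather than assigned a T₅₀).
    """
    times = trace.times()
    values = trace.values - trace.background
    if window_end_s is None:
        window_end_s = float(times[-1]) + trace.frame_interval_s
    after = np.nonzero((times >= peak_time_s) & (times < window_end_s))[0]
    if len(after) == 0:
        return None
    peak_val = float(values[after[0]])
    half = baseline_f + 0.5 * (peak_val - baseline_f)
    if peak_val <= baseline_f:
        return None
    below = np.nonzero(values[after] <= half)[0]
    if len(below) == 0:
        return None
    j = after[below[0]]
    if j == after[0]:
        return 0.0
    v1, v2 = values[j - 1], values[j]
    t1, t2 = times[j - 1], times[j]
    t_cross = t1 + (v1 - half) / (v1 - v2) * (t2 - t1) if v1 != v2 else t2
    return float(t_cross - peak_time_s)


def adjacent_normalize(cell_measure: ResponseMeasure,
                       control_measure: ResponseMeasure | None,
                       config: QuantConfig = DEFAULT_QUANT
                       ) -> ResponseMeasure:
    """Correct a cell's ΔF/F₀ for out-of-focus contamination.

    Default dialect subtracts the adjacent-control ΔF/F₀ (scattered
    light adds to the measured signal); ``ratio`` divides the relative
    fluorescence changes instead.  A contamination flag marks cases
    where the control itself crosses the detection threshold.  Missing
    controls leave the cell uncorrected with a warning.
    """
    if control_measure is None:
        log.warning("no adjacent control; cell processed uncorrected")
        return cell_measure
    if config.normalization == "subtract":
        corrected = cell_measure.peak_dff_pct - control_measure.peak_dff_pct
    elif config.normalization == "ratio":
        corrected = 100.0 * ((1 + cell_measure.peak_dff_pct / 100.0)
                             / (1 + control_measure.peak_dff_pct / 100.0) - 1)
    else:
        raise ValueError(f"unknown dialect {config.normalization!r}")
    contaminated = detect_response(control_measure, config.k_sd,
                                   config.min_peak_dff_pct)
    return replace(cell_measure, peak_dff_pct=float(corrected),
                   contaminated=contaminated)


def detect_response(measure: ResponseMeasure, k_sd: float = 3.0,
                    min_peak_dff_pct: float = 5.0) -> bool:
    """Did the ROI respond?  Peak ΔF/F₀ must exceed ``k_sd`` baseline
    SDs and the absolute floor.  Negative corrected peaks never count."""
    threshold = max(k_sd * measure.baseline_sd_dff, min_peak_dff_pct)
    return bool(measure.peak_dff_pct > threshold)


def count_transients(trace: FluorescenceTrace,
                     pulse_times: Sequence[float],
                     config: QuantConfig = DEFAULT_QUANT) -> int:
    """Number of stimulus pulses resolved as distinct transients.

    A transient is a local maximum of the ΔF/F₀ trace with prominence of
    at least ``prominence_fraction`` of the trace's peak amplitude,
    phase-locked to a pulse (the maximum falls within half an
    inter-pulse interval, plus one frame, after the pulse).  The train
    is *resolved* when the count equals the pulse count; summation at
    high rates erases the per-spike maxima and the count drops.
    """
    pulses = np.sort(np.asarray(pulse_times, dtype=float))
    if len(pulses) == 0:
        return 0
    times = trace.times()
    values = trace.values - trace.background
    pre = values[times < pulses[0]]
    f0 = float(pre.mean()) if len(pre) else float(values[0])
    if f0 <= 0:
        raise DegenerateBaselineError("non-positive baseline")
    dff = (values - f0) / f0
    amplitude = float(dff.max())
    if amplitude <= 0:
        return 0
    prominence = config.prominence_fraction * amplitude
    peaks, _ = find_peaks(dff, prominence=prominence)
    if len(pulses) > 1:
        isis = np.diff(pulses)
        windows = np.concatenate([isis / 2, [isis[-1] / 2]])
    else:
        windows = np.array([times[-1] - pulses[0]])
    count = 0
    used: set[int] = set()
    for pulse, w in zip(pulses, windows):
        hi = pulse + w + trace.frame_interval_s
        for i, p in enumerate(peaks):
            if i in used:
                continue
            if pulse < times[p] <= hi:
                count += 1
                used.add(i)
                break
    return count


def percent_change(resp_later: float, resp_base: float) -> float:
    """Signed fractional change of a response between two sessions."""
    if resp_base <= 0:
        raise ZeroBaselineResponseError(
            "baseline response is zero; cell belongs to the de-novo/"
            "silent-afferent path, not percent change")
    return (resp_later - resp_base) / resp_base


def classify_gcamp_positive(signal: float, bg_mean: float,
                            bg_sd: float, k_sd: float = 5.0) -> bool:
    """Immunofluorescence positivity: signal above bg_mean + 5·bg_sd."""
    if bg_sd < 0:
        raise ValueError("background SD must be non-negative")
    return bool(signal > bg_mean + k_sd * bg_sd)


def conduction_velocity(distance_m: float, latency_s: float) -> float:
    """Axonal conduction velocity (m/s) from electrode distance and
    spike latency."""
    if distance_m <= 0 or latency_s <= 0:
        raise ValueError("distance and latency must be positive")
    return distance_m / latency_s


# ---------------------------------------------------------------------------
# per-session quantification


def event_windows(event, config: QuantConfig = DEFAULT_QUANT
                  ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Baseline and response windows for one stimulus event."""
    baseline = (max(event.onset_s - config.baseline_window_s, 0.0),
                event.onset_s)
    response = (event.onset_s, event.offset_s + config.response_extra_s)
    return baseline, response


def _event_param(event) -> float:
    if event.kind == "mechanical":
        return float(event.params["force_mN"])
    if event.kind == "electrical_train":
        return float(event.params["frequency_Hz"])
    return float("nan")


def quantify_traces(traces: Mapping[str, FluorescenceTrace],
                    protocol: StimulusProtocol,
                    config: QuantConfig = DEFAULT_QUANT,
                    controls: Mapping[str, FluorescenceTrace] | None = None,
                    ) -> pd.DataFrame:
    """Quantify every (cell, stimulus) pair of one session.

    Returns the tidy result table; cells with a degenerate baseline are
    excluded and logged.  When ``controls`` maps cell ids to
    adjacent-control traces, each measure is contamination-corrected
    before detection.
    """
    rows = []
    for cell_id, trace in traces.items():
        for idx, event in enumerate(protocol.events):
            bwin, rwin = event_windows(event, config)
            try:
                measure = compute_dff(trace, bwin, rwin, config)
            except DegenerateBaselineError as exc:
                log.warning("excluding %s event %d: %s", cell_id, idx, exc)
                continue
            if controls is not None and cell_id in controls:
                ctrl = compute_dff(controls[cell_id], bwin, rwin, config)
                measure = adjacent_normalize(measure, ctrl, config)
            responded = detect_response(measure, config.k_sd,
                                        config.min_peak_dff_pct)
            t50 = None
            if responded:
                f0 = (trace.values - trace.background)[
                    _window_slice(trace.times(), *bwin)].mean()
                t50 = compute_t50(trace, measure.peak_time_s, float(f0),
                                  window_end_s=rwin[1])
            rows.append({
                "cell_id": cell_id, "session": protocol.session_label,
                "event_index": idx, "kind": event.kind,
                "param": _event_param(event),
                "peak_dff_pct": measure.peak_dff_pct,
                "t50_s": t50 if t50 is not None else np.nan,
                "responded": responded,
                "baseline_sd_dff": measure.baseline_sd_dff,
                "contaminated": measure.contaminated,
            })
    return pd.DataFrame(rows)


def quantify_stack(stack: ImageStack, rois: Sequence[ROI],
                   protocol: StimulusProtocol,
                   config: QuantConfig = DEFAULT_QUANT,
                   background: float | None = None) -> pd.DataFrame:
    """Extract per-ROI traces from a movie and quantify the session."""
    if background is None:
        background = estimate_background(stack)
    cells = {r.id: r for r in rois if r.role == "cell"}
    traces = {cid: extract_trace(stack, roi, background)
              for cid, roi in cells.items()}
    controls = {}
    for cid in cells:
        ctrl_roi = control_for(rois, cid)
        if ctrl_roi is not None:
            controls[cid] = extract_trace(stack, ctrl_roi, background)
    return quantify_traces(traces, protocol, config,
                           controls=controls or None)
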