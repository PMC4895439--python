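"""Step detection and event extraction from force-spectroscopy traces.

The detector fits a piecewise-constant level sequence to the extension
channel of a clamp (or ramp) trace and reports every level increment of at
least ``min_step`` nm preceded by a dwell of at least ``min_dwell`` s:

1. median pre-filter (half-width 5 samples) to suppress impulsive noise;
2. binary-segmentation change-point search on the filtered signal with a
   BIC-style penalty scaled by a robust noise estimate (median absolute
   first difference of the raw signal);
3. segment levels taken as per-segment medians of the raw signal; adjacent
   levels closer than ``min_step`` and segments shorter than ``min_dwell``
   are merged.

The 2 nm default floor reflects the smallest unfolding lengths resolvable in
the experiments the simulator emulates.  On noiseless staircases the
procedure is exact.  First-passage times (pulse start to the final step) are
measured per trace; traces that never reach the expected total extension are
flagged censored and excluded from mean-first-passage-time averages but kept
for step statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from ._changepoint import binary_segmentation
from .trace import EventTable, StepEvent, Trace

__all__ = [
    "DetectorParams",
    "detect_steps",
    "first_passage_time",
    "summarize",
]


@dataclass(frozen=True)
class DetectorParams:
    """Tunable parameters of the step detector.

    ``min_dwell`` defaults to two sample intervals (the spec floor of what a
    sampled trace can resolve); analyses of feedback-limited instruments
    typically raise it to the feedback response time (~50 ms).
    """

    min_step: float = 2.0  # nm, smallest reported step
    min_dwell: float | None = None  # s; None -> 2 / sampling_rate
    penalty: float = 3.0  # multiplies sigma^2 * log(n) in the split test
    median_halfwidth: int = 5  # samples, pre-filter half-width
    completion_tol: float = 2.5  # nm, slack when testing total-length completion

    def resolved(self, sampling_rate: float) -> "DetectorParams":
        md = self.min_dwell if self.min_dwell is not None else 2.0 / sampling_rate
        if md < 1.0 / sampling_rate:
            raise ValueError("min_dwell must be at least one sample interval")
        if self.min_step <= 0:
            raise ValueError("min_step must be positive")
        return replace(self, min_dwell=md)


def _analysis_window(trace: Trace) -> slice:
    """Samples belonging to the analysed pulse (before any fingerprint jump)."""
    if trace.protocol == "clamp":
        assert trace.setpoint is not None
        band = max(2.0, 0.1 * trace.setpoint)
        inside = np.abs(trace.force - trace.setpoint) <= band
        idx = np.flatnonzero(inside)
        if idx.size == 0:
            return slice(0, 0)
        start = idx[0]
        # first departure from the band after the pulse begins ends the window
        departures = np.flatnonzero(~inside[start:])
        stop = start + (departures[0] if departures.size else inside.size - start)
        return slice(int(start), int(stop))
    if trace.protocol == "ramp":
        cap = float(trace.meta.get("force_cap", 300.0))
        below = np.flatnonzero(trace.force >= cap - 1e-9)
        stop = int(below[0]) if below.size else trace.n_samples
        return slice(0, max(stop, 2))
    raise ValueError(
        f"detect_steps supports clamp and ramp traces, got {trace.protocol!r} "
        "(use split_cycles first for cycles traces)"
    )


def _merge_segments(
    y: np.ndarray,
    boundaries: list[int],
    min_samples: int,
    min_step: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge small/indistinct segments; return (boundary indices, levels)."""
    edges = [0] + list(boundaries) + [y.size]
    segs = [[edges[i], edges[i + 1]] for i in range(len(edges) - 1)]

    def level(seg):
        return float(np.median(y[seg[0] : seg[1]]))

    levels = [level(s) for s in segs]

    changed = True
    while changed and len(segs) > 1:
        changed = False
        # 1) absorb interior segments shorter than the dwell floor into the
        #    closer neighbour; the first and last segments are kept even when
        #    short -- they anchor the pulse-start baseline and the final
        #    level, and dropping them would corrupt every step length
        for i, seg in enumerate(segs):
            if i in (0, len(segs) - 1):
                continue
            if seg[1] - seg[0] < min_samples and len(segs) > 1:
                if i == 0:
                    j = 1
                elif i == len(segs) - 1:
                    j = i - 1
                else:
                    j = i - 1 if abs(levels[i - 1] - levels[i]) <= abs(
                        levels[i + 1] - levels[i]
                    ) else i + 1
                a, b = min(i, j), max(i, j)
                segs[a] = [segs[a][0], segs[b][1]]
                del segs[b]
                levels[a] = level(segs[a])
                del levels[b]
                changed = True
                break
        if changed:
            continue
        # 2) merge adjacent segments whose levels are not min_step apart
        for i in range(len(segs) - 1):
            if abs(levels[i + 1] - levels[i]) < min_step:
                segs[i] = [segs[i][0], segs[i + 1][1]]
                del segs[i + 1]
                levels[i] = level(segs[i])
                del levels[i + 1]
                changed = True
                break
    bounds = np.array([s[0] for s in segs[1:]], dtype=int)
    return bounds, np.array(levels, dtype=float)


def fit_levels(
    trace: Trace, params: DetectorParams | None = None
) -> tuple[np.ndarray, np.ndarray, slice]:
    """Piecewise-constant fit of the analysis window.

    Returns (boundary sample indices relative to the window, level values nm,
    window slice).  Exposed for diagnostics; :func:`detect_steps` is the
    user-facing entry point.
    """
    params = (params or DetectorParams()).resolved(trace.sampling_rate)
    window = _analysis_window(trace)
    y = trace.extension[window]
    n = y.size
    if n < 2:
        warnings.warn(f"{trace.trace_id}: empty analysis window", stacklevel=2)
        return np.array([], dtype=int), np.array([np.nan]), window

    width = 2 * params.median_halfwidth + 1
    yf = median_filter(y, size=min(width, n), mode="nearest") if n > 2 else y

    diffs = np.abs(np.diff(y))
    sigma = np.median(diffs) / (np.sqrt(2.0) * 0.6745) if diffs.size else 0.0
    scale = max(float(y.max() - y.min()), 1.0)
    pen = params.penalty * max(sigma, 1e-7 * scale) ** 2 * np.log(n)

    min_samples = max(2, int(round(params.min_dwell * trace.sampling_rate)))
    boundaries = binary_segmentation(yf, penalty=pen, min_size=2)
    bounds, levels = _merge_segments(y, boundaries, min_samples, params.min_step)
    return bounds, levels, window


def detect_steps(trace: Trace, params: DetectorParams | None = None) -> list[StepEvent]:
    """Detect unfolding steps in a clamp or ramp trace.

    Returns the detected steps in time order.  Step length is the level
    increment (nm); ``dwell_before`` is the time spent at the preceding level
    (measured from the pulse start for the first step); ``force_at_step`` is
    read off the force channel at the step sample.
    """
    bounds, levels, window = fit_levels(trace, params)
    if bounds.size == 0:
        return []
    t = trace.time[window]
    f = trace.force[window]
    t0 = t[0]
    events: list[StepEvent] = []
    cumulative = 0.0
    prev_t = t0
    idx = 0
    for k, b in enumerate(bounds):
        step = float(levels[k + 1] - levels[k])
        t_step = float(t[b])
        if step <= 0:
            # residual negative increments can survive merging on drifting
            # ramp baselines; they are not unfolding steps
            prev_t = t_step
            continue
        cumulative += step
        events.append(
            StepEvent(
                trace_id=trace.trace_id,
                step_index=idx,
                step_length=step,
                cumulative_length=cumulative,
                dwell_before=t_step - prev_t,
                force_at_step=float(f[b]),
                t_step=t_step,
            )
        )
        prev_t = t_step
        idx += 1
    return events


def first_passage_time(
    trace: Trace,
    events: Sequence[StepEvent],
    expected_total: float | None = None,
    completion_tol: float = 2.5,
) -> tuple[float, bool]:
    """First-passage time to complete unfolding and a censoring flag.

    The first-passage time is measured from the pulse start to the last
    detected step.  When ``expected_total`` (nm) is given the trace counts as
    complete only if the summed step lengths reach it within
    ``completion_tol``; otherwise any trace with at least one step is taken
    as complete.  Censored traces return (nan, True).
    """
    window = _analysis_window(trace)
    if not events:
        return float("nan"), True
    total = events[-1].cumulative_length
    if expected_total is not None and total < expected_total - completion_tol:
        return float("nan"), True
    t0 = float(trace.time[window][0])
    return float(events[-1].t_step - t0), False


def summarize(
    traces: Iterable[Trace],
    params: DetectorParams | None = None,
    expected_total: float | dict | None = None,
) -> EventTable:
    """Detect steps in a homogeneous batch and build the event table.

    ``expected_total`` may be a scalar (nm), or a mapping from force
    condition to nm, used for censoring complete-unfolding first-passage
    times.  The batch must share one protocol.
    """
    traces = list(traces)
    params = params or DetectorParams()
    if not traces:
        return EventTable(
            events=pd.DataFrame(), traces=pd.DataFrame(columns=["trace_id"])
        )
    protocols = {t.protocol for t in traces}
    if len(protocols) > 1:
        raise ValueError(f"mixed protocols in batch: {sorted(protocols)}")

    all_events: list[StepEvent] = []
    rows = []
    for trace in traces:
        events = detect_steps(trace, params)
        cond = trace.setpoint if trace.protocol == "clamp" else trace.ramp_rate
        if isinstance(expected_total, dict):
            exp = expected_total.get(cond)
        else:
            exp = expected_total
        fpt, censored = first_passage_time(
            trace, events, expected_total=exp, completion_tol=params.completion_tol
        )
        all_events.extend(events)
        rows.append(
            {
                "trace_id": trace.trace_id,
                "protocol": trace.protocol,
                "force_condition": cond,
                "n_steps": len(events),
                "n_intermediates": max(len(events) - 1, 0),
                "total_length": events[-1].cumulative_length if events else 0.0,
                "first_passage_time": fpt,
                "censored": censored,
            }
        )
    return EventTable.from_events(all_events, pd.DataFrame(rows))
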