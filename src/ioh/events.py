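"""Hypotension events and burden metrics on the 1 Hz MAP series.

An event is a maximal run of consecutive valid seconds with MAP strictly
below threshold (default 65 mmHg) lasting at least one minute. Burden is
summarized by the area under threshold (AUT, mmHg*min, accumulated over ALL
sub-threshold seconds including sub-minute transients) and its time-weighted
average (TWA = AUT / valid minutes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    HYPOTENSION_THRESHOLD_MMHG,
    HypotensionEvent,
    MAPSeries,
    MIN_EVENT_DURATION_S,
)


def detect_events(map_series: MAPSeries,
                  threshold: float = HYPOTENSION_THRESHOLD_MMHG,
                  min_duration_s: float = MIN_EVENT_DURATION_S,
                  merge_gap_s: float = 0.0) -> list[HypotensionEvent]:
    """Find sustained sub-threshold events.

    Runs are broken by invalid seconds (hypotension is never asserted across
    missing data) and by any valid second at or above threshold. Runs at
    least ``min_duration_s`` long become events; ``merge_gap_s`` optionally
    merges runs separated by short gaps before the duration test (default 0,
    no merging).
    """
    values = map_series.values
    below = (values < threshold) & map_series.valid_mask
    edges = np.flatnonzero(np.diff(np.concatenate([[0], below.view(np.int8), [0]])))
    runs = list(zip(edges[::2], edges[1::2]))        # half-open [start, stop)

    if merge_gap_s > 0 and len(runs) > 1:
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            if s - merged[-1][1] <= merge_gap_s:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        runs = [tuple(r) for r in merged]

    t0 = map_series.start_time_s
    out = []
    for s, e in runs:
        if e - s >= min_duration_s:
            seg = values[s:e]
            seg = seg[np.isfinite(seg)]
            aut = float(np.sum(np.maximum(0.0, threshold - seg)) / 60.0)
            out.append(HypotensionEvent(onset_s=t0 + float(s), offset_s=t0 + float(e),
                                        nadir_mmHg=float(np.nanmin(values[s:e])),
                                        aut_contribution=aut))
    return out


@dataclass
class SeveritySummary:
    """Per-patient hypotension burden (Table-1-style statistics)."""

    n_events: int
    total_hypotension_min: float
    mean_event_duration_min: float
    time_fraction_below65: float     # percent of valid time
    aut_mmHg_min: float
    twa_mmHg: float
    mean_map_mmHg: float
    valid_duration_min: float


def severity_summary(map_series: MAPSeries, events: list[HypotensionEvent],
                     threshold: float = HYPOTENSION_THRESHOLD_MMHG) -> SeveritySummary:
    """Burden metrics over the valid part of the series.

    AUT integrates depth below threshold over every valid sub-threshold
    second (events and transients alike); TWA divides by total valid
    minutes; the time fraction is a percentage of valid seconds.
    """
    valid = map_series.valid_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("empty series: no valid seconds")
    v = map_series.values[valid]
    aut = float(np.sum(np.maximum(0.0, threshold - v)) / 60.0)
    valid_min = n_valid / 60.0
    durations_min = [e.duration_s / 60.0 for e in events]
    return SeveritySummary(
        n_events=len(events),
        total_hypotension_min=float(sum(durations_min)),
        mean_event_duration_min=float(np.mean(durations_min)) if durations_min else 0.0,
        time_fraction_below65=float(np.mean(v < threshold) * 100.0),
        aut_mmHg_min=aut,
        twa_mmHg=aut / valid_min,
        mean_map_mmHg=float(v.mean()),
        valid_duration_min=valid_min,
    )


def event_map_distribution(datapoints, map_series_by_patient: dict,
                           gray_zone: tuple = (65.0, 75.0),
                           observation_offset_s: float = 80.0):
    """Per-item 1-minute mean MAP with class labels, plus the Gray-Zone share.

    Positives average the first 60 s of their matched event; negatives
    average the first 60 s of the prediction window (the minute starting at
    t_now + observation window). Items whose averaging minute contains
    masked seconds are dropped and counted.

    Returns ``(rows, gray_zone_fraction, n_dropped)`` where each row is
    ``(patient_id, label, mean_map_mmHg, in_gray_zone)``.
    """
    rows = []
    n_dropped = 0
    for pt in datapoints:
        if pt.label not in ("positive", "negative"):
            continue
        series = map_series_by_patient[pt.patient_id]
        if pt.label == "positive":
            start = pt.matched_event_onset_s
        else:
            start = pt.t_now_s + observation_offset_s
        a = int(round(start - series.start_time_s))
        b = a + 60
        if a < 0 or b > len(series) or not series.valid_mask[a:b].all():
            n_dropped += 1
            continue
        m = float(series.values[a:b].mean())
        rows.append((pt.patient_id, pt.label, m,
                     gray_zone[0] <= m <= gray_zone[1]))
    neg = [r for r in rows if r[1] == "negative"]
    gz = (sum(r[3] for r in neg) / len(neg)) if neg else float("nan")
    return rows, gz, n_dropped
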