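"""Poisson-process sliding-window framing, labeling and dataset assembly.

Candidate times ``t_now`` advance by clipped exponential steps. Each anchors
three consecutive windows: an 80 s observation window (whose final 20 s are
the model input), a 300 s prediction window, and a 60 s slack window.
A point is positive when a hypotension-event onset falls in the prediction
window, negative when no event touches any of the three windows, and is
skipped when an event is already active during observation, when an onset
falls in the slack window, or when signal quality in the extraction zone is
insufficient.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .types import (
    ABPWaveform,
    BeatRecord,
    CANONICAL_FS,
    HypotensionEvent,
    MAPSeries,
    PreprocessedPatient,
)

SKIP_EVENT_IN_OBSERVATION = "event_in_observation"
SKIP_EVENT_IN_SLACK = "event_in_slack"
SKIP_POOR_QUALITY = "poor_quality"
LABELS = ("positive", "negative")


@dataclass
class WindowConfig:
    """Window geometry and sampling-rate parameters (seconds).

    ``mean_interval_s`` is the mean of the exponential inter-sample step
    (rate 1/3 per minute); steps are clipped to [floor, cap] with the cap at
    3 minutes.
    """

    observation_s: float = 80.0
    extraction_s: float = 20.0
    prediction_s: float = 300.0
    slack_s: float = 60.0
    mean_interval_s: float = 180.0
    interval_cap_s: float = 180.0
    interval_floor_s: float = 0.0
    min_zone_coverage: float = 0.95    # valid-beat coverage of the extraction zone

    def __post_init__(self) -> None:
        if self.extraction_s > self.observation_s:
            raise ValueError("extraction zone must fit inside observation window")
        if self.interval_floor_s > self.interval_cap_s:
            raise ValueError("interval floor must not exceed cap")

    @property
    def frame_s(self) -> float:
        """Total frame span: observation + prediction + slack."""
        return self.observation_s + self.prediction_s + self.slack_s

    @property
    def segment_samples(self) -> int:
        return int(round(self.extraction_s * CANONICAL_FS))


@dataclass
class LabeledDataPoint:
    """One candidate time with its label (or skip reason) and input segment."""

    patient_id: str
    t_now_s: float
    label: str                                  # positive/negative or a skip reason
    segment: np.ndarray | None = None           # 2500 samples, 20 s at 125 Hz
    segment_mean_map_mmHg: float = np.nan
    matched_event_onset_s: float | None = None


@dataclass
class LabeledDataset:
    """Labeled points plus provenance; skipped candidates are tallied only."""

    points: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.by_patient: dict[str, list] = {}
        for p in self.points:
            self.by_patient.setdefault(p.patient_id, []).append(p)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.by_patient)

    def labels(self) -> np.ndarray:
        return np.asarray([1 if p.label == "positive" else 0 for p in self.points])

    def segment_means(self) -> np.ndarray:
        return np.asarray([p.segment_mean_map_mmHg for p in self.points])

    def subset(self, patient_ids) -> "LabeledDataset":
        keep = set(patient_ids)
        return LabeledDataset(points=[p for p in self.points if p.patient_id in keep],
                              provenance=dict(self.provenance))

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.points:
            h.update(f"{p.patient_id}|{p.t_now_s:.6f}|{p.label}|"
                     f"{p.segment_mean_map_mmHg:.9f}".encode())
            if p.segment is not None:
                h.update(np.ascontiguousarray(p.segment).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Candidate times
# ---------------------------------------------------------------------------

def draw_time_points(record_duration_s: float, config: WindowConfig,
                     seed: int) -> np.ndarray:
    """Clipped-exponential renewal times; every frame fits inside the record."""
    rng = np.random.default_rng(seed)
    limit = record_duration_s - config.frame_s
    times = []
    t = 0.0
    while True:
        step = float(np.clip(rng.exponential(config.mean_interval_s),
                             config.interval_floor_s, config.interval_cap_s))
        t += step
        if t > limit:
            break
        times.append(t)
    return np.asarray(times)


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

def frame_and_label(t_now_s: float, events: list[HypotensionEvent],
                    config: WindowConfig | None = None) -> tuple[str, float | None]:
    """Label one candidate time against ordered disjoint events.

    Decision order: (1) any event interval intersecting the observation
    window -> skip; (2) earliest event onset inside the prediction window
    -> positive; (3) any onset inside the slack window -> skip; (4) negative.
    Intervals are half-open. Returns ``(label_or_skip, matched_onset)``.
    """
    config = config or WindowConfig()
    obs_end = t_now_s + config.observation_s
    pred_end = obs_end + config.prediction_s
    slack_end = pred_end + config.slack_s
    for ev in events:
        if ev.onset_s < obs_end and ev.offset_s > t_now_s:
            return SKIP_EVENT_IN_OBSERVATION, None
    for ev in events:
        if obs_end <= ev.onset_s < pred_end:
            return "positive", ev.onset_s
    for ev in events:
        if pred_end <= ev.onset_s < slack_end:
            return SKIP_EVENT_IN_SLACK, None
    return "negative", None


# ---------------------------------------------------------------------------
# Segment extraction
# ---------------------------------------------------------------------------

def extract_segment(waveform: ABPWaveform, beats: list[BeatRecord],
                    t_now_s: float, config: WindowConfig | None = None):
    """Extract the 20 s input segment ending the observation window.

    The zone is ``[t_now + 60, t_now + 80)``. Returns
    ``(segment, segment_mean_map)`` where the mean is over valid per-beat
    MAPs of beats overlapping the zone, or the string ``poor_quality`` when
    the zone extends beyond the record or less than ``min_zone_coverage`` of
    it is covered by valid beats.
    """
    config = config or WindowConfig()
    z0 = t_now_s + (config.observation_s - config.extraction_s)
    z1 = t_now_s + config.observation_s
    fs = waveform.fs
    a = int(round(z0 * fs))
    b = a + config.segment_samples
    if a < 0 or b > len(waveform.samples):
        return SKIP_POOR_QUALITY
    overlapping = [bt for bt in beats if bt.valid and bt.end_s > z0 and bt.onset_s < z1]
    coverage = sum(min(bt.end_s, z1) - max(bt.onset_s, z0) for bt in overlapping)
    if coverage / config.extraction_s < config.min_zone_coverage:
        return SKIP_POOR_QUALITY
    seg = waveform.samples[a:b].copy()
    mean_map = float(np.mean([bt.map_mmHg for bt in overlapping]))
    return seg, mean_map


def _zone_mean_from_series(series: MAPSeries, t_now_s: float,
                           config: WindowConfig):
    """MAP-level fallback: zone mean from valid 1 Hz seconds (fast path)."""
    z0 = t_now_s + (config.observation_s - config.extraction_s)
    a = int(round(z0 - series.start_time_s))
    b = a + int(round(config.extraction_s))
    if a < 0 or b > len(series):
        return SKIP_POOR_QUALITY
    window_valid = series.valid_mask[a:b]
    if window_valid.mean() < config.min_zone_coverage:
        return SKIP_POOR_QUALITY
    return float(np.nanmean(series.values[a:b]))


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(patients: list[PreprocessedPatient],
                  config: WindowConfig | None = None,
                  seed: int = 0) -> LabeledDataset:
    """Label candidate times for every patient and collect the kept points.

    Patients carrying a waveform + beats get true 125 Hz segments; patients
    with only a MAP series (fast path for large-cohort statistics) get
    segment=None and a zone mean computed from valid 1 Hz seconds.
    Per-patient candidate streams are derived from ``seed`` so the dataset
    is reproducible and independent of patient order.
    """
    config = config or WindowConfig()
    if not patients:
        raise ValueError("no eligible patients")
    points = []
    tallies = {SKIP_EVENT_IN_OBSERVATION: 0, SKIP_EVENT_IN_SLACK: 0,
               SKIP_POOR_QUALITY: 0}
    for idx, pat in enumerate(patients):
        sub = np.random.default_rng([int(seed) % (2 ** 31), idx]).integers(2 ** 31)
        for t_now in draw_time_points(pat.duration_s, config, int(sub)):
            label, onset = frame_and_label(t_now, pat.events, config)
            if label not in LABELS:
                tallies[label] += 1
                continue
            if pat.waveform is not None and pat.beats is not None:
                res = extract_segment(pat.waveform, pat.beats, t_now, config)
                if res == SKIP_POOR_QUALITY:
                    tallies[SKIP_POOR_QUALITY] += 1
                    continue
                seg, mean_map = res
            else:
                res = _zone_mean_from_series(pat.map_series, t_now, config)
                if res == SKIP_POOR_QUALITY:
                    tallies[SKIP_POOR_QUALITY] += 1
                    continue
                seg, mean_map = None, res
            points.append(LabeledDataPoint(
                patient_id=pat.patient_id, t_now_s=float(t_now), label=label,
                segment=seg, segment_mean_map_mmHg=mean_map,
                matched_event_onset_s=onset))
    provenance = {"seed": int(seed), "n_patients": len(patients),
                  "skips": tallies,
                  "config": json.loads(json.dumps(asdict(config)))}
    return LabeledDataset(points=points, provenance=provenance)


def delta_mean(dataset: LabeledDataset) -> float:
    """Class separation: mean negative-segment MAP minus mean positive-segment MAP."""
    pos = [p.segment_mean_map_mmHg for p in dataset.points if p.label == "positive"]
    neg = [p.segment_mean_map_mmHg for p in dataset.points if p.label == "negative"]
    if not pos or not neg:
        raise ValueError("undefined class separation: a class is absent")
    return float(np.mean(neg) - np.mean(pos))


def augment_positives(dataset: LabeledDataset,
                      patients_by_id: dict[str, PreprocessedPatient],
                      shifts_s=(-10.0, -5.0),
                      config: WindowConfig | None = None,
                      seed: int = 0) -> LabeledDataset:
    """Add time-shifted copies of positive segments; labels are re-verified.

    Each positive gains one extra point per shift whose shifted candidate
    time still labels positive (checked through ``frame_and_label``); shifts
    that change the label or hit poor-quality zones are skipped. Negatives
    are untouched and augmented points keep their patient identity, so
    patient-grouped fold integrity is preserved.
    """
    config = config or WindowConfig()
    new_points = list(dataset.points)
    for p in dataset.points:
        if p.label != "positive":
            continue
        pat = patients_by_id[p.patient_id]
        for shift in shifts_s:
            t_new = p.t_now_s + float(shift)
            if t_new < 0:
                continue
            label, onset = frame_and_label(t_new, pat.events, config)
            if label != "positive":
                continue
            if pat.waveform is not None and pat.beats is not None:
                res = extract_segment(pat.waveform, pat.beats, t_new, config)
                if res == SKIP_POOR_QUALITY:
                    continue
                seg, mean_map = res
            else:
                res = _zone_mean_from_series(pat.map_series, t_new, config)
                if res == SKIP_POOR_QUALITY:
                    continue
                seg, mean_map = None, res
            new_points.append(LabeledDataPoint(
                patient_id=p.patient_id, t_now_s=t_new, label="positive",
                segment=seg, segment_mean_map_mmHg=mean_map,
                matched_event_onset_s=onset))
    prov = dict(dataset.provenance)
    prov["augmentation_shifts_s"] = list(shifts_s)
    return LabeledDataset(points=new_points, provenance=prov)
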