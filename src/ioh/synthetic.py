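"""Synthetic arterial-blood-pressure generator with known ground truth.

Produces 125 Hz pulsatile ABP records whose mean-arterial-pressure (MAP)
trajectory, beat times, hypotension events and artifact intervals are all
known exactly, so every downstream stage (beat detection, event detection,
window labeling, predictors) can be audited against truth.

Model
-----
* MAP trajectory: 1 Hz Gaussian random walk around a baseline, plus scripted
  or randomly placed hypotensive dips. A dip is a rectangular excursion to a
  target level smoothed by 10 s linear ramps; when the target level is below
  the 65 mmHg event threshold, the dip geometry is arranged so that the time
  spent below threshold equals the requested dip duration.
* Heart rate: slow 1/min sinusoid around the baseline rate plus white
  per-beat jitter, clipped to [30, 180] bpm.
* Pulse morphology: each beat is a two-component bell template (systolic
  upstroke + dicrotic bump), recentred and rescaled per beat so that the
  beat-interval sample mean equals the local MAP exactly and the
  peak-to-trough amplitude equals the configured pulse pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    ABPWaveform,
    GroundTruth,
    HYPOTENSION_THRESHOLD_MMHG,
    MAPSeries,
    MIN_EVENT_DURATION_S,
    PatientMeta,
    PreprocessedPatient,
)

RAMP_S = 10.0          # dip edge ramp
HR_SINE_PERIOD_S = 60.0  # slow heart-rate modulation period

ARTIFACT_KINDS = ("square_wave", "high_frequency_noise", "flatline", "spike")


@dataclass
class SynthConfig:
    """Parameters of one synthetic patient record.

    ``map_drift_sd`` is the random-walk scale in mmHg per sqrt-minute.
    ``dip_depth_range_mmHg`` is the drop below baseline; with the default
    baseline of 80 mmHg, depths above 15 mmHg cross the 65 mmHg threshold.
    ``scripted_dips`` entries are ``(start_s, level_mmHg, duration_s)`` and
    are applied in addition to the randomly placed dips.
    """

    duration_s: float = 1800.0
    fs: float = 125.0
    map_baseline_mmHg: float = 80.0
    map_drift_sd: float = 1.0
    hr_baseline_bpm: float = 70.0
    hr_jitter_sd: float = 2.0
    pulse_pressure_mmHg: float = 45.0
    dip_rate_per_hour: float = 0.0
    dip_depth_range_mmHg: tuple = (10.0, 25.0)
    dip_duration_range_s: tuple = (30.0, 240.0)
    artifact_rate_per_hour: float = 0.0
    hr_sine_amp_bpm: float = 3.0
    seed: int = 0
    scripted_dips: list = field(default_factory=list)
    scripted_artifacts: list = field(default_factory=list)  # (start_s, duration_s, kind)

    def validate(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.dip_depth_range_mmHg[0] > self.dip_depth_range_mmHg[1]:
            raise ValueError("dip depth range must be ordered lo <= hi")
        if self.dip_duration_range_s[0] > self.dip_duration_range_s[1]:
            raise ValueError("dip duration range must be ordered lo <= hi")
        if self.dip_rate_per_hour < 0 or self.artifact_rate_per_hour < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SimulatedPatient:
    """One cohort member: waveform (optional), truth, and demographics."""

    patient_id: str
    truth: GroundTruth
    waveform: ABPWaveform | None
    meta: PatientMeta
    config: SynthConfig
    group: str = ""          # "dipper" or "stable" in steered cohorts


# ---------------------------------------------------------------------------
# MAP trajectory
# ---------------------------------------------------------------------------

def _dip_weight(t: np.ndarray, start: float, level: float, duration: float,
                baseline: float) -> np.ndarray:
    """Normalized dip profile in [0, 1]: ramps + plateau.

    For dips crossing the 65 mmHg threshold the ramps are shifted inward so
    that the below-threshold span equals ``duration`` exactly (in continuous
    time; 1 Hz tabulation quantizes by +-1 s).
    """
    depth = baseline - level
    if depth <= 0:
        return np.zeros_like(t)
    thr = HYPOTENSION_THRESHOLD_MMHG
    if level < thr < baseline:
        w65 = (baseline - thr) / depth        # weight at which MAP crosses 65
        down0 = start - RAMP_S * w65
        plateau0 = down0 + RAMP_S
        plateau1 = start + duration - RAMP_S * (1.0 - w65)
    else:
        down0 = start - RAMP_S
        plateau0 = start
        plateau1 = start + duration
    up1 = plateau1 + RAMP_S
    if plateau1 < plateau0:                   # degenerate: triangular dip
        mid = 0.5 * (plateau0 + plateau1)
        plateau0 = plateau1 = mid
        up1 = mid + RAMP_S
        down0 = mid - RAMP_S
    w = np.zeros_like(t, dtype=float)
    ramp_in = (t >= down0) & (t < plateau0)
    w[ramp_in] = (t[ramp_in] - down0) / (plateau0 - down0)
    w[(t >= plateau0) & (t <= plateau1)] = 1.0
    ramp_out = (t > plateau1) & (t <= up1)
    w[ramp_out] = (up1 - t[ramp_out]) / (up1 - plateau1)
    return w


def simulate_map_trajectory(config: SynthConfig, rng: np.random.Generator
                            ) -> tuple[np.ndarray, list]:
    """Build the 1 Hz true MAP trajectory and the list of applied dips.

    Returns ``(trajectory, dips)`` with ``dips`` as (start_s, level, duration_s).
    """
    n = int(round(config.duration_s))
    t = np.arange(n, dtype=float)
    step_sd = config.map_drift_sd / math.sqrt(60.0)
    walk = np.cumsum(rng.normal(0.0, step_sd, size=n)) if step_sd > 0 else np.zeros(n)
    traj = config.map_baseline_mmHg + walk

    dips = list(config.scripted_dips)
    n_random = rng.poisson(config.dip_rate_per_hour * config.duration_s / 3600.0)
    for _ in range(n_random):
        start = rng.uniform(0.0, config.duration_s)
        depth = rng.uniform(*config.dip_depth_range_mmHg)
        duration = rng.uniform(*config.dip_duration_range_s)
        dips.append((start, config.map_baseline_mmHg - depth, duration))

    if dips:
        # combine overlapping dips by the deepest excursion, not additively
        drop = np.zeros(n)
        for start, level, duration in dips:
            w = _dip_weight(t, start, level, duration, config.map_baseline_mmHg)
            drop = np.maximum(drop, w * (config.map_baseline_mmHg - level))
        traj = traj - drop
    return np.clip(traj, 25.0, 240.0), dips


def scan_events(map_values: np.ndarray,
                threshold: float = HYPOTENSION_THRESHOLD_MMHG,
                min_duration_s: float = MIN_EVENT_DURATION_S) -> list:
    """Brute-force run-length scan for sub-threshold events on a 1 Hz series.

    Returns ``[(onset_s, offset_s)]`` for maximal runs of at least
    ``min_duration_s`` consecutive seconds strictly below ``threshold``.
    NaN seconds break runs.
    """
    below = np.asarray(map_values) < threshold   # NaN compares False
    events = []
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_duration_s:
                events.append((float(i), float(j)))
            i = j
        else:
            i += 1
    return events


# ---------------------------------------------------------------------------
# Beats and waveform rendering
# ---------------------------------------------------------------------------

def simulate_beat_times(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Beat onset times from a slowly modulated, jittered heart rate."""
    times = [0.0]
    t = 0.0
    while True:
        hr = (config.hr_baseline_bpm
              + config.hr_sine_amp_bpm * math.sin(2 * math.pi * t / HR_SINE_PERIOD_S)
              + (rng.normal(0.0, config.hr_jitter_sd)
                 if config.hr_jitter_sd > 0 else 0.0))
        hr = min(max(hr, 30.0), 180.0)
        t += 60.0 / hr
        if t >= config.duration_s:
            break
        times.append(t)
    return np.asarray(times)


def _pulse_template(phase: np.ndarray) -> np.ndarray:
    """Unnormalized beat shape: systolic upstroke + dicrotic bump."""
    return (np.exp(-0.5 * ((phase - 0.30) / 0.09) ** 2)
            + 0.42 * np.exp(-0.5 * ((phase - 0.62) / 0.12) ** 2))


def render_waveform(config: SynthConfig, traj_1hz: np.ndarray,
                    beat_times: np.ndarray, patient_id: str = "anon") -> ABPWaveform:
    """Render the pulsatile 125 Hz waveform from trajectory and beat times."""
    n_samples = int(round(config.duration_s * config.fs))
    sample_t = np.arange(n_samples) / config.fs
    map_hi = np.interp(sample_t, np.arange(len(traj_1hz), dtype=float), traj_1hz)
    samples = map_hi.copy()

    bounds = np.concatenate([beat_times, [config.duration_s]])
    idx = np.round(bounds * config.fs).astype(int)
    idx = np.clip(idx, 0, n_samples)
    # dense-grid constants for short/partial beats
    dense = _pulse_template(np.linspace(0.0, 1.0, 256, endpoint=False))
    dense_mean, dense_ptp = dense.mean(), np.ptp(dense)

    pp = config.pulse_pressure_mmHg
    for i in range(len(beat_times)):
        a, b = idx[i], idx[i + 1]
        if b - a < 2:
            continue
        phase = (sample_t[a:b] - bounds[i]) / (bounds[i + 1] - bounds[i])
        f = _pulse_template(phase)
        full_beat = bounds[i + 1] <= config.duration_s and (b - a) >= 4
        if full_beat:
            g = (f - f.mean())
            ptp = np.ptp(g)
            g = g / ptp if ptp > 0 else g
        else:
            g = (f - dense_mean) / dense_ptp
        # per-beat mean stays equal to the local MAP mean by construction
        samples[a:b] = map_hi[a:b] + pp * g
    return ABPWaveform(samples=samples, fs=config.fs, patient_id=patient_id)


# ---------------------------------------------------------------------------
# Patient- and cohort-level entry points
# ---------------------------------------------------------------------------

def simulate_patient(config: SynthConfig, patient_id: str = "anon",
                     rng: np.random.Generator | None = None,
                     render: bool = True) -> tuple[ABPWaveform | None, GroundTruth]:
    """Simulate one patient; returns the waveform and full ground truth.

    With ``render=False`` only the 1 Hz truth is produced (fast path for
    large-cohort statistics); the waveform slot is None.
    """
    config.validate()
    if config.duration_s < 60.0 / config.hr_baseline_bpm:
        raise ValueError("degenerate duration: shorter than one beat period")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    traj, _dips = simulate_map_trajectory(config, rng)
    beat_times = simulate_beat_times(config, rng)
    events = scan_events(traj)
    truth = GroundTruth(true_map_trajectory=traj, true_beat_times=beat_times,
                        true_events=events, artifact_intervals=[])
    waveform = None
    if render:
        waveform = render_waveform(config, traj, beat_times, patient_id)
        if config.artifact_rate_per_hour > 0 or config.scripted_artifacts:
            waveform, truth = inject_artifacts(waveform, truth, config, rng)
    return waveform, truth


def inject_artifacts(waveform: ABPWaveform, truth: GroundTruth,
                     config: SynthConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[ABPWaveform, GroundTruth]:
    """Overwrite waveform stretches with measurement artifacts.

    Kinds: square_wave (2 Hz rail-to-rail switching), high_frequency_noise,
    flatline, spike. Every injected interval is recorded in
    ``truth.artifact_intervals``; samples outside the intervals are
    bit-identical to the input. Overlapping intervals are merged.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    duration = waveform.duration_s
    intervals = [(s, s + d, k) for s, d, k in config.scripted_artifacts]
    n_random = rng.poisson(config.artifact_rate_per_hour * duration / 3600.0)
    for _ in range(n_random):
        start = rng.uniform(0.0, max(duration - 20.0, 1.0))
        dur = rng.uniform(5.0, 20.0)
        kind = ARTIFACT_KINDS[rng.integers(len(ARTIFACT_KINDS))]
        intervals.append((start, min(start + dur, duration), kind))
    if not intervals:
        return waveform, truth

    intervals.sort(key=lambda iv: iv[0])
    merged = [list(intervals[0])]
    for s, e, k in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e, k])

    fs = waveform.fs
    samples = waveform.samples.copy()
    for s, e, kind in merged:
        a, b = int(round(s * fs)), min(int(round(e * fs)), len(samples))
        if b <= a:
            continue
        seg_t = np.arange(a, b) / fs
        if kind == "flatline":
            samples[a:b] = samples[a]
        elif kind == "square_wave":
            samples[a:b] = 100.0 + 50.0 * np.sign(np.sin(2 * math.pi * 2.0 * seg_t))
        elif kind == "high_frequency_noise":
            samples[a:b] = samples[a:b] + rng.normal(0.0, 25.0, size=b - a)
        elif kind == "spike":
            samples[a:b] = samples[a:b].mean()
            step = max(int(0.3 * fs), 1)
            for j, pos in enumerate(range(a, b, step)):
                hi = min(pos + 2, b)
                samples[pos:hi] += 80.0 if j % 2 == 0 else -60.0
        else:
            raise ValueError(f"unknown artifact kind: {kind}")
    new_truth = GroundTruth(
        true_map_trajectory=truth.true_map_trajectory,
        true_beat_times=truth.true_beat_times,
        true_events=truth.true_events,
        artifact_intervals=truth.artifact_intervals + [tuple(m) for m in merged],
    )
    return ABPWaveform(samples=samples, fs=fs, start_time_s=waveform.start_time_s,
                       patient_id=waveform.patient_id), new_truth


def truth_to_patient(truth: GroundTruth, patient_id: str,
                     meta: PatientMeta | None = None) -> PreprocessedPatient:
    """Wrap ground truth as a preprocessed patient (MAP-level fast path)."""
    from .events import detect_events   # local import avoids cycle at module load
    series = MAPSeries(values=truth.true_map_trajectory,
                       valid_mask=np.ones(len(truth.true_map_trajectory), bool))
    events = detect_events(series)
    return PreprocessedPatient(patient_id=patient_id, map_series=series,
                               events=events, meta=meta)


# ---------------------------------------------------------------------------
# Cohort with steered class separation
# ---------------------------------------------------------------------------

DIPPER_BASELINE_MMHG = 76.0     # hypotension-prone group baseline
DIPPER_DIP_RATE_PER_H = 6.0
BASELINE_PATIENT_SD = 1.5       # per-patient baseline spread within a group


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2 ** 31), index])


def _build_cohort(config_template: SynthConfig, n_patients: int, seed: int,
                  stable_baseline: float, stable_fraction: float,
                  render: bool) -> list:
    patients = []
    meta_rng = _patient_rng(seed, 10_000_019)
    n_stable = int(round(stable_fraction * n_patients))
    for i in range(n_patients):
        rng = _patient_rng(seed, i)
        stable = i < n_stable
        offs = float(np.clip(rng.normal(0.0, BASELINE_PATIENT_SD), -4.0, 4.0))
        if stable:
            cfg = replace(config_template,
                          map_baseline_mmHg=stable_baseline + offs,
                          dip_rate_per_hour=0.0, scripted_dips=[],
                          seed=config_template.seed)
        else:
            cfg = replace(config_template,
                          map_baseline_mmHg=DIPPER_BASELINE_MMHG + offs,
                          dip_rate_per_hour=DIPPER_DIP_RATE_PER_H,
                          dip_depth_range_mmHg=(12.0, 24.0),
                          scripted_dips=[], seed=config_template.seed)
        waveform, truth = simulate_patient(cfg, patient_id=f"p{i:04d}",
                                           rng=rng, render=render)
        meta = PatientMeta(patient_id=f"p{i:04d}",
                           age_years=float(meta_rng.uniform(19, 85)),
                           asa_class=int(meta_rng.choice([1, 2, 3, 4],
                                                         p=[0.15, 0.55, 0.25, 0.05])))
        patients.append(SimulatedPatient(patient_id=f"p{i:04d}", truth=truth,
                                         waveform=waveform, meta=meta, config=cfg,
                                         group="stable" if stable else "dipper"))
    return patients


def simulate_cohort(config_template: SynthConfig, n_patients: int,
                    delta_mean_target: float, seed: int,
                    stable_fraction: float = 0.5,
                    render: bool = True) -> list:
    """Simulate a cohort whose labeled-dataset class separation is steerable.

    Half the patients (``stable_fraction``) are event-free with a high MAP
    baseline; the rest are hypotension-prone at a low baseline. The
    class-separation statistic (mean negative-segment MAP minus mean
    positive-segment MAP) is then approximately affine in the stable-group
    baseline, so one seeded MAP-level calibration pass solves the baseline
    that lands the empirical value near ``delta_mean_target``.

    Returns a list of :class:`SimulatedPatient`.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if delta_mean_target < 0:
        raise ValueError("unreachable delta_mean_target: must be >= 0")
    if not 0.0 < stable_fraction < 1.0 or int(round(stable_fraction * n_patients)) in (0, n_patients):
        # need both groups present for steering; single patient falls back
        if n_patients == 1:
            return _build_cohort(config_template, 1, seed,
                                 DIPPER_BASELINE_MMHG + delta_mean_target,
                                 stable_fraction=0.0 if stable_fraction < 0.5 else 1.0,
                                 render=render)
        raise ValueError("stable_fraction must leave both groups non-empty")

    from .sampling import WindowConfig, build_dataset, delta_mean

    b0 = DIPPER_BASELINE_MMHG + max(delta_mean_target, 1.0) + 4.0
    pilot = _build_cohort(config_template, n_patients, seed, b0,
                          stable_fraction, render=False)
    pre = [truth_to_patient(p.truth, p.patient_id, p.meta) for p in pilot]
    ds = build_dataset(pre, WindowConfig(), seed=seed)
    stable_ids = {p.patient_id for p in pilot if p.group == "stable"}
    negs = [pt for pt in ds.points if pt.label == "negative"]
    if not negs or not any(pt.label == "positive" for pt in ds.points):
        raise ValueError("pilot cohort produced no labeled points of both classes; "
                         "increase duration or dip rate")
    q = sum(pt.patient_id in stable_ids for pt in negs) / len(negs)
    d0 = delta_mean(ds)
    if q <= 0:
        raise ValueError("no stable-group negatives; cannot steer class separation")
    b_hi = b0 + (delta_mean_target - d0) / q
    b_hi = float(np.clip(b_hi, 66.0, 130.0))
    return _build_cohort(config_template, n_patients, seed, b_hi,
                         stable_fraction, render=render)
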