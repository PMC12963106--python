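"""Raw ABP to validated beats and a regular 1 Hz MAP series.

Stages: FFT resampling to the canonical 125 Hz, beat detection via a
derivative-of-Gaussian bandpass and the Shannon energy envelogram, beat-level
signal-abnormality flagging, the >=90% clean-signal patient filter, and
linear interpolation of valid per-beat MAP onto a 1 Hz grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .types import ABPWaveform, BeatRecord, CANONICAL_FS, MAPSeries

CLEAN_FRACTION_THRESHOLD = 0.90
MAP_INTERP_MAX_GAP_S = 5.0


def resample_to_125(waveform: ABPWaveform) -> ABPWaveform:
    """FFT-based downsampling to the canonical 125 Hz.

    Records already at 125 Hz are returned unchanged; upsampling is refused.
    """
    if waveform.fs == CANONICAL_FS:
        return waveform
    if waveform.fs < CANONICAL_FS:
        raise ValueError("upsampling not supported: fs < 125 Hz")
    n_out = int(round(len(waveform.samples) * CANONICAL_FS / waveform.fs))
    out = signal.resample(waveform.samples, n_out)
    return ABPWaveform(samples=out, fs=CANONICAL_FS,
                       start_time_s=waveform.start_time_s,
                       patient_id=waveform.patient_id)


# ---------------------------------------------------------------------------
# Beat detection
# ---------------------------------------------------------------------------

@dataclass
class BeatDetectorConfig:
    """Envelogram detector parameters (all in seconds unless noted)."""

    gauss_sigma_s: float = 0.1         # derivative-of-Gaussian bandpass width
    envelope_window_s: float = 0.12    # Shannon-energy moving average
    refractory_s: float = 0.3          # minimum peak spacing
    peak_search_s: float = 0.15        # raw-signal search radius around envelope peak
    min_prominence_frac: float = 0.15  # envelope prominence vs its 95th percentile
    # amplitude gate rejecting dicrotic bumps: candidate raw value must reach
    # this fraction of the local pressure range
    min_height_frac: float = 0.6
    local_window_s: float = 1.0


def _shannon_envelope(x: np.ndarray, fs: float, cfg: BeatDetectorConfig) -> np.ndarray:
    deriv = ndimage.gaussian_filter1d(x, sigma=cfg.gauss_sigma_s * fs, order=1)
    # robust normalization to [-1, 1]: a loud artifact must not suppress the
    # envelope over the rest of the record
    scale = np.percentile(np.abs(deriv), 98)
    if scale <= 0:
        return np.zeros_like(x)
    d = np.clip(deriv / scale, -1.0, 1.0)
    d2 = np.maximum(d * d, 1e-12)
    energy = -d2 * np.log(d2)
    win = max(int(round(cfg.envelope_window_s * fs)), 1)
    return ndimage.uniform_filter1d(energy, size=win)


def detect_beats(waveform: ABPWaveform,
                 cfg: BeatDetectorConfig | None = None) -> list[BeatRecord]:
    """Detect beats on a canonical 125 Hz record.

    Each beat interval runs onset-to-next-onset; SBP/DBP are the raw extrema
    within the interval and MAP is the raw arithmetic mean over it. The last
    beat inherits the previous period and is clipped to the record end.
    Constant input yields no beats.
    """
    if waveform.fs != CANONICAL_FS:
        raise ValueError("detect_beats expects a canonical 125 Hz waveform")
    x = waveform.samples
    fs = waveform.fs
    if len(x) < 2 * fs or np.ptp(x) == 0:
        return []
    env = _shannon_envelope(x, fs, cfg := cfg or BeatDetectorConfig())
    prominence = cfg.min_prominence_frac * np.percentile(env, 95)
    if prominence <= 0:
        return []
    peaks, _ = signal.find_peaks(env, distance=max(int(cfg.refractory_s * fs), 1),
                                 prominence=prominence)
    if len(peaks) < 2:
        return []

    radius = int(cfg.peak_search_s * fs)
    half_win = int(cfg.local_window_s * fs)
    sys_idx = []
    for p in peaks:
        a, b = max(p - radius, 0), min(p + radius + 1, len(x))
        c = a + int(np.argmax(x[a:b]))
        # reject dicrotic bumps: the systolic peak dominates the local range
        wa, wb = max(c - half_win, 0), min(c + half_win + 1, len(x))
        lo, hi = x[wa:wb].min(), x[wa:wb].max()
        if hi > lo and (x[c] - lo) / (hi - lo) >= cfg.min_height_frac:
            sys_idx.append(c)
    sys_idx = np.unique(sys_idx)
    # refractory on the accepted systolic peaks: of any pair closer than the
    # refractory period keep the taller
    keep = []
    for c in sys_idx:
        if keep and (c - keep[-1]) < cfg.refractory_s * fs:
            if x[c] > x[keep[-1]]:
                keep[-1] = c
        else:
            keep.append(c)
    sys_idx = np.asarray(keep)
    if len(sys_idx) < 2:
        return []

    # beat onset = trough preceding the systolic peak
    onsets = []
    for k, p in enumerate(sys_idx):
        a = sys_idx[k - 1] if k > 0 else max(p - int(1.5 * fs), 0)
        onsets.append(a + int(np.argmin(x[a:p])) if p > a else p)
    onsets = np.asarray(onsets)

    beats: list[BeatRecord] = []
    for k in range(len(onsets)):
        a = onsets[k]
        b = onsets[k + 1] if k + 1 < len(onsets) else min(
            a + (onsets[k] - onsets[k - 1] if k > 0 else int(fs)), len(x))
        if b - a < 2:
            continue
        seg = x[a:b]
        beats.append(BeatRecord(
            onset_s=a / fs,
            systolic_peak_s=sys_idx[k] / fs,
            diastolic_trough_s=(a + int(np.argmin(seg))) / fs,
            sbp_mmHg=float(seg.max()),
            dbp_mmHg=float(seg.min()),
            map_mmHg=float(seg.mean()),
            period_s=(b - a) / fs,
            sample_var_mmHg2=float(seg.var()),
        ))
    return beats


# ---------------------------------------------------------------------------
# Signal abnormality index
# ---------------------------------------------------------------------------

@dataclass
class AbnormalityRules:
    """Beat-level plausibility rules (a classical signal-abnormality index).

    Every threshold is configurable; a beat is valid iff no rule fires.
    """

    sbp_range: tuple = (30.0, 300.0)
    dbp_range: tuple = (10.0, 200.0)
    map_range: tuple = (20.0, 200.0)
    pulse_pressure_range: tuple = (10.0, 90.0)
    period_range_s: tuple = (0.3, 3.0)
    max_delta_sbp: float = 20.0        # vs previous valid beat
    max_delta_period_s: float = 0.5
    max_reference_age_s: float = 5.0   # delta rules need a recent valid reference
    min_sample_var: float = 0.01       # flatline detector, mmHg^2


def flag_abnormal_beats(beats: list[BeatRecord],
                        rules: AbnormalityRules | None = None) -> list[BeatRecord]:
    """Annotate each beat with abnormality codes and update validity.

    Order-preserving; the delta rules compare against the most recent beat
    that itself passed all rules.
    """
    rules = rules or AbnormalityRules()
    out: list[BeatRecord] = []
    prev_valid: BeatRecord | None = None
    for b in beats:
        codes = set()
        if not rules.sbp_range[0] <= b.sbp_mmHg <= rules.sbp_range[1]:
            codes.add("sbp_range")
        if not rules.dbp_range[0] <= b.dbp_mmHg <= rules.dbp_range[1]:
            codes.add("dbp_range")
        if not rules.map_range[0] <= b.map_mmHg <= rules.map_range[1]:
            codes.add("map_range")
        pp = b.sbp_mmHg - b.dbp_mmHg
        if not rules.pulse_pressure_range[0] <= pp <= rules.pulse_pressure_range[1]:
            codes.add("pulse_pressure")
        if not rules.period_range_s[0] <= b.period_s <= rules.period_range_s[1]:
            codes.add("period_range")
        if (prev_valid is not None
                and b.onset_s - prev_valid.end_s <= rules.max_reference_age_s):
            if abs(b.sbp_mmHg - prev_valid.sbp_mmHg) > rules.max_delta_sbp:
                codes.add("delta_sbp")
            if abs(b.period_s - prev_valid.period_s) > rules.max_delta_period_s:
                codes.add("delta_period")
        if np.isfinite(b.sample_var_mmHg2) and b.sample_var_mmHg2 < rules.min_sample_var:
            codes.add("flatline")
        nb = BeatRecord(**{**b.__dict__, "valid": not codes,
                           "abnormality_codes": frozenset(codes)})
        if nb.valid:
            prev_valid = nb
        out.append(nb)
    return out


def clean_fraction(beats: list[BeatRecord], total_duration_s: float) -> float:
    """Fraction of the record covered by valid beats, clipped to [0, 1].

    The patient-inclusion rule is ``clean_fraction >= 0.90``.
    """
    if total_duration_s <= 0:
        raise ValueError("total_duration_s must be positive")
    covered = sum(b.period_s for b in beats if b.valid)
    return float(min(max(covered / total_duration_s, 0.0), 1.0))


def passes_clean_filter(beats: list[BeatRecord], total_duration_s: float,
                        threshold: float = CLEAN_FRACTION_THRESHOLD) -> bool:
    return clean_fraction(beats, total_duration_s) >= threshold


def beats_to_map_series(beats: list[BeatRecord], duration_s: float,
                        max_gap_s: float = MAP_INTERP_MAX_GAP_S) -> MAPSeries:
    """1 Hz MAP series by linear interpolation between valid beat MAPs.

    Seconds farther than ``max_gap_s`` from any valid beat time are masked
    invalid; with no valid beats the series is fully masked.
    """
    n = int(round(duration_s))
    grid = np.arange(n, dtype=float)
    valid = [b for b in beats if b.valid]
    if not valid:
        return MAPSeries(values=np.full(n, np.nan), valid_mask=np.zeros(n, bool))
    bt = np.asarray([0.5 * (b.onset_s + b.end_s) for b in valid])
    bm = np.asarray([b.map_mmHg for b in valid])
    values = np.interp(grid, bt, bm)
    # distance from each second to the nearest valid beat time
    pos = np.searchsorted(bt, grid)
    left = np.where(pos > 0, grid - bt[np.maximum(pos - 1, 0)], np.inf)
    right = np.where(pos < len(bt), bt[np.minimum(pos, len(bt) - 1)] - grid, np.inf)
    mask = np.minimum(left, right) <= max_gap_s
    return MAPSeries(values=np.where(mask, values, np.nan), valid_mask=mask)


def preprocess_patient(waveform: ABPWaveform,
                       detector: BeatDetectorConfig | None = None,
                       rules: AbnormalityRules | None = None):
    """Full per-patient pipeline: resample, detect, flag, MAP series.

    Returns ``(beats, map_series, quality)`` where quality is a dict with the
    clean fraction and the inclusion decision.
    """
    wf = resample_to_125(waveform)
    beats = flag_abnormal_beats(detect_beats(wf, detector), rules)
    series = beats_to_map_series(beats, wf.duration_s)
    frac = clean_fraction(beats, wf.duration_s)
    quality = {"clean_fraction": frac,
               "included": frac >= CLEAN_FRACTION_THRESHOLD,
               "n_beats": len(beats),
               "n_valid_beats": sum(b.valid for b in beats)}
    return beats, series, quality
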