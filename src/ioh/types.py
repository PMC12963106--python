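"""Core domain containers shared across the pipeline.

Conventions: time is in seconds from record start, intervals are half-open
``[start, end)``, sample indices are 0-based, and the canonical waveform
sampling rate is 125 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

#: Canonical sampling rate for arterial blood pressure waveforms (Hz).
CANONICAL_FS = 125.0

#: Hypotension threshold on mean arterial pressure (mmHg).
HYPOTENSION_THRESHOLD_MMHG = 65.0

#: Minimum sustained duration below threshold to count as an event (s).
MIN_EVENT_DURATION_S = 60.0


@dataclass
class ABPWaveform:
    """Continuous arterial blood pressure recording for one patient."""

    samples: np.ndarray          # pressure in mmHg
    fs: float                    # sampling rate, Hz
    start_time_s: float = 0.0
    patient_id: str = "anon"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def time_axis(self) -> np.ndarray:
        return self.start_time_s + np.arange(len(self.samples)) / self.fs


@dataclass
class BeatRecord:
    """One detected cardiac beat with its pressure summary and quality flags.

    The beat interval is ``[onset_s, onset_s + period_s)``; ``map_mmHg`` is the
    arithmetic mean of the raw waveform over that interval (not the classical
    DBP + PP/3 estimate).
    """

    onset_s: float
    systolic_peak_s: float
    diastolic_trough_s: float
    sbp_mmHg: float
    dbp_mmHg: float
    map_mmHg: float
    period_s: float
    valid: bool = True
    abnormality_codes: frozenset = frozenset()
    sample_var_mmHg2: float = np.nan   # beat-interval sample variance, for flatline QC

    @property
    def end_s(self) -> float:
        return self.onset_s + self.period_s


@dataclass
class MAPSeries:
    """Regular 1 Hz mean-arterial-pressure series with a validity mask.

    Invalid seconds carry NaN and must never enter statistics.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if len(self.values) != len(self.valid_mask):
            raise ValueError("values and valid_mask must have equal length")
        # enforce sentinel on invalid positions
        self.values = np.where(self.valid_mask, self.values, np.nan)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def valid_seconds(self) -> int:
        return int(self.valid_mask.sum())


@dataclass
class HypotensionEvent:
    """A sustained interval of MAP below threshold (an IOH event)."""

    onset_s: float
    offset_s: float
    nadir_mmHg: float
    aut_contribution: float = 0.0   # mmHg·min accumulated within the event

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class GroundTruth:
    """Generator-side annotations used to audit the analysis pipeline."""

    true_map_trajectory: np.ndarray                 # 1 Hz, mmHg
    true_beat_times: np.ndarray                     # onset times, s
    true_events: list                               # [(onset_s, offset_s)]
    artifact_intervals: list = field(default_factory=list)  # [(start_s, end_s, kind)]


@dataclass
class PatientMeta:
    """Demographics used by cohort filters."""

    patient_id: str
    age_years: float = np.nan
    asa_class: int = -1


@dataclass
class PreprocessedPatient:
    """Everything downstream sampling needs for one patient.

    ``waveform``/``beats`` may be None for the MAP-level fast path used for
    large-cohort statistics, in which case segment extraction falls back to
    the 1 Hz MAP series.
    """

    patient_id: str
    map_series: MAPSeries
    events: list                      # HypotensionEvent, ordered
    waveform: ABPWaveform | None = None
    beats: list | None = None
    meta: PatientMeta | None = None
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s == 0.0:
            self.duration_s = float(len(self.map_series))
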