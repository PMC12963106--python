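"""Readers and writers: CSV waveforms, beat tables, MAP series, HDF5
datasets, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .sampling import LabeledDataPoint, LabeledDataset
from .types import ABPWaveform, BeatRecord, MAPSeries


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

def read_waveform_csv(path, fs: float | None = None,
                      patient_id: str | None = None) -> ABPWaveform:
    """CSV with columns time_s, abp_mmHg. ``fs`` inferred from time axis if
    not given."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        if len(t) < 2:
            raise ValueError("cannot infer fs from fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    return ABPWaveform(samples=df["abp_mmHg"].to_numpy(dtype=float),
                       fs=round(fs, 6), start_time_s=float(t[0]),
                       patient_id=patient_id or Path(path).stem)


def write_waveform_csv(waveform: ABPWaveform, path) -> None:
    pd.DataFrame({"time_s": waveform.time_axis(),
                  "abp_mmHg": waveform.samples}).to_csv(path, index=False)


def read_waveform_hdf5(path, dataset: str = "abp") -> ABPWaveform:
    with h5py.File(path, "r") as f:
        d = f[dataset]
        return ABPWaveform(samples=d[...], fs=float(d.attrs["fs"]),
                           start_time_s=float(d.attrs.get("start_time_s", 0.0)),
                           patient_id=str(d.attrs.get("patient_id", "anon")))


def write_waveform_hdf5(waveform: ABPWaveform, path, dataset: str = "abp") -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset(dataset, data=waveform.samples)
        d.attrs["fs"] = waveform.fs
        d.attrs["start_time_s"] = waveform.start_time_s
        d.attrs["patient_id"] = waveform.patient_id


# ---------------------------------------------------------------------------
# Beats and MAP series
# ---------------------------------------------------------------------------

_BEAT_COLS = ["onset_s", "systolic_peak_s", "diastolic_trough_s", "sbp_mmHg",
              "dbp_mmHg", "map_mmHg", "period_s", "valid", "abnormality_codes",
              "sample_var_mmHg2"]


def beats_to_frame(beats: list[BeatRecord]) -> pd.DataFrame:
    rows = [{**{c: getattr(b, c) for c in _BEAT_COLS if c != "abnormality_codes"},
             "abnormality_codes": ";".join(sorted(b.abnormality_codes))}
            for b in beats]
    return pd.DataFrame(rows, columns=_BEAT_COLS)


def frame_to_beats(df: pd.DataFrame) -> list[BeatRecord]:
    out = []
    for row in df.itertuples(index=False):
        codes = frozenset(c for c in str(row.abnormality_codes).split(";")
                          if c and c != "nan")
        out.append(BeatRecord(onset_s=row.onset_s,
                              systolic_peak_s=row.systolic_peak_s,
                              diastolic_trough_s=row.diastolic_trough_s,
                              sbp_mmHg=row.sbp_mmHg, dbp_mmHg=row.dbp_mmHg,
                              map_mmHg=row.map_mmHg, period_s=row.period_s,
                              valid=bool(row.valid), abnormality_codes=codes,
                              sample_var_mmHg2=row.sample_var_mmHg2))
    return out


def write_map_series_csv(series: MAPSeries, path) -> None:
    pd.DataFrame({"time_s": series.start_time_s + np.arange(len(series)),
                  "map_mmHg": series.values,
                  "valid": series.valid_mask}).to_csv(path, index=False)


def read_map_series_csv(path) -> MAPSeries:
    df = pd.read_csv(path)
    return MAPSeries(values=df["map_mmHg"].to_numpy(dtype=float),
                     valid_mask=df["valid"].to_numpy(dtype=bool),
                     start_time_s=float(df["time_s"].iloc[0]))


# ---------------------------------------------------------------------------
# Labeled datasets (HDF5: metadata table + segment array + provenance JSON)
# ---------------------------------------------------------------------------

def write_dataset_hdf5(dataset: LabeledDataset, path) -> None:
    n = len(dataset.points)
    with h5py.File(path, "w") as f:
        f.attrs["provenance"] = json.dumps(dataset.provenance)
        f.create_dataset("patient_id", data=np.asarray(
            [p.patient_id for p in dataset.points], dtype="S32"))
        f.create_dataset("t_now_s", data=[p.t_now_s for p in dataset.points])
        f.create_dataset("label", data=np.asarray(
            [p.label for p in dataset.points], dtype="S16"))
        f.create_dataset("segment_mean_map_mmHg",
                         data=[p.segment_mean_map_mmHg for p in dataset.points])
        f.create_dataset("matched_event_onset_s", data=[
            np.nan if p.matched_event_onset_s is None else p.matched_event_onset_s
            for p in dataset.points])
        has_seg = [p.segment is not None for p in dataset.points]
        f.create_dataset("has_segment", data=has_seg)
        if n and all(has_seg):
            f.create_dataset("segments", data=np.stack(
                [p.segment for p in dataset.points]).astype(np.float32))


def read_dataset_hdf5(path) -> LabeledDataset:
    with h5py.File(path, "r") as f:
        prov = json.loads(f.attrs["provenance"])
        pids = [s.decode() for s in f["patient_id"][...]]
        labels = [s.decode() for s in f["label"][...]]
        t_now = f["t_now_s"][...]
        means = f["segment_mean_map_mmHg"][...]
        onsets = f["matched_event_onset_s"][...]
        segments = f["segments"][...] if "segments" in f else None
        points = []
        for i in range(len(pids)):
            points.append(LabeledDataPoint(
                patient_id=pids[i], t_now_s=float(t_now[i]), label=labels[i],
                segment=None if segments is None else segments[i].astype(float),
                segment_mean_map_mmHg=float(means[i]),
                matched_event_onset_s=None if np.isnan(onsets[i])
                else float(onsets[i])))
    return LabeledDataset(points=points, provenance=prov)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
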