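"""Shared fixtures: small synthetic records reused across test modules."""

import numpy as np
import pytest

import ioh


@pytest.fixture(scope="session")
def clean_record():
    """120 s artifact-free record at a constant scripted MAP of 80 mmHg."""
    cfg = ioh.SynthConfig(duration_s=120.0, dip_rate_per_hour=0.0,
                          map_drift_sd=0.0, seed=11)
    waveform, truth = ioh.simulate_patient(cfg)
    return cfg, waveform, truth


@pytest.fixture(scope="session")
def clean_preprocessed(clean_record):
    cfg, waveform, truth = clean_record
    beats, series, quality = ioh.preprocess_patient(waveform)
    return cfg, waveform, truth, beats, series, quality


@pytest.fixture(scope="session")
def event_record():
    """10 min record with one scripted hypotensive dip to 55 mmHg for 120 s."""
    cfg = ioh.SynthConfig(duration_s=600.0, dip_rate_per_hour=0.0,
                          map_drift_sd=0.0, seed=5,
                          scripted_dips=[(240.0, 55.0, 120.0)])
    waveform, truth = ioh.simulate_patient(cfg)
    return cfg, waveform, truth


@pytest.fixture(scope="session")
def map_level_cohort():
    """Fast-path cohort (1 Hz truth only) with steered class separation."""
    template = ioh.SynthConfig(duration_s=5400.0, map_drift_sd=1.0)
    cohort = ioh.simulate_cohort(template, n_patients=40, delta_mean_target=12.0,
                                 seed=21, render=False)
    patients = [ioh.truth_to_patient(p.truth, p.patient_id, p.meta)
                for p in cohort]
    dataset = ioh.build_dataset(patients, ioh.WindowConfig(), seed=21)
    return cohort, patients, dataset


def random_map_series(rng, n=900, scale=12.0, base=72.0, mask_frac=0.05):
    """Random-walk 1 Hz MAP series with occasional masked seconds."""
    values = base + np.cumsum(rng.normal(0, scale / 30.0, size=n))
    mask = rng.random(n) >= mask_frac
    return ioh.MAPSeries(values=np.where(mask, values, np.nan), valid_mask=mask)
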