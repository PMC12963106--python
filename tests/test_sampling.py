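"""Window framing, labeling, segment extraction, dataset assembly."""

import numpy as np
import pytest

import ioh
from ioh.sampling import (
    SKIP_EVENT_IN_OBSERVATION,
    SKIP_EVENT_IN_SLACK,
    SKIP_POOR_QUALITY,
)


def ev(onset, offset):
    return ioh.HypotensionEvent(onset_s=onset, offset_s=offset, nadir_mmHg=60.0)


def oracle_label(t_now, events, obs=80.0, pred=300.0, slack=60.0):
    """Independent interval-logic oracle for frame labeling."""
    for onset, offset in events:
        if onset < t_now + obs and offset > t_now:
            return SKIP_EVENT_IN_OBSERVATION
    in_pred = [onset for onset, _ in events
               if t_now + obs <= onset < t_now + obs + pred]
    if in_pred:
        return "positive"
    for onset, _ in events:
        if t_now + obs + pred <= onset < t_now + obs + pred + slack:
            return SKIP_EVENT_IN_SLACK
    return "negative"


class TestDrawTimePoints:
    def test_empty_for_short_record(self):
        assert len(ioh.draw_time_points(0.0, ioh.WindowConfig(), seed=1)) == 0

    def test_deterministic(self):
        a = ioh.draw_time_points(7200.0, ioh.WindowConfig(), seed=42)
        b = ioh.draw_time_points(7200.0, ioh.WindowConfig(), seed=42)
        np.testing.assert_array_equal(a, b)

    def test_all_frames_fit(self):
        cfg = ioh.WindowConfig()
        t = ioh.draw_time_points(3600.0, cfg, seed=3)
        assert np.all(t + cfg.frame_s <= 3600.0)

    def test_mean_count_matches_renewal_oracle(self):
        # Monte-Carlo oracle: clipped-exponential renewal process
        cfg = ioh.WindowConfig()
        duration = 7200.0
        limit = duration - cfg.frame_s
        rng = np.random.default_rng(99)
        oracle_counts = []
        for _ in range(1000):
            t, n = 0.0, 0
            while True:
                t += float(np.clip(rng.exponential(cfg.mean_interval_s),
                                   cfg.interval_floor_s, cfg.interval_cap_s))
                if t > limit:
                    break
                n += 1
            oracle_counts.append(n)
        ours = [len(ioh.draw_time_points(duration, cfg, seed=s)) for s in range(1000)]
        assert np.mean(ours) == pytest.approx(np.mean(oracle_counts), rel=0.02)


class TestFrameAndLabel:
    @pytest.mark.parametrize("events,expected", [
        ([(381.0, 460.0)], SKIP_EVENT_IN_SLACK),    # onset at t_now + 6 m 21 s
        ([(200.0, 290.0)], "positive"),
        ([(-30.0, 40.0)], SKIP_EVENT_IN_OBSERVATION),
        ([], "negative"),
        ([(80.0, 150.0)], "positive"),              # onset exactly at window start
        ([(380.0, 460.0)], SKIP_EVENT_IN_SLACK),    # boundary of prediction window
        ([(440.0, 520.0)], "negative"),             # beyond slack
    ])
    def test_boundary_cases(self, events, expected):
        label, onset = ioh.frame_and_label(0.0, [ev(*e) for e in events])
        assert label == expected
        if expected == "positive":
            assert onset == events[0][0]

    def test_earliest_onset_matched(self):
        label, onset = ioh.frame_and_label(
            0.0, [ev(150.0, 220.0), ev(300.0, 370.0)])
        assert label == "positive" and onset == 150.0

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(2000):
            t_now = float(rng.uniform(0, 600))
            events = []
            t = 0.0
            for _ in range(rng.integers(0, 4)):
                t += float(rng.uniform(0, 400))
                dur = float(rng.uniform(60, 200))
                events.append((t, t + dur))
                t += dur
            label, _ = ioh.frame_and_label(t_now, [ev(*e) for e in events])
            assert label == oracle_label(t_now, events)


class TestExtractSegment:
    def test_clean_record_segment(self, clean_preprocessed):
        _, waveform, _, beats, _, _ = clean_preprocessed
        res = ioh.extract_segment(waveform, beats, 10.0)
        assert res != SKIP_POOR_QUALITY
        seg, mean_map = res
        assert len(seg) == 2500
        assert mean_map == pytest.approx(80.0, abs=1.0)

    def test_flatline_zone_poor_quality(self):
        cfg = ioh.SynthConfig(duration_s=240, dip_rate_per_hour=0, map_drift_sd=0,
                              seed=9, scripted_artifacts=[(60.0, 30.0, "flatline")])
        waveform, _ = ioh.simulate_patient(cfg)
        beats, _, _ = ioh.preprocess_patient(waveform)
        assert ioh.extract_segment(waveform, beats, 10.0) == SKIP_POOR_QUALITY

    def test_zone_beyond_record_end(self, clean_preprocessed):
        _, waveform, _, beats, _, _ = clean_preprocessed
        assert ioh.extract_segment(waveform, beats,
                                   waveform.duration_s - 10.0) == SKIP_POOR_QUALITY


class TestBuildDataset:
    def test_no_event_cohort_all_negative(self):
        cfg = ioh.SynthConfig(duration_s=2400, dip_rate_per_hour=0, seed=2)
        _, truth = ioh.simulate_patient(cfg, render=False)
        ds = ioh.build_dataset([ioh.truth_to_patient(truth, "p0")], seed=2)
        assert len(ds) > 0
        assert all(p.label == "negative" for p in ds.points)

    def test_positives_match_truth_events(self, map_level_cohort):
        cohort, patients, dataset = map_level_cohort
        truth_by_id = {p.patient_id: p.truth for p in cohort}
        for pt in dataset.points:
            if pt.label == "positive":
                onsets = [on for on, _ in truth_by_id[pt.patient_id].true_events]
                assert pt.matched_event_onset_s in onsets
                assert pt.t_now_s + 80.0 <= pt.matched_event_onset_s < pt.t_now_s + 380.0

    def test_label_recovery_from_truth(self, map_level_cohort):
        # labels computed from detected events equal labels from ground truth
        cohort, patients, dataset = map_level_cohort
        truth_by_id = {p.patient_id: p.truth for p in cohort}
        for pt in dataset.points:
            label, _ = ioh.frame_and_label(
                pt.t_now_s,
                [ev(on, off) for on, off in truth_by_id[pt.patient_id].true_events])
            assert label == pt.label

    def test_deterministic_hash(self, map_level_cohort):
        _, patients, dataset = map_level_cohort
        again = ioh.build_dataset(patients, ioh.WindowConfig(), seed=21)
        assert again.content_hash() == dataset.content_hash()

    def test_no_eligible_patients_rejected(self):
        with pytest.raises(ValueError, match="no eligible patients"):
            ioh.build_dataset([], seed=0)

    def test_no_leakage_invariant(self, map_level_cohort):
        cohort, _, dataset = map_level_cohort
        truth_by_id = {p.patient_id: p.truth for p in cohort}
        for pt in dataset.points:
            events = truth_by_id[pt.patient_id].true_events
            if pt.label == "negative":
                assert not any(pt.t_now_s <= on < pt.t_now_s + 440.0
                               for on, _ in events)
            # extraction zone never overlaps an event interval
            z0, z1 = pt.t_now_s + 60.0, pt.t_now_s + 80.0
            assert not any(on < z1 and off > z0 for on, off in events)


class TestDeltaMean:
    def _mini(self, neg_vals, pos_vals):
        pts = ([ioh.LabeledDataPoint("a", 0.0, "negative", segment_mean_map_mmHg=v)
                for v in neg_vals]
               + [ioh.LabeledDataPoint("a", 0.0, "positive", segment_mean_map_mmHg=v)
                  for v in pos_vals])
        return ioh.LabeledDataset(points=pts)

    def test_simple_difference(self):
        assert ioh.delta_mean(self._mini([86, 86], [74, 74])) == pytest.approx(12.0)

    def test_identical_distributions_zero(self):
        assert ioh.delta_mean(self._mini([80, 90], [80, 90])) == pytest.approx(0.0)

    def test_matches_two_pass_mean(self):
        rng = np.random.default_rng(12)
        neg = rng.uniform(70, 95, 200)
        pos = rng.uniform(60, 85, 50)
        assert ioh.delta_mean(self._mini(neg, pos)) == pytest.approx(
            neg.mean() - pos.mean(), rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            ioh.delta_mean(self._mini([80.0], []))


class TestAugmentPositives:
    def test_empty_shifts_identity(self, map_level_cohort):
        _, patients, dataset = map_level_cohort
        by_id = {p.patient_id: p for p in patients}
        out = ioh.augment_positives(dataset, by_id, shifts_s=())
        assert len(out) == len(dataset)

    def test_bound_and_labels(self, map_level_cohort):
        cohort, patients, dataset = map_level_cohort
        by_id = {p.patient_id: p for p in patients}
        k = sum(p.label == "positive" for p in dataset.points)
        out = ioh.augment_positives(dataset, by_id, shifts_s=(-5.0,))
        k2 = sum(p.label == "positive" for p in out.points)
        assert k <= k2 <= 2 * k
        assert sum(p.label == "negative" for p in out.points) == \
            sum(p.label == "negative" for p in dataset.points)
        # every augmented point re-labels positive against truth events
        truth_by_id = {p.patient_id: p.truth for p in cohort}
        for pt in out.points[len(dataset.points):]:
            label, _ = ioh.frame_and_label(
                pt.t_now_s,
                [ev(on, off) for on, off in truth_by_id[pt.patient_id].true_events])
            assert label == "positive"
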