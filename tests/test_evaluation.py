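"""Evaluation: folds, metrics, transfer matrix, standardization, filters."""

import numpy as np
import pytest

import ioh
from test_predictors import mann_whitney_auc


def score_dataset(n_pos=60, n_neg=200, n_patients=20, seed=0, sep=12.0):
    """Labeled dataset of segment means with patient structure."""
    rng = np.random.default_rng(seed)
    pts = []
    for i in range(n_pos + n_neg):
        label = "positive" if i < n_pos else "negative"
        base = 74.0 if label == "positive" else 74.0 + sep
        pts.append(ioh.LabeledDataPoint(
            patient_id=f"p{rng.integers(n_patients):03d}", t_now_s=float(i),
            label=label,
            segment_mean_map_mmHg=float(base + rng.normal(0, 4))))
    return ioh.LabeledDataset(points=pts)


class TestMakeFolds:
    def test_ten_patients_five_folds(self):
        ds = score_dataset(n_patients=10, seed=1)
        folds = ioh.make_folds(ds, k=5, seed=3)
        all_test = [pid for f in folds for pid in f.test_patients]
        assert len(all_test) == len(set(all_test)) == len(ds.patient_ids)
        for f in folds:
            assert len(f.test_patients) == 2
            assert not f.train_patients & f.val_patients
            assert not f.train_patients & f.test_patients
            assert not f.val_patients & f.test_patients
            assert f.train_patients | f.val_patients | f.test_patients == \
                set(ds.patient_ids)

    def test_deterministic(self):
        ds = score_dataset(seed=2)
        a = ioh.make_folds(ds, seed=5)
        b = ioh.make_folds(ds, seed=5)
        assert [f.test_patients for f in a] == [f.test_patients for f in b]

    def test_too_few_patients(self):
        ds = score_dataset(n_patients=3, seed=3)
        with pytest.raises(ValueError):
            ioh.make_folds(ds, k=5)


class TestRocPrAuc:
    def test_perfect_separation(self):
        auc, ap, _ = ioh.roc_pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0 and ap == 1.0

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(4)
        auc, _, _ = ioh.roc_pr_auc(rng.random(4000),
                                   (rng.random(4000) < 0.3).astype(int))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=300)
        labels = (rng.random(300) < 0.4).astype(int)
        auc, _, _ = ioh.roc_pr_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ioh.roc_pr_auc([0.1, 0.9], [1, 1])


class TestOperatingPoint:
    def test_exact_specificity_with_distinct_scores(self):
        rng = np.random.default_rng(6)
        scores = np.concatenate([rng.normal(2, 1, 40), rng.normal(0, 1, 10)])
        labels = np.array([1] * 40 + [0] * 10)
        rep = ioh.operating_point_metrics(scores, labels)
        assert rep.specificity == pytest.approx(0.8, abs=1e-12)
        assert rep.fpr == pytest.approx(1.0 - rep.specificity, abs=1e-12)

    def test_matches_brute_force_confusion_matrix(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=500)
        labels = (rng.random(500) < 0.25).astype(int)
        rep = ioh.operating_point_metrics(scores, labels)
        pred = scores >= rep.threshold
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        fn = np.sum(~pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        assert rep.sensitivity == pytest.approx(tp / (tp + fn))
        assert rep.specificity == pytest.approx(tn / (tn + fp))
        assert rep.ppv == pytest.approx(tp / (tp + fp))
        assert rep.npv == pytest.approx(tn / (tn + fn))
        assert rep.accuracy == pytest.approx((tp + tn) / 500)
        assert rep.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))

    def test_degenerate_scores_flagged(self):
        rep = ioh.operating_point_metrics(np.ones(50), [1] * 25 + [0] * 25)
        assert rep.specificity_warning

    def test_brier_and_calibration_for_probabilities(self):
        rng = np.random.default_rng(8)
        p = rng.random(400)
        y = (rng.random(400) < p).astype(int)
        rep = ioh.operating_point_metrics(p, y)
        assert rep.brier == pytest.approx(np.mean((p - y) ** 2), rel=1e-12)
        assert 0 < len(rep.calibration_curve) <= 10


class TestAggregateFolds:
    def _rep(self, auc):
        return {"auc_roc": auc, "accuracy": 0.8}

    def test_identical_reports_zero_width(self):
        out = ioh.aggregate_folds([self._rep(0.7)] * 5)
        assert out["auc_roc"] == (pytest.approx(0.7), pytest.approx(0.0))

    def test_two_reports_mean(self):
        out = ioh.aggregate_folds([self._rep(0.6), self._rep(0.8)])
        assert out["auc_roc"][0] == pytest.approx(0.7)

    def test_hand_computed_ci(self):
        vals = [0.6, 0.65, 0.7, 0.75, 0.8]
        out = ioh.aggregate_folds([self._rep(v) for v in vals])
        expected = 1.96 * np.std(vals, ddof=1) / np.sqrt(5)
        assert out["auc_roc"][1] == pytest.approx(expected, rel=1e-9)

    def test_single_report_flagged(self):
        out = ioh.aggregate_folds([self._rep(0.7)])
        assert out["ci_undefined"]


class TestCrossDatasetMatrix:
    def test_self_transfer_and_null(self):
        ds_a = score_dataset(seed=10, n_patients=25)
        pts_b = [ioh.LabeledDataPoint(patient_id="q" + p.patient_id,
                                      t_now_s=p.t_now_s, label=p.label,
                                      segment_mean_map_mmHg=p.segment_mean_map_mmHg)
                 for p in score_dataset(seed=11, n_patients=25).points]
        ds_b = ioh.LabeledDataset(points=pts_b)
        matrix = ioh.cross_dataset_matrix({"a": ds_a, "b": ds_b},
                                          ioh.MapThrTrainer(), seed=1)
        assert len(matrix) == 4
        # matched generative parameters: transfer close to within-dataset
        assert abs(matrix[("a", "b")] - matrix[("b", "b")]) < 0.05
        assert abs(matrix[("b", "a")] - matrix[("a", "a")]) < 0.05

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(13)
        ds_a = score_dataset(seed=12, n_patients=25)
        pts = [ioh.LabeledDataPoint(patient_id="q" + p.patient_id,
                                    t_now_s=p.t_now_s,
                                    label=("positive" if rng.random() < 0.25
                                           else "negative"),
                                    segment_mean_map_mmHg=float(rng.uniform(60, 95)))
               for p in score_dataset(seed=14, n_patients=25).points]
        ds_null = ioh.LabeledDataset(points=pts)
        matrix = ioh.cross_dataset_matrix({"a": ds_a, "null": ds_null},
                                          ioh.MapThrTrainer(), seed=2)
        assert matrix[("a", "null")] == pytest.approx(0.5, abs=0.12)

    def test_patient_collision_rejected(self):
        ds = score_dataset(seed=15)
        with pytest.raises(ValueError, match="collision"):
            ioh.cross_dataset_matrix({"a": ds, "b": ds}, ioh.MapThrTrainer())


class TestStandardizeDeltaMean:
    def test_target_zero(self):
        ds = score_dataset(seed=16, n_pos=150, n_neg=600, sep=10.0)
        out = ioh.standardize_delta_mean(ds, 0.0, seed=3)
        assert ioh.delta_mean(out) == pytest.approx(0.0, abs=0.25)

    def test_output_is_subset(self):
        ds = score_dataset(seed=17, n_pos=150, n_neg=600, sep=10.0)
        out = ioh.standardize_delta_mean(ds, 4.0, seed=4)
        keys = {(p.patient_id, p.t_now_s, p.label) for p in ds.points}
        assert all((p.patient_id, p.t_now_s, p.label) in keys for p in out.points)
        assert len(out) <= len(ds)

    def test_infeasible_target_reports_range(self):
        ds = score_dataset(seed=18, n_pos=100, n_neg=300, sep=8.0)
        with pytest.raises(ValueError, match="achievable"):
            ioh.standardize_delta_mean(ds, 60.0)


class TestCohortFilter:
    def _metas(self):
        return [ioh.PatientMeta("a", age_years=55.0, asa_class=2),
                ioh.PatientMeta("b", age_years=60.0, asa_class=2),
                ioh.PatientMeta("c", age_years=67.0, asa_class=3),
                ioh.PatientMeta("d", age_years=30.0, asa_class=1)]

    def test_middle_age_in_neither_cohort(self):
        metas = self._metas()
        young = {m.patient_id for m in ioh.cohort_filter(metas, "age_young")}
        old = {m.patient_id for m in ioh.cohort_filter(metas, "age_old")}
        assert young == {"a", "d"}      # 55 is inclusive
        assert old == {"c"}
        assert "b" not in young | old   # age 60 excluded by both

    def test_asa_filter_and_composition(self):
        metas = self._metas()
        both = ioh.cohort_filter(ioh.cohort_filter(metas, "age_young"), "asa_eq_2")
        combined = ioh.cohort_filter(
            metas, lambda m: 18 <= m.age_years <= 55 and m.asa_class == 2)
        assert {m.patient_id for m in both} == {m.patient_id for m in combined} == {"a"}

    def test_missing_metadata_named(self):
        with pytest.raises(ValueError, match="age_years"):
            ioh.cohort_filter([ioh.PatientMeta("x")], "age_young")
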