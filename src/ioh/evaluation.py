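"""Patient-grouped evaluation: folds, metrics, transfer matrices, controls.

Implements 5-fold patient-grouped cross-validation with a 70/10/20
train/validation/test split, discrimination and calibration metrics at the
80%-specificity operating point, fold aggregation with normal-approximation
95% confidence intervals, train-on-A/test-on-B transfer matrices, the
binned stratified resampling that standardizes the class-separation
statistic, and demographic cohort filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve, \
    precision_recall_curve

from ._validation import check_both_classes
from .predictors import CnnSpec, MapThrModel, TrainConfig, mapthr_score, train_cnn
from .sampling import LabeledDataset
from .types import PatientMeta

TARGET_SPECIFICITY = 0.80
CI_Z = 1.96
CALIBRATION_BINS = 10


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    fold_id: int
    train_patients: set
    val_patients: set
    test_patients: set


def make_folds(dataset: LabeledDataset, k: int = 5,
               fractions: tuple = (0.7, 0.1, 0.2), seed: int = 0) -> list[FoldSplit]:
    """Patient-level k-fold assignment stratified by hypotension prevalence.

    Patients are ordered by their positive-point prevalence (seeded jitter
    breaks ties) and dealt round-robin into k test folds, so each test set
    sees a similar prevalence mix. For each fold the remaining patients are
    split into validation (fractions[1] of all patients) and training.
    """
    ids = dataset.patient_ids
    if len(ids) < k:
        raise ValueError(f"need at least {k} patients, got {len(ids)}")
    rng = np.random.default_rng(seed)
    prevalence = {pid: np.mean([p.label == "positive"
                                for p in dataset.by_patient[pid]]) for pid in ids}
    jitter = {pid: rng.random() for pid in ids}
    ordered = sorted(ids, key=lambda pid: (prevalence[pid], jitter[pid]))
    test_sets = [set(ordered[i::k]) for i in range(k)]

    folds = []
    val_frac_of_rest = fractions[1] / (fractions[0] + fractions[1])
    for fold_id, test in enumerate(test_sets, start=1):
        rest = [pid for pid in ordered if pid not in test]
        n_val = max(int(round(val_frac_of_rest * len(rest))), 1)
        val_pick = rng.permutation(len(rest))[:n_val]
        val = {rest[i] for i in val_pick}
        train = set(rest) - val
        folds.append(FoldSplit(fold_id=fold_id, train_patients=train,
                               val_patients=val, test_patients=test))
    return folds


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_pr_auc(scores, labels):
    """ROC-AUC and PR-AUC with the underlying curve points.

    Returns ``(auc_roc, auc_pr, curves)`` where curves maps "roc" to
    (fpr, tpr, thresholds) and "pr" to (precision, recall, thresholds).
    """
    labels = np.asarray(labels)
    check_both_classes(labels, "labels")
    auc_roc = float(roc_auc_score(labels, scores))
    auc_pr = float(average_precision_score(labels, scores))
    curves = {"roc": roc_curve(labels, scores),
              "pr": precision_recall_curve(labels, scores)}
    return auc_roc, auc_pr, curves


@dataclass
class MetricsReport:
    auc_roc: float
    auc_pr: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    fpr: float
    brier: float
    threshold: float
    calibration_curve: list = field(default_factory=list)
    specificity_warning: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def operating_point_metrics(scores, labels,
                            target_specificity: float = TARGET_SPECIFICITY,
                            threshold: float | None = None) -> MetricsReport:
    """All point metrics at the cutoff fixing specificity at the target.

    The cutoff is the smallest observed score such that at least
    ``target_specificity`` of the negatives score below it, selected on the
    evaluated score set itself; predictions at or above the cutoff are
    positive. Pass ``threshold`` to reuse a cutoff chosen elsewhere (e.g. on
    a validation set). When scores look like probabilities the Brier score
    and a 10-bin calibration curve are included.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    check_both_classes(labels, "labels")
    neg = np.sort(scores[labels == 0])
    n_neg = len(neg)
    warning = False
    if threshold is None:
        need = int(np.ceil(target_specificity * n_neg))
        if need >= n_neg:
            threshold = neg[-1] + 1.0
            warning = True
        else:
            threshold = float(neg[need])
        if np.sum(neg < threshold) / n_neg < target_specificity:
            warning = True     # heavy ties: target unreachable exactly

    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    f1 = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
    auc_roc, auc_pr, _ = roc_pr_auc(scores, labels)

    probabilistic = np.all((scores >= 0) & (scores <= 1))
    brier = float(np.mean((scores - (labels == 1)) ** 2)) if probabilistic else np.nan
    calib = []
    if probabilistic:
        edges = np.linspace(0, 1, CALIBRATION_BINS + 1)
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = (scores >= lo) & (scores < hi if hi < 1 else scores <= hi)
            if in_bin.any():
                calib.append((float(scores[in_bin].mean()),
                              float(np.mean(labels[in_bin] == 1))))
    return MetricsReport(auc_roc=auc_roc, auc_pr=auc_pr,
                         accuracy=(tp + tn) / len(labels),
                         sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
                         f1=f1, fpr=1.0 - spec, brier=brier,
                         threshold=float(threshold), calibration_curve=calib,
                         specificity_warning=warning)


def aggregate_folds(reports: list) -> dict:
    """Mean and 95% CI half-width (1.96 * sd / sqrt(k)) per scalar metric.

    A single report yields NaN half-widths with a flag in the result.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    dicts = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in reports]
    k = len(dicts)
    out = {"n_folds": k, "ci_undefined": k < 2}
    for key in dicts[0]:
        vals = [d[key] for d in dicts]
        if not all(isinstance(v, (int, float, np.floating)) for v in vals):
            continue
        vals = np.asarray(vals, dtype=float)
        mean = float(np.mean(vals))
        half = float(CI_Z * np.std(vals, ddof=1) / np.sqrt(k)) if k > 1 else np.nan
        out[key] = (mean, half)
    return out


# ---------------------------------------------------------------------------
# Trainers (uniform interface over both predictors)
# ---------------------------------------------------------------------------

class MapThrTrainer:
    """Training-free baseline: scores are negated segment mean MAPs."""

    def fit(self, train_ds: LabeledDataset, val_ds: LabeledDataset, seed: int):
        return MapThrModel()

    def score(self, model, ds: LabeledDataset) -> np.ndarray:
        return mapthr_score(ds.segment_means())


class CnnTrainer:
    """Trains the 1-D CNN on stored 20 s segments."""

    def __init__(self, spec: CnnSpec | None = None,
                 config: TrainConfig | None = None):
        self.spec = spec or CnnSpec()
        self.config = config or TrainConfig()

    @staticmethod
    def _segments(ds: LabeledDataset) -> np.ndarray:
        segs = [p.segment for p in ds.points]
        if any(s is None for s in segs):
            raise ValueError("dataset lacks waveform segments; CNN needs them")
        return np.stack(segs)

    def fit(self, train_ds, val_ds, seed: int):
        cfg = TrainConfig(**{**asdict(self.config), "seed": int(seed)})
        return train_cnn(self._segments(train_ds), train_ds.labels(),
                         self._segments(val_ds), val_ds.labels(),
                         spec=self.spec, config=cfg)

    def score(self, model, ds: LabeledDataset) -> np.ndarray:
        return model.predict_proba(self._segments(ds))


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def crossval_auc(dataset: LabeledDataset, trainer, seed: int = 0,
                 k: int = 5) -> dict:
    """Within-dataset patient-grouped k-fold CV; returns aggregate AUCs."""
    folds = make_folds(dataset, k=k, seed=seed)
    aucs = []
    for fold in folds:
        model = trainer.fit(dataset.subset(fold.train_patients),
                            dataset.subset(fold.val_patients), seed + fold.fold_id)
        test = dataset.subset(fold.test_patients)
        scores = trainer.score(model, test)
        aucs.append(float(roc_auc_score(test.labels(), scores)))
    arr = np.asarray(aucs)
    return {"auc_mean": float(arr.mean()),
            "auc_ci": float(CI_Z * arr.std(ddof=1) / np.sqrt(k)),
            "fold_aucs": aucs}


def cross_dataset_matrix(datasets: dict, trainer, seed: int = 0,
                         k: int = 5) -> dict:
    """Train-on-row, test-on-column ROC-AUC matrix.

    Diagonal cells are within-dataset k-fold CV means; off-diagonal cells
    train on the full source (with an internal validation split) and test on
    the full target. Patient identifiers must be unique across datasets.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    seen: dict[str, str] = {}
    for name, ds in datasets.items():
        for pid in ds.patient_ids:
            if pid in seen and seen[pid] != name:
                raise ValueError(f"patient id collision across datasets: {pid}")
            seen[pid] = name

    matrix = {}
    for src_name, src in datasets.items():
        for tgt_name, tgt in datasets.items():
            if src_name == tgt_name:
                matrix[(src_name, tgt_name)] = crossval_auc(
                    src, trainer, seed=seed, k=k)["auc_mean"]
            else:
                rng = np.random.default_rng(seed)
                ids = src.patient_ids
                n_val = max(int(round(0.125 * len(ids))), 1)
                val_ids = set(np.asarray(ids)[rng.permutation(len(ids))[:n_val]])
                model = trainer.fit(src.subset(set(ids) - val_ids),
                                    src.subset(val_ids), seed)
                scores = trainer.score(model, tgt)
                matrix[(src_name, tgt_name)] = float(
                    roc_auc_score(tgt.labels(), scores))
    return matrix


# ---------------------------------------------------------------------------
# Class-separation standardization
# ---------------------------------------------------------------------------

def standardize_delta_mean(dataset: LabeledDataset, target_delta: float,
                           bin_width: float = 2.5, seed: int = 0,
                           tolerance: float = 0.25) -> LabeledDataset:
    """Resample so the class-separation statistic hits ``target_delta``.

    Points are binned by segment mean MAP. Positives are kept in full
    (uniform resampling); negative per-bin quotas follow an exponential tilt
    on the bin index, with the tilt parameter found by bisection so the
    expected resampled negative mean lands at (positive mean + target).
    Sampling is without replacement and seeded; the output is a subset of
    the input. Raises with the achievable range when the target is
    infeasible.
    """
    if target_delta < 0:
        raise ValueError("target_delta must be >= 0")
    pos = [p for p in dataset.points if p.label == "positive"]
    neg = [p for p in dataset.points if p.label == "negative"]
    if not pos or not neg:
        raise ValueError("both classes required")
    pos_mean = float(np.mean([p.segment_mean_map_mmHg for p in pos]))
    target_neg_mean = pos_mean + target_delta

    neg_maps = np.asarray([p.segment_mean_map_mmHg for p in neg])
    lo = np.floor(neg_maps.min() / bin_width) * bin_width
    bins = np.floor((neg_maps - lo) / bin_width).astype(int)
    m = bins.max() + 1
    counts = np.bincount(bins, minlength=m).astype(float)
    sums = np.bincount(bins, weights=neg_maps, minlength=m)
    with np.errstate(invalid="ignore"):
        mu = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    j = np.arange(m, dtype=float)

    def expected_mean(beta: float) -> float:
        w = counts * np.exp(-beta * (j - (0.0 if beta >= 0 else m - 1)))
        return float(np.sum(w * mu) / np.sum(w))

    b_lo, b_hi = -50.0, 50.0
    reach_hi, reach_lo = expected_mean(b_lo), expected_mean(b_hi)
    if not (reach_lo - 1e-9 <= target_neg_mean <= reach_hi + 1e-9):
        raise ValueError(
            "infeasible target: achievable class separation in "
            f"[{reach_lo - pos_mean:.2f}, {reach_hi - pos_mean:.2f}] mmHg, "
            f"requested {target_delta:.2f}")
    for _ in range(200):      # expected_mean decreases in beta
        mid = 0.5 * (b_lo + b_hi)
        if expected_mean(mid) > target_neg_mean:
            b_lo = mid
        else:
            b_hi = mid
    beta = 0.5 * (b_lo + b_hi)

    w = counts * np.exp(-beta * (j - (0.0 if beta >= 0 else m - 1)))
    quotas = np.minimum(np.round(w).astype(int), counts.astype(int))
    rng = np.random.default_rng(seed)
    chosen = []
    for bin_idx in range(m):
        members = [i for i, b in enumerate(bins) if b == bin_idx]
        q = quotas[bin_idx]
        if q <= 0 or not members:
            continue
        pick = rng.choice(len(members), size=min(q, len(members)), replace=False)
        chosen.extend(neg[members[i]] for i in pick)
    if not chosen:
        raise ValueError("resampling produced no negatives; widen bins")

    out = LabeledDataset(points=pos + chosen,
                         provenance={**dataset.provenance,
                                     "standardization": {
                                         "target_delta": target_delta,
                                         "bin_width": bin_width,
                                         "beta": beta, "seed": int(seed)}})
    achieved = (float(np.mean([p.segment_mean_map_mmHg for p in chosen]))
                - pos_mean)
    if abs(achieved - target_delta) > tolerance:
        raise ValueError(f"standardization missed target: achieved "
                         f"{achieved:.3f} vs {target_delta:.3f} "
                         f"(tolerance {tolerance})")
    return out


# ---------------------------------------------------------------------------
# Cohort filters
# ---------------------------------------------------------------------------

AGE_YOUNG = (18.0, 55.0)     # inclusive bounds
AGE_OLD_MIN = 67.0           # ages 56-66 belong to neither cohort


def cohort_filter(patients, criterion):
    """Select patients by demographic criterion.

    ``criterion`` is "age_young" (18-55 inclusive), "age_old" (>= 67),
    "asa_eq_2", or a callable on :class:`PatientMeta`. Items may be
    PatientMeta or any object with a ``meta`` attribute. Missing metadata
    raises naming the field.
    """
    def meta_of(p) -> PatientMeta:
        return p if isinstance(p, PatientMeta) else p.meta

    def pred(meta: PatientMeta) -> bool:
        if callable(criterion):
            return bool(criterion(meta))
        if criterion in ("age_young", "age_old"):
            if meta is None or not np.isfinite(meta.age_years):
                raise ValueError("missing metadata field: age_years")
            if criterion == "age_young":
                return AGE_YOUNG[0] <= meta.age_years <= AGE_YOUNG[1]
            return meta.age_years >= AGE_OLD_MIN
        if criterion == "asa_eq_2":
            if meta is None or meta.asa_class < 0:
                raise ValueError("missing metadata field: asa_class")
            return meta.asa_class == 2
        raise ValueError(f"unknown criterion: {criterion}")

    return [p for p in patients if pred(meta_of(p))]
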