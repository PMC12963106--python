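"""MAP-threshold baseline classifier.

The simplest clinically grounded predictor: compare the mean MAP of the
20-second input segment against a threshold (thresholds 55-85 mmHg cover
the plausible operating range). Lower MAP means higher hypotension risk, so
the continuous risk score is the negated mean MAP; sweeping the threshold
over the observed range traces out the same ROC curve as ranking by that
score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SWEEP_RANGE_MMHG = (55.0, 85.0)


def mapthr_score(segment_mean_map):
    """Risk score: negated mean MAP (monotone decreasing in MAP)."""
    arr = np.asarray(segment_mean_map, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("segment mean MAP must be finite")
    return -arr


def mapthr_classify(segment_mean_map, threshold_mmHg: float):
    """Classify: mean MAP above the threshold is non-hypotension (negative).

    Ties classify positive (alarm-conservative). Returns 1 for positive,
    0 for negative; scalar in, scalar out.
    """
    arr = np.asarray(segment_mean_map, dtype=float)
    out = (arr <= threshold_mmHg).astype(int)
    return int(out) if np.isscalar(segment_mean_map) else out


@dataclass
class MapThrModel:
    """Threshold rule in score mode (threshold=None) or classify mode."""

    threshold_mmHg: float | None = None
    sweep_range: tuple = SWEEP_RANGE_MMHG

    def __post_init__(self) -> None:
        if self.threshold_mmHg is not None and not (
                self.sweep_range[0] <= self.threshold_mmHg <= self.sweep_range[1]):
            raise ValueError("threshold outside sweep range")

    def predict_scores(self, segment_mean_map) -> np.ndarray:
        return mapthr_score(segment_mean_map)

    def predict_labels(self, segment_mean_map) -> np.ndarray:
        if self.threshold_mmHg is None:
            raise ValueError("no threshold set; model is in score mode")
        return mapthr_classify(segment_mean_map, self.threshold_mmHg)
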