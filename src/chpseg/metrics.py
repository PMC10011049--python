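"""Volumetric evaluation: per-subject overlap and volume-error scores,

cohort mean +- SEM, and predicted-vs-reference volume correlation.

With X the predicted mask and Y the ground truth (x_i, y_i their voxels):

    Dice      = 2 * sum_i min(x_i, y_i) / (sum_i x_i + sum_i y_i)
    Recall    = sum_i x_i y_i / sum_i y_i
    Precision = sum_i x_i y_i / sum_i x_i
    VER       = (sum_i x_i - sum_i y_i) / sum_i y_i      (signed)
    AVER      = |VER|

Cohort results are mean +- standard error of the mean (sample std / sqrt(n)),
and the agreement between predicted and reference volumes is summarized with
Pearson's r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from chpseg.io_preproc import LabelMask

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricsRow:
    subject_id: str
    dice: float
    recall: float
    precision: float
    ver: float
    aver: float
    predicted_voxels: int
    reference_voxels: int
    voxel_volume_mm3: float = 1.0

    @property
    def predicted_mm3(self) -> float:
        return self.predicted_voxels * self.voxel_volume_mm3

    @property
    def reference_mm3(self) -> float:
        return self.reference_voxels * self.voxel_volume_mm3


@dataclass(frozen=True)
class CohortReport:
    n_subjects: int
    mean: dict[str, float]
    sem: dict[str, float]
    pearson_r: float | None


def _as_binary(x) -> np.ndarray:
    g = x.grid if isinstance(x, LabelMask) else np.asarray(x)
    return np.asarray(g, dtype=np.float64)


def _check(x, y):
    x, y = _as_binary(x), _as_binary(y)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    return x, y


def dice_score(x, y) -> float:
    """Overlap Dice (min formulation); two empty masks score 1 (flagged)."""
    x, y = _check(x, y)
    denom = x.sum() + y.sum()
    if denom == 0:
        log.warning("both masks empty: Dice defined as 1 by convention")
        return 1.0
    return float(2.0 * np.minimum(x, y).sum() / denom)


def recall(x, y) -> float:
    """|X & Y| / |Y|; undefined when the ground truth is empty."""
    x, y = _check(x, y)
    ys = y.sum()
    if ys == 0:
        raise ValueError("recall undefined: ground-truth mask is empty")
    return float((x * y).sum() / ys)


def precision(x, y) -> float:
    """|X & Y| / |X|; undefined when the prediction is empty."""
    x, y = _check(x, y)
    xs = x.sum()
    if xs == 0:
        raise ValueError("precision undefined: predicted mask is empty")
    return float((x * y).sum() / xs)


def volume_error_rate(x, y) -> tuple[float, float]:
    """(VER, AVER): signed and absolute relative volume error of X vs Y."""
    x, y = _check(x, y)
    ys = y.sum()
    if ys == 0:
        raise ValueError("volume error rate undefined: ground-truth mask is empty")
    ver = float((x.sum() - ys) / ys)
    return ver, abs(ver)


def evaluate_pair(subject_id: str, pred: LabelMask, ref: LabelMask) -> MetricsRow:
    """All per-subject scores for one prediction/ground-truth pair."""
    x, y = _check(pred, ref)
    ver, aver = volume_error_rate(pred, ref)
    voxel_mm3 = float(np.prod(ref.spacing)) if isinstance(ref, LabelMask) else 1.0
    return MetricsRow(
        subject_id=subject_id,
        dice=dice_score(pred, ref),
        recall=recall(pred, ref),
        precision=precision(pred, ref) if x.sum() > 0 else 0.0,
        ver=ver,
        aver=aver,
        predicted_voxels=int(x.sum()),
        reference_voxels=int(y.sum()),
        voxel_volume_mm3=voxel_mm3,
    )


_SCORES = ("dice", "recall", "precision", "ver", "aver")


def cohort_summary(rows: list[MetricsRow]) -> CohortReport:
    """Cohort mean +- SEM per score, plus Pearson's r between predicted and

    reference volumes.  SEM needs n >= 2; r needs n >= 3 and non-constant
    volumes on both sides (otherwise it is reported as None with a warning
    for degenerate volume spreads, or raised for insufficient n).
    """
    n = len(rows)
    if n < 2:
        raise ValueError("undefined statistic SEM: need at least 2 subjects")
    mean, sem = {}, {}
    for s in _SCORES:
        vals = np.array([getattr(r, s) for r in rows], dtype=float)
        mean[s] = float(vals.mean())
        sem[s] = float(vals.std(ddof=1) / np.sqrt(n))
    pv = np.array([r.predicted_voxels for r in rows], dtype=float)
    rv = np.array([r.reference_voxels for r in rows], dtype=float)
    if n < 3:
        raise ValueError("undefined statistic pearson_r: need at least 3 subjects")
    if np.ptp(pv) == 0 or np.ptp(rv) == 0:
        log.warning("constant volumes across the cohort: Pearson r undefined")
        r = None
    else:
        r = float(stats.pearsonr(pv, rv).statistic)
    return CohortReport(n_subjects=n, mean=mean, sem=sem, pearson_r=r)
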