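"""Sample-level agreement between detected and ground-truth label sequences.

Implements Cohen's kappa, the multiclass Matthews correlation coefficient,
the complementary normalized Levenshtein distance (1-NLD), and per-class
signal-detection d' with the Hautus log-linear correction at extreme rates.
Ground-truth UNDEFINED samples carry no truth value and are excluded
pairwise by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import AlignmentError, EventLabel

__all__ = [
    "SDTCounts",
    "confusion_matrix",
    "cohens_kappa",
    "mcc",
    "one_minus_nld",
    "sample_dprime",
    "agreement_report",
]


@dataclass(frozen=True)
class SDTCounts:
    """Signal-detection counts with derived rates and sensitivity.

    ``negatives`` is the denominator of the false-alarm rate (correct
    rejections + false alarms at the sample level; the negative-window
    count at the boundary level).  ``d'`` is ``z(TPr) - z(FAr)``; when any
    rate is extreme (0 or 1, including the no-hits / no-false-alarms
    cases), the log-linear correction adds 0.5 to the hit and false-alarm
    counts and 1 to the positive and negative totals before taking
    quantiles, keeping d' finite.
    """

    hits: int
    misses: int
    false_alarms: int
    negatives: int
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.false_alarms, self.negatives) < 0:
            raise ValueError("SDT counts must be non-negative")

    @property
    def n_positives(self) -> int:
        return self.hits + self.misses

    @property
    def tpr(self) -> float:
        return self.hits / self.n_positives if self.n_positives else math.nan

    @property
    def far(self) -> float:
        return self.false_alarms / self.negatives if self.negatives else math.nan

    @property
    def ppv(self) -> float:
        denom = self.hits + self.false_alarms
        return self.hits / denom if denom else math.nan

    @property
    def f1(self) -> float:
        p, r = self.ppv, self.tpr
        if math.isnan(p) or math.isnan(r) or (p + r) == 0:
            return math.nan
        return 2 * p * r / (p + r)

    @property
    def dprime(self) -> float:
        if self.n_positives == 0 or self.negatives == 0:
            return math.nan
        tpr, far = self.tpr, self.far
        if self.corrected or tpr in (0.0, 1.0) or far in (0.0, 1.0):
            tpr = (self.hits + 0.5) / (self.n_positives + 1)
            far = (self.false_alarms + 0.5) / (self.negatives + 1)
        return float(norm.ppf(tpr) - norm.ppf(far))

    def to_dict(self) -> dict:
        return {
            "hits": self.hits,
            "misses": self.misses,
            "false_alarms": self.false_alarms,
            "negatives": self.negatives,
            "tpr": self.tpr,
            "far": self.far,
            "ppv": self.ppv,
            "f1": self.f1,
            "dprime": self.dprime,
        }


def _paired(
    gt: np.ndarray, pred: np.ndarray, exclude_undefined: bool
) -> tuple[np.ndarray, np.ndarray]:
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.size != pred.size:
        raise AlignmentError(f"sequence lengths differ: {gt.size} vs {pred.size}")
    if exclude_undefined:
        keep = gt != int(EventLabel.UNDEFINED)
        gt, pred = gt[keep], pred[keep]
    return gt, pred


def confusion_matrix(
    gt: np.ndarray, pred: np.ndarray, exclude_undefined: bool = True
) -> pd.DataFrame:
    """Square count table over the labels present in either sequence (GT rows)."""
    gt, pred = _paired(gt, pred, exclude_undefined)
    classes = np.union1d(np.unique(gt), np.unique(pred))
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((classes.size, classes.size), dtype=int)
    for g, p in zip(gt, pred):
        cm[idx[g], idx[p]] += 1
    names = [EventLabel(int(c)).name for c in classes]
    return pd.DataFrame(cm, index=names, columns=names)


def cohens_kappa(
    gt: np.ndarray, pred: np.ndarray, exclude_undefined: bool = True
) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e)."""
    cm = confusion_matrix(gt, pred, exclude_undefined).to_numpy(dtype=float)
    n = cm.sum()
    if n == 0:
        return math.nan
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n))
    if p_e == 1.0:
        warnings.warn("kappa undefined: expected agreement is 1", stacklevel=2)
        return math.nan
    return float((p_o - p_e) / (1.0 - p_e))


def mcc(gt: np.ndarray, pred: np.ndarray, exclude_undefined: bool = True) -> float:
    """Multiclass Matthews correlation coefficient (covariance form).

    A zero-variance denominator (a constant sequence on either side)
    conventionally yields 0, with a warning.
    """
    cm = confusion_matrix(gt, pred, exclude_undefined).to_numpy(dtype=float)
    s = cm.sum()
    c = np.trace(cm)
    t = cm.sum(axis=1)  # GT marginals
    p = cm.sum(axis=0)  # prediction marginals
    cov_yp = c * s - t @ p
    denom = math.sqrt((s**2 - p @ p) * (s**2 - t @ t))
    if denom == 0:
        warnings.warn("MCC denominator is zero; returning 0", stacklevel=2)
        return 0.0
    return float(cov_yp / denom)


def one_minus_nld(gt: np.ndarray, pred: np.ndarray) -> float:
    """1 - normalized Levenshtein distance between the two label strings.

    Unit-cost insert/delete/substitute edit distance, normalized by the
    longer sequence's length.  Two empty sequences score 1 by convention.
    UNDEFINED samples are kept: edit distance is a whole-string measure
    and dropping positions would change its meaning.
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.size == 0 and pred.size == 0:
        return 1.0
    a = "".join(chr(65 + int(v)) for v in gt)
    b = "".join(chr(65 + int(v)) for v in pred)
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def sample_dprime(
    gt: np.ndarray,
    pred: np.ndarray,
    positive: EventLabel,
    exclude_undefined: bool = True,
) -> SDTCounts:
    """Per-class sample-level signal-detection counts and d'.

    A predicted-positive sample matching the GT is a hit, otherwise a
    false alarm; GT-positive samples the detector missed are misses; all
    GT-negative samples form the negative total.
    """
    gt, pred = _paired(gt, pred, exclude_undefined)
    pos = int(positive)
    hits = int(np.sum((pred == pos) & (gt == pos)))
    false_alarms = int(np.sum((pred == pos) & (gt != pos)))
    misses = int(np.sum((gt == pos) & (pred != pos)))
    negatives = int(np.sum(gt != pos))
    return SDTCounts(hits, misses, false_alarms, negatives)


def agreement_report(
    gt: np.ndarray,
    pred: np.ndarray,
    positives: tuple[EventLabel, ...] = (EventLabel.FIXATION, EventLabel.SACCADE),
    exclude_undefined: bool = True,
) -> dict:
    """All sample-level metrics plus the confusion matrix, in one record."""
    cm = confusion_matrix(gt, pred, exclude_undefined)
    report = {
        "cohens_kappa": cohens_kappa(gt, pred, exclude_undefined),
        "mcc": mcc(gt, pred, exclude_undefined),
        "one_minus_nld": one_minus_nld(gt, pred),
        "confusion_matrix": cm,
        "dprime": {},
    }
    for label in positives:
        counts = sample_dprime(gt, pred, label, exclude_undefined)
        report["dprime"][label.name] = counts.to_dict() if counts.n_positives else None
    return report
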