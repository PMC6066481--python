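"""ROC-based cutoff selection and marker dichotomization.

The assay cutoff between low and high expressors is chosen by maximizing
the Youden index J = sensitivity + specificity - 1 over the observed score
values, with a positive call defined as score >= threshold.  That makes
the selected cutoff directly usable with the >= dichotomization rule the
clinical test applies (value >= cutoff -> 'H+').

The default published cutoff consumed downstream is 1100 NCN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateLabelsError, InvalidInputError

__all__ = [
    "PUBLISHED_CUTOFF_NCN",
    "RocCurve",
    "ThresholdResult",
    "roc_curve",
    "youden_threshold",
    "dichotomize",
    "dead_at_horizon",
]

PUBLISHED_CUTOFF_NCN = 1100.0


@dataclass
class RocCurve:
    thresholds: np.ndarray   # descending candidate thresholds (observed scores)
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass
class ThresholdResult:
    cutoff: float
    youden_j: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float


def roc_curve(scores, labels) -> RocCurve:
    """ROC over the observed score values with the >= calling rule.

    ``labels`` are binary outcomes (1 = positive class).  Sensitivity and
    specificity are evaluated at every distinct observed score; the AUC is
    the trapezoidal area of the resulting curve (equal to the
    Mann–Whitney U probability with ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise InvalidInputError("scores and labels must be aligned 1-d arrays")
    if not np.all(np.isfinite(scores)):
        raise InvalidInputError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both outcome classes must be present")

    thresholds = np.unique(scores)[::-1]
    pos_sorted = np.sort(scores[labels == 1])
    neg_sorted = np.sort(scores[labels == 0])
    # calls at threshold t: score >= t
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="left")
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg

    # trapezoidal AUC over (FPR, TPR), closing the curve at (0,0) and (1,1)
    fpr = np.concatenate(([0.0], 1 - spec, [1.0]))
    tpr = np.concatenate(([0.0], sens, [1.0]))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, sens, spec, auc)


def youden_threshold(roc: RocCurve) -> ThresholdResult:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Ties in the maximal J are broken toward the smallest qualifying
    threshold (the more sensitive call).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best_j = j.max()
    # thresholds are descending; the last argmax is the smallest threshold
    idx = np.where(j >= best_j - 1e-12)[0][-1]
    return ThresholdResult(
        cutoff=float(roc.thresholds[idx]),
        youden_j=float(j[idx]),
        sensitivity_at_cutoff=float(roc.sensitivity[idx]),
        specificity_at_cutoff=float(roc.specificity[idx]),
    )


def dichotomize(values, cutoff: float) -> pd.Series:
    """Marker status per sample: 'H+' iff value >= cutoff, 'H-' below.

    Missing values yield the status '' (unset); their count is reported by
    the caller when excluding them downstream.
    """
    if not np.isfinite(cutoff):
        raise InvalidInputError("cutoff must be finite")
    values = pd.Series(values, dtype=float)
    status = pd.Series("", index=values.index, dtype=object)
    ok = values.notna()
    status[ok & (values >= cutoff)] = "H+"
    status[ok & (values < cutoff)] = "H-"
    return status


def dead_at_horizon(os_time, os_event, horizon: float) -> pd.Series:
    """Binary ROC outcome: dead by the horizon vs alive with adequate follow-up.

    Patients censored before the horizon are excluded (NaN) because their
    vital status at the horizon is unknown.
    """
    if horizon <= 0:
        raise InvalidInputError("horizon must be > 0")
    os_time = pd.Series(os_time, dtype=float)
    os_event = pd.Series(os_event).astype(int)
    out = pd.Series(np.nan, index=os_time.index)
    dead_by = (os_event == 1) & (os_time <= horizon)
    alive_through = os_time >= horizon
    out[dead_by] = 1.0
    out[alive_through & ~dead_by] = 0.0
    return out
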