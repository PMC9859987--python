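"""Evaluation statistics: ROC/AUC against responder labels, planned-vs-delivered t-tests.

AUC uses midrank tie handling (equal to the Mann-Whitney probability that a
random responder outscores a random non-responder, with half credit for
ties).  The planned-vs-delivered comparison defaults to a paired t-test
(plans and delivered doses are matched per patient); a two-sample mode is
also available and the output names the mode used.  No multiple-testing
correction is applied; p-values are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["ROCResult", "PairedComparison", "roc_auc", "compare_ntcp", "evaluate_cohort"]


@dataclass
class ROCResult:
    """ROC curve and its area for a set of scores against binary labels."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int

    @property
    def curve(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


@dataclass
class PairedComparison:
    """t-test comparison of two score vectors (e.g. planned vs delivered NTCP)."""

    mean_diff: float
    t_stat: float
    p_value: float
    n: int
    mode: str
    degenerate: bool = False


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC of continuous scores against boolean labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an ROC curve")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr, n_pos=n_pos, n_neg=n_neg)


def compare_ntcp(planned, delivered, mode: str = "paired") -> PairedComparison:
    """Compare two NTCP (or metric) vectors with a t-test.

    ``mode="paired"`` (default) tests the per-patient differences
    delivered - planned against zero; ``mode="two-sample"`` uses an unpaired
    t-test.  Zero-variance paired differences are flagged degenerate: p = 1
    when there is literally no difference, p = nan for a constant nonzero
    shift (the test statistic is undefined, not infinitely significant).
    """
    planned = np.asarray(planned, dtype=float)
    delivered = np.asarray(delivered, dtype=float)
    if mode == "paired":
        if planned.shape != delivered.shape:
            raise ValueError("paired mode requires equal-length vectors")
        if planned.size < 2:
            raise ValueError("need at least two pairs")
        diffs = delivered - planned
        mean_diff = float(diffs.mean())
        if np.std(diffs, ddof=1) == 0.0:
            if mean_diff == 0.0:
                return PairedComparison(0.0, 0.0, 1.0, planned.size, mode, degenerate=True)
            return PairedComparison(
                mean_diff, float("nan"), float("nan"), planned.size, mode, degenerate=True
            )
        t, p = stats.ttest_rel(delivered, planned)
        return PairedComparison(mean_diff, float(t), float(p), planned.size, mode)
    if mode == "two-sample":
        if planned.size < 2 or delivered.size < 2:
            raise ValueError("need at least two observations per group")
        mean_diff = float(delivered.mean() - planned.mean())
        if np.std(planned, ddof=1) == 0.0 and np.std(delivered, ddof=1) == 0.0:
            p_val = 1.0 if mean_diff == 0.0 else float("nan")
            t_val = 0.0 if mean_diff == 0.0 else float("nan")
            return PairedComparison(
                mean_diff, t_val, p_val, planned.size + delivered.size, mode,
                degenerate=True,
            )
        t, p = stats.ttest_ind(delivered, planned)
        return PairedComparison(mean_diff, float(t), float(p), planned.size + delivered.size, mode)
    raise ValueError("mode must be 'paired' or 'two-sample'")


def evaluate_cohort(
    planned_scores, delivered_scores, labels, *, organ: str = "", mode: str = "paired"
) -> dict:
    """Summary block for one organ: NTCP mean +/- SD, t-test, AUCs.

    Shapes the per-organ report row: mean and SD of planned and delivered
    NTCP, the planned-vs-delivered p-value, and the AUC of each score set
    against the responder labels.
    """
    planned_scores = np.asarray(planned_scores, dtype=float)
    delivered_scores = np.asarray(delivered_scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    comp = compare_ntcp(planned_scores, delivered_scores, mode=mode)
    return {
        "organ": organ,
        "n": int(labels.size),
        "n_responders": int(labels.sum()),
        "planned_ntcp_mean": float(planned_scores.mean()),
        "planned_ntcp_sd": float(planned_scores.std(ddof=1)),
        "delivered_ntcp_mean": float(delivered_scores.mean()),
        "delivered_ntcp_sd": float(delivered_scores.std(ddof=1)),
        "t_mode": comp.mode,
        "t_stat": comp.t_stat,
        "p_value": comp.p_value,
        "degenerate": comp.degenerate,
        "auc_planned": roc_auc(planned_scores, labels).auc,
        "auc_delivered": roc_auc(delivered_scores, labels).auc,
        "multiple_testing_correction": "none (raw p-values)",
    }
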