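"""ROC curves and AUC with confidence intervals for score-based discrimination.

The AUC is computed as the Mann-Whitney statistic via midranks — the
probability that a random case outscores a random control, counting ties as
half — so it is exact under ties and invariant to any strictly increasing
transform of the scores. Confidence intervals: DeLong (paired placements,
the default) or Hanley-McNeil (distribution-free approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RocResult", "auc_mann_whitney", "auc_ci", "roc_curve", "roc_analysis"]

_Z95 = 1.959963984540054


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    curve: np.ndarray  # (k, 2) array of (FPR, TPR), from (0,0) to (1,1)
    ci_method: str = "delong"


def _split(scores: np.ndarray, status: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    if scores.shape != status.shape:
        raise ValueError("scores and status must have equal length")
    cases = scores[status == 1]
    controls = scores[status == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def auc_mann_whitney(scores: np.ndarray, status: np.ndarray) -> float:
    """AUC = P(score_case > score_control) + 0.5 P(tie), via midranks."""
    cases, controls = _split(scores, status)
    n1, n0 = cases.size, controls.size
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_var(cases: np.ndarray, controls: np.ndarray, auc: float) -> float:
    n1, n0 = cases.size, controls.size
    # placements by midranks: rank of each case among controls and vice versa
    all_ranks = stats.rankdata(np.concatenate([cases, controls]))
    case_ranks = stats.rankdata(cases)
    control_ranks = stats.rankdata(controls)
    v10 = (all_ranks[:n1] - case_ranks) / n0          # per-case placement
    v01 = 1.0 - (all_ranks[n1:] - control_ranks) / n1  # per-control placement
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return s10 / n1 + s01 / n0


def auc_ci(
    auc: float,
    n_case: int,
    n_control: int,
    method: str = "delong",
    scores: np.ndarray | None = None,
    status: np.ndarray | None = None,
) -> tuple[float, float]:
    """95% CI for an AUC.

    ``hanley`` needs only the AUC and the two class sizes; ``delong`` needs
    the raw scores/status to form the paired placements. Degenerate AUCs (0
    or 1) yield a clipped interval.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need at least 2 subjects per class")
    if method == "hanley":
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc * auc / (1.0 + auc)
        var = (
            auc * (1 - auc)
            + (n_case - 1) * (q1 - auc * auc)
            + (n_control - 1) * (q2 - auc * auc)
        ) / (n_case * n_control)
    elif method == "delong":
        if scores is None or status is None:
            raise ValueError("delong CI needs scores and status")
        cases, controls = _split(scores, status)
        var = _delong_var(cases, controls, auc)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    half = _Z95 * float(np.sqrt(max(var, 0.0)))
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_curve(scores: np.ndarray, status: np.ndarray) -> np.ndarray:
    """Full threshold sweep: (FPR, TPR) points from (0,0) to (1,1).

    Every unique score is a threshold (no vertex dropping), so the
    trapezoidal area under the returned polyline equals the midrank AUC
    exactly.
    """
    from sklearn.metrics import roc_curve as _sk_roc

    _split(scores, status)  # validation
    fpr, tpr, _ = _sk_roc(status, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def roc_analysis(scores: np.ndarray, status: np.ndarray,
                 ci_method: str = "delong") -> RocResult:
    """AUC, 95% CI and the full ROC polyline in one call."""
    cases, controls = _split(scores, status)
    auc = auc_mann_whitney(scores, status)
    ci = auc_ci(auc, cases.size, controls.size, method=ci_method,
                scores=scores, status=status)
    return RocResult(
        auc=auc, ci_low=ci[0], ci_high=ci[1],
        curve=roc_curve(scores, status), ci_method=ci_method,
    )
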