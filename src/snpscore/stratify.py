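"""Score binning, per-stratum disease likelihood, trend tests, between-stratum ORs.

"Likelihood" here is the in-sample case proportion within a stratum. Because
the cohort is case-control sampled, it depends on the study's case:control
ratio — it is *not* an absolute population risk and should only be compared
across strata of the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratumTable",
    "assign_strata_fixed",
    "assign_strata_quantile",
    "stratum_likelihood",
    "cochran_armitage_trend",
    "stratum_or",
]


@dataclass
class StratumTable:
    """Ordered strata with case/control counts, likelihoods and the trend p."""

    labels: list[str]
    bounds: list[tuple[float, float]]
    n_case: np.ndarray
    n_control: np.ndarray
    likelihood_pct: np.ndarray          # NaN for empty strata
    chi2_trend: float | None = None
    p_trend: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "lower": [b[0] for b in self.bounds],
                "upper": [b[1] for b in self.bounds],
                "n_case": self.n_case,
                "n_control": self.n_control,
                "likelihood_pct": self.likelihood_pct,
            }
        )


def assign_strata_fixed(scores: np.ndarray, cutpoints: tuple[float, ...]
                        ) -> np.ndarray:
    """Half-open binning at fixed cutpoints: [c_i, c_{i+1}), top bin [c_last, inf).

    With the conventional cutpoints (0.8, 1.2) this yields low (< 0.8),
    medium ([0.8, 1.2)) and high (>= 1.2).
    """
    cut = np.asarray(cutpoints, dtype=float)
    if cut.size == 0 or (np.diff(cut) <= 0).any():
        raise ValueError("cutpoints must be non-empty and strictly increasing")
    return np.searchsorted(cut, np.asarray(scores, dtype=float), side="right")


def assign_strata_quantile(scores: np.ndarray, k: int = 4) -> np.ndarray:
    """Split at the pooled cohort's k-quantiles; boundary ties go to the lower group."""
    scores = np.asarray(scores, dtype=float)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if scores.size < k:
        raise ValueError("fewer subjects than groups")
    if np.unique(scores).size == 1:
        raise ValueError("all scores identical; quantile strata undefined")
    bounds = np.quantile(scores, np.arange(1, k) / k)
    return np.searchsorted(bounds, scores, side="left")


def stratum_likelihood(strata: np.ndarray, status: np.ndarray,
                       labels: list[str] | None = None,
                       bounds: list[tuple[float, float]] | None = None,
                       k: int | None = None) -> StratumTable:
    """Tabulate case/control counts and case-percentage per ordered stratum.

    Empty strata get NaN likelihood (flagged, not fatal). The trend test is
    not run here; see :func:`cochran_armitage_trend`.
    """
    strata = np.asarray(strata, dtype=int)
    status = np.asarray(status, dtype=int)
    if strata.shape != status.shape:
        raise ValueError("strata and status must have equal length")
    k = int(strata.max()) + 1 if k is None else k
    n_case = np.bincount(strata[status == 1], minlength=k)
    n_control = np.bincount(strata[status == 0], minlength=k)
    total = n_case + n_control
    with np.errstate(invalid="ignore", divide="ignore"):
        lik = np.where(total > 0, 100.0 * n_case / total, np.nan)
    if labels is None:
        labels = [f"stratum_{i}" for i in range(k)]
    if bounds is None:
        bounds = [(np.nan, np.nan)] * k
    return StratumTable(
        labels=list(labels),
        bounds=list(bounds),
        n_case=n_case,
        n_control=n_control,
        likelihood_pct=lik,
    )


def cochran_armitage_trend(table: np.ndarray,
                           scores: np.ndarray | None = None
                           ) -> tuple[float, float]:
    """Cochran-Armitage 1-df chi-square test for trend in proportions.

    ``table`` is k x 2 ordered counts (columns: cases, controls). Ordinal
    scores default to 0, 1, ..., k-1; no continuity correction. The result is
    invariant to affine rescaling of the scores. Returns ``(chi2, p)``.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise ValueError("need a k x 2 table with k >= 2")
    if (t < 0).any():
        raise ValueError("negative counts")
    if (t.sum(axis=0) == 0).any():
        raise ValueError("a status column has zero total")
    k = t.shape[0]
    w = np.arange(k, dtype=float) if scores is None else np.asarray(scores, float)
    if w.shape != (k,):
        raise ValueError("scores length must match number of strata")
    n_i = t.sum(axis=1)
    r_i = t[:, 0]
    n = n_i.sum()
    r = r_i.sum()
    pbar = r / n
    num = float(w @ (r_i - n_i * pbar))
    var = pbar * (1 - pbar) * float(w * w @ n_i - (w @ n_i) ** 2 / n)
    if var == 0:
        raise ValueError("degenerate table: trend variance is zero")
    chi2 = num * num / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def stratum_or(table: np.ndarray, ref: int, target: int
               ) -> tuple[float, bool]:
    """Cross-product OR of a target stratum's case odds versus a reference.

    Zero cells get the 0.5 continuity correction, flagged in the returned
    boolean. Returns ``(or_, corrected)``.
    """
    t = np.asarray(table, dtype=float)
    for idx in (ref, target):
        if not 0 <= idx < t.shape[0]:
            raise IndexError(f"stratum index {idx} out of range")
        if t[idx].sum() == 0:
            raise ValueError(f"stratum {idx} is empty")
    sub = t[[target, ref]]
    corrected = bool((sub == 0).any())
    if corrected:
        sub = sub + 0.5
    or_ = (sub[0, 0] * sub[1, 1]) / (sub[0, 1] * sub[1, 0])
    return float(or_), corrected
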