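"""Per-SNP QC and case-control association statistics.

The screening path mirrors standard candidate-SNP practice: Hardy-Weinberg
exact test in controls, allelic 2x2 odds ratio with a Woolf (log-OR) 95% CI
and a chi-square p-value — switching to Fisher's exact test when the combined
minor-allele frequency falls below 5% — plus a Bonferroni-corrected
significance threshold. Logistic regression is provided separately for
covariate (age) adjustment, and pairwise LD r² is estimated from unphased
genotypes by EM so correlated SNPs can be pruned from score panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .data import MISSING, GenotypeTable

__all__ = [
    "AssocResult",
    "GroupComparison",
    "allele_counts",
    "hwe_exact_test",
    "allelic_or_ci",
    "allelic_or_from_freqs",
    "fisher_exact_p",
    "logistic_assoc",
    "bonferroni_alpha",
    "ld_r2",
    "group_compare",
    "score_case_logistic",
    "association_scan",
]

FISHER_MAF_THRESHOLD = 0.05


@dataclass(frozen=True)
class AssocResult:
    """One SNP's row of an association screen (allele-based)."""

    rsid: str
    minor_allele: str
    major_allele: str
    f_a: float          # minor-allele frequency in cases
    f_u: float          # minor-allele frequency in controls
    or_: float          # allelic odds ratio, minor vs major, cases over controls
    ci_low: float
    ci_high: float
    p: float
    test: str           # "chi2" | "fisher"
    hwe_p_controls: float
    zero_cell_corrected: bool = False

    def __post_init__(self) -> None:
        assert self.ci_low <= self.or_ <= self.ci_high or self.test == "fisher"
        assert 0.0 <= self.p <= 1.0


@dataclass(frozen=True)
class GroupComparison:
    """A two-group comparison of a continuous variable (e.g. age, score)."""

    variable: str
    stat: float
    p: float
    test: str                    # "t_test" | "mann_whitney" | "logistic"
    p_adjusted: float | None = None   # age-adjusted logistic p, when computed


# ------------------------------------------------------------- allele counts

def allele_counts(dosage: np.ndarray, status: np.ndarray) -> np.ndarray:
    """2x2 allele table [[case_counted, case_other], [ctrl_counted, ctrl_other]].

    ``dosage`` counts one allele per the container's orientation; missing
    calls (``MISSING``) are excluded pairwise. Raises if either status group
    is empty or a group has only missing calls.
    """
    dosage = np.asarray(dosage)
    status = np.asarray(status)
    if dosage.shape != status.shape:
        raise ValueError("dosage and status must have equal length")
    table = np.zeros((2, 2), dtype=np.int64)
    for row, grp in enumerate((1, 0)):
        g = dosage[(status == grp) & (dosage != MISSING)]
        if (status == grp).sum() == 0:
            name = "case" if grp == 1 else "control"
            raise ValueError(f"no {name} subjects")
        if g.size == 0:
            raise ValueError("all genotypes missing in one status group")
        table[row, 0] = int(g.sum())
        table[row, 1] = int(2 * g.size - g.sum())
    return table


# -------------------------------------------------------------- HWE exact test

def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton-style enumeration).

    Conditional on the observed allele counts, heterozygote counts follow a
    known one-parameter distribution; the p-value sums the probabilities of
    all heterozygote configurations no more probable than the observed one.
    Monomorphic SNPs return 1.0 by convention.
    """
    for c in (n_hom_minor, n_het, n_hom_major):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        raise ValueError("no genotyped subjects")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n - n_minor
    if n_minor == 0 or n_major == 0:
        return 1.0
    rare = min(n_minor, n_major)
    # valid heterozygote counts share the parity of the rare-allele count
    h = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - h) // 2
    hom_common = n - h - hom_rare
    feasible = hom_common >= 0
    h, hom_rare, hom_common = h[feasible], hom_rare[feasible], hom_common[feasible]
    logp = (
        h * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(h + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = np.searchsorted(h, n_het)
    if obs >= h.size or h[obs] != n_het:
        raise ValueError(
            f"heterozygote count {n_het} impossible for allele count {rare}"
        )
    p = float(prob[prob <= prob[obs] * (1 + 1e-12)].sum())
    return min(p, 1.0)


# ------------------------------------------------------------- odds ratio, CI

def allelic_or_ci(table: np.ndarray) -> tuple[float, float, float, float, bool]:
    """Allelic OR, Woolf 95% CI and chi-square p from a 2x2 allele table.

    Table layout ``[[case_minor, case_major], [ctrl_minor, ctrl_major]]``.
    Zero cells get the Haldane-Anscombe 0.5 correction for OR/CI (flagged in
    the returned boolean); the chi-square p is computed on the raw table.

    Returns ``(or_, ci_low, ci_high, p, corrected)``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in allele table")
    corrected = bool((t == 0).any())
    tc = t + 0.5 if corrected else t
    or_ = (tc[0, 0] * tc[1, 1]) / (tc[0, 1] * tc[1, 0])
    se = float(np.sqrt((1.0 / tc).sum()))
    ci_low = float(or_ * np.exp(-1.959963984540054 * se))
    ci_high = float(or_ * np.exp(1.959963984540054 * se))
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(or_), ci_low, ci_high, float(p), corrected


def allelic_or_from_freqs(f_a: float, f_u: float) -> float:
    """Allelic OR from the two allele frequencies: odds(cases)/odds(controls)."""
    for f in (f_a, f_u):
        if not 0.0 < f < 1.0:
            raise ValueError("frequencies must lie strictly in (0, 1)")
    return (f_a / (1.0 - f_a)) / (f_u / (1.0 - f_u))


def fisher_exact_p(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tail sum)."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 integer table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m for m tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


# ------------------------------------------------------- logistic association

def logistic_assoc(
    dosage: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, float, tuple[float, float]]:
    """Per-allele (additive) logistic association.

    Returns ``(beta, OR, p, (ci_low, ci_high))`` for the dosage term, with a
    Wald p-value and 95% CI. Missing dosages are dropped (with the matching
    covariate rows). Raises on constant dosage or perfect separation.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status, dtype=float)
    keep = dosage != MISSING
    dosage, status = dosage[keep], status[keep]
    X = dosage[:, None]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != keep.size:
            cov = cov.T
        X = np.column_stack([dosage, cov[keep]])
    if np.unique(dosage).size < 2:
        raise ValueError("dosage is constant; association undefined")
    X = sm.add_constant(X, prepend=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(status, X).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "logistic fit failed (perfect separation?); use the exact/Fisher path"
        ) from exc
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se > 50:
        raise ValueError(
            "unstable logistic fit (quasi-separation); use the exact/Fisher path"
        )
    p = float(fit.pvalues[1])
    ci = (float(np.exp(beta - 1.959963984540054 * se)),
          float(np.exp(beta + 1.959963984540054 * se)))
    return beta, float(np.exp(beta)), p, ci


# ------------------------------------------------------------------- LD (r²)

def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray, *,
          tol: float = 1e-12, max_iter: int = 1000) -> float:
    """Squared allelic correlation r² between two SNPs from unphased genotypes.

    Haplotype frequencies are estimated by EM (double heterozygotes are the
    only ambiguous class), then r² = D² / (pA qA pB qB). Pairwise-complete
    subjects only; both SNPs must be polymorphic in that subset.
    """
    a = np.asarray(dosage_a)
    b = np.asarray(dosage_b)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep].astype(int), b[keep].astype(int)
    if a.size < 2:
        raise ValueError("fewer than 2 pairwise-complete subjects")
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    n = a.size
    p_a = a.sum() / (2 * n)
    p_b = b.sum() / (2 * n)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic SNP: r² undefined")

    # haplotypes: 11 (counted/counted), 10, 01, 00
    n_dh = counts[1, 1]  # double heterozygotes: phase-ambiguous
    base11 = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    base10 = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base01 = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base00 = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    h = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                  (1 - p_a) * (1 - p_b)])
    for _ in range(max_iter):
        cis = h[0] * h[3]           # 11/00 phase weight
        trans = h[1] * h[2]         # 10/01 phase weight
        frac = 0.5 if cis + trans == 0 else cis / (cis + trans)
        new = np.array(
            [
                base11 + n_dh * frac,
                base10 + n_dh * (1 - frac),
                base01 + n_dh * (1 - frac),
                base00 + n_dh * frac,
            ],
            dtype=float,
        ) / (2 * n)
        if np.abs(new - h).max() < tol:
            h = new
            break
        h = new
    d = h[0] - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return float(min(max(r2, 0.0), 1.0))


# ---------------------------------------------------------- group comparisons

def group_compare(
    values_case: np.ndarray,
    values_control: np.ndarray,
    method: str = "t_test",
    variable: str = "value",
) -> GroupComparison:
    """Two-sided two-group comparison: Student's t or Mann-Whitney U.

    Mann-Whitney uses midranks with the tie correction (asymptotic normal
    approximation), appropriate for skewed variables such as the genetic
    score; the t-test is for approximately normal variables such as age.
    """
    x = np.asarray(values_case, dtype=float)
    y = np.asarray(values_control, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "t_test":
        if x.size < 2 or y.size < 2:
            raise ValueError("t-test needs at least 2 values per group")
        if np.array_equal(np.sort(x), np.sort(y)):
            return GroupComparison(variable, 0.0, 1.0, "t_test")
        stat, p = stats.ttest_ind(x, y, equal_var=True)
    elif method == "mann_whitney":
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic")
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(variable, float(stat), float(p), method)


def score_case_logistic(
    scores: np.ndarray,
    status: np.ndarray,
    age: np.ndarray | None = None,
    variable: str = "score",
) -> GroupComparison:
    """Wald p for the score term in a logistic case model, age-adjusted.

    A constant (or absent) age column degrades to the unadjusted model with a
    warning rather than failing.
    """
    scores = np.asarray(scores, dtype=float)
    cov = None
    if age is not None:
        age = np.asarray(age, dtype=float)
        if np.unique(age[~np.isnan(age)]).size < 2:
            warnings.warn("age is constant; fitting unadjusted model")
        else:
            cov = np.where(np.isnan(age), np.nanmean(age), age)
    beta, _, p, _ = logistic_assoc(scores, status, covariates=cov)
    return GroupComparison(variable, beta, p, "logistic", p_adjusted=p)


# ------------------------------------------------------------------ the scan

def association_scan(table: GenotypeTable, alpha: float = 0.05) -> pd.DataFrame:
    """Screen every SNP: minor-allele frequencies, OR with 95% CI, p, HWE.

    The minor allele is defined in the combined sample, and the Fisher exact
    test replaces the allelic chi-square when the combined minor-allele
    frequency is below 5%. Output columns follow the conventional screen
    layout; a ``significant`` flag applies the Bonferroni threshold
    ``alpha / n_snps``.
    """
    if table.status is None:
        raise ValueError("genotype table has no case/control status")
    rows = []
    threshold = bonferroni_alpha(alpha, table.n_snps)
    for j, rsid in enumerate(table.snp_ids):
        g = table.dosage[:, j]
        called = g != MISSING
        if not called.any():
            raise ValueError(f"SNP {rsid}: all genotypes missing")
        freq_counted = g[called].sum() / (2 * called.sum())
        minor_is_counted = freq_counted <= 0.5
        if minor_is_counted:
            minor, major = table.counted_allele[j], table.other_allele[j]
            gm = g
        else:
            minor, major = table.other_allele[j], table.counted_allele[j]
            gm = np.where(called, 2 - g, MISSING).astype(np.int8)
        t = allele_counts(gm, table.status)
        f_a = t[0, 0] / t[0].sum()
        f_u = t[1, 0] / t[1].sum()
        maf_all = t[:, 0].sum() / t.sum()
        or_, lo, hi, p_chi2, corrected = allelic_or_ci(t)
        if maf_all < FISHER_MAF_THRESHOLD:
            p, test = fisher_exact_p(t), "fisher"
        else:
            p, test = p_chi2, "chi2"
        gc = gm[(table.status == 0) & called]
        hwe_p = hwe_exact_test(
            int((gc == 2).sum()), int((gc == 1).sum()), int((gc == 0).sum())
        )
        rows.append(
            {
                "rsid": rsid,
                "minor": minor,
                "major": major,
                "F_A": f_a,
                "F_U": f_u,
                "OR": or_,
                "L95": lo,
                "U95": hi,
                "P": p,
                "test": test,
                "hwe_p_controls": hwe_p,
                "zero_cell_corrected": corrected,
                "significant": p < threshold,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["bonferroni_threshold"] = threshold
    return df
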