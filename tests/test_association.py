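"""Association statistics: allele tables, HWE exact test, ORs, LD, comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from snpscore import (
    MISSING,
    allele_counts,
    allelic_or_ci,
    allelic_or_from_freqs,
    association_scan,
    bonferroni_alpha,
    fisher_exact_p,
    group_compare,
    hwe_exact_test,
    ld_r2,
    logistic_assoc,
    score_case_logistic,
)
from snpscore.simulate import haplotype_freqs_for_r2


# ------------------------------------------------------------- oracle helpers

def hwe_p_bruteforce(n_aa, n_ab, n_bb):
    """Full enumeration of the heterozygote distribution given allele counts."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab

    def log_prob(h):
        hom_a = (na - h) // 2
        hom_b = n - h - hom_a
        if hom_a < 0 or hom_b < 0:
            return -math.inf
        return (
            h * math.log(2)
            + gammaln(n + 1)
            - gammaln(hom_a + 1)
            - gammaln(h + 1)
            - gammaln(hom_b + 1)
            + gammaln(na + 1)
            + gammaln(2 * n - na + 1)
            - gammaln(2 * n + 1)
        )

    hs = [h for h in range(min(na, 2 * n - na) + 1)
          if (na - h) % 2 == 0 and n - h - (na - h) // 2 >= 0]
    probs = {h: math.exp(log_prob(h)) for h in hs}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def fisher_p_bruteforce(table):
    """Sum of hypergeometric probabilities <= observed over fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = stats.hypergeom.pmf(x, n, c1, r1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


# --------------------------------------------------------------- allele counts

class TestAlleleCounts:
    def test_counts_and_frequencies(self):
        dosage = np.array([2, 1, 0, 1, 0, 0])
        status = np.array([1, 1, 1, 0, 0, 0])
        t = allele_counts(dosage, status)
        assert t[0].tolist() == [3, 3]   # cases: 3 counted of 6
        assert t[1].tolist() == [1, 5]

    def test_reconstructed_study_counts(self):
        # 346 cases at minor frequency 0.36 -> round(0.36 * 692) = 249 alleles
        n_minor = round(0.36 * 692)
        g = np.zeros(346, dtype=int)
        g[: n_minor // 2] = 2
        if n_minor % 2:
            g[n_minor // 2] = 1
        status = np.concatenate([np.ones(346, int), np.zeros(4, int)])
        g2 = np.concatenate([g, np.array([0, 0, 1, 1])])
        t = allele_counts(g2, status)
        assert t[0, 0] == 249
        assert t[0].sum() == 692

    def test_missing_excluded_pairwise(self):
        t = allele_counts(np.array([2, MISSING, 0]), np.array([1, 1, 0]))
        assert t[0].sum() == 2

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="no control"):
            allele_counts(np.array([1, 2]), np.array([1, 1]))

    def test_all_missing_group_errors(self):
        with pytest.raises(ValueError, match="missing"):
            allele_counts(np.array([MISSING, 1]), np.array([1, 0]))


# ----------------------------------------------------------------- HWE exact

class TestHweExact:
    def test_perfect_proportions_near_one(self):
        assert hwe_exact_test(25, 50, 25) > 0.9

    def test_all_heterozygote_extreme(self):
        assert hwe_exact_test(0, 100, 0) < 1e-6

    def test_monomorphic_convention(self):
        assert hwe_exact_test(0, 0, 50) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(3, 10, 12), (0, 5, 20), (7, 1, 4), (2, 2, 2), (10, 0, 10)],
    )
    def test_matches_full_enumeration(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_p_bruteforce(*counts), rel=1e-9
        )

    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
    )
    def test_valid_probability_and_oracle(self, a, h, b):
        if a + h + b == 0:
            return
        p = hwe_exact_test(a, h, b)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(hwe_p_bruteforce(a, h, b), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


# ------------------------------------------------------------------ OR and CI

class TestAllelicOr:
    @pytest.mark.parametrize(
        "f_a,f_u,expected",
        [(0.375, 0.409, 0.87), (0.094, 0.087, 1.09)],
    )
    def test_frequency_reconstruction(self, f_a, f_u, expected):
        assert round(allelic_or_from_freqs(f_a, f_u), 2) == expected

    def test_identity_when_frequencies_equal(self):
        assert allelic_or_from_freqs(0.3, 0.3) == pytest.approx(1.0)

    def test_table_and_frequency_forms_agree(self, rng):
        for _ in range(20):
            t = rng.integers(1, 200, size=(2, 2))
            or_, lo, hi, p, corr = allelic_or_ci(t)
            f_a = t[0, 0] / t[0].sum()
            f_u = t[1, 0] / t[1].sum()
            assert or_ == pytest.approx(allelic_or_from_freqs(f_a, f_u),
                                        rel=1e-12)
            assert lo <= or_ <= hi
            assert not corr

    def test_ci_is_woolf(self):
        t = np.array([[30, 70], [20, 80]])
        or_, lo, hi, p, _ = allelic_or_ci(t)
        se = math.sqrt(1 / 30 + 1 / 70 + 1 / 20 + 1 / 80)
        assert lo == pytest.approx(or_ * math.exp(-1.96 * se), rel=1e-3)
        chi2 = stats.chi2_contingency(t, correction=False)[0]
        assert p == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_zero_cell_flagged_and_corrected(self):
        or_, lo, hi, p, corrected = allelic_or_ci([[10, 0], [5, 15]])
        assert corrected
        assert math.isfinite(hi)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            allelic_or_ci([[0, 10], [0, 20]])


class TestFisher:
    def test_identical_rows(self):
        assert fisher_exact_p([[1, 9], [1, 9]]) == pytest.approx(1.0)

    def test_fully_separated_closed_form(self):
        assert fisher_exact_p([[10, 0], [0, 10]]) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9
        )

    def test_low_frequency_snp_detectable(self):
        # counts rebuilt from a reported rare-allele association
        t = [[20, 672], [36, 2224]]
        assert fisher_exact_p(t) < 0.05

    @given(
        st.integers(0, 12), st.integers(0, 12),
        st.integers(0, 12), st.integers(0, 12),
    )
    def test_matches_enumeration_small_margins(self, a, b, c, d):
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        assert fisher_exact_p([[a, b], [c, d]]) == pytest.approx(
            fisher_p_bruteforce([[a, b], [c, d]]), rel=1e-7
        )


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 10, 0.005), (0.05, 1, 0.05), (0.01, 4, 0.0025)]
    )
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


# -------------------------------------------------------------------- logistic

class TestLogistic:
    def test_null_estimate_near_one(self, rng):
        g = rng.binomial(2, 0.4, 2000)
        y = rng.binomial(1, 0.3, 2000)
        beta, or_, p, ci = logistic_assoc(g, y)
        assert ci[0] < 1.0 < ci[1]

    def test_recovers_simulated_effect(self, rng):
        g = rng.binomial(2, 0.5, 3000)
        logit = -1.0 + g * math.log(1.67)
        y = rng.random(3000) < 1 / (1 + np.exp(-logit))
        beta, or_, p, ci = logistic_assoc(g, y.astype(int))
        assert ci[0] < 1.67 < ci[1]
        assert p < 0.01

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_assoc(np.ones(50), np.random.default_rng(0).binomial(1, 0.5, 50))

    def test_separation_rejected(self):
        g = np.array([0] * 20 + [2] * 20)
        y = np.array([0] * 20 + [1] * 20)
        with pytest.raises(ValueError):
            logistic_assoc(g, y)


# ------------------------------------------------------------------------- LD

class TestLdR2:
    def test_identical_vectors(self, rng):
        g = rng.binomial(2, 0.4, 500)
        assert ld_r2(g, g) == pytest.approx(1.0, abs=1e-9)

    def test_independent_snps_near_zero(self, rng):
        a = rng.binomial(2, 0.3, 10_000)
        b = rng.binomial(2, 0.4, 10_000)
        assert ld_r2(a, b) < 0.01

    def test_generative_round_trip(self, rng):
        h = haplotype_freqs_for_r2(0.3, 0.4, 0.58)
        hap = rng.choice(4, size=(20_000, 2), p=h)
        a = (hap < 2).sum(axis=1)
        b = (hap % 2 == 0).sum(axis=1)
        assert ld_r2(a, b) == pytest.approx(0.58, abs=0.03)

    def test_symmetry_and_label_invariance(self, rng):
        a = rng.binomial(2, 0.3, 400)
        b = np.clip(a + rng.integers(-1, 2, 400), 0, 2)
        r = ld_r2(a, b)
        assert ld_r2(b, a) == pytest.approx(r, abs=1e-9)
        assert ld_r2(2 - a, b) == pytest.approx(r, abs=1e-9)
        assert ld_r2(a, 2 - b) == pytest.approx(r, abs=1e-9)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(np.zeros(10, dtype=int), np.array([0, 1] * 5))


# ----------------------------------------------------------- group comparisons

class TestGroupCompare:
    def test_identical_groups_t(self):
        x = np.array([1.0, 2.0, 3.0])
        assert group_compare(x, x, "t_test").p == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 60)
        for m in ("t_test", "mann_whitney"):
            assert group_compare(x, y, m).p == pytest.approx(
                group_compare(y, x, m).p, rel=1e-9
            )

    def test_shift_detected(self, rng):
        x = rng.normal(0.4, 1.0, 300)
        y = rng.normal(0.0, 1.0, 1000)
        assert group_compare(x, y, "t_test").p < 0.001
        assert group_compare(x, y, "mann_whitney").p < 0.001

    def test_small_group_t_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0], [1.0, 2.0], "t_test")

    def test_constant_age_warns(self, rng):
        s = rng.normal(1, 0.3, 400)
        y = (rng.random(400) < 1 / (1 + np.exp(-(s - 1)))).astype(int)
        with pytest.warns(UserWarning, match="constant"):
            score_case_logistic(s, y, np.full(400, 50.0))


# ----------------------------------------------------------------------- scan

class TestAssociationScan:
    def test_effect_snps_flagged_on_fixture(self, score1_fixture):
        table, _ = score1_fixture
        df = association_scan(table)
        assert df.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 4)
        assert set(df["rsid"]) == set(table.snp_ids)
        assert ((df["F_A"] >= 0) & (df["F_A"] <= 0.75)).all()
        assert (df["L95"] <= df["OR"]).all() and (df["OR"] <= df["U95"]).all()

    def test_fisher_switch_for_rare_alleles(self, rng):
        from snpscore import SimConfig, SimSnp, simulate_case_control

        cfg = SimConfig(
            n_case=100, n_control=300,
            snps=(SimSnp("rsRare", 0.02, 1.0),), ld_pairs=(), seed=13,
        )
        df = association_scan(simulate_case_control(cfg))
        assert df.loc[0, "test"] == "fisher"
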