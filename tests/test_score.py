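"""The genetic score: genotypic ORs, population normalization, model building."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from snpscore import (
    MISSING,
    ScoreModel,
    SnpModelEntry,
    ValidationError,
    build_model,
    genetic_score,
    genotypic_or,
    population_average_risk,
    score_table,
    snp_relative_risk,
)

ors = st.floats(0.2, 5.0, allow_nan=False)
freqs = st.floats(0.01, 0.99, allow_nan=False)


class TestGenotypicOr:
    def test_two_risk_alleles_squares(self):
        assert genotypic_or(1.41, 2) == pytest.approx(1.9881)

    def test_non_carrier_is_one(self):
        assert genotypic_or(3.7, 0) == 1.0

    def test_neutral_allele(self):
        for g in (0, 1, 2):
            assert genotypic_or(1.0, g) == 1.0

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError):
            genotypic_or(1.5, 3)


class TestPopulationAverageRisk:
    def test_hand_value(self):
        assert population_average_risk(2.0, 0.5) == pytest.approx(2.25)

    def test_study_or_value(self):
        # 0.51² · 1.67² + 2 · 0.51 · 0.49 · 1.67 + 0.49²
        assert population_average_risk(1.67, 0.51) == pytest.approx(1.8002, abs=5e-5)

    def test_neutral_allele(self):
        assert population_average_risk(1.0, 0.37) == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_monomorphic_rejected(self, p):
        with pytest.raises(ValueError):
            population_average_risk(1.5, p)


class TestSnpRelativeRisk:
    def test_composition(self):
        assert snp_relative_risk(2.0, 0.5, 2) == pytest.approx(4 / 2.25)
        assert snp_relative_risk(2.0, 0.5, 0) == pytest.approx(1 / 2.25)

    def test_neutral(self):
        assert snp_relative_risk(1.0, 0.3, 1) == pytest.approx(1.0)

    @given(ors, freqs)
    def test_hwe_weighted_mean_is_one(self, or_, p):
        """The normalization identity: E_HWE[factor] = 1 exactly."""
        w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
        mean = sum(
            w[g] * snp_relative_risk(or_, p, g) for g in (0, 1, 2)
        )
        assert mean == pytest.approx(1.0, abs=1e-12)


def study_model():
    return ScoreModel(
        entries=(
            SnpModelEntry("rs10054504", "T", 1.41, 0.45),
            SnpModelEntry("rs7023329", "A", 1.67, 0.51),
            SnpModelEntry("rs718314", "G", 1.79, 0.30),
        )
    )


class TestGeneticScore:
    def test_all_neutral_model_scores_one(self):
        m = ScoreModel(entries=(SnpModelEntry("rs1", "A", 1.0 + 1e-12, 0.4),))
        s, _, _ = genetic_score({"rs1": 2}, m)
        assert s == pytest.approx(1.0)

    def test_single_snp_identity(self):
        m = ScoreModel(entries=(SnpModelEntry("rs1", "A", 1.5, 0.3),))
        s, factors, _ = genetic_score({"rs1": 1}, m)
        assert s == pytest.approx(snp_relative_risk(1.5, 0.3, 1))
        assert factors == {"rs1": s}

    def test_three_snp_hand_product(self):
        m = study_model()
        expected = math.prod(
            snp_relative_risk(e.allelic_or, e.risk_allele_freq, 2) for e in m
        )
        s, _, n_miss = genetic_score(
            {"rs10054504": 2, "rs7023329": 2, "rs718314": 2}, m
        )
        assert s == pytest.approx(expected, rel=1e-12)
        assert n_miss == 0
        assert s > 1.0  # triple homozygous risk carrier is above average

    def test_missing_snp_contributes_unit_factor(self):
        m = study_model()
        s_full, _, _ = genetic_score(
            {"rs10054504": 2, "rs7023329": 1, "rs718314": 0}, m
        )
        s_miss, factors, n_miss = genetic_score(
            {"rs10054504": 2, "rs7023329": 1, "rs718314": MISSING}, m
        )
        assert n_miss == 1
        assert factors["rs718314"] == 1.0
        assert s_miss == pytest.approx(
            s_full / snp_relative_risk(1.79, 0.30, 0)
        )

    def test_all_missing_rejected(self):
        m = study_model()
        with pytest.raises(ValidationError, match="undefined"):
            genetic_score({r: MISSING for r in m.rsids}, m)

    def test_unsupplied_snp_rejected(self):
        with pytest.raises(ValidationError, match="not supplied"):
            genetic_score({"rs10054504": 1}, study_model())

    @given(
        st.lists(st.tuples(ors.filter(lambda x: x >= 1.0), freqs),
                 min_size=1, max_size=5)
    )
    def test_monotone_in_each_dosage(self, panel):
        m = ScoreModel(
            entries=tuple(
                SnpModelEntry(f"rs{i}", "A", o, p)
                for i, (o, p) in enumerate(panel)
            )
        )
        base = {f"rs{i}": 0 for i in range(len(panel))}
        prev, _, _ = genetic_score(base, m)
        for g in (1, 2):
            cur, _, _ = genetic_score({k: g for k in base}, m)
            assert cur >= prev - 1e-12
            prev = cur

    def test_log_score_matches_additive_form(self, rng):
        """log(score) = Σ g·log(OR) − Σ log(popmean): independent route."""
        m = study_model()
        for _ in range(25):
            dosages = {r: int(rng.integers(0, 3)) for r in m.rsids}
            s, _, _ = genetic_score(dosages, m)
            log_s = sum(
                dosages[e.rsid] * math.log(e.allelic_or)
                - math.log(
                    population_average_risk(e.allelic_or, e.risk_allele_freq)
                )
                for e in m
            )
            assert math.log(s) == pytest.approx(log_s, abs=1e-10)


class TestBuildModel:
    CANDS = [
        ("rs10054504", "T", "C", 1.41),
        ("rs7023329", "G", "A", 0.60),
        ("rs718314", "G", "A", 1.79),
        ("rs1049380", "A", "G", 1.58),
    ]
    FREQS = {"rs10054504": 0.45, "rs7023329": 0.49, "rs718314": 0.30,
             "rs1049380": 0.40}

    def test_protective_or_inverted(self):
        m = build_model(self.CANDS[:2], self.FREQS)
        e = next(x for x in m if x.rsid == "rs7023329")
        assert e.risk_allele == "A"
        assert round(e.allelic_or, 2) == 1.67
        assert e.risk_allele_freq == pytest.approx(0.51)

    def test_ld_pair_pruned_below_threshold(self):
        ld = {frozenset({"rs718314", "rs1049380"}): 0.58}
        m = build_model(self.CANDS, self.FREQS, ld=ld, ld_threshold=0.5,
                        keep=["rs718314"])
        assert "rs1049380" not in m.rsids
        assert "rs718314" in m.rsids

    def test_ld_pair_kept_above_threshold(self):
        ld = {frozenset({"rs718314", "rs1049380"}): 0.58}
        m = build_model(self.CANDS, self.FREQS, ld=ld, ld_threshold=0.6)
        assert {"rs718314", "rs1049380"} <= set(m.rsids)

    def test_smaller_p_wins_without_designation(self):
        ld = {frozenset({"rs718314", "rs1049380"}): 0.58}
        pv = {"rs718314": 5.26e-8, "rs1049380": 0.0025}
        m = build_model(self.CANDS, self.FREQS, ld=ld, ld_threshold=0.5,
                        pvalues=pv)
        assert "rs718314" in m.rsids and "rs1049380" not in m.rsids

    def test_unresolved_pair_errors_naming_both(self):
        ld = {frozenset({"rs718314", "rs1049380"}): 0.58}
        with pytest.raises(ValidationError, match="rs1049380.*rs718314|rs718314.*rs1049380"):
            build_model(self.CANDS, self.FREQS, ld=ld, ld_threshold=0.5)


class TestScoreTable:
    def test_missing_model_snp_listed(self, score1_fixture):
        table, model = score1_fixture
        bad = ScoreModel(
            entries=model.entries + (SnpModelEntry("rs999", "A", 1.5, 0.3),)
        )
        with pytest.raises(ValidationError, match="rs999"):
            score_table(table, bad)

    def test_scores_positive_and_factor_product(self, score1_fixture):
        table, model = score1_fixture
        df = score_table(table, model)
        assert (df["score"] > 0).all()
        fac = df[[f"factor_{r}" for r in model.rsids]].prod(axis=1)
        np.testing.assert_allclose(df["score"], fac, rtol=1e-12)
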