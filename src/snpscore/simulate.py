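"""Case-control genotype simulation with known truth.

The generator produces cohorts with the statistical structure the analysis
assumes, so every pipeline stage can be exercised end-to-end with a known
answer:

* SNPs are biallelic and in Hardy-Weinberg proportions in the general
  population (two Bernoulli(p) alleles per subject); designated pairs are
  drawn from two-locus haplotypes constructed to hit a target LD r².
* Disease is logistic in risk-allele dosage: log-odds = baseline +
  Σ g·log(OR). This is the generative model whose per-allele OR equals the
  multiplicative allelic OR the score assumes, and the per-allele OR is
  preserved under case-control ascertainment (the intercept absorbs it).
* Rejection sampling accumulates subjects until the requested numbers of
  cases and controls are reached, mirroring case-control recruitment; ages
  are then drawn per group from configurable normals.

Defaults emulate the renal-cell-carcinoma study conditions this package
grew from: 346 cases / 1,130 controls; a four-SNP risk panel with per-allele
ORs 1.41, 1.67, 1.79, 1.58; one SNP pair correlated at r² = 0.58; case ages
55.9 ± 12.5 vs control ages 51.2 ± 9.7 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeTable, ScoreModel, SnpModelEntry
from .score import snp_relative_risk

__all__ = [
    "SimSnp",
    "SimConfig",
    "STUDY_SNPS",
    "haplotype_freqs_for_r2",
    "simulate_population",
    "simulate_case_control",
    "expected_auc",
    "make_fixture",
]


@dataclass(frozen=True)
class SimSnp:
    """One simulated SNP: rsid, risk-allele frequency and per-allele OR."""

    rsid: str
    risk_allele_freq: float
    allelic_or: float
    risk_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self) -> None:
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ValueError(f"{self.rsid}: frequency outside (0, 1)")
        if not self.allelic_or > 0:
            raise ValueError(f"{self.rsid}: OR must be positive")


# The study panel: ORs from the significant-SNP summary; the rs7023329 risk
# (major) allele frequency is recoverable from the printed control minor
# frequency (1 - 0.490); the other frequencies are realistic Han-Chinese-like
# values chosen once (see docs/methods.md).
STUDY_SNPS: tuple[SimSnp, ...] = (
    SimSnp("rs10054504", 0.45, 1.41, "T", "C"),
    SimSnp("rs7023329", 0.51, 1.67, "A", "G"),
    SimSnp("rs718314", 0.30, 1.79, "G", "A"),
    SimSnp("rs1049380", 0.40, 1.58, "A", "G"),
)


@dataclass
class SimConfig:
    """Study-condition defaults for cohort simulation."""

    n_case: int = 346
    n_control: int = 1130
    snps: tuple[SimSnp, ...] = STUDY_SNPS
    ld_pairs: tuple[tuple[str, str, float], ...] = (
        ("rs718314", "rs1049380", 0.58),
    )
    negative_d: bool = False
    baseline_log_odds: float = -4.0
    age_case_mean: float = 55.9
    age_case_sd: float = 12.5
    age_control_mean: float = 51.2
    age_control_sd: float = 9.7
    seed: int = 0
    draw_budget: int = 5_000_000

    def __post_init__(self) -> None:
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsid in config")
        for a, b, r2 in self.ld_pairs:
            if a not in rsids or b not in rsids:
                raise ValueError(f"LD pair ({a}, {b}) references unknown SNP")
            if not 0.0 <= r2 <= 1.0:
                raise ValueError("target r² outside [0, 1]")

    def snp(self, rsid: str) -> SimSnp:
        return next(s for s in self.snps if s.rsid == rsid)

    def score_model(self, rsids: list[str] | None = None,
                    ld_prune_r2: float = 0.5) -> ScoreModel:
        """The true generating model as a ScoreModel (optionally a subset)."""
        snps = self.snps if rsids is None else [self.snp(r) for r in rsids]
        return ScoreModel(
            entries=tuple(
                SnpModelEntry(s.rsid, s.risk_allele, s.allelic_or,
                              s.risk_allele_freq, "external")
                for s in snps
            ),
            ld_prune_r2=ld_prune_r2,
        )


def haplotype_freqs_for_r2(p_a: float, p_b: float, r2: float,
                           negative_d: bool = False) -> np.ndarray:
    """Two-locus haplotype frequencies (AB, Ab, aB, ab) hitting a target r².

    D = ±sqrt(r² · p_a q_a p_b q_b); the positive sign couples the two
    counted alleles unless ``negative_d``. Raises if the implied D pushes any
    haplotype frequency outside [0, 1], reporting the feasible maximum r².
    """
    for p in (p_a, p_b):
        if not 0.0 < p < 1.0:
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r² must lie in [0, 1]")
    qa, qb = 1.0 - p_a, 1.0 - p_b
    denom = p_a * qa * p_b * qb
    d = np.sqrt(r2 * denom)
    if negative_d:
        d = -d
        d_max = min(p_a * p_b, qa * qb)
    else:
        d_max = min(p_a * qb, qa * p_b)
    if abs(d) > d_max + 1e-12:
        r2_max = d_max * d_max / denom
        raise ValueError(
            f"target r²={r2} infeasible for frequencies ({p_a}, {p_b}); "
            f"maximum attainable r² is {r2_max:.4f}"
        )
    h = np.array(
        [p_a * p_b + d, p_a * qb - d, qa * p_b - d, qa * qb + d]
    )
    return np.clip(h, 0.0, None)


def _draw_genotypes(config: SimConfig, n: int, rng: np.random.Generator
                    ) -> np.ndarray:
    """n x m risk-allele dosage matrix honouring the config's LD pairs."""
    m = len(config.snps)
    idx = {s.rsid: j for j, s in enumerate(config.snps)}
    paired = {r for a, b, _ in config.ld_pairs for r in (a, b)}
    g = np.empty((n, m), dtype=np.int8)
    for j, s in enumerate(config.snps):
        if s.rsid not in paired:
            g[:, j] = rng.binomial(2, s.risk_allele_freq, size=n).astype(np.int8)
    for a, b, r2 in config.ld_pairs:
        pa = config.snp(a).risk_allele_freq
        pb = config.snp(b).risk_allele_freq
        h = haplotype_freqs_for_r2(pa, pb, r2, config.negative_d)
        # two haplotypes per subject; haplotype k carries allele A iff k < 2
        hap = rng.choice(4, size=(n, 2), p=h / h.sum())
        g[:, idx[a]] = (hap < 2).sum(axis=1).astype(np.int8)
        g[:, idx[b]] = (hap % 2 == 0).sum(axis=1).astype(np.int8)
    return g


def _as_table(config: SimConfig, g: np.ndarray, status=None, age=None,
              prefix: str = "S") -> GenotypeTable:
    n = g.shape[0]
    return GenotypeTable(
        subject_ids=[f"{prefix}{i + 1:06d}" for i in range(n)],
        dosage=g,
        snp_ids=[s.rsid for s in config.snps],
        counted_allele=[s.risk_allele for s in config.snps],
        other_allele=[s.other_allele for s in config.snps],
        status=status,
        age=age,
    )


def simulate_population(config: SimConfig, n: int,
                        rng: np.random.Generator | None = None) -> GenotypeTable:
    """Draw n subjects from the general population (no phenotype)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    return _as_table(config, _draw_genotypes(config, n, rng), prefix="P")


def simulate_case_control(config: SimConfig,
                          rng: np.random.Generator | None = None
                          ) -> GenotypeTable:
    """Sample a case-control cohort of exactly n_case / n_control subjects.

    Population subjects are drawn in batches; disease status is Bernoulli in
    the logistic risk; draws continue until both quotas fill. Raises if the
    configured draw budget is exhausted first (a symptom of an extreme
    baseline).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    log_or = np.log([s.allelic_or for s in config.snps])
    cases, controls = [], []
    drawn = 0
    batch = max(4 * (config.n_case + config.n_control), 1000)
    while True:
        need_case = config.n_case - sum(len(c) for c in cases)
        need_control = config.n_control - sum(len(c) for c in controls)
        if need_case <= 0 and need_control <= 0:
            break
        if drawn >= config.draw_budget:
            raise RuntimeError(
                f"draw budget {config.draw_budget} exhausted with "
                f"{need_case} cases / {need_control} controls still needed; "
                "baseline_log_odds may be too extreme"
            )
        g = _draw_genotypes(config, batch, rng)
        drawn += batch
        logit = config.baseline_log_odds + g @ log_or
        disease = rng.random(batch) < 1.0 / (1.0 + np.exp(-logit))
        if need_case > 0:
            cases.append(g[disease][:need_case])
        if need_control > 0:
            controls.append(g[~disease][:need_control])
    g_case = np.vstack([c for c in cases if len(c)]) if cases else \
        np.empty((0, len(config.snps)), dtype=np.int8)
    g_control = np.vstack([c for c in controls if len(c)])
    g_all = np.vstack([g_case, g_control])
    status = np.concatenate(
        [np.ones(config.n_case, dtype=np.int8),
         np.zeros(config.n_control, dtype=np.int8)]
    )
    age = np.concatenate(
        [
            rng.normal(config.age_case_mean, config.age_case_sd, config.n_case),
            rng.normal(config.age_control_mean, config.age_control_sd,
                       config.n_control),
        ]
    ).round(1)
    return _as_table(config, g_all, status=status, age=age)


def expected_auc(config: SimConfig, rsids: list[str] | None = None) -> float:
    """Exact AUC of the true genetic score under the generating model.

    Enumerates every genotype combination of the scored SNPs (honouring LD
    pairs), computes P(combo | case) and P(combo | control) from the logistic
    risk, and sums P(S_case > S_control) + ½ P(tie). An integration oracle
    for the simulated pipeline; feasible for small panels (3^m combos).
    """
    scored = [s.rsid for s in config.snps] if rsids is None else list(rsids)

    # genotype distribution per independent unit (single SNP or LD pair);
    # all config SNPs enter the risk, whether or not they are scored
    units: list[tuple[list[str], np.ndarray, np.ndarray]] = []
    used: set[str] = set()
    for s in config.snps:
        if s.rsid in used:
            continue
        partner = None
        for (a, b, r2) in config.ld_pairs:
            if s.rsid in (a, b):
                partner = (b if s.rsid == a else a, r2)
        if partner is None:
            probs = np.array(
                [
                    (1 - s.risk_allele_freq) ** 2,
                    2 * s.risk_allele_freq * (1 - s.risk_allele_freq),
                    s.risk_allele_freq ** 2,
                ]
            )
            units.append(([s.rsid], np.arange(3)[:, None], probs))
            used.add(s.rsid)
        else:
            other, r2 = partner
            t = config.snp(other)
            h = haplotype_freqs_for_r2(
                s.risk_allele_freq, t.risk_allele_freq, r2, config.negative_d
            )
            h = h / h.sum()
            combos, probs = [], []
            for k1 in range(4):
                for k2 in range(4):
                    ga = (k1 < 2) + (k2 < 2)
                    gb = (k1 % 2 == 0) + (k2 % 2 == 0)
                    combos.append((ga, gb))
                    probs.append(h[k1] * h[k2])
            arr = np.array(combos)
            pr = np.array(probs)
            # collapse duplicate genotype pairs
            uniq, inv = np.unique(arr, axis=0, return_inverse=True)
            agg = np.bincount(inv, weights=pr)
            units.append(([s.rsid, other], uniq, agg))
            used |= {s.rsid, other}

    # cartesian product over units
    rsid_order: list[str] = []
    combos = np.zeros((1, 0), dtype=int)
    probs = np.ones(1)
    for rsids_u, geno_u, pr_u in units:
        rsid_order += rsids_u
        combos = np.hstack(
            [np.repeat(combos, len(geno_u), axis=0),
             np.tile(geno_u, (len(combos), 1))]
        )
        probs = (probs[:, None] * pr_u[None, :]).ravel()

    log_or = np.array(
        [np.log(config.snp(r).allelic_or) for r in rsid_order]
    )
    risk = 1.0 / (1.0 + np.exp(-(config.baseline_log_odds + combos @ log_or)))
    p_case = probs * risk
    p_control = probs * (1 - risk)
    p_case /= p_case.sum()
    p_control /= p_control.sum()

    scored_mask = np.array([r in scored for r in rsid_order])
    # the genetic score is monotone in the scored-dosage log-OR sum
    score = np.exp(combos[:, scored_mask] @ log_or[scored_mask])
    order = np.argsort(score)
    score, p_case, p_control = score[order], p_case[order], p_control[order]
    # merge ties before the pairwise sum
    uniq, inv = np.unique(np.round(np.log(score), 12), return_inverse=True)
    pc = np.bincount(inv, weights=p_case)
    pu = np.bincount(inv, weights=p_control)
    cum_pu = np.concatenate([[0.0], np.cumsum(pu)])[:-1]
    return float((pc * (cum_pu + 0.5 * pu)).sum())


def make_fixture(preset: str, n_case: int = 80, n_control: int = 240,
                 seed: int = 2016) -> tuple[GenotypeTable, ScoreModel]:
    """Small deterministic cohort + matching score model for tests and docs.

    Presets: ``score1`` (rs10054504/rs7023329/rs718314 panel), ``score2``
    (rs1049380 substituted for rs718314), ``null`` (same SNPs, all ORs 1).
    """
    if preset == "score1":
        rsids = ["rs10054504", "rs7023329", "rs718314"]
        snps = STUDY_SNPS
    elif preset == "score2":
        rsids = ["rs10054504", "rs7023329", "rs1049380"]
        snps = STUDY_SNPS
    elif preset == "null":
        rsids = ["rs10054504", "rs7023329", "rs718314"]
        snps = tuple(
            SimSnp(s.rsid, s.risk_allele_freq, 1.0, s.risk_allele, s.other_allele)
            for s in STUDY_SNPS
        )
    else:
        raise ValueError(f"unknown preset {preset!r}")
    config = SimConfig(n_case=n_case, n_control=n_control, snps=snps, seed=seed)
    table = simulate_case_control(config)
    return table, config.score_model(rsids)
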