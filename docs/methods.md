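# Methods

## The genetic score

Each scored SNP contributes a relative-risk factor: the genotypic odds ratio
`OR**g` under the multiplicative (log-additive) allelic model, divided by the
population-average genotypic OR `w = p²·OR² + 2p(1−p)·OR + (1−p)²`, where `p`
is the risk-allele frequency and Hardy–Weinberg proportions are assumed. The
subject's score is the product of the factors over the panel. Two identities
follow and are asserted in the test suite:

* per SNP, the HWE-weighted mean factor is exactly 1 (checked to 1e-12);
* for subjects drawn at the model's frequencies **under linkage
  equilibrium**, the expected score is 1. Correlated SNPs break this — the
  product of two positively correlated above-1 factors has mean above 1 —
  which is the statistical reason score panels are LD-pruned, not just a
  bookkeeping convention.

Assumptions worth stating: ORs are treated as fixed external inputs (they
are not re-estimated during scoring; the association module exists for
estimation), risk factors combine multiplicatively with no interaction or
dominance terms, and the frequency `p` should describe the population the
subject is compared against. The frequency source is configurable —
`external` (reference panel) or `controls` (computed from the cohort) — and
is recorded in every model entry; external is the default when supplied
because control-derived frequencies inherit sampling noise and
case-control ascertainment.

A missing genotype contributes a neutral factor of 1 (the population-average
risk) and increments `n_missing`; this shrinks the subject toward the
population mean rather than biasing the score in either direction. A subject
missing every panel SNP has no defined score and is an error.

## Model building

`build_model` re-orients protective entries (OR < 1 becomes 1/OR on the
other allele, frequency becomes 1−p) so every stored OR is ≥ 1, matching how
risk panels are conventionally reported. Of any SNP pair whose r² meets the
pruning threshold (default 0.5), one member is retained: an explicitly
designated one, else the one with the smaller association p-value, else the
build fails naming the pair. Pruning uses r² from `ld_r2`, an EM estimate of
haplotype frequencies from unphased genotypes (double heterozygotes are the
only ambiguous class; convergence tolerance 1e-12, cap 1,000 iterations).

## Association screen

Per SNP: the minor allele is defined in the combined sample; allele counts
exclude missing genotypes pairwise. The OR is the 2×2 cross-product ratio
with a Woolf (log-OR ± 1.96·SE) 95% CI; the p-value is the Pearson
chi-square of the allele table without continuity correction, switching to
the two-sided Fisher exact test when the combined minor-allele frequency is
below 5%. The combined-sample frequency is used for the switch because it is
the symmetric choice when neither group is singled out. Zero cells receive
the Haldane–Anscombe 0.5 correction for the OR/CI only, and the result is
flagged rather than silently adjusted. Logistic regression (additive dosage,
Wald inference) is provided separately for covariate adjustment; whether a
screen's published p-values came from the crude allelic test or a logistic
fit is often unstated, so both routes are exposed. The Hardy–Weinberg check
is the conditional-on-allele-counts exact enumeration (no mid-p variant),
computed in controls; monomorphic SNPs return p = 1 by convention. The
Bonferroni threshold is alpha divided by the number of SNPs screened.

## Stratification and evaluation

Fixed-cutpoint strata are half-open intervals `[c_i, c_{i+1})` with the top
stratum closed below only — the single consistent reading of overlapping
printed labels like "0.8–1.2" next to "≥1.2". Quantile strata split at the
pooled (cases + controls) quantiles with boundary ties assigned to the lower
group, making heavily tied data deterministic. "Likelihood" is the
in-sample case percentage per stratum; it depends on the case:control
sampling ratio and is not calibrated to population incidence — the package
reports it as such and nothing more. The trend test is standard
Cochran–Armitage with integer scores 0..k−1 and no continuity correction
(affine-invariant in the scores; for k = 2 it equals the 2×2 chi-square).
Between-stratum ORs are cross-product ratios with a flagged 0.5 correction
on zero cells.

AUC is the midrank Mann–Whitney statistic; the ROC polyline sweeps every
unique score so its trapezoidal area equals the midrank AUC to machine
precision. The default 95% CI is DeLong's paired-placement variance, with
Hanley–McNeil available for comparison; the choice matters little above a
thousand subjects (asserted in tests) and DeLong is the field's default.

## The simulator

`simulate_case_control` draws genotypes for a general population —
independent SNPs as two Bernoulli(p) alleles, designated pairs as two
haplotypes from frequencies constructed to hit a target r² (positive
disequilibrium D by default; a flag selects negative) — then assigns disease
by a logistic model, log-odds = baseline + Σ g·log(OR), and accumulates
subjects by rejection sampling until the case and control quotas fill. This
is the generative model whose per-allele OR equals the multiplicative OR the
score assumes, and the OR is preserved under case-control ascertainment.
Ages are drawn per group from normal distributions after status is known.

Defaults are the emulated study's conditions: 346 cases / 1,130 controls;
panel ORs 1.41 (rs10054504), 1.67 (rs7023329), 1.79 (rs718314), 1.58
(rs1049380); the rs718314–rs1049380 pair at r² = 0.58; case ages 55.9 ± 12.5
vs control ages 51.2 ± 9.7 years. Risk-allele frequencies are not published
for this panel: rs7023329's A-allele frequency 0.51 is recovered from the
printed control minor-allele frequency (1 − 0.490); the others (0.45, 0.30,
0.40) are realistic Han-Chinese-range values fixed once. The baseline
log-odds default of −4 is arbitrary (≈ 5–6% pre-ascertainment disease rate);
it shifts only the intercept and is irrelevant to OR recovery. The draw
budget (5,000,000 subjects) guards against unreachable quotas under extreme
baselines. Seeding: one master seed drives a single generator stream;
identical configs and seeds give byte-identical cohorts.

What the simulator does **not** emulate: genotyping error and missingness
patterns, population structure or admixture, realistic genome-wide LD beyond
the designated pairs, covariate-genotype correlation, and secular or
recruitment effects on age. Passing tests therefore demonstrate that the
statistical machinery is correct under the model's own assumptions, not that
those assumptions hold in any particular cohort.

`expected_auc` is an exact oracle for the simulated pipeline: it enumerates
every genotype combination (including LD-pair joint distributions), computes
the case and control genotype distributions implied by the logistic risk,
and integrates P(score_case > score_control) + ½P(tie) directly. Large-cohort
empirical AUCs are checked against it to 0.005.

## Problem sizes and numerical choices

Tests run at the sizes the checks need: exactness identities at 1,000 random
parameter draws; population-mean and LD round-trips at 20,000–50,000
subjects; CI-coverage at 500 replicates of the full study dimensions;
type-I-error calibration at 10,000 replicates. Exact-test p-value
comparisons use a 1 + 1e-12 relative tolerance when summing "no more
probable than observed" configurations, avoiding floating-point ties.
Degenerate inputs fail loudly: monomorphic SNPs in LD or OR computations,
empty status groups, constant dosage in logistic fits, all-identical scores
in quantile binning, and exhausted simulation budgets all raise with
specific messages, except where a convention is standard (monomorphic HWE
p = 1, empty stratum flagged NaN).

## Known limitations

* The score's population normalization is only as good as the supplied
  risk-allele frequencies; a mismatched reference population shifts every
  score multiplicatively.
* The allelic chi-square assumes HWE in the combined sample; the screen
  reports the control HWE p so users can judge, but does not gate on it.
* DeLong intervals can degenerate at AUC near 0 or 1 with small samples;
  the package flags rather than widens them.
* Ped/map and TSV inputs are two-character biallelic genotypes only; no
  imputed (fractional) dosages.
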