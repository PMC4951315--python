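"""Simulate a case-control cohort with the emulated study structure.

Draws 346 cases and 1,130 controls carrying a four-SNP risk panel (per-allele
ORs 1.41-1.79, one SNP pair in LD at r²=0.58), with older cases than
controls, and writes the genotypes plus the true score model to TSV.
"""

from snpscore import SimConfig, simulate_case_control, write_genotypes_tsv, \
    write_score_model

config = SimConfig(seed=1)
cohort = simulate_case_control(config)
write_genotypes_tsv(cohort, "scratch_cohort.tsv")
write_score_model(config.score_model(["rs10054504", "rs7023329", "rs718314"]),
                  "scratch_model.tsv")

n_case = int(cohort.status.sum())
print(f"cohort: {n_case} cases / {cohort.n_subjects - n_case} controls, "
      f"{cohort.n_snps} SNPs")
print(f"mean age cases {cohort.age[cohort.status == 1].mean():.1f}, "
      f"controls {cohort.age[cohort.status == 0].mean():.1f}")
print("wrote scratch_cohort.tsv and scratch_model.tsv")
# The age gap mirrors typical case-control recruitment; genotype frequencies
# differ between groups only through the logistic disease model.
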