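"""Per-SNP association screen on a simulated cohort.

For each SNP: minor-allele frequencies in cases (F_A) and controls (F_U),
the allelic OR with its Woolf 95% CI, a chi-square p (Fisher exact when the
combined minor-allele frequency is under 5%), and the HWE exact p in
controls. SNPs are flagged against the Bonferroni threshold alpha / n_snps.
"""

from snpscore import SimConfig, association_scan, simulate_case_control

config = SimConfig(seed=1)
cohort = simulate_case_control(config)
screen = association_scan(cohort, alpha=0.05)

cols = ["rsid", "minor", "major", "F_A", "F_U", "OR", "L95", "U95", "P",
        "hwe_p_controls", "significant"]
print(screen[cols].round(4).to_string(index=False))
print(f"\nBonferroni threshold: {screen.attrs['bonferroni_threshold']:.4g}")
# An OR above 1 means the minor allele is enriched in cases. With true
# per-allele ORs of 1.4-1.8, the stronger SNPs clear the corrected threshold
# at this sample size while the weakest (true OR 1.41) is borderline; HWE
# p-values in controls should look unremarkable.
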