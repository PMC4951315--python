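"""Build an LD-pruned risk model and compute population-normalized scores.

A protective OR (0.60 for the G allele) is re-oriented into a risk-allele
entry (A, 1.67); of the SNP pair in LD at r² = 0.58 only the more significant
member is kept. Each subject's score multiplies per-SNP relative risks
(genotypic OR over the HWE population average), so the population mean is 1.
"""

from snpscore import SimConfig, build_model, ld_r2, score_table, \
    simulate_case_control

config = SimConfig(seed=1)
cohort = simulate_case_control(config)

candidates = [
    ("rs10054504", "T", "C", 1.41),
    ("rs7023329", "G", "A", 0.60),   # protective as reported; gets inverted
    ("rs718314", "G", "A", 1.79),
    ("rs1049380", "A", "G", 1.58),
]
freqs = {"rs10054504": 0.45, "rs7023329": 0.49, "rs718314": 0.30,
         "rs1049380": 0.40}
r2 = ld_r2(cohort.dosage_of("rs718314"), cohort.dosage_of("rs1049380"))
model = build_model(
    candidates, freqs,
    ld={frozenset({"rs718314", "rs1049380"}): r2}, ld_threshold=0.5,
    pvalues={"rs718314": 5.26e-8, "rs1049380": 0.0025},
)
print(f"estimated r²(rs718314, rs1049380) = {r2:.3f}")
print("model:", [(e.rsid, e.risk_allele, e.allelic_or) for e in model])

scores = score_table(cohort, model)
for grp, name in ((1, "cases"), (0, "controls")):
    s = scores.loc[scores.status == grp, "score"]
    print(f"{name}: median score {s.median():.2f} "
          f"(IQR {s.quantile(0.25):.2f}-{s.quantile(0.75):.2f})")
# Scores above 1 mean above-average inherited risk; the case median should
# sit clearly above the control median.
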