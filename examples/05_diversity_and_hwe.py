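"""Per-population diversity summaries and Hardy-Weinberg screening.

Builds the standard per-population diversity table (alleles, allelic
richness, heterozygosities, F_IS) and runs exact HWE tests per locus with
a false-discovery-rate adjustment.
"""
from gentag import simulate as sim
from gentag.popstats import adjust_pvalues, diversity_summary, hwe_exact_test

ds = sim.field_survey_dataset(seed=31)
summary = diversity_summary(ds, g_genes=14)  # richness rarefied to 7 diploids
print(summary.table().round(3).to_string(index=False))

pop = ds.populations[0]
pvals, labels = [], []
for locus in ds.locus_names:
    res = hwe_exact_test(ds, pop, locus, seed=32)
    if res.applicable:
        pvals.append(res.p_value)
        labels.append(locus)
adjusted = adjust_pvalues(pvals, "fdr_bh")
n_sig = int((adjusted <= 0.05).sum())
print(f"\nHWE exact tests in {pop}: {len(pvals)} loci, "
      f"{n_sig} out of equilibrium after FDR correction")
# Under random mating (how the data were simulated) most loci should sit
# comfortably inside Hardy-Weinberg expectations after FDR control.
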