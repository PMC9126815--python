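"""Worst-case fold-change selection on a simulated sequencing design.

Simulates the 4-population × 2-condition count design with planted
fold changes, then runs RPM → >10 RPM filter → worst-case 1.5-fold
selection, cross-population intersection, PCA and Fisher enrichment.
"""

import numpy as np

import socialphys as sp
from socialphys.synth import SyntheticCountDesign, simulate_counts

design = SyntheticCountDesign(n_genes=2000, de_fraction=0.05,
                              log2fc_range=(1.5, 2.5), dispersion=0.02,
                              de_populations=("D1pos", "D1neg"), seed=4)
table, truth = simulate_counts(design)
rpm = sp.filter_expressed(sp.rpm_normalize(table), min_rpm=10.0)
print(f"genes above 10 RPM: {len(rpm)} / {design.n_genes}")

results = {}
for pop in ("D1pos", "D1neg"):
    a = table.sample_ids(population=pop, infection="infected", condition="scr")
    b = table.sample_ids(population=pop, infection="infected", condition="sh")
    results[pop] = sp.worst_case_fc(rpm, a, b, threshold=1.5)
    print(f"{pop}: {len(results[pop].selected)} genes selected at "
          f"worst-case 1.5-fold")

inter = sp.intersect_de(results)
print(f"shared across populations: {len(inter['shared'])}, "
      f"union: {len(inter['union'])}")

pca = sp.pca_transform(rpm.loc[sorted(inter["union"])])
print("PC1 variance fraction:", round(pca["explained_variance_ratio"][0], 3))

# enrichment of the D1pos selection in the planted-truth set
universe = set(rpm.index)
enr = sp.fisher_enrichment(set(results["D1pos"].selected),
                           set(truth.index[truth.is_de]) & universe, universe)
print(f"Fisher enrichment vs planted truth: OR = {enr.odds_ratio:.1f}, "
      f"p = {enr.p_value:.2e}")
# The selection recovers the planted genes (high odds ratio, tiny p);
# scr/sh samples of the affected populations separate along PC1.
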