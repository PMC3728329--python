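"""ddCt quantification and microarray-vs-qPCR concordance.

Ct values are converted to fold changes relative to the RPL13a internal
reference and the unirradiated control group A; concordance with the
array estimates is summarized by OLS of qPCR log2 fold change on array
log2 fold change.
"""

import numpy as np

import radresponse as rr

params = rr.SimulationParams(n_probesets=5000, seed=1)
matrix, design, truth = rr.simulate_probeset_matrix(params)
filtered, _ = rr.iqr_filter(matrix)
fit = rr.fit_group_means(filtered, design)

# validate the 8 most strongly affected detected transcripts
effects = (truth.table["lt_effect"].abs() + truth.table["ac_effect"].abs())
genes = list(effects.loc[filtered.row_ids].sort_values(ascending=False).head(8).index)
ct = rr.simulate_qpcr(truth, genes, params)

array_fc, qpcr_fc = [], []
for gene in genes:
    for group in "BCDE":
        res = rr.ddct_fold_change(ct, gene, group, "A")
        qpcr_fc.append(-res.ddct)           # log2 fold change from ddCt
        array_fc.append(fit.means.at[gene, group] - fit.means.at[gene, "A"])

gene, group = genes[0], "D"
res = rr.ddct_fold_change(ct, gene, group, "A")
print(f"example: {gene} in group {group}: ddCt = {res.ddct:.2f} "
      f"-> fold change {res.fold_change:.2f}")

conc = rr.concordance(np.array(array_fc), np.array(qpcr_fc))
print(f"\nconcordance over {conc.n} (gene, group) points:")
print(f"  R^2 = {conc.r2:.3f}  slope = {conc.slope:.3f}  "
      f"intercept = {conc.intercept:.3f} (x{conc.fold_offset:.2f} on the fold scale)")
# R^2 near 1 and slope near 1 mean the two platforms agree; a slope or
# offset above 1 would indicate qPCR reporting systematically larger changes.
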