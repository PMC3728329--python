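# radresponse

Tools for contrasting the **long-term** transcriptional response to ionizing
radiation with the **acute** response in the same tissue, built around a
five-group microarray design: an unirradiated control (A), two groups
irradiated as embryos at 0.1 or 1.0 Gy and profiled 16 weeks later (B, C —
the long-term response), and two groups irradiated as adults at the same
doses 4 h before profiling (D, E — the acute response), with three replicate
pools per group. The package is aimed at analysts who want this
analysis chain as a tested, reusable Python library rather than a one-off
script: every stage is importable on its own, and a synthetic-data generator
with known ground truth makes the whole chain verifiable end to end.

## What it computes

**Preprocessing.** The RMA chain for raw probe-level intensities —
normal+exponential convolution background correction, quantile
normalization, log2, and median-polish summarization of the additive model
log2 I_ij ≈ μ + probe_i + sample_j — or, starting from a probe-set-level
matrix, just the detection filter: probe sets with IQR < 0.2 log2 units
across samples are treated as undetected and removed.

**Moderated contrasts.** Per probe set, a one-way cell-means model over the
five groups. Residual variances s²_g (df d_g) are shrunk by the
empirical-Bayes scaled-inverse-χ² prior (d₀, s₀²), estimated from the
moments of log s²_g via digamma/trigamma equations:

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)

Six contrasts of the group means are tested with moderated t statistics on
d₀ + d_g df — TIME (long-term vs acute), DOSE (0.1 vs 1.0 Gy), TIME×DOSE,
and each response class (and all irradiated samples) vs control. No
contrast may be called significant unless the omnibus moderated F over the
four between-group df is itself significant after Benjamini–Hochberg
adjustment at 5% FDR (the "overall-F gate").

**Response classification.** Each comparison is encoded −1/0/+1; probe sets
with dose dependence, interaction, or discrepant control comparisons are
excluded, and the rest partition into *long-term-primary* and
*acute-primary* categories with ranked top-gene tables (fold change
2^|β̂|, reciprocal convention for decreases).

**Gene-set tests.** For each gene set, inter-sample Euclidean distances
over the member probe sets are embedded in two dimensions by classical
(Torgerson) MDS; group separation of the coordinates is measured by
Hotelling's T² (two pooled sides) or Pillai's trace (five groups), with
significance from permuting the full sample labeling:
p = (1 + #{perm ≥ obs}) / (B + 1), BH-adjusted across sets.

**qPCR cross-validation.** ΔΔCt fold changes against the RPL13a internal
reference (FC = 2^−ΔΔCt) and OLS concordance of qPCR vs array log2 fold
changes (slope, intercept, R²).

## Worked example

```python
import radresponse as rr

params = rr.SimulationParams(n_probesets=5000, seed=1)
matrix, design, truth = rr.simulate_probeset_matrix(params)
filtered, removed = rr.iqr_filter(matrix, rr.FilterConfig(0.2))
mfit = rr.moderated_tests(rr.fit_group_means(filtered, design), q=0.05)
print(len(removed), int(mfit.gate.sum()), round(mfit.prior.d0, 2))
```

prints `1071 1614 4.47`: of 5,000 simulated probe sets, 1,071 fall below
the detection filter, 1,614 pass the overall-F gate, and the estimated
prior df (4.47) recovers the simulated value of 4. Continuing,

```python
categories = rr.classify_all(mfit)
print(categories["category"].value_counts().to_dict())
```

gives `{'unassigned': 2435, 'acute_primary': 704, 'long_term_primary': 577,
'excluded_discrepant': 158, 'excluded_dose': 43, 'excluded_interaction': 12}`
— the partition of tested probe sets into response categories. The scripts
in `examples/` walk through each capability (simulation, differential
expression, classification, pathway MANOVA, qPCR concordance, and the
file-based end-to-end pipeline) and print what every number means.

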