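# Methods

## The design and its factors

Five treatment groups with three replicate pools each: A (unirradiated
control), B and C (irradiated early in development at 0.1 and 1.0 Gy,
profiled 16 weeks later — the long-term response), D and E (irradiated as
adults at the same doses 4 h before profiling — the acute response). Two
derived factors span the irradiated groups: exposure timing
(long-term = B∪C vs acute = D∪E) and dose (0.1 Gy = B∪D vs 1.0 Gy = C∪E).
All expression values are log2; fold changes are reported as 2^|Δ| with a
direction flag, so fold-up and fold-down values are reciprocals.

## Preprocessing

`background_correct` fits the normal+exponential convolution model per
array: observed intensity X = S + N with S ~ Exp(α) (true signal) and
N ~ N(μ, σ²) (optical/background noise), returning the posterior mean
E[S | X = x] = a + σ·φ(a/σ)/Φ(a/σ) with a = x − μ − σ²/α. The parameters
are estimated by maximum likelihood of the convolution density, started
from method-of-moments values (the skewness identifies α through
E[(X−EX)³] = 2α³); the likelihood is optimized in (μ, log σ, log α) with
Nelder–Mead. On simulated signal+background mixtures this recovers the
mean true signal within a few percent, which a pure mode/KDE plug-in
estimator did not reliably achieve on heavy-tailed intensity data.

`quantile_normalize` maps every column onto the across-column mean of the
order statistics; ties within a column receive the mean of their
tied-rank reference values. The transform is idempotent (exactly so for
tie-free data) and preserves within-column rank order.

`median_polish_summarize` fits log2 I ≈ overall + probe + sample per probe
set by alternating median sweeps, stopping when the total absolute
residual changes by less than 1% per cycle or after 10 cycles, and
returns overall + sample effects as the probe-set expression profile.
Single-probe sets pass through unchanged.

`iqr_filter` removes rows with interquartile range strictly below the
threshold (default 0.2 log2 units). The quartile interpolation rule
matters because the cutoff sits among real data values; the default is
linear interpolation of order statistics (R's type-7 quantile), and the
rule is exposed in `FilterConfig`.

## Moderated linear models

Per probe set a one-way cell-means fit gives group means, the residual
variance s²_g on d_g = n − k df, and contrast estimates β̂_c with unscaled
variance v_c = Σ_j c_j²/n_j. The empirical-Bayes prior assumes
s²_g ~ s₀²·F(d_g, d₀); taking z = log s²_g,

    E[z]   = log s₀² + ψ(d_g/2) − log(d_g/2) − ψ(d₀/2) + log(d₀/2)
    Var[z] = ψ′(d_g/2) + ψ′(d₀/2)

so d₀ solves ψ′(d₀/2) = Var[e] − ψ′(d_g/2) (Newton iteration on the
trigamma inverse) and s₀² follows from the mean equation. When the
observed spread of log variances does not exceed the theoretical χ²
spread, d₀ = ∞ and every posterior variance equals s₀²; note that in
this limit s₀² = s²·exp(log(d_g/2) − ψ(d_g/2)), the chi-square log-bias
correction of the common observed value, which approaches s² only as
d_g grows. Zero variances are excluded from the moment fit but still
shrunk. Posterior variances s̃²_g interpolate monotonically between the
d₀ = 0 (no moderation) and d₀ = ∞ (fully pooled) limits, and the whole
fit is cross-checked against Bioconductor limma in the test suite.

Moderated t = β̂_c/(s̃_g√v_c) on d₀ + d_g df (normal/χ² references in the
infinite-d₀ limit). The omnibus moderated F spans all k − 1 between-group
df by default ("full" gate); a 3-df variant over the TIME/DOSE/TIME×DOSE
subspace is available (`gate="contrasts"`) because the source text does
not state whether the omnibus test spans all five groups. BH adjustment
is applied separately within each contrast family and to the F family,
and the gate requires the F's adjusted p < q (default q = 0.05
everywhere). `bh_adjust` delegates to statsmodels' `fdr_bh` and is tested
against a literal step-up implementation.

## Response classification

Tri-state calls are nonzero only when the probe set passed the gate and
the comparison's adjusted p < q; the sign is the sign of β̂. Categories
are assigned in precedence order: DOSE ≠ 0 → excluded_dose; TIME×DOSE ≠ 0
→ excluded_interaction; opposite-sign LT and AC control calls →
excluded_discrepant; TIME ≠ 0 with at least one control comparison called
→ long_term_primary or acute_primary (when both are called — necessarily
with equal sign at this point — the side with the larger |log2 effect|
wins, ties to long-term, flagged in the output). Everything else is
unassigned. The precedence order is a package decision: the source
criteria enumerate the exclusions and the inclusion rule but not their
full interaction, and this ordering reproduces every stated case,
including "unchanged / up, less / down, less" cross-response annotations
in the ranked tables. The all-irradiated-vs-control comparison is
recorded but does not participate in assignment. The partition is total:
all 3⁶ = 729 tri-state patterns map to exactly one category (enumerated
in the tests). Ranked tables collapse probe sets sharing a gene symbol to
the one with the largest |fold change| and can drop unannotated rows.

## Gene-set tests

Classical (Torgerson) MDS: double-center −½·J·D²·J, eigendecompose, keep
the top-k eigenpairs with negative eigenvalues truncated at zero; the
coordinate of largest magnitude in each dimension is made positive so
the embedding is deterministic. With k = n − 1 the distance matrix of a
Euclidean configuration is reconstructed to < 1e−8.

The separation statistic on the 2-D coordinates is Hotelling's T² for
two groups and Pillai's trace tr(H(H+E)⁻¹) for more; rank-deficient
scatter matrices are handled with the Moore–Penrose pseudo-inverse
(flagged), which makes the statistic reduce exactly to its
lower-dimensional value when a coordinate is constant — a ridge would
only do so approximately.

Permutation scheme: distances and coordinates are computed once from all
samples; the statistic is evaluated on the samples carrying the compared
labels (e.g. control A vs pooled acute D∪E), and the null permutes the
full five-group labeling of all 15 samples. Permuting only the 9 samples
of a two-sided comparison would leave just C(9,3) = 84 distinct
labelings — a p-value floor of ~0.013 — whereas the full labeling has
15!/(3!)⁵ configurations and supports permutation p-values of order
10⁻³–10⁻⁴, the precision at which gene-set results of this design are
reported. p = (1 + #{perm ≥ obs})/(B + 1); B defaults to 9999. Distances
use the log2 values without re-standardization (a per-row z-score option
exists, as scaling before the distance computation is a genuinely open
choice). Sets with fewer than 3 members present in the filtered matrix
are skipped with a recorded reason, and BH FDR is applied across sets
within one comparison family.

## qPCR

ΔCt = mean Ct_target − mean Ct_reference per group, ΔΔCt relative to the
control group, FC = E^−ΔΔCt with amplification efficiency E = 2 (the
classic assumption; the parameter is exposed). The reference gene
defaults to RPL13a. Concordance is OLS of qPCR on array log2 fold
changes over per-gene, per-group mean points; both the slope and the
intercept (a multiplicative offset on the fold scale, 2^intercept) are
reported because a systematic platform difference can show up in either.

## The synthetic-data generator

Defaults emulate the study conditions: 5,000 probe sets, 5 × 3 samples, a
dominant timing effect (30% of rows) against a rare dose (1%) and
interaction (1%) effect, 10% near-constant "undetected" rows for the
detection filter, baseline log2 expression N(7, 2²), and per-row
variances from the scaled-inverse-χ² family with d₀ = 4, s₀² = 0.05 — the
same family the moderation model assumes, so the empirical-Bayes
estimator's target is well-defined and parameter recovery is a fair
test. Timing-affected rows split 40/40/20 into long-term-primary
(long-term vs control effect up to |log2 7| ≈ 2.8, matching the ~5–7-fold
dynamic range of the long-term response), acute-primary (up to
|log2 30| ≈ 4.9, the ~25–30-fold acute range), and pure-timing rows
(opposite half-effects in the two response classes, which exercise the
discrepant exclusion); primary rows carry a same-sign smaller secondary
effect on the other side half the time, mirroring the "up, less / down,
less" patterns. Ten planted gene sets of 20 unaffected rows each, half
given a coordinated +1 log2 acute shift, provide pathway-test truth; Ct
values are Ct = 30 − log2 expression + N(0, 0.2²) with a
constant-expression RPL13a reference. Probe-level output adds zero-sum
probe affinities N(0, 0.7²), probe-level noise N(0, 0.25²) on the log2
scale, and exponential background (mean 30) on the raw scale. A single
seed fixes every output bit-for-bit.

What the generator does **not** emulate: spatial chip artifacts,
probe-sequence (GC) effects, intensity-dependent variance trends,
cross-hybridization, correlated residuals between probe sets outside the
planted sets, and batch effects. Passing tests therefore demonstrate the
statistical machinery is correct under its stated model, not that the
model captures every failure mode of real arrays.

## Problem sizes and numerical choices

The test suite and the acceptance script use cohorts of 1,200–5,000 probe
sets, 20 null cohorts of 1,500 rows for gate calibration, and 1,000 null
gene sets × 199 permutations for permutation-test calibration — sizes
chosen so the full validation runs in well under a minute while leaving
Monte-Carlo error comfortably inside the asserted bounds. Median polish:
tolerance 0.01 on the relative change of total absolute residual, max 10
cycles. Trigamma inverse: Newton, 50 iterations, relative tolerance
1e−10. MDS eigenvalues clipped at zero; distance-matrix symmetry checked
to 1e−8. Permutation p-values use a 1e−12 tolerance when counting
perm ≥ obs so bit-identical re-draws of the observed labeling count as
ties. Degenerate inputs (all-zero variances, empty comparisons, sets
smaller than 3, zero-variance regressors) raise typed errors or recorded
skips rather than propagating NaNs.

## Known limitations

- GEO series-matrix parsing covers the standard text layout (metadata
  lines, one table block); exotic multi-table files are out of scope.
- The qPCR error model treats replicate ΔCt values as independent; shared
  plate effects are not modeled.
- The pathway statistic is computed on a fixed 2-D embedding; information
  in higher embedding dimensions is deliberately discarded, as the method
  is defined on two dimensions.
- With only three replicates per group, the dose and interaction
  contrasts have limited power; the generator's defaults reflect that
  rather than compensate for it.
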