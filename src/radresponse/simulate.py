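"""Synthetic data with known truth, matching the five-group study design.

The generator emulates the structure the analysis assumes: five treatment
groups (A control, B/C long-term 0.1/1.0 Gy, D/E acute 0.1/1.0 Gy) with
three replicates each, thousands of probe sets, a dominant exposure-timing
effect with a much smaller dose effect, heteroscedastic per-probe-set
variances drawn from the scaled-inverse-chi2 family the empirical-Bayes
moderation model assumes, a slab of near-constant "undetected" rows for
the IQR filter to remove, planted coordinated gene sets for the pathway
test, and matched qPCR Ct values for the ddCt cross-validation.

Planted effect magnitudes follow the two response regimes: long-term
effects up to ~log2(7) (the most affected long-term transcripts changed
~5-7 fold) and acute effects up to ~log2(30) (~25-30 fold).

Truth classes per probe set:

    none                no planted effect
    time                long-term and acute groups shifted oppositely
    dose                0.1 vs 1.0 Gy shift
    interaction         timing x dose interaction
    long_term_primary   long-term vs control effect; acute zero or
                        same-sign smaller
    acute_primary       acute vs control effect; long-term zero or
                        same-sign smaller
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GROUPS, ExpressionMatrix, SampleDesign
from .diffexpr import CONTRASTS
from .errors import DataError, ParameterError
from .pathway import GeneSetCollection
from .qpcr import DEFAULT_REFERENCE

__all__ = [
    "SimulationParams",
    "TruthTable",
    "simulate_probeset_matrix",
    "simulate_probe_level",
    "simulate_qpcr",
]

LOG2_7 = float(np.log2(7.0))
LOG2_30 = float(np.log2(30.0))


@dataclass
class SimulationParams:
    """All knobs of the generator; a fixed seed fixes every output bit-for-bit."""

    n_probesets: int = 5000
    n_groups: int = 5
    n_reps: int = 3
    frac_time: float = 0.30          # probe sets whose expression depends on timing
    frac_dose: float = 0.01          # dose effect is an order of magnitude rarer
    frac_interaction: float = 0.01
    #: planted |log2 effect| bounds per effect kind
    effect_log2: dict = field(default_factory=lambda: {
        "long_term": (0.5, LOG2_7),
        "acute": (0.5, LOG2_30),
        "time": (0.5, 2.0),
        "dose": (0.5, 1.5),
        "interaction": (0.5, 1.5),
    })
    baseline_mean: float = 7.0       # log2 units
    baseline_sd: float = 2.0
    d0_true: float = 4.0             # prior df of the variance distribution
    s0sq_true: float = 0.05          # prior variance (log2^2 units)
    frac_undetected: float = 0.10    # near-constant rows, removed by the IQR filter
    n_sets: int = 10                 # planted gene sets (half shifted, half null)
    set_size: int = 20
    set_shift: float = 1.0           # coordinated log2 shift of shifted sets (acute groups)
    probes_per_set: int = 11
    probe_affinity_sd: float = 0.7   # log2 spread of per-probe affinities
    probe_noise_sd: float = 0.25     # log2 measurement noise at probe level
    bg_scale: float = 30.0           # mean of the exponential raw-scale background
    ct_intercept: float = 30.0       # Ct of a transcript at log2 expression 0
    ct_noise_sd: float = 0.2         # cycles
    ct_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_time", "frac_dose", "frac_interaction", "frac_undetected"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.frac_time + self.frac_dose + self.frac_interaction > 1.0 + 1e-12:
            raise ParameterError("effect fractions must sum to <= 1")
        if (self.frac_time + self.frac_dose + self.frac_interaction
                + self.frac_undetected) > 1.0 + 1e-12:
            raise ParameterError("effect + undetected fractions must sum to <= 1")
        for name in ("n_probesets", "n_groups", "n_reps", "probes_per_set", "ct_reps"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        if self.probes_per_set < 2:
            raise ParameterError("probes_per_set must be >= 2")
        if not 2 <= self.n_groups <= len(GROUPS):
            raise ParameterError(f"n_groups must be in [2, {len(GROUPS)}]")
        if self.d0_true <= 0 or self.s0sq_true <= 0:
            raise ParameterError("d0_true and s0sq_true must be positive")
        if self.n_sets and self.set_size < 3:
            raise ParameterError("set_size must be >= 3")

    @property
    def groups(self) -> list[str]:
        return list(GROUPS[: self.n_groups])


@dataclass
class TruthTable:
    """Ground truth emitted alongside every simulated dataset."""

    table: pd.DataFrame          # per probe set: class, variance, four effect columns
    group_means: pd.DataFrame    # true mean log2 expression, probe sets x groups
    sets: GeneSetCollection      # planted gene sets
    set_shifted: pd.Series       # set id -> bool

    def contrast_effects(self) -> pd.DataFrame:
        """True value of each study contrast per probe set."""
        groups = list(self.group_means.columns)
        out = {}
        for name, c in CONTRASTS.items():
            cvec = np.asarray(c)[: len(groups)]
            out[name] = self.group_means.to_numpy() @ cvec
        return pd.DataFrame(out, index=self.group_means.index)


def _class_counts(params: SimulationParams) -> dict[str, int]:
    n = params.n_probesets
    n_time_total = int(round(params.frac_time * n))
    n_lt = int(round(0.4 * n_time_total))
    n_ac = int(round(0.4 * n_time_total))
    n_pure = n_time_total - n_lt - n_ac
    counts = {
        "long_term_primary": n_lt,
        "acute_primary": n_ac,
        "time": n_pure,
        "dose": int(round(params.frac_dose * n)),
        "interaction": int(round(params.frac_interaction * n)),
        "undetected": int(round(params.frac_undetected * n)),
    }
    total = sum(counts.values())
    if total > n:
        raise ParameterError("effect fractions allocate more rows than n_probesets")
    counts["none"] = n - total
    return counts


def _draw_mag(rng: np.random.Generator, bounds: tuple[float, float], size: int) -> np.ndarray:
    lo, hi = bounds
    return rng.uniform(lo, hi, size)


def simulate_probeset_matrix(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, SampleDesign, TruthTable]:
    """Simulate the probe-set x sample log2 matrix with its design and truth."""
    rng = np.random.default_rng([params.seed, 0])
    n = params.n_probesets
    groups = params.groups
    ids = [f"ps{i:05d}" for i in range(n)]

    counts = _class_counts(params)
    order = rng.permutation(n)
    classes = np.empty(n, dtype=object)
    pos = 0
    slabs = {}
    for cls in ("long_term_primary", "acute_primary", "time", "dose",
                "interaction", "undetected", "none"):
        k = counts[cls]
        slabs[cls] = order[pos: pos + k]
        classes[slabs[cls]] = "none" if cls == "undetected" else cls
        pos += k
    undetected = np.zeros(n, dtype=bool)
    undetected[slabs["undetected"]] = True

    lt_eff = np.zeros(n)
    ac_eff = np.zeros(n)
    dose_eff = np.zeros(n)
    int_eff = np.zeros(n)

    idx = slabs["long_term_primary"]
    if idx.size:
        sign = rng.choice([-1.0, 1.0], idx.size)
        mag = _draw_mag(rng, params.effect_log2["long_term"], idx.size)
        lt_eff[idx] = sign * mag
        secondary = rng.random(idx.size) < 0.5
        ac_eff[idx] = np.where(
            secondary, sign * mag * rng.uniform(0.2, 0.7, idx.size), 0.0
        )
    idx = slabs["acute_primary"]
    if idx.size:
        sign = rng.choice([-1.0, 1.0], idx.size)
        mag = _draw_mag(rng, params.effect_log2["acute"], idx.size)
        ac_eff[idx] = sign * mag
        secondary = rng.random(idx.size) < 0.5
        lt_eff[idx] = np.where(
            secondary, sign * mag * rng.uniform(0.2, 0.7, idx.size), 0.0
        )
    idx = slabs["time"]
    if idx.size:
        delta = rng.choice([-1.0, 1.0], idx.size) * _draw_mag(
            rng, params.effect_log2["time"], idx.size
        )
        lt_eff[idx] = delta / 2.0
        ac_eff[idx] = -delta / 2.0
    idx = slabs["dose"]
    if idx.size:
        dose_eff[idx] = rng.choice([-1.0, 1.0], idx.size) * _draw_mag(
            rng, params.effect_log2["dose"], idx.size
        )
    idx = slabs["interaction"]
    if idx.size:
        int_eff[idx] = rng.choice([-1.0, 1.0], idx.size) * _draw_mag(
            rng, params.effect_log2["interaction"], idx.size
        )

    # planted gene sets: members drawn from the unaffected pool; shifted sets
    # receive a coordinated acute-group shift (they become acute_primary rows)
    sets: dict[str, list[str]] = {}
    shifted: dict[str, bool] = {}
    if params.n_sets:
        pool = list(slabs["none"])
        need = params.n_sets * params.set_size
        if need > len(pool):
            raise ParameterError(
                f"gene sets need {need} unaffected rows but only {len(pool)} exist"
            )
        chosen = rng.choice(len(pool), size=need, replace=False)
        n_shifted = params.n_sets // 2
        for s in range(params.n_sets):
            member_rows = [pool[j] for j in chosen[s * params.set_size:(s + 1) * params.set_size]]
            set_id = f"set{s:03d}"
            sets[set_id] = [ids[r] for r in member_rows]
            is_shifted = s < n_shifted
            shifted[set_id] = is_shifted
            if is_shifted:
                rows = np.array(member_rows)
                ac_eff[rows] = params.set_shift
                classes[rows] = "acute_primary"

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, n)
    means = pd.DataFrame(
        {g: baseline.copy() for g in groups}, index=ids
    )
    for g in groups:
        col = means[g].to_numpy()
        if g in ("B", "C"):
            col += lt_eff
        if g in ("D", "E"):
            col += ac_eff
        if g in ("B", "D"):
            col += dose_eff / 2.0
        if g in ("C", "E"):
            col -= dose_eff / 2.0
        if g == "B":
            col += int_eff / 4.0
        if g == "C":
            col -= int_eff / 4.0
        if g == "D":
            col -= int_eff / 4.0
        if g == "E":
            col += int_eff / 4.0
        means[g] = col

    if np.isinf(params.d0_true):
        variances = np.full(n, params.s0sq_true)
    else:
        chi2 = rng.chisquare(params.d0_true, n)
        variances = params.s0sq_true * params.d0_true / chi2
    variances[undetected] = np.minimum(variances[undetected], 0.0025)

    samples = [f"{g}{r + 1}" for g in groups for r in range(params.n_reps)]
    design = SampleDesign.from_groups({s: s[0] for s in samples})
    noise = rng.normal(size=(n, len(samples))) * np.sqrt(variances)[:, None]
    values = means[[s[0] for s in samples]].to_numpy() + noise
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=ids, columns=samples), scale="log2"
    )
    matrix.data.index.name = "probe_set"

    truth_tbl = pd.DataFrame(
        {
            "class": classes,
            "variance": variances,
            "lt_effect": lt_eff,
            "ac_effect": ac_eff,
            "dose_effect": dose_eff,
            "interaction_effect": int_eff,
            "undetected": undetected,
        },
        index=ids,
    )
    truth_tbl.index.name = "probe_set"
    truth = TruthTable(
        table=truth_tbl,
        group_means=means,
        sets=GeneSetCollection(sets, {k: f"planted set ({'shifted' if v else 'null'})"
                                      for k, v in shifted.items()}),
        set_shifted=pd.Series(shifted, dtype=bool),
    )
    return matrix, design, truth


def simulate_probe_level(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, pd.Series, TruthTable]:
    """Simulate raw-scale probe-level intensities for the RMA chain.

    Per probe j of probe set i: intensity = 2^(signal_is + affinity_ij +
    noise) + exponential background, where signal_is is the probe-set
    log2 value from :func:`simulate_probeset_matrix` and affinities sum
    to zero within each probe set.  Truth refers to the probe-set level.
    """
    matrix, design, truth = simulate_probeset_matrix(params)
    rng = np.random.default_rng([params.seed, 1])
    n, m = matrix.shape
    J = params.probes_per_set
    affinities = rng.normal(0.0, params.probe_affinity_sd, (n, J))
    affinities -= affinities.mean(axis=1, keepdims=True)

    signal = matrix.values  # n x m
    log2_probe = (
        signal[:, None, :]
        + affinities[:, :, None]
        + (rng.normal(0.0, params.probe_noise_sd, (n, J, m))
           if params.probe_noise_sd > 0 else 0.0)
    )
    raw = np.exp2(log2_probe)
    if params.bg_scale > 0:
        raw = raw + rng.exponential(params.bg_scale, (n, J, m))

    probe_ids = [f"{ps}:{j:02d}" for ps in matrix.row_ids for j in range(J)]
    probe_map = pd.Series(
        np.repeat(matrix.row_ids.to_numpy(), J), index=probe_ids, name="probe_set"
    )
    probe_matrix = ExpressionMatrix(
        pd.DataFrame(raw.reshape(n * J, m), index=probe_ids, columns=matrix.col_ids),
        scale="raw",
    )
    return probe_matrix, probe_map, truth


def simulate_qpcr(
    truth: TruthTable,
    genes: list[str],
    params: SimulationParams,
) -> pd.DataFrame:
    """Simulate a Ct table for the requested genes plus the reference gene.

    Ct = intercept - true log2 expression + noise; the reference gene has
    constant expression across groups, so its fold change is 1 in
    expectation.
    """
    missing = [g for g in genes if g not in truth.group_means.index]
    if missing:
        raise DataError(f"genes absent from truth: {missing[:5]}")
    rng = np.random.default_rng([params.seed, 2])
    groups = list(truth.group_means.columns)
    rows = []
    ref_level = params.baseline_mean

    def emit(gene: str, level_by_group):
        for g in groups:
            for r in range(params.ct_reps):
                ct = params.ct_intercept - level_by_group(g) + (
                    rng.normal(0.0, params.ct_noise_sd) if params.ct_noise_sd > 0 else 0.0
                )
                rows.append({"gene": gene, "group": g, "replicate": r + 1, "ct": ct})

    emit(DEFAULT_REFERENCE, lambda g: ref_level)
    for gene in genes:
        emit(gene, lambda g, gene=gene: truth.group_means.at[gene, g])
    return pd.DataFrame(rows, columns=["gene", "group", "replicate", "ct"])
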