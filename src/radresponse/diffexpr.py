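"""Five-group moderated linear models, contrasts, the overall-F gate, and BH FDR.

Per probe set the model is a one-way cell-means layout over the groups A-E.
Residual variances are moderated by the empirical-Bayes scaled-inverse-chi2
prior: s_g^2 are assumed to follow s0^2 * F(d_g, d0), the prior parameters
(d0, s0^2) are estimated by matching the mean and variance of log s_g^2 via
digamma/trigamma moment equations, and the posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces s_g^2 in every t and F statistic, with d0 + d_g degrees of freedom.

Six contrasts of the group means mu_A..mu_E are tested:

    TIME        (mu_B+mu_C)/2 - (mu_D+mu_E)/2   long-term vs acute
    DOSE        (mu_B+mu_D)/2 - (mu_C+mu_E)/2   0.1 Gy vs 1.0 Gy
    TIMExDOSE   (mu_B-mu_C) - (mu_D-mu_E)       timing x dose interaction
    LT_vs_CTRL  (mu_B+mu_C)/2 - mu_A
    AC_vs_CTRL  (mu_D+mu_E)/2 - mu_A
    TRT_vs_CTRL (mu_B+mu_C+mu_D+mu_E)/4 - mu_A

No contrast may be called significant unless the probe set's omnibus
between-group moderated F test is itself significant after BH adjustment
(the "overall-F gate"), which limits the multiplicity cost of reading six
comparisons per probe set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import GROUPS, ExpressionMatrix, SampleDesign
from .errors import DataError, DesignError, ParameterError

__all__ = [
    "CONTRASTS",
    "GroupFit",
    "VariancePrior",
    "ModeratedFit",
    "fit_group_means",
    "squeeze_variances",
    "moderated_tests",
    "bh_adjust",
]

#: Named contrast vectors over the ordered group means (A, B, C, D, E).
CONTRASTS: dict[str, np.ndarray] = {
    "TIME": np.array([0.0, 0.5, 0.5, -0.5, -0.5]),
    "DOSE": np.array([0.0, 0.5, -0.5, 0.5, -0.5]),
    "TIMExDOSE": np.array([0.0, 1.0, -1.0, -1.0, 1.0]),
    "LT_vs_CTRL": np.array([-1.0, 0.5, 0.5, 0.0, 0.0]),
    "AC_vs_CTRL": np.array([-1.0, 0.0, 0.0, 0.5, 0.5]),
    "TRT_vs_CTRL": np.array([-1.0, 0.25, 0.25, 0.25, 0.25]),
}


@dataclass
class GroupFit:
    """Per-probe-set least-squares fit of the cell-means model."""

    means: pd.DataFrame          # probe sets x groups
    s2: pd.Series                # residual variance per probe set
    df_residual: int             # n_samples - n_groups, shared
    n_per_group: pd.Series       # replicate count per group


@dataclass
class VariancePrior:
    """Empirical-Bayes variance prior and the posterior (squeezed) variances."""

    d0: float                    # prior degrees of freedom (np.inf allowed)
    s0sq: float                  # prior variance
    s2_post: pd.Series           # posterior variances per probe set


@dataclass
class ModeratedFit:
    """Full moderated-test results for one matrix + design."""

    group_fit: GroupFit
    prior: VariancePrior
    contrasts: dict[str, np.ndarray]
    q: float
    coefficients: pd.DataFrame   # beta-hat per contrast
    stdev_unscaled: pd.Series    # sqrt(v_c) per contrast (shared across rows)
    t: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    F: pd.Series
    F_df1: int
    F_p: pd.Series
    F_p_adj: pd.Series
    gate: pd.Series              # bool: overall-F BH-significant at q
    gate_mode: str = "full"

    @property
    def df_total(self) -> float:
        return self.prior.d0 + self.group_fit.df_residual

    def to_frame(self) -> pd.DataFrame:
        """One row per probe set: estimates, fold changes, t, p, adjusted p, F, gate."""
        out = {}
        for name in self.contrasts:
            beta = self.coefficients[name]
            out[f"{name}.log2fc"] = beta
            out[f"{name}.fold_change"] = 2.0 ** np.abs(beta)
            out[f"{name}.direction"] = np.where(beta >= 0, "up", "down")
            out[f"{name}.t"] = self.t[name]
            out[f"{name}.p"] = self.p[name]
            out[f"{name}.p_adj"] = self.p_adj[name]
        out["F"] = self.F
        out["F.p"] = self.F_p
        out["F.p_adj"] = self.F_p_adj
        out["gate"] = self.gate
        frame = pd.DataFrame(out, index=self.coefficients.index)
        frame.index.name = "probe_set"
        return frame


def fit_group_means(m: ExpressionMatrix, design: SampleDesign) -> GroupFit:
    """Ordinary least squares of the cell-means model, one row at a time.

    Returns per-row group means and the pooled residual variance with
    ``n - k`` degrees of freedom (k = number of groups present).
    """
    design = design.align_to(m)
    groups = design.groups_present()
    if not groups:
        raise DesignError("no samples in any group")
    vals = m.values
    n_total = vals.shape[1]
    counts = {}
    means = {}
    rss = np.zeros(vals.shape[0])
    for g in groups:
        cols = [i for i, s in enumerate(m.col_ids) if design.groups[s] == g]
        counts[g] = len(cols)
        sub = vals[:, cols]
        mg = sub.mean(axis=1)
        means[g] = mg
        rss += ((sub - mg[:, None]) ** 2).sum(axis=1)
    df = n_total - len(groups)
    if df <= 0:
        raise DesignError("no residual degrees of freedom: need replicates in some group")
    s2 = rss / df
    means_df = pd.DataFrame(means, index=m.row_ids)[groups]
    return GroupFit(
        means=means_df,
        s2=pd.Series(s2, index=m.row_ids, name="s2"),
        df_residual=df,
        n_per_group=pd.Series(counts, name="n"),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(
    s2: pd.Series | np.ndarray, df: float
) -> tuple[float, float, pd.Series]:
    """Estimate the scaled-inverse-chi2 variance prior and squeeze variances.

    Matches the first two moments of log s_g^2 to the log of a scaled F
    distribution: with z = log(s^2),

        E[z]   = log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2)
        Var[z] = psi'(df/2) + psi'(d0/2)

    so d0 solves psi'(d0/2) = Var[e] - psi'(df/2) with
    e = z - psi(df/2) + log(df/2).  When the observed spread of log
    variances is at or below the theoretical chi2 spread, d0 is infinite
    and every posterior variance equals s0^2.

    Zero variances are excluded from the moment fit but still squeezed.
    Returns (d0, s0sq, s2_post).
    """
    index = s2.index if isinstance(s2, pd.Series) else pd.RangeIndex(len(s2))
    s2v = np.asarray(s2, dtype=float)
    if df <= 0:
        raise ParameterError("residual degrees of freedom must be positive")
    pos = s2v > 0
    if not pos.any():
        raise DataError("all residual variances are zero; cannot estimate prior")
    if pos.sum() < 10:
        raise DataError(f"need >= 10 rows with positive variance, have {int(pos.sum())}")
    z = np.log(s2v[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0sq = float(np.exp(emean))
    s2_post = _posterior_variances(s2v, df, d0, s0sq)
    return d0, s0sq, pd.Series(s2_post, index=index, name="s2_post")


def _posterior_variances(s2: np.ndarray, df: float, d0: float, s0sq: float) -> np.ndarray:
    if np.isinf(d0):
        return np.full_like(s2, s0sq, dtype=float)
    if d0 == 0:
        return s2.astype(float)
    return (d0 * s0sq + df * s2) / (d0 + df)


# ---------------------------------------------------------------------------
# moderated t / F tests
# ---------------------------------------------------------------------------

def _t_sf2(t: np.ndarray, df: float) -> np.ndarray:
    """Two-sided p from |t| with possibly infinite df."""
    if np.isinf(df):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df)


def _f_sf(F: np.ndarray, df1: int, df2: float) -> np.ndarray:
    if np.isinf(df2):
        return stats.chi2.sf(df1 * F, df1)
    return stats.f.sf(F, df1, df2)


def moderated_tests(
    fit: GroupFit,
    contrasts: dict[str, np.ndarray] | None = None,
    q: float = 0.05,
    gate: str = "full",
    d0: float | None = None,
    s0sq: float | None = None,
) -> ModeratedFit:
    """Moderated t per contrast, the overall moderated F, BH FDR, and the gate.

    Parameters
    ----------
    contrasts
        Name -> coefficient vector over the ordered groups present
        (defaults to the six study contrasts over A-E).
    q
        FDR level for both the per-contrast calls and the F gate.
    gate
        ``"full"``: omnibus F over all between-group degrees of freedom of
        the one-way layout (k-1 numerator df).  ``"contrasts"``: F over the
        TIME/DOSE/TIMExDOSE contrast subspace only (3 df).
    d0, s0sq
        Override the empirical-Bayes prior (``d0=0`` disables moderation;
        ``d0=np.inf`` pools every variance at s0sq, estimated if not given).
    """
    if not 0 < q < 1:
        raise ParameterError(f"FDR level q must be in (0, 1), got {q}")
    if gate not in ("full", "contrasts"):
        raise ParameterError(f"gate must be 'full' or 'contrasts', got {gate!r}")
    if contrasts is None:
        contrasts = CONTRASTS
    groups = list(fit.means.columns)
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        if c.shape != (len(groups),):
            raise DesignError(f"contrast {name!r} has wrong length for groups {groups}")
        if abs(c.sum()) > 1e-9:
            raise DesignError(f"contrast {name!r} coefficients do not sum to 0")
        if np.any((np.abs(c) > 1e-12) & (fit.n_per_group[groups].to_numpy() == 0)):
            raise DesignError(f"contrast {name!r} uses a group with no samples")

    # prior
    if d0 is None:
        d0_hat, s0sq_hat, s2_post = squeeze_variances(fit.s2, fit.df_residual)
    else:
        d0_hat = float(d0)
        if s0sq is not None:
            s0sq_hat = float(s0sq)
        elif d0_hat != 0:
            _, s0sq_hat, _ = squeeze_variances(fit.s2, fit.df_residual)
        else:
            s0sq_hat = float("nan")  # unused: d0=0 means no moderation
        s2_post = pd.Series(
            _posterior_variances(fit.s2.to_numpy(), fit.df_residual, d0_hat, s0sq_hat),
            index=fit.s2.index,
        )
    prior = VariancePrior(d0=d0_hat, s0sq=s0sq_hat, s2_post=s2_post)
    df_total = d0_hat + fit.df_residual

    means = fit.means.to_numpy()
    n_g = fit.n_per_group[groups].to_numpy(dtype=float)
    s2p = s2_post.to_numpy()

    coef, tstat, praw, padj, sdu = {}, {}, {}, {}, {}
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        beta = means @ c
        v_c = float(np.sum(c**2 / n_g))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / np.sqrt(s2p * v_c)
        t = np.where(beta == 0, 0.0, t)
        p = np.where(np.isnan(t), 1.0, _t_sf2(np.nan_to_num(t), df_total))
        p = np.minimum(p, 1.0)
        coef[name], tstat[name], praw[name] = beta, t, p
        padj[name] = bh_adjust(p)
        sdu[name] = np.sqrt(v_c)

    # omnibus moderated F
    if gate == "full":
        grand = (means * n_g).sum(axis=1) / n_g.sum()
        ssb = ((means - grand[:, None]) ** 2 * n_g).sum(axis=1)
        df1 = len(groups) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ssb / df1) / s2p
    else:
        names3 = ["TIME", "DOSE", "TIMExDOSE"]
        missing = [n for n in names3 if n not in contrasts]
        if missing:
            raise DesignError(f"gate='contrasts' requires contrasts {missing}")
        C = np.vstack([np.asarray(contrasts[n], dtype=float) for n in names3])
        V = C @ np.diag(1.0 / n_g) @ C.T
        Vinv = np.linalg.inv(V)
        B = means @ C.T
        df1 = C.shape[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.einsum("ij,jk,ik->i", B, Vinv, B) / df1 / s2p
    F = np.nan_to_num(F, nan=0.0, posinf=np.inf)
    F_p = _f_sf(F, df1, df_total)
    F_p_adj = bh_adjust(F_p)
    gate_flag = F_p_adj < q

    idx = fit.means.index
    return ModeratedFit(
        group_fit=fit,
        prior=prior,
        contrasts={k: np.asarray(v, dtype=float) for k, v in contrasts.items()},
        q=q,
        coefficients=pd.DataFrame(coef, index=idx),
        stdev_unscaled=pd.Series(sdu),
        t=pd.DataFrame(tstat, index=idx),
        p=pd.DataFrame(praw, index=idx),
        p_adj=pd.DataFrame(padj, index=idx),
        F=pd.Series(F, index=idx, name="F"),
        F_df1=df1,
        F_p=pd.Series(F_p, index=idx, name="F.p"),
        F_p_adj=pd.Series(F_p_adj, index=idx, name="F.p_adj"),
        gate=pd.Series(gate_flag, index=idx, name="gate"),
        gate_mode=gate,
    )


def bh_adjust(p: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone in the raw p-values, each adjusted value >= raw and <= 1;
    a test is significant at FDR level q iff its adjusted value < q.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ParameterError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr.ravel(), method="fdr_bh")
    return adjusted.reshape(arr.shape)
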