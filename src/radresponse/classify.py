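"""Tri-state contrast calls and the long-term / acute response partition.

Each of the six comparisons is encoded per probe set as -1 / 0 / +1:
+1 when the first side of the comparison is significantly higher, -1 when
significantly lower, 0 when not significant.  A call can only be nonzero
when the probe set passed the overall-F gate AND the comparison's
BH-adjusted p fell below the FDR level.

The tri-state vectors are then partitioned, in precedence order:

1. significant DOSE dependence            -> excluded_dose
2. significant TIMExDOSE interaction      -> excluded_interaction
3. opposite-sign LT and AC control calls  -> excluded_discrepant
4. TIME significant and at least one control comparison significant
   (with any second control call of the same sign) -> long_term_primary
   or acute_primary, the side with the larger |log2 effect| when both
   control comparisons are called
5. otherwise                              -> unassigned

Ties (both control comparisons called with equal |effect|, or no effect
sizes supplied) go to long_term_primary and are flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .diffexpr import ModeratedFit
from .errors import ParameterError

__all__ = [
    "COMPARISONS",
    "CATEGORIES",
    "tri_state",
    "classify_response",
    "classify_all",
    "rank_top_genes",
    "order_heatmap_rows",
]

COMPARISONS = ("TIME", "DOSE", "TIMExDOSE", "LT_vs_CTRL", "AC_vs_CTRL", "TRT_vs_CTRL")

CATEGORIES = (
    "long_term_primary",
    "acute_primary",
    "excluded_dose",
    "excluded_interaction",
    "excluded_discrepant",
    "unassigned",
)

#: Which control comparison carries the category's primary effect.
PRIMARY_COMPARISON = {"long_term_primary": "LT_vs_CTRL", "acute_primary": "AC_vs_CTRL"}


def tri_state(fit: ModeratedFit, q: float | None = None) -> pd.DataFrame:
    """Encode gate AND significance AND sign for each comparison.

    Returns a probe-set x comparison DataFrame of values in {-1, 0, 1}.
    """
    q = fit.q if q is None else q
    if not 0 < q < 1:
        raise ParameterError(f"q must be in (0, 1), got {q}")
    names = [c for c in COMPARISONS if c in fit.p_adj.columns]
    calls = pd.DataFrame(0, index=fit.p_adj.index, columns=names, dtype=int)
    gate = fit.gate.to_numpy()
    for name in names:
        sig = gate & (fit.p_adj[name].to_numpy() < q)
        sign = np.sign(fit.coefficients[name].to_numpy()).astype(int)
        calls[name] = np.where(sig, sign, 0)
    return calls


def classify_response(
    call, lt_effect: float | None = None, ac_effect: float | None = None
) -> str:
    """Assign one response category to a single tri-state vector.

    ``call`` is a mapping (or Series) with keys TIME, DOSE, TIMExDOSE,
    LT_vs_CTRL, AC_vs_CTRL (TRT_vs_CTRL is recorded upstream but does not
    participate).  ``lt_effect``/``ac_effect`` are the log2 contrast
    estimates used to break the both-called case; when absent the tie goes
    to long_term_primary.
    """
    try:
        time_c = int(call["TIME"])
        dose_c = int(call["DOSE"])
        td_c = int(call["TIMExDOSE"])
        lt_c = int(call["LT_vs_CTRL"])
        ac_c = int(call["AC_vs_CTRL"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ParameterError(f"malformed tri-state vector: {exc}") from None
    for v in (time_c, dose_c, td_c, lt_c, ac_c):
        if v not in (-1, 0, 1):
            raise ParameterError(f"tri-state values must be in {{-1,0,1}}, got {v}")

    if dose_c != 0:
        return "excluded_dose"
    if td_c != 0:
        return "excluded_interaction"
    if lt_c * ac_c == -1:
        return "excluded_discrepant"
    if time_c != 0 and lt_c != 0 and ac_c != 0:
        # same sign by construction; larger |log2 effect| wins, tie -> long-term
        if lt_effect is not None and ac_effect is not None and abs(ac_effect) > abs(lt_effect):
            return "acute_primary"
        return "long_term_primary"
    if time_c != 0 and lt_c != 0:
        return "long_term_primary"
    if time_c != 0 and ac_c != 0:
        return "acute_primary"
    return "unassigned"


def classify_all(fit: ModeratedFit, q: float | None = None) -> pd.DataFrame:
    """Tri-state calls plus category for every tested probe set.

    Returns a DataFrame with the six call columns, ``category``, and a
    ``tie`` flag marking both-called probe sets whose |LT| and |AC|
    effects are equal (assigned long_term_primary by convention).
    """
    calls = tri_state(fit, q)
    lt = fit.coefficients["LT_vs_CTRL"]
    ac = fit.coefficients["AC_vs_CTRL"]
    cats = [
        classify_response(row, lt_effect=lt[idx], ac_effect=ac[idx])
        for idx, row in calls.iterrows()
    ]
    out = calls.copy()
    out["category"] = cats
    both = (calls["LT_vs_CTRL"] != 0) & (calls["AC_vs_CTRL"] != 0)
    out["tie"] = both & (np.abs(lt) == np.abs(ac)) & (out["category"] == "long_term_primary")
    return out


def _cross_annotation(direction: str, other_call: int) -> str:
    if other_call == 0:
        return "unchanged"
    return "up, less" if direction == "up" else "down, less"


def rank_top_genes(
    fit: ModeratedFit,
    categories: pd.DataFrame,
    annotation: pd.Series | dict | None = None,
    n: int = 10,
    category: str = "long_term_primary",
    drop_unannotated: bool = False,
) -> pd.DataFrame:
    """Ranked top-n increased and top-n decreased genes within a category.

    Ranking uses the category's control comparison (LT_vs_CTRL for
    long_term_primary, AC_vs_CTRL for acute_primary), up- and
    down-regulated separately by fold change.  Probe sets sharing a gene
    symbol are collapsed to the one with the largest |fold change|.  Fold
    changes for decreases use the reciprocal convention (2^|log2fc|, so
    fold-up and fold-down are reciprocals of one another).  The emitted p
    is the TIME comparison's adjusted p; the cross-response column reports
    whether the other response class was unchanged or changed less.
    """
    if category not in PRIMARY_COMPARISON:
        raise ParameterError(f"rankable categories are {sorted(PRIMARY_COMPARISON)}")
    primary = PRIMARY_COMPARISON[category]
    other = "AC_vs_CTRL" if primary == "LT_vs_CTRL" else "LT_vs_CTRL"
    members = categories.index[categories["category"] == category]
    if annotation is None:
        annotation = pd.Series(dtype=object)
    else:
        annotation = pd.Series(annotation)

    rows = []
    for ps in members:
        beta = fit.coefficients.at[ps, primary]
        symbol = annotation.get(ps, "")
        if drop_unannotated and not symbol:
            continue
        rows.append(
            {
                "probe_set": ps,
                "symbol": symbol,
                "direction": "up" if beta >= 0 else "down",
                "log2fc": beta,
                "fold_change": 2.0 ** abs(beta),
                "p_time": fit.p_adj.at[ps, "TIME"],
                "cross_response": _cross_annotation(
                    "up" if beta >= 0 else "down", int(categories.at[ps, other])
                ),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["rank", "probe_set", "symbol", "direction", "log2fc",
                     "fold_change", "p_time", "cross_response"]
        )
    table = pd.DataFrame(rows)
    # collapse duplicate probe sets per symbol, keeping the largest |fold change|
    table = table.sort_values(
        ["fold_change", "probe_set"], ascending=[False, True], kind="mergesort"
    )
    annotated = table["symbol"] != ""
    table = pd.concat(
        [table[annotated].drop_duplicates(subset="symbol", keep="first"), table[~annotated]]
    )
    parts = []
    for direction in ("up", "down"):
        side = table[table["direction"] == direction].sort_values(
            ["fold_change", "probe_set"], ascending=[False, True], kind="mergesort"
        ).head(n)
        side = side.copy()
        side.insert(0, "rank", np.arange(1, len(side) + 1))
        parts.append(side)
    return pd.concat(parts, ignore_index=True)


def order_heatmap_rows(
    matrix: ExpressionMatrix, categories: pd.DataFrame, fit: ModeratedFit
) -> list[str]:
    """Deterministic heat-map row order: category block, sign, |fold change|.

    Within each category block, up-regulated rows (by the category's
    primary comparison, TIME for non-primary categories) precede
    down-regulated ones, each sorted by |fold change| descending; probe-set
    id breaks ties so the ordering is invariant to input row permutation.
    """
    ids = [ps for ps in matrix.row_ids if ps in categories.index]
    cat_rank = {c: i for i, c in enumerate(CATEGORIES)}

    def key(ps: str):
        cat = categories.at[ps, "category"]
        comp = PRIMARY_COMPARISON.get(cat, "TIME")
        beta = fit.coefficients.at[ps, comp]
        sign_rank = 0 if beta >= 0 else 1
        return (cat_rank[cat], sign_rank, -abs(beta), str(ps))

    return sorted(ids, key=key)
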