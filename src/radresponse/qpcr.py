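"""Relative quantification by the ddCt method and array/qPCR concordance.

The comparative-Ct (ddCt) method quantifies a target transcript relative
to an internal reference gene (default RPL13a) and a control group:

    dCt  = mean Ct_target - mean Ct_reference        (per group)
    ddCt = dCt_treated - dCt_control
    fold change = efficiency^(-ddCt),  efficiency = 2 for ideal doubling

Concordance between platforms is summarized by ordinary least squares of
qPCR log2 fold change on microarray log2 fold change over per-gene,
per-group mean points: slope, intercept (a systematic multiplicative
offset on the fold-change scale), and R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, FormatError, ParameterError

__all__ = [
    "DEFAULT_REFERENCE",
    "ConcordanceFit",
    "read_ct_table",
    "write_ct_table",
    "ddct_fold_change",
    "concordance",
]

DEFAULT_REFERENCE = "RPL13a"

CT_COLUMNS = ("gene", "group", "replicate", "ct")


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct table TSV with columns gene, group, replicate, ct."""
    tbl = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in tbl.columns]
    if missing:
        raise FormatError(f"{path}: Ct table missing columns {missing}")
    if not np.isfinite(tbl["ct"].to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite Ct values")
    return tbl


def write_ct_table(tbl: pd.DataFrame, path) -> None:
    tbl.to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class DdctResult:
    gene: str
    treated: str
    control: str
    ddct: float
    fold_change: float
    dct_sd_treated: float     # replicate-level spread of dCt, treated group
    dct_sd_control: float


def _group_dct(ct: pd.DataFrame, target: str, reference: str, group: str):
    ref = ct[(ct["gene"] == reference) & (ct["group"] == group)]["ct"]
    tgt = ct[(ct["gene"] == target) & (ct["group"] == group)]["ct"]
    if ref.empty:
        raise DataError(f"reference gene {reference!r} not measured in group {group!r}")
    if tgt.empty:
        raise DataError(f"target gene {target!r} not measured in group {group!r}")
    dct = float(tgt.mean() - ref.mean())
    # replicate-level spread: pairwise-independent approximation
    sd = float(np.sqrt(tgt.var(ddof=1) / len(tgt) + ref.var(ddof=1) / len(ref))) \
        if len(tgt) > 1 and len(ref) > 1 else float("nan")
    return dct, sd


def ddct_fold_change(
    ct: pd.DataFrame,
    target: str,
    treated: str,
    control: str,
    reference: str = DEFAULT_REFERENCE,
    efficiency: float = 2.0,
) -> DdctResult:
    """Fold change of ``target`` in ``treated`` relative to ``control``."""
    if efficiency <= 1.0:
        raise ParameterError(f"amplification efficiency must exceed 1, got {efficiency}")
    dct_t, sd_t = _group_dct(ct, target, reference, treated)
    dct_c, sd_c = _group_dct(ct, target, reference, control)
    ddct = dct_t - dct_c
    return DdctResult(
        gene=target, treated=treated, control=control, ddct=ddct,
        fold_change=float(efficiency ** (-ddct)),
        dct_sd_treated=sd_t, dct_sd_control=sd_c,
    )


@dataclass
class ConcordanceFit:
    slope: float
    intercept: float
    r2: float
    n: int
    #: multiplicative offset on the fold-change scale implied by the intercept
    fold_offset: float


def concordance(array_log2fc, qpcr_log2fc) -> ConcordanceFit:
    """OLS of qPCR log2 fold change on microarray log2 fold change.

    Inputs are aligned vectors (or Series sharing an index) of per-gene,
    per-group mean log2 fold changes.  Needs >= 3 paired points and
    non-constant array values.
    """
    if isinstance(array_log2fc, pd.Series) and isinstance(qpcr_log2fc, pd.Series):
        qpcr_log2fc = qpcr_log2fc.loc[array_log2fc.index]
    x = np.asarray(array_log2fc, dtype=float)
    y = np.asarray(qpcr_log2fc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("array and qPCR fold-change vectors must align")
    if x.size < 3:
        raise DataError(f"concordance needs >= 3 paired points, have {x.size}")
    if np.ptp(x) == 0:
        raise DataError("zero variance in array fold changes; regression undefined")
    res = stats.linregress(x, y)
    return ConcordanceFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=int(x.size),
        fold_offset=float(2.0**res.intercept),
    )
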