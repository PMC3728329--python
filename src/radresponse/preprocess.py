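"""RMA-style preprocessing chain and the detection (IQR) filter.

The chain mirrors the Robust Multiarray Average convention for
oligonucleotide arrays: normal+exponential convolution background
correction on raw intensities, quantile normalization across samples,
log2 transform, and median-polish summarization of probes into probe
sets.  Downstream analysis then drops probe sets whose expression is
essentially flat across all samples (interquartile range below a
threshold, default 0.2 log2 units), treating them as undetected.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SampleDesign
from .errors import DataError, FormatError, ParameterError

__all__ = [
    "FilterConfig",
    "read_matrix",
    "write_matrix",
    "read_design",
    "write_design",
    "background_correct",
    "quantile_normalize",
    "median_polish_summarize",
    "iqr_filter",
]


@dataclass
class FilterConfig:
    """Detection-filter settings.

    iqr_threshold
        Rows with IQR strictly below this value (log2 units) are removed.
        The rule is strictly "less than": a row whose IQR equals the
        threshold is kept.
    quantile_rule
        Interpolation convention passed to :func:`numpy.quantile`
        (``"linear"`` matches the default of R's ``quantile`` type 7, the
        convention under which the 0.2 cutoff was defined).
    """

    iqr_threshold: float = 0.2
    quantile_rule: str = "linear"

    def __post_init__(self) -> None:
        if self.iqr_threshold < 0:
            raise ParameterError(f"iqr_threshold must be >= 0, got {self.iqr_threshold}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path, format: str = "tsv", scale: str = "log2") -> ExpressionMatrix:
    """Read an expression matrix from a TSV or a GEO series-matrix file.

    TSV layout: one header row of sample identifiers, first column row
    identifiers.  Series-matrix layout: ``!``-prefixed metadata lines, with
    the numeric table between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end``; sample metadata lines (``!Sample_*``) are
    retained on the returned matrix as the attribute ``sample_metadata``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "tsv":
        return _read_tsv_matrix(path, scale)
    if format == "series_matrix":
        return _read_series_matrix(path, scale)
    raise ParameterError(f"unknown matrix format {format!r}")


def _parse_table(lines: list[str], path, start_line: int, scale: str) -> ExpressionMatrix:
    if not lines:
        raise FormatError(f"{path}: empty value table")
    header = lines[0].rstrip("\n").split("\t")
    ncol = len(header) - 1
    if ncol < 1:
        raise FormatError(f"{path}, line {start_line}: header has no sample columns")
    ids, rows = [], []
    for offset, line in enumerate(lines[1:], start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        lineno = start_line + offset
        if len(fields) != ncol + 1:
            raise FormatError(
                f"{path}, line {lineno}: expected {ncol + 1} fields, found {len(fields)}"
            )
        ids.append(fields[0].strip('"'))
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}, line {lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise FormatError(f"{path}: value table has no data rows")
    data = pd.DataFrame(rows, index=ids, columns=[h.strip('"') for h in header[1:]])
    data.index.name = header[0].strip('"') or "probe_set"
    return ExpressionMatrix(data, scale=scale)


def _read_tsv_matrix(path: Path, scale: str) -> ExpressionMatrix:
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    return _parse_table(lines, path, 1, scale)


def _read_series_matrix(path: Path, scale: str) -> ExpressionMatrix:
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    sample_meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    table_start = 0
    for lineno, line in enumerate(lines, start=1):
        if line.lower().startswith("!series_matrix_table_begin"):
            in_table = True
            table_start = lineno + 1
            continue
        if line.lower().startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            table_lines.append(line)
        elif line.startswith("!Sample_"):
            key, *vals = line.split("\t")
            sample_meta[key.lstrip("!")] = [v.strip('"') for v in vals]
    if not table_lines:
        raise FormatError(f"{path}: no series_matrix_table_begin/end block found")
    matrix = _parse_table(table_lines, path, table_start, scale)
    declared = sample_meta.get("Sample_geo_accession")
    if declared and len(declared) != matrix.shape[1]:
        raise FormatError(
            f"{path}: value table has {matrix.shape[1]} samples but metadata declares {len(declared)}"
        )
    matrix.sample_metadata = sample_meta  # type: ignore[attr-defined]
    return matrix


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a tab-delimited matrix (header = sample IDs, first column = row IDs)."""
    df = matrix.data.copy()
    if df.index.name is None:
        df.index.name = "probe_set"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_design(path) -> SampleDesign:
    tbl = pd.read_csv(path, sep="\t", index_col=0)
    return SampleDesign(tbl[["group"]])


def write_design(design: SampleDesign, path) -> None:
    tbl = design.table.copy()
    if tbl.index.name is None:
        tbl.index.name = "sample"
    tbl.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# background correction (normal + exponential convolution)
# ---------------------------------------------------------------------------

def _normexp_loglik(theta: np.ndarray, x: np.ndarray) -> float:
    """Negative log-likelihood of the normal+exponential convolution.

    theta = (mu, log sigma, log alpha).  Density:
    f(x) = (1/alpha) exp((mu - x)/alpha + sigma^2/(2 alpha^2))
           * Phi((x - mu - sigma^2/alpha)/sigma)
    """
    mu, log_sigma, log_alpha = theta
    sigma = np.exp(log_sigma)
    alpha = np.exp(log_alpha)
    z = (x - mu - sigma**2 / alpha) / sigma
    ll = (-log_alpha + (mu - x) / alpha + sigma**2 / (2 * alpha**2)
          + stats.norm.logcdf(z))
    return -float(np.sum(ll))


def _normexp_params(x: np.ndarray, col: str) -> tuple[float, float, float]:
    """Estimate (mu, sigma, alpha) of the normal+exponential convolution model.

    mu, sigma describe the additive normal background noise, alpha the mean
    of the exponential true-signal component.  Maximum likelihood, started
    from method-of-moments values (the skewness identifies the exponential
    component: E[x] = mu + alpha, Var = sigma^2 + alpha^2, third central
    moment = 2 alpha^3).
    """
    from scipy.optimize import minimize

    if np.ptp(x) == 0:
        raise DataError(f"column {col!r} has zero variance; cannot fit background model")
    m1 = float(np.mean(x))
    var = float(np.var(x))
    m3 = float(np.mean((x - m1) ** 3))
    alpha0 = (m3 / 2.0) ** (1.0 / 3.0) if m3 > 0 else np.sqrt(var) / 2.0
    alpha0 = float(np.clip(alpha0, 1e-6, None))
    sigma0 = float(np.sqrt(max(var - alpha0**2, 1e-4 * var)))
    mu0 = m1 - alpha0
    theta0 = np.array([mu0, np.log(sigma0), np.log(alpha0)])
    res = minimize(_normexp_loglik, theta0, args=(x,), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000})
    mu, log_sigma, log_alpha = res.x if res.fun < _normexp_loglik(theta0, x) else theta0
    return float(mu), float(np.exp(log_sigma)), float(np.exp(log_alpha))


def _normexp_signal(x: np.ndarray, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """Posterior expected signal E[S | X = x] under the convolution model."""
    mu_sf = x - mu - sigma**2 / alpha
    # log-scale Mills ratio for numerical stability at very negative arguments
    log_phi = stats.norm.logpdf(mu_sf / sigma)
    log_Phi = stats.norm.logcdf(mu_sf / sigma)
    signal = mu_sf + sigma * np.exp(log_phi - log_Phi)
    return np.maximum(signal, 1e-10)


def background_correct(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Per-column normal+exponential convolution background correction.

    Requires a raw-scale matrix of strictly positive intensities; returns
    strictly positive background-corrected intensities.
    """
    if raw.scale != "raw":
        raise ParameterError("background_correct expects a raw-scale matrix")
    vals = raw.values
    if (vals <= 0).any():
        raise DataError("background correction requires strictly positive intensities")
    out = np.empty_like(vals)
    for j, col in enumerate(raw.col_ids):
        x = vals[:, j]
        mu, sigma, alpha = _normexp_params(x, str(col))
        out[:, j] = _normexp_signal(x, mu, sigma, alpha)
    return ExpressionMatrix(
        pd.DataFrame(out, index=raw.row_ids, columns=raw.col_ids), scale="raw"
    )


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the common across-column mean quantile profile.

    Each column's values are replaced by the mean, across columns, of the
    order statistics at the same rank; ties within a column receive the
    mean of their tied-rank reference values.  Rank order within a column
    is preserved.
    """
    vals = m.values
    n, k = vals.shape
    if k < 2:
        raise ParameterError("quantile normalization needs at least 2 columns")
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(k):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        restored = np.empty(n)
        restored[order] = reference
        # ties get the mean of their tied-rank reference values
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inverse, weights=restored)
            restored = sums[inverse] / counts[inverse]
        out[:, j] = restored
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.row_ids, columns=m.col_ids), scale=m.scale
    )


# ---------------------------------------------------------------------------
# median polish summarization
# ---------------------------------------------------------------------------

def _median_polish(block: np.ndarray, tol: float, max_cycles: int) -> np.ndarray:
    """Fit log2 ~ overall + probe + sample by alternating median sweeps.

    Returns overall + sample effects (the probe-set expression per sample).
    """
    z = block.copy()
    overall = 0.0
    row_eff = np.zeros(z.shape[0])
    col_eff = np.zeros(z.shape[1])
    prev_abs = np.abs(z).sum()
    for _ in range(max_cycles):
        rmed = np.median(z, axis=1)
        z -= rmed[:, None]
        row_eff += rmed
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta
        cmed = np.median(z, axis=0)
        z -= cmed[None, :]
        col_eff += cmed
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta
        cur_abs = np.abs(z).sum()
        if prev_abs == 0 or abs(prev_abs - cur_abs) < tol * prev_abs:
            break
        prev_abs = cur_abs
    return overall + col_eff


def median_polish_summarize(
    probes: ExpressionMatrix,
    probe_map: pd.Series | dict,
    tol: float = 0.01,
    max_cycles: int = 10,
) -> ExpressionMatrix:
    """Summarize a log2 probe-level matrix into probe-set expression values.

    probe_map maps each probe identifier to its probe set.  Probe sets with
    a single probe pass through unchanged.  Probe sets are emitted in first
    appearance order of the mapping restricted to the matrix rows.
    """
    if probes.scale != "log2":
        raise ParameterError("median_polish_summarize expects log2 scale")
    pmap = pd.Series(probe_map)
    missing = [p for p in probes.row_ids if p not in pmap.index]
    if missing:
        raise DataError(f"probes without a probe-set mapping: {missing[:5]}")
    pmap = pmap.loc[probes.row_ids]
    vals = probes.values
    order: list[str] = []
    rows: list[np.ndarray] = []
    idx_of = {p: i for i, p in enumerate(probes.row_ids)}
    for ps, members in pmap.groupby(pmap, sort=False).groups.items():
        block = vals[[idx_of[p] for p in members], :]
        order.append(str(ps))
        if block.shape[0] == 1:
            rows.append(block[0])
        else:
            rows.append(_median_polish(block, tol=tol, max_cycles=max_cycles))
    data = pd.DataFrame(np.vstack(rows), index=order, columns=probes.col_ids)
    data.index.name = "probe_set"
    return ExpressionMatrix(data, scale="log2")


# ---------------------------------------------------------------------------
# detection (IQR) filter
# ---------------------------------------------------------------------------

def iqr_filter(
    m: ExpressionMatrix, cfg: FilterConfig | float = FilterConfig()
) -> tuple[ExpressionMatrix, pd.Index]:
    """Remove probe sets whose interquartile range is below the threshold.

    Returns the surviving matrix and the index of removed row identifiers.
    A row with IQR exactly equal to the threshold is kept (the rule is
    strictly "less than").
    """
    if not isinstance(cfg, FilterConfig):
        cfg = FilterConfig(iqr_threshold=float(cfg))
    vals = m.values
    q1, q3 = np.quantile(vals, [0.25, 0.75], axis=1, method=cfg.quantile_rule)
    iqr = q3 - q1
    keep = iqr >= cfg.iqr_threshold
    removed = m.row_ids[~keep]
    return ExpressionMatrix(m.data.loc[keep], scale=m.scale), removed
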