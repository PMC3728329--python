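"""Gene-set tests: classical MDS + MANOVA statistic + permutation null.

For each gene set, inter-sample Euclidean distances are computed over the
set's probe sets, the samples are embedded in two dimensions by classical
(Torgerson) multidimensional scaling, and group separation of the 2-D
coordinates is measured by Hotelling's T^2 (two groups) or Pillai's trace
(more than two groups) — a multivariate extension of Hotelling's T^2 to
the gene-set level.  Significance comes from permuting sample labels
(coordinates are computed once; only labels permute), and BH FDR is
applied across sets within a comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import ExpressionMatrix, SampleDesign
from .diffexpr import bh_adjust
from .errors import DataError, FormatError, ParameterError

__all__ = [
    "GeneSetCollection",
    "PathwayResult",
    "read_gmt",
    "write_gmt",
    "classical_mds",
    "manova_stat",
    "permutation_test",
    "pathway_fdr",
    "test_collection",
]

#: comparison label -> (groups of side 1, groups of side 2); None = five-group layout
COMPARISON_LAYOUTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]] | None] = {
    "acute_vs_control": (("A",), ("D", "E")),
    "longterm_vs_control": (("A",), ("B", "C")),
    "dose": (("B", "D"), ("C", "E")),
    "all_groups": None,
}


class GeneSetCollection(dict):
    """Mapping of set id -> list of member probe-set ids, with descriptions."""

    def __init__(self, sets: dict[str, list[str]] | None = None,
                 descriptions: dict[str, str] | None = None):
        super().__init__(sets or {})
        self.descriptions = dict(descriptions or {})


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated id, description, members."""
    path = Path(path)
    sets, desc = {}, {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}, line {lineno}: GMT line needs id, description, >=1 member")
        set_id = fields[0]
        if set_id in sets:
            raise FormatError(f"{path}, line {lineno}: duplicate set id {set_id!r}")
        sets[set_id] = [f for f in fields[2:] if f]
        desc[set_id] = fields[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_id, members in collection.items():
            desc = collection.descriptions.get(set_id, "")
            fh.write("\t".join([set_id, desc, *members]) + "\n")


@dataclass
class PathwayResult:
    """One gene set x one comparison."""

    set_id: str
    comparison: str
    n_members: int                      # probe sets used (after intersection)
    statistic: float | None
    p: float | None
    q: float | None = None
    coordinates: pd.DataFrame | None = field(default=None, repr=False)
    skipped: str | None = None          # reason, when the set was not testable
    singular: bool = False              # pseudo-inverse used for a rank-deficient scatter


# ---------------------------------------------------------------------------
# classical (Torgerson) MDS
# ---------------------------------------------------------------------------

def classical_mds(d: np.ndarray, k: int = 2) -> np.ndarray:
    """Embed a distance matrix into k Euclidean dimensions.

    Double-centers -1/2 * J D^2 J, eigendecomposes, and returns the top-k
    eigenvector * sqrt(eigenvalue) coordinates ordered by decreasing
    eigenvalue.  Negative eigenvalues are truncated at zero, so if fewer
    than k positive eigenvalues exist the trailing coordinates are zero.
    Sign convention: in each dimension the coordinate of largest magnitude
    is made positive, so the embedding is deterministic.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ParameterError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ParameterError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-8) or np.any(d < -1e-12):
        raise ParameterError("distance matrix must be nonnegative with zero diagonal")
    n = d.shape[0]
    if not 1 <= k:
        raise ParameterError("k must be >= 1")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    k_eff = min(k, n)
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    if k_eff < k:
        coords = np.hstack([coords, np.zeros((n, k - k_eff))])
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords


# ---------------------------------------------------------------------------
# MANOVA statistics
# ---------------------------------------------------------------------------

def _scatter_matrices(coords: np.ndarray, labels: np.ndarray):
    """Between-group (H) and within-group (E) scatter of the coordinates."""
    grand = coords.mean(axis=0)
    H = np.zeros((coords.shape[1], coords.shape[1]))
    E = np.zeros_like(H)
    for g in np.unique(labels):
        sub = coords[labels == g]
        mg = sub.mean(axis=0)
        dg = (mg - grand)[:, None]
        H += sub.shape[0] * dg @ dg.T
        centered = sub - mg
        E += centered.T @ centered
    return H, E


def _solve_psd(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, bool]:
    """A^{-1} B, falling back to the pseudo-inverse when A is rank-deficient."""
    if np.linalg.matrix_rank(A, tol=1e-10 * max(np.trace(A), 1e-300)) < A.shape[0]:
        return np.linalg.pinv(A) @ B, True
    return np.linalg.solve(A, B), False


def manova_stat(coords: np.ndarray, labels) -> float:
    """Group-separation statistic of the embedded coordinates.

    Two groups: Hotelling's T^2.  More than two: Pillai's trace
    tr(H (H+E)^{-1}).  Rank-deficient scatter (e.g. a constant dimension)
    is handled with a pseudo-inverse, which reduces the statistic exactly
    to its lower-dimensional value.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    labels = np.asarray(labels)
    if coords.shape[0] != labels.shape[0]:
        raise ParameterError("coords and labels length mismatch")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ParameterError("need at least 2 groups")
    if (counts < 2).any():
        raise ParameterError("every group needs at least 2 samples")
    n = coords.shape[0]
    if len(uniq) == 2:
        g1 = coords[labels == uniq[0]]
        g2 = coords[labels == uniq[1]]
        diff = g1.mean(axis=0) - g2.mean(axis=0)
        pooled = (
            (g1 - g1.mean(axis=0)).T @ (g1 - g1.mean(axis=0))
            + (g2 - g2.mean(axis=0)).T @ (g2 - g2.mean(axis=0))
        ) / (n - 2)
        solved, _ = _solve_psd(pooled, diff)
        n1, n2 = len(g1), len(g2)
        return float(n1 * n2 / (n1 + n2) * diff @ solved)
    H, E = _scatter_matrices(coords, labels)
    solved, _ = _solve_psd(H + E, H)
    return float(np.trace(solved))


def _hotelling_batch(coords: np.ndarray, idx0: np.ndarray, idx1: np.ndarray) -> np.ndarray:
    """Hotelling T^2 for B label draws; idx0/idx1 are B x n_g row-index arrays."""
    B, n1 = idx0.shape
    n2 = idx1.shape[1]
    n = n1 + n2
    p = coords.shape[1]
    g1 = coords[idx0]                                    # B x n1 x p
    g2 = coords[idx1]
    m1 = g1.mean(axis=1)
    m2 = g2.mean(axis=1)
    diff = m1 - m2                                       # B x p
    S1 = np.einsum("bij,bik->bjk", g1, g1) - n1 * np.einsum("bj,bk->bjk", m1, m1)
    S2 = np.einsum("bij,bik->bjk", g2, g2) - n2 * np.einsum("bj,bk->bjk", m2, m2)
    W = (S1 + S2) / (n - 2)
    out = np.empty(B)
    if p == 2:
        a, b, c = W[:, 0, 0], W[:, 0, 1], W[:, 1, 1]
        det = a * c - b * b
        ok = det > 1e-300
        dx, dy = diff[:, 0], diff[:, 1]
        quad = (c * dx * dx - 2 * b * dx * dy + a * dy * dy) / np.where(ok, det, 1.0)
        out = np.where(ok, n1 * n2 / n * quad, np.nan)
        for i in np.flatnonzero(~ok):
            solved, _ = _solve_psd(W[i], diff[i])
            out[i] = n1 * n2 / n * diff[i] @ solved
        return out
    for i in range(B):
        solved, _ = _solve_psd(W[i], diff[i])
        out[i] = n1 * n2 / n * diff[i] @ solved
    return out


def _pillai_batch(coords: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Pillai trace for B label draws; group_idx[g] is a B x n_g index array."""
    B = group_idx[0].shape[0]
    p = coords.shape[1]
    counts = np.array([idx.shape[1] for idx in group_idx], dtype=float)
    n = counts.sum()
    sums = np.stack([coords[idx].sum(axis=1) for idx in group_idx], axis=1)  # B x G x p
    grand = sums.sum(axis=1) / n                                            # B x p
    means = sums / counts[None, :, None]
    dev = means - grand[:, None, :]
    H = np.einsum("g,bgj,bgk->bjk", counts, dev, dev)
    # total scatter of the included samples per draw
    sq = np.einsum("ij,ik->ijk", coords, coords)
    Ssum = np.stack(
        [sq[idx].sum(axis=1) for idx in group_idx], axis=1
    ).sum(axis=1)                                                           # B x p x p
    T = Ssum - n * np.einsum("bj,bk->bjk", grand, grand)
    out = np.empty(B)
    for b in range(B):
        solved, _ = _solve_psd(T[b], H[b])
        out[b] = np.trace(solved)
    return out


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _comparison_labels(design: SampleDesign, comparison: str) -> np.ndarray:
    """Side labels over ALL design samples: 0/1 for the compared sides, -1 excluded.

    For the five-group comparison (``all_groups``) the labels are the
    integer-coded group labels themselves.
    """
    if comparison not in COMPARISON_LAYOUTS:
        raise ParameterError(
            f"unknown comparison {comparison!r}; choose from {sorted(COMPARISON_LAYOUTS)}"
        )
    layout = COMPARISON_LAYOUTS[comparison]
    groups = design.groups.to_numpy()
    if layout is None:
        uniq = np.unique(groups)
        return np.searchsorted(uniq, groups)
    side1, side2 = layout
    labels = np.full(len(groups), -1, dtype=int)
    labels[np.isin(groups, side1)] = 0
    labels[np.isin(groups, side2)] = 1
    if not (labels == 0).any() or not (labels == 1).any():
        raise DataError(f"comparison {comparison!r} has an empty side")
    return labels


def permutation_test(
    m: ExpressionMatrix,
    members: list[str],
    design: SampleDesign,
    comparison: str = "acute_vs_control",
    B: int = 9999,
    seed: int = 0,
    set_id: str = "",
    standardize: bool = False,
    keep_coordinates: bool = True,
) -> PathwayResult:
    """Permutation MANOVA for one gene set and one comparison.

    The inter-sample distances over the set's probe sets and the 2-D
    embedding are computed once from ALL samples in the design; the
    statistic is evaluated on the samples carrying the compared labels
    (e.g. control A vs pooled acute D+E).  The permutation null shuffles
    the full five-group sample labeling, so the label configuration space
    is 15!/(3!)^5 rather than the few dozen splits of a 9-sample subset —
    the resolution required for permutation p-values of order 1e-3.
    p = (1 + #{perm >= observed}) / (B + 1).  Sets with fewer than 3
    members surviving intersection with the matrix are skipped (the
    result carries the reason).
    """
    import warnings

    if B < 99:
        warnings.warn(f"B={B} permutations gives a coarse p-value floor of {1/(B+1):.3g}")
    present = [g for g in members if g in m.row_ids]
    if len(present) < 3:
        return PathwayResult(
            set_id=set_id, comparison=comparison, n_members=len(present),
            statistic=None, p=None,
            skipped=f"only {len(present)} members present in matrix (need >= 3)",
        )
    design = design.align_to(m)
    labels = _comparison_labels(design, comparison)
    samples = list(design.samples)
    sub = m.data.loc[present, samples].to_numpy(dtype=float)
    if standardize:
        sd = sub.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        sub = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    D = squareform(pdist(sub.T, metric="euclidean"))
    coords = classical_mds(D, k=2)
    included = labels >= 0
    observed = manova_stat(coords[included], labels[included])

    rng = np.random.default_rng(seed)
    n = len(labels)
    perms = np.empty((B, n), dtype=int)
    for b in range(B):
        perms[b] = rng.permutation(n)
    uniq = np.unique(labels[included])
    if len(uniq) == 2:
        idx0 = perms[:, labels == 0]
        idx1 = perms[:, labels == 1]
        perm_stats = _hotelling_batch(coords, idx0, idx1)
    else:
        group_idx = [perms[:, labels == g] for g in uniq]
        perm_stats = _pillai_batch(coords, group_idx)
    p = (1.0 + np.sum(perm_stats >= observed - 1e-12)) / (B + 1.0)
    coord_df = (
        pd.DataFrame(coords, index=samples, columns=["dim1", "dim2"])
        if keep_coordinates else None
    )
    return PathwayResult(
        set_id=set_id, comparison=comparison, n_members=len(present),
        statistic=observed, p=float(p), coordinates=coord_df,
    )


def pathway_fdr(results: list[PathwayResult]) -> list[PathwayResult]:
    """BH step-up over the permutation p-values of one comparison family."""
    comparisons = {r.comparison for r in results if r.p is not None}
    if len(comparisons) > 1:
        raise ParameterError("pathway_fdr adjusts one comparison family at a time")
    tested = [r for r in results if r.p is not None]
    if tested:
        qvals = bh_adjust([r.p for r in tested])
        for r, qv in zip(tested, qvals):
            r.q = float(qv)
    return results


def test_collection(
    m: ExpressionMatrix,
    collection: GeneSetCollection,
    design: SampleDesign,
    comparison: str = "acute_vs_control",
    B: int = 9999,
    seed: int = 0,
    standardize: bool = False,
) -> list[PathwayResult]:
    """Run permutation_test on every set of a collection and apply FDR.

    Each set gets a child seed drawn deterministically from ``seed`` in
    collection order, so a fixed seed reproduces every p-value exactly.
    """
    base = np.random.default_rng(seed)
    results = []
    for set_id, members in collection.items():
        child_seed = int(base.integers(0, 2**31 - 1))
        results.append(
            permutation_test(
                m, members, design, comparison=comparison, B=B,
                seed=child_seed, set_id=set_id, standardize=standardize,
                keep_coordinates=False,
            )
        )
    return pathway_fdr(results)
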