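"""End-to-end orchestration: configuration, stage sequencing, writers, manifest.

``run_all`` executes preprocess -> differential expression -> response
classification -> pathway tests (-> qPCR concordance when a Ct table is
supplied), writing plain-text TSV/JSON artifacts plus a run manifest that
records seeds and the row counts at every stage.  A single global seed
expands deterministically into per-stage seeds, so one config reproduces
every output byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_all, rank_top_genes
from .containers import ExpressionMatrix, SampleDesign
from .diffexpr import fit_group_means, moderated_tests
from .errors import ParameterError, RadResponseError
from .pathway import read_gmt, test_collection
from .preprocess import (FilterConfig, iqr_filter, read_design, read_matrix,
                         write_design, write_matrix)
from .qpcr import DEFAULT_REFERENCE, concordance, ddct_fold_change, read_ct_table
from .simulate import SimulationParams, simulate_probeset_matrix, simulate_qpcr

logger = logging.getLogger("radresponse")

__all__ = ["PipelineConfig", "run_all", "simulate_to_dir"]


@dataclass
class PipelineConfig:
    """Paths and analysis settings for one pipeline run."""

    matrix: str
    design: str
    outdir: str
    sets: str | None = None
    annotation: str | None = None
    ct: str | None = None
    matrix_format: str = "tsv"
    iqr_threshold: float = 0.2
    q: float = 0.05
    gate: str = "full"
    permutations: int = 9999
    comparisons: list[str] = field(default_factory=lambda: ["acute_vs_control",
                                                            "longterm_vs_control"])
    qpcr_reference: str = DEFAULT_REFERENCE
    qpcr_control_group: str = "A"
    top_n: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ParameterError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("matrix", "design"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ParameterError(f"config {name} file does not exist: {p}")
        for name in ("sets", "annotation", "ct"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ParameterError(f"config {name} file does not exist: {p}")


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng([int(seed), 97])
    return {stage: int(rng.integers(0, 2**31 - 1))
            for stage in ("pathway", "qpcr")}


def run_all(cfg: PipelineConfig) -> dict:
    """Run every configured stage; return the manifest (also written to disk)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "config": {k: v for k, v in asdict(cfg).items()},
        "stages": {},
    }
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    try:
        # ---- preprocess ---------------------------------------------------
        matrix = read_matrix(cfg.matrix, format=cfg.matrix_format)
        design = read_design(cfg.design).align_to(matrix)
        filtered, removed = iqr_filter(matrix, FilterConfig(cfg.iqr_threshold))
        emit("filtered_matrix.tsv", lambda p: write_matrix(filtered, p))
        emit("removed_probesets.tsv",
             lambda p: pd.Series(removed, name="probe_set").to_csv(
                 p, sep="\t", index=False, lineterminator="\n"))
        manifest["stages"]["preprocess"] = {
            "input_rows": int(matrix.shape[0]),
            "removed": int(len(removed)),
            "kept": int(filtered.shape[0]),
        }
        logger.info("preprocess: %d rows in, %d removed by IQR < %g, %d kept",
                    matrix.shape[0], len(removed), cfg.iqr_threshold, filtered.shape[0])

        # ---- differential expression --------------------------------------
        fit = fit_group_means(filtered, design)
        mfit = moderated_tests(fit, q=cfg.q, gate=cfg.gate)
        de_table = mfit.to_frame()
        emit("de.tsv", lambda p: de_table.to_csv(p, sep="\t", lineterminator="\n"))
        manifest["stages"]["diffexpr"] = {
            "tested": int(de_table.shape[0]),
            "d0": float(mfit.prior.d0) if np.isfinite(mfit.prior.d0) else "inf",
            "s0sq": float(mfit.prior.s0sq),
            "gated": int(mfit.gate.sum()),
            "significant": {
                name: int(((mfit.p_adj[name] < cfg.q) & mfit.gate).sum())
                for name in mfit.contrasts
            },
        }

        # ---- classification ----------------------------------------------
        categories = classify_all(mfit, q=cfg.q)
        emit("categories.tsv",
             lambda p: categories.to_csv(p, sep="\t", lineterminator="\n"))
        annotation = None
        if cfg.annotation:
            ann = pd.read_csv(cfg.annotation, sep="\t", index_col=0)
            annotation = ann.iloc[:, 0]
        for cat in ("long_term_primary", "acute_primary"):
            ranked = rank_top_genes(mfit, categories, annotation,
                                    n=cfg.top_n, category=cat)
            emit(f"top_genes_{cat}.tsv",
                 lambda p, r=ranked: r.to_csv(p, sep="\t", index=False,
                                              lineterminator="\n"))
        cat_counts = categories["category"].value_counts().to_dict()
        manifest["stages"]["classify"] = {k: int(v) for k, v in cat_counts.items()}

        # ---- pathway ------------------------------------------------------
        if cfg.sets:
            collection = read_gmt(cfg.sets)
            pathway_summary = {}
            for comparison in cfg.comparisons:
                results = test_collection(
                    filtered, collection, design, comparison=comparison,
                    B=cfg.permutations, seed=seeds["pathway"],
                )
                rows = [{
                    "set_id": r.set_id, "comparison": r.comparison,
                    "n_members": r.n_members, "statistic": r.statistic,
                    "p": r.p, "q": r.q, "skipped": r.skipped or "",
                } for r in results]
                tbl = pd.DataFrame(rows)
                emit(f"pathway_{comparison}.tsv",
                     lambda p, t=tbl: t.to_csv(p, sep="\t", index=False,
                                               lineterminator="\n"))
                pathway_summary[comparison] = {
                    "tested": int(sum(r.p is not None for r in results)),
                    "skipped": int(sum(r.p is None for r in results)),
                    "significant": int(sum(
                        r.q is not None and r.q < cfg.q for r in results)),
                }
            manifest["stages"]["pathway"] = pathway_summary
        else:
            manifest["stages"]["pathway"] = "skipped: no gene-set file supplied"

        # ---- qPCR ---------------------------------------------------------
        if cfg.ct:
            ct = read_ct_table(cfg.ct)
            targets = sorted(set(ct["gene"]) - {cfg.qpcr_reference})
            treated_groups = [g for g in sorted(set(ct["group"]))
                              if g != cfg.qpcr_control_group]
            rows = []
            for gene in targets:
                for grp in treated_groups:
                    res = ddct_fold_change(ct, gene, grp, cfg.qpcr_control_group,
                                           reference=cfg.qpcr_reference)
                    entry = {"gene": gene, "group": grp, "ddct": res.ddct,
                             "fold_change": res.fold_change,
                             "qpcr_log2fc": -res.ddct}
                    if gene in mfit.coefficients.index:
                        comp = "LT_vs_CTRL" if grp in ("B", "C") else "AC_vs_CTRL"
                        entry["array_log2fc"] = float(
                            mfit.group_fit.means.at[gene, grp]
                            - mfit.group_fit.means.at[gene, "A"])
                        entry["comparison"] = comp
                    rows.append(entry)
            qtbl = pd.DataFrame(rows)
            emit("qpcr_fold_changes.tsv",
                 lambda p: qtbl.to_csv(p, sep="\t", index=False,
                                       lineterminator="\n"))
            paired = qtbl.dropna(subset=["array_log2fc"]) if "array_log2fc" in qtbl \
                else pd.DataFrame()
            qpcr_manifest: dict = {"targets": len(targets),
                                   "paired_points": int(len(paired))}
            if len(paired) >= 3 and paired["array_log2fc"].nunique() > 1:
                fit_c = concordance(paired["array_log2fc"], paired["qpcr_log2fc"])
                emit("qpcr_concordance.json",
                     lambda p: Path(p).write_text(json.dumps(asdict(fit_c),
                                                             indent=2) + "\n"))
                qpcr_manifest["concordance"] = asdict(fit_c)
            manifest["stages"]["qpcr"] = qpcr_manifest
        else:
            manifest["stages"]["qpcr"] = "skipped: no Ct table supplied"

    except RadResponseError:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    return manifest


def simulate_to_dir(params: SimulationParams, outdir,
                    qpcr_genes: int = 5) -> dict:
    """Generate a full synthetic dataset and write every input artifact.

    Writes the expression matrix, design, gene sets (GMT), truth table,
    and a Ct table for a few strongly affected genes; returns the paths.
    """
    from .pathway import write_gmt
    from .qpcr import write_ct_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, design, truth = simulate_probeset_matrix(params)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "design": outdir / "design.tsv",
        "sets": outdir / "sets.gmt",
        "truth": outdir / "truth.tsv",
        "ct": outdir / "ct.tsv",
    }
    write_matrix(matrix, paths["matrix"])
    write_design(design, paths["design"])
    write_gmt(truth.sets, paths["sets"])
    truth.table.to_csv(paths["truth"], sep="\t", lineterminator="\n")
    effects = truth.table["lt_effect"].abs() + truth.table["ac_effect"].abs()
    genes = list(effects.sort_values(ascending=False).head(qpcr_genes).index)
    ct = simulate_qpcr(truth, genes, params)
    write_ct_table(ct, paths["ct"])
    return {k: str(v) for k, v in paths.items()}
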