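"""End-to-end pipeline: adjust -> QC -> PLS/VIP -> threshold -> prune ->
forward stepwise (RF and/or SVM) -> reports, with a machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype import GenotypeMatrix, filter_maf, read_genotypes
from .metrics import render_reports, single_marker_scan
from .phenotype import AdjustedMeans
from .stepwise import ForwardStepwise, ModelSpec, overfitting_curve
from .vip import PLSVIP, prune_correlated, threshold_vip

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Configuration for a full pipeline run; defaults are the standard ones.

    Thresholds: MAF >= 0.05 to keep a SNP, VIP >= 2.0 to shortlist it,
    |r| < 0.7 to survive pruning.  CV: 10-fold for PLS component choice,
    5-fold for classifier evaluation.
    """

    genotypes: str = None
    ratings: str = None
    outdir: str = "mlgwas_out"
    maf_threshold: float = 0.05
    vip_cutoff: float = 2.0
    corr_cutoff: float = 0.7
    pls_folds: int = 10
    pls_max_components: int = 10
    clf_folds: int = 5
    rf_trees: int = 500
    models: tuple = ("random_forest", "svm_radial")
    mode: str = "greedy"  # forward-selection semantics: greedy | vip-order
    max_iters: int = None
    curve_grid: tuple = None
    seed: int = 0
    debug_liability: bool = False

    def validate(self):
        if not (0 <= self.maf_threshold <= 0.5):
            raise ValueError("maf_threshold must be in [0, 0.5]")
        if self.vip_cutoff < 0 or not (0 < self.corr_cutoff <= 1):
            raise ValueError("invalid vip/corr cutoffs")
        if self.mode not in ("greedy", "vip-order"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for m in self.models:
            if m not in ("random_forest", "svm_radial"):
                raise ValueError(f"unknown model family {m!r}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("models", "curve_grid"):
            if k in doc and doc[k] is not None:
                doc[k] = tuple(doc[k])
        return cls(**doc).validate()


def run_pipeline(config: PipelineConfig, genotypes: GenotypeMatrix = None,
                 ratings: pd.DataFrame = None) -> dict:
    """Execute every stage in funnel order and write the report bundle.

    ``genotypes``/``ratings`` may be passed in memory; otherwise they are
    read from the configured paths.  Returns the manifest dictionary (also
    written to ``outdir/manifest.json``); on a stage failure the manifest is
    still written with the failed stage marked, and the exception re-raised.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "versions": {
            "mlgwas": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "stages": [],
    }
    results = {}

    def stage(name, fn):
        try:
            out = fn()
        except Exception:
            manifest["stages"].append({"name": name, "status": "failed"})
            _write_manifest(manifest, outdir)
            logger.exception("stage %r failed; partial outputs kept in %s",
                             name, outdir)
            raise
        entry = {"name": name, "status": "ok"}
        entry.update(out.pop("_counts", {}))
        results.update(out)
        manifest["stages"].append(entry)
        return out

    def load():
        g = genotypes if genotypes is not None else read_genotypes(config.genotypes)
        r = ratings if ratings is not None else pd.read_csv(config.ratings)
        return {"genotypes": g, "ratings": r,
                "_counts": {"lines": g.n_lines, "snps": g.n_snps,
                            "plots": len(r)}}

    def adjust():
        res = AdjustedMeans(results["ratings"]).fit()
        res.to_csv(outdir / "adjusted_phenotypes.csv")
        return {"adjusted": res,
                "_counts": {"genotypes": len(res.adjusted_scores),
                            "classes": res.class_counts().to_dict()}}

    def qc():
        g, n_removed = filter_maf(results["genotypes"], config.maf_threshold)
        adj = results["adjusted"]
        common = [l for l in g.line_ids if l in adj.adjusted_scores.index]
        if len(common) < 2:
            raise ValueError("genotypes and ratings share < 2 line ids")
        idx = [g.line_ids.index(l) for l in common]
        X = g.imputed().iloc[idx]
        y = adj.adjusted_scores.loc[common]
        cls = adj.classes.loc[common]
        return {"g_filtered": g, "X": X, "y": y, "cls": cls,
                "_counts": {"snps_removed_maf": n_removed,
                            "snps_kept": g.n_snps, "lines_matched": len(common)}}

    def pls_vip():
        X, y = results["X"], results["y"]
        maxc = min(config.pls_max_components, X.shape[0] - 1, X.shape[1])
        fit = PLSVIP(X, y, max_components=maxc, cv_folds=config.pls_folds,
                     seed=config.seed,
                     snp_meta=results["g_filtered"].snp_meta).fit()
        return {"vip_fit": fit,
                "_counts": {"n_components": fit.n_components}}

    def select():
        fit = results["vip_fit"]
        shortlist = threshold_vip(fit.vip_table, config.vip_cutoff)
        if shortlist:
            selected = prune_correlated(results["X"][shortlist], fit.vip,
                                        r_cutoff=config.corr_cutoff,
                                        snp_meta=results["g_filtered"].snp_meta)
        else:
            logger.warning("empty VIP shortlist at cutoff %s; downstream "
                           "selection skipped", config.vip_cutoff)
            selected = []
        vt = fit.vip_table.copy()
        vt["kept_after_threshold"] = vt["snp_id"].isin(shortlist)
        vt["kept_after_pruning"] = vt["snp_id"].isin(selected)
        (outdir / "selected_snps.txt").write_text(
            "".join(s + "\n" for s in selected))
        return {"shortlist": shortlist, "selected": selected, "vip_table": vt,
                "_counts": {"vip_shortlist": len(shortlist),
                            "after_pruning": len(selected)}}

    def stepwise():
        sel = results["selected"]
        out = {"traces": {}, "best": {}, "_counts": {}}
        if not sel:
            return out
        max_iters = (min(config.max_iters, len(sel))
                     if config.max_iters else None)
        for fam in config.models:
            spec = ModelSpec(family=fam, rf_trees=config.rf_trees,
                             cv_folds=config.clf_folds, seed=config.seed)
            res = ForwardStepwise(results["X"], results["cls"], sel, spec,
                                  mode=config.mode,
                                  vip=results["vip_fit"].vip).fit(
                max_iters=max_iters)
            res.to_csv(outdir / f"trace_{fam}.csv")
            out["traces"][fam] = res
            out["best"][fam] = res.best_subset
            out["_counts"][f"best_n_snps_{fam}"] = len(res.best_subset)
        return out

    def scan():
        tab = single_marker_scan(results["X"], results["y"],
                                 snp_meta=results["g_filtered"].snp_meta)
        return {"scan": tab,
                "_counts": {"snps_flagged_lod": int(tab["flagged"].sum())}}

    def report():
        traces = results.get("traces", {})
        first = next(iter(traces.values())) if traces else None
        curve = None
        if results.get("selected"):
            ranked = results["shortlist"]
            spec = ModelSpec(family=config.models[0], rf_trees=config.rf_trees,
                             cv_folds=config.clf_folds, seed=config.seed)
            grid = None
            if config.curve_grid:
                grid = sorted({min(s, len(ranked)) for s in config.curve_grid})
            curve = overfitting_curve(results["X"], results["cls"], ranked,
                                      spec, grid=grid)
        cm = None
        if first is not None:
            cm = first.best_metrics()["confusion"]
        files = render_reports(
            outdir,
            vip_table=results.get("vip_table"),
            trace=first.trace if first is not None else None,
            curve=curve,
            scan=results.get("scan"),
            confusion_matrix=cm,
        )
        return {"_counts": {"report_files": len(files)}}

    stage("load", load)
    stage("adjust", adjust)
    stage("qc", qc)
    stage("pls_vip", pls_vip)
    stage("select", select)
    stage("stepwise", stepwise)
    stage("scan", scan)
    stage("report", report)
    manifest["selected_snps"] = results.get("selected", [])
    manifest["best_subsets"] = {k: v for k, v in results.get("best", {}).items()}
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
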