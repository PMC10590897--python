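"""Confusion-matrix metrics, a single-marker comparator scan, and reports.

Per-class metrics use the one-vs-rest convention: for each tolerance class,
TP/TN/FP/FN are counted against "everything else", and

    overall accuracy = correct / n * 100%
    class accuracy   = (TP + TN) / (TP + TN + FP + FN)
    precision        = TP / (TP + FP)        (the "-" sentinel when TP+FP = 0)
    specificity      = TN / (TN + FP)

The single-marker scan is a plain per-SNP linear regression of the adjusted
score on dosage, reported as LOD = -log10(p); it is a comparator for the
VIP-based selection, not a replacement for a structure-aware GWAS model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype import CLASS_ORDER

logger = logging.getLogger(__name__)

SENTINEL = "-"  # undefined metric (e.g. precision with no predicted positives)
LOD_FLAG_THRESHOLD = 4.0


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = observed class, columns = predicted class."""

    counts: pd.DataFrame

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts.to_numpy()))

    def one_vs_rest(self, label: str) -> dict:
        """TP/TN/FP/FN for one class against the rest."""
        if label not in self.counts.index:
            raise ValueError(f"unknown class {label!r}")
        m = self.counts
        tp = int(m.loc[label, label])
        fp = int(m[label].sum() - tp)
        fn = int(m.loc[label].sum() - tp)
        tn = self.n - tp - fp - fn
        return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}


def confusion(observed, predicted, labels=None) -> ConfusionMatrix:
    """Cross-tabulate observed vs predicted tolerance classes."""
    observed = list(observed)
    predicted = list(predicted)
    if len(observed) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(observed)} observed vs {len(predicted)} predicted"
        )
    labels = list(labels) if labels is not None else CLASS_ORDER
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for o, p in zip(observed, predicted):
        counts.loc[o, p] += 1
    return ConfusionMatrix(counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Correct classifications over all samples, as a percentage."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * cm.trace / cm.n


def class_metrics(cm: ConfusionMatrix, label: str):
    """(accuracy, precision, specificity) for one class, one-vs-rest.

    Precision is the ``"-"`` sentinel when the class was never predicted.
    """
    c = cm.one_vs_rest(label)
    tp, tn, fp, fn = c["TP"], c["TN"], c["FP"], c["FN"]
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    precision = SENTINEL if tp + fp == 0 else tp / (tp + fp)
    specificity = SENTINEL if tn + fp == 0 else tn / (tn + fp)
    return accuracy, precision, specificity


def metric_bundle(observed, predicted) -> dict:
    """Overall + per-class metric dictionary for one set of predictions."""
    cm = confusion(observed, predicted)
    out = {"overall_accuracy": overall_accuracy(cm) / 100.0, "confusion": cm}
    for label in cm.counts.index:
        acc, prec, spec = class_metrics(cm, label)
        out[f"{label}_accuracy"] = acc
        out[f"{label}_precision"] = prec
        out[f"{label}_specificity"] = spec
    return out


# ---------------------------------------------------------------------------
# comparator single-marker scan
# ---------------------------------------------------------------------------

def single_marker_scan(X, y, flag_threshold: float = LOD_FLAG_THRESHOLD,
                       snp_meta: pd.DataFrame = None) -> pd.DataFrame:
    """Per-SNP simple linear regression of the adjusted score on dosage.

    Returns a table (snp_id, effect, p_value, lod, flagged) with
    LOD = -log10(p) from the two-sided slope t-test and SNPs above the LOD
    flag threshold marked.  Zero-variance SNPs are skipped with a log entry.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y are not row-aligned")
    if n < 3:
        raise ValueError("need at least 3 lines for the slope t-test")
    M = X.to_numpy(dtype=float)
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("skipping %d zero-variance SNPs in scan", int((~keep).sum()))
    Mc = M[:, keep] - M[:, keep].mean(axis=0)
    yc = y - y.mean()
    sxx = (Mc**2).sum(axis=0)
    beta = Mc.T @ yc / sxx
    # residual SS of y on each single SNP
    syy = float(yc @ yc)
    rss = syy - beta**2 * sxx
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / np.sqrt(sigma2 / sxx)
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    lod = -np.log10(p)
    out = pd.DataFrame(
        {
            "snp_id": np.asarray(X.columns)[keep],
            "effect": beta,
            "p_value": p,
            "lod": lod,
            "flagged": lod > flag_threshold,
        }
    )
    if snp_meta is not None:
        out.insert(1, "chrom", snp_meta.loc[out["snp_id"], "chrom"].to_numpy())
        out.insert(2, "pos", snp_meta.loc[out["snp_id"], "pos"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def _fmt(v):
    return v if isinstance(v, str) else f"{v:.2f}"


def trace_table(trace: pd.DataFrame) -> pd.DataFrame:
    """Round a step trace for printing (2 decimals, sentinel preserved)."""
    out = trace.copy()
    for c in out.columns:
        if out[c].dtype == object or c in ("snp_added", "snps"):
            continue
        if np.issubdtype(out[c].dtype, np.floating):
            out[c] = out[c].round(2)
    return out


def render_reports(outdir, vip_table=None, trace=None, curve=None, scan=None,
                   confusion_matrix=None) -> list:
    """Write the CSV report bundle; returns the list of files written.

    Emits whatever artifacts are present: a VIP Manhattan table, the
    forward-selection trace, the accuracy-vs-subset-size curve, the
    single-marker scan table, and the pooled confusion matrix.  Output is
    deterministic: two runs from the same inputs are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    skipped = []

    def emit(df, name):
        path = outdir / name
        df.to_csv(path, index=False, lineterminator="\n")
        written.append(path)

    if vip_table is not None and len(vip_table):
        emit(vip_table, "vip_manhattan.csv")
    else:
        skipped.append("vip")
    if trace is not None and len(trace):
        emit(trace_table(trace), "selection_trace.csv")
    else:
        skipped.append("trace")
    if curve is not None and len(curve):
        emit(curve, "overfitting_curve.csv")
    else:
        skipped.append("curve")
    if scan is not None and len(scan):
        emit(scan, "single_marker_scan.csv")
    else:
        skipped.append("scan")
    if confusion_matrix is not None:
        cm = confusion_matrix.counts.copy()
        cm.index.name = "observed"
        path = outdir / "confusion_matrix.csv"
        cm.to_csv(path, lineterminator="\n")
        written.append(path)
    else:
        skipped.append("confusion")
    if not written:
        raise ValueError("no artifacts to report")
    with open(outdir / "report_manifest.txt", "w") as fh:
        for p in written:
            fh.write(p.name + "\n")
        for s in skipped:
            fh.write(f"# stage skipped: {s}\n")
    return written
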