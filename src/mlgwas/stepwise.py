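"""Forward stepwise SNP selection under cross-validated RF / SVM classifiers.

The final funnel stage: starting from the VIP-ranked, correlation-pruned SNP
set, grow a predictor subset one SNP at a time, scoring each candidate set
by stratified 5-fold cross-validated classification of the three tolerance
classes.  The trace of per-iteration metrics is kept past the first
non-improvement so the overfitting curve (accuracy falling as noise SNPs
accumulate) is observable; the reported best subset is the accuracy argmax.

Random forests use the floor(sqrt(p)) features-per-split rule; the RBF-kernel
SVM tunes cost and gamma by an inner grid search on the training folds only
(one-vs-one multi-class voting, the libsvm convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from . import metrics as _metrics
from .phenotype import CLASS_ORDER

logger = logging.getLogger(__name__)

SVM_COST_GRID = (0.01, 0.1, 1, 10, 100, 1000)
SVM_GAMMA_GRID = (0.0001, 0.001, 0.01, 0.5, 1)


@dataclass
class ModelSpec:
    """Classifier family and cross-validation configuration.

    ``family`` is ``"random_forest"`` or ``"svm_radial"``.  Defaults mirror
    the standard configuration for this pipeline: 500 trees with
    floor(sqrt(p)) features per split for the forest; the usual cost/gamma
    grids for the radial SVM; stratified 5-fold outer CV.
    """

    family: str = "random_forest"
    rf_trees: int = 500
    svm_cost_grid: tuple = SVM_COST_GRID
    svm_gamma_grid: tuple = SVM_GAMMA_GRID
    cv_folds: int = 5
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("random_forest", "svm_radial"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.cv_folds < 2 or self.inner_folds < 2:
            raise ValueError("need >= 2 CV folds")
        if not self.svm_cost_grid or not self.svm_gamma_grid:
            raise ValueError("SVM grids must be non-empty")

    def build(self, n_classes_in_train: int = 3):
        if self.family == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.rf_trees,
                max_features="sqrt",
                random_state=self.seed,
                n_jobs=1,
            )
        grid = {"C": list(self.svm_cost_grid), "gamma": list(self.svm_gamma_grid)}
        return GridSearchCV(
            SVC(kernel="rbf", decision_function_shape="ovo"),
            grid,
            cv=StratifiedKFold(
                n_splits=self.inner_folds, shuffle=True, random_state=self.seed
            ),
            scoring="accuracy",
            n_jobs=1,
        )


def evaluate_subset(X, classes, snp_set, spec: ModelSpec) -> dict:
    """Stratified k-fold CV metrics for one SNP subset.

    Out-of-fold predictions are pooled into a single confusion matrix and
    the overall + per-class metric bundle is returned (plus the fitted fold
    assignment under ``"folds"`` for reproducibility checks).  The SVM's
    cost/gamma grid search runs inside each training fold only.
    """
    X = pd.DataFrame(X)
    if not snp_set:
        raise ValueError("empty SNP subset")
    y = np.asarray(classes)
    keep_rows = np.ones(len(y), dtype=bool)
    present = pd.Series(y).value_counts()
    singletons = present[present < 2].index.tolist()
    if singletons:
        # a single-member class cannot be stratified into >= 2 folds
        logger.warning("excluding single-member classes from CV: %s",
                       singletons)
        keep_rows = ~np.isin(y, singletons)
        X, y = X.loc[keep_rows], y[keep_rows]
        present = pd.Series(y).value_counts()
    if len(present) < 2:
        raise ValueError("need >= 2 classes present")
    folds = spec.cv_folds
    if present.min() < folds:
        folds = max(2, int(present.min()))
        logger.warning(
            "class with %d members < %d folds; reducing to %d folds",
            present.min(), spec.cv_folds, folds,
        )
    M = X[list(snp_set)].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    pred = np.empty(len(y), dtype=object)
    fold_id = np.empty(len(y), dtype=int)
    for k, (train, test) in enumerate(skf.split(M, y)):
        clf = spec.build()
        if len(np.unique(y[train])) < 2:  # pragma: no cover - stratified guard
            logger.warning("training fold %d lost a class; refitting anyway", k)
        clf.fit(M[train], y[train])
        pred[test] = clf.predict(M[test])
        fold_id[test] = k
    bundle = _metrics.metric_bundle(y, pred)
    bundle["folds"] = fold_id
    bundle["n_folds"] = folds
    return bundle


def _trace_row(iteration, snp_added, snps, bundle) -> dict:
    row = {
        "iteration": iteration,
        "snp_added": snp_added,
        "n_snps": len(snps),
        "snps": ";".join(snps),
        "overall_accuracy": bundle["overall_accuracy"],
    }
    for label in CLASS_ORDER:
        for m in ("accuracy", "precision", "specificity"):
            row[f"{label}_{m}"] = bundle[f"{label}_{m}"]
    return row


class ForwardStepwise:
    """Forward stepwise SNP selection model.

    Parameters
    ----------
    X : DataFrame (lines x SNPs)
        Dosage matrix containing at least the candidate SNPs.
    classes : array of str
        Tolerance class per line, row-aligned with ``X``.
    candidates : list of str
        Candidate SNPs in descending-VIP order (the first is the seed SNP).
    spec : ModelSpec
    mode : {"greedy", "vip-order"}
        ``"greedy"`` evaluates every remaining candidate at each iteration
        and keeps the best addition; ``"vip-order"`` adds SNPs in the fixed
        candidate order.  Both emit the same trace shape.
    vip : Series, optional
        VIP per candidate, used to break accuracy ties (higher VIP wins,
        then candidate order).  Defaults to candidate order alone.
    """

    def __init__(self, X, classes, candidates, spec: ModelSpec = None,
                 mode: str = "greedy", vip: pd.Series = None):
        if not list(candidates):
            raise ValueError("empty candidate list")
        if mode not in ("greedy", "vip-order"):
            raise ValueError(f"unknown selection mode {mode!r}")
        self.X = pd.DataFrame(X)
        self.classes = np.asarray(classes)
        self.candidates = list(candidates)
        self.spec = spec or ModelSpec()
        self.mode = mode
        self.vip = vip

    def _tie_key(self, snp):
        rank = self.candidates.index(snp)
        v = -float(self.vip[snp]) if self.vip is not None else 0.0
        return (v, rank)

    def fit(self, max_iters: int = None, patience: int = 0) -> "StepwiseResults":
        """Run the selection loop and return a :class:`StepwiseResults`.

        The trace always continues to ``max_iters`` (default: all
        candidates) so the post-optimum decline is recorded.  ``patience``
        (non-improving iterations tolerated) only marks where the classical
        "stop at no further improvement" rule would have concluded; it is
        reported as ``stopping_iteration`` but never truncates the trace.
        """
        cands = self.candidates
        if max_iters is None:
            max_iters = len(cands)
        if not (1 <= max_iters <= len(cands)):
            raise ValueError("max_iters must be in [1, n_candidates]")
        current: list = []
        remaining = list(cands)
        rows = []
        best_acc, stalls = -np.inf, 0
        stopping_iteration = None
        for it in range(1, max_iters + 1):
            if it == 1:
                # seed with the highest-VIP SNP in both modes
                add, bundle = cands[0], None
                bundle = evaluate_subset(self.X, self.classes, [cands[0]], self.spec)
            elif self.mode == "vip-order":
                add = remaining[0]
                bundle = evaluate_subset(
                    self.X, self.classes, current + [add], self.spec
                )
            else:
                scored = []
                for snp in remaining:
                    b = evaluate_subset(
                        self.X, self.classes, current + [snp], self.spec
                    )
                    scored.append((snp, b))
                add, bundle = max(
                    scored,
                    key=lambda sb: (sb[1]["overall_accuracy"],) + tuple(
                        -k for k in self._tie_key(sb[0])
                    ),
                )
            current = current + [add]
            remaining.remove(add)
            rows.append(_trace_row(it, add, current, bundle))
            acc = bundle["overall_accuracy"]
            if acc > best_acc:
                best_acc, stalls = acc, 0
            else:
                stalls += 1
                if stalls > patience and stopping_iteration is None:
                    stopping_iteration = it
            if not remaining:
                break
        trace = pd.DataFrame(rows)
        # best subset = accuracy argmax over the whole trace, earliest on ties
        i_best = int(trace["overall_accuracy"].idxmax())
        best_subset = trace.loc[i_best, "snps"].split(";")
        return StepwiseResults(self, trace, best_subset,
                               best_iteration=int(trace.loc[i_best, "iteration"]),
                               stopping_iteration=stopping_iteration)


class StepwiseResults:
    """Trace and optimum of a forward stepwise selection run."""

    def __init__(self, model, trace: pd.DataFrame, best_subset: list,
                 best_iteration: int, stopping_iteration: int = None):
        self.model = model
        self.trace = trace
        self.best_subset = best_subset
        self.best_iteration = best_iteration
        #: where the "no further improvement" stopping rule would have halted
        self.stopping_iteration = stopping_iteration

    @property
    def best_accuracy(self) -> float:
        return float(self.trace["overall_accuracy"].max())

    def best_metrics(self) -> dict:
        """Re-evaluate the best subset (same seed); equals the trace row."""
        return evaluate_subset(
            self.model.X, self.model.classes, self.best_subset, self.model.spec
        )

    def summary(self) -> str:
        t = self.trace
        lines = [
            f"Forward stepwise selection ({self.model.spec.family}, "
            f"mode={self.model.mode})",
            f"  candidates: {len(self.model.candidates)}    "
            f"iterations: {len(t)}",
            f"  best: iteration {self.best_iteration} "
            f"({len(self.best_subset)} SNPs), overall accuracy "
            f"{self.best_accuracy:.2f}",
            f"  best subset: {', '.join(self.best_subset)}",
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        _metrics.trace_table(self.trace).to_csv(path, index=False,
                                                lineterminator="\n")


def forward_select(X, classes, candidates, spec: ModelSpec = None,
                   max_iters: int = None, patience: int = 0,
                   mode: str = "greedy", vip: pd.Series = None) -> StepwiseResults:
    """Convenience wrapper: ``ForwardStepwise(...).fit(...)``."""
    return ForwardStepwise(X, classes, candidates, spec, mode=mode, vip=vip).fit(
        max_iters=max_iters, patience=patience
    )


def overfitting_curve(X, classes, ranked_snps, spec: ModelSpec = None,
                      grid=None) -> pd.DataFrame:
    """Overall CV accuracy using the top-s VIP-ranked SNPs for each size s."""
    spec = spec or ModelSpec()
    ranked = list(ranked_snps)
    if grid is None:
        grid = [1, 2, 5, 10, 20, 50, 100, len(ranked)]
        grid = sorted({s for s in grid if s <= len(ranked)})
    rows = []
    for s in grid:
        if s > len(ranked):
            raise ValueError(f"subset size {s} exceeds {len(ranked)} ranked SNPs")
        b = evaluate_subset(X, classes, ranked[:s], spec)
        rows.append({"subset_size": s, "overall_accuracy": b["overall_accuracy"]})
    return pd.DataFrame(rows)
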