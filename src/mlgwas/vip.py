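"""PLS regression of damage scores on SNP dosages, VIP scoring, and pruning.

The first stage of the selection funnel: fit a partial-least-squares
regression with the adjusted damage score as the response and all SNP
dosages (centered, unit-scaled) as predictors, score every SNP by its
Variable Importance in Projection, keep SNPs with VIP >= 2.0, then greedily
drop the lower-VIP member of any SNP pair with |Pearson r| >= 0.7.

VIP for predictor j over A components:

    VIP_j = sqrt( p * sum_a [ SS_a * (w_ja / ||w_a||)^2 ] / sum_a SS_a )

where w_a are the component-a predictor weights and SS_a the response sum of
squares explained by component a.  The mean of the squared VIPs over all p
predictors is identically 1, so scores well above 1 mark influential SNPs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)


class PLSVIP:
    """PLS model of a quantitative phenotype on SNP dosages.

    Parameters
    ----------
    X : DataFrame (lines x SNPs)
        Dosage matrix; columns are SNP ids.  Missing values must already be
        imputed.
    y : Series or array
        Adjusted damage score per line, row-aligned with ``X``.
    max_components : int
        Largest candidate component count for cross-validation.
    cv_folds : int
        Folds for the component-count selection (default 10).
    seed : int
        Fixes the CV fold assignment.
    snp_meta : DataFrame, optional
        Per-SNP ``chrom``/``pos`` used for deterministic tie-breaking and for
        report tables.
    """

    def __init__(self, X, y, max_components: int = 10, cv_folds: int = 10,
                 seed: int = 0, snp_meta: pd.DataFrame = None):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y are not row-aligned")
        if np.ptp(y) == 0:
            raise ValueError("constant response: PLS is undefined")
        limit = min(X.shape[0] - 1, X.shape[1])
        if not (1 <= max_components <= limit):
            raise ValueError(f"max_components must be in [1, {limit}]")
        self.X = X
        self.y = y
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.seed = seed
        self.snp_meta = snp_meta

    def fit(self, n_components: int = None) -> "VIPResults":
        """Fit the PLS model and compute VIP scores.

        The component count is chosen by the one-standard-error rule on the
        10-fold cross-validated RMSEP (smallest count whose CV error is within
        one SE of the minimum); pass ``n_components`` to override.
        """
        cv_curve = None
        if n_components is None:
            cv_curve = self._cv_rmsep()
            n_components = _one_se_choice(cv_curve)
        pls = PLSRegression(n_components=n_components, scale=True)
        pls.fit(self.X.to_numpy(), self.y)
        ss = _explained_ss(pls)
        vip = _vip_scores(pls.x_weights_, ss)
        table = pd.DataFrame({"snp_id": list(self.X.columns), "vip": vip})
        if self.snp_meta is not None:
            table["chrom"] = self.snp_meta.loc[table["snp_id"], "chrom"].to_numpy()
            table["pos"] = self.snp_meta.loc[table["snp_id"], "pos"].to_numpy()
        # y is unit-scaled inside the fit, so its total SS is n - 1
        return VIPResults(
            model=self,
            pls=pls,
            n_components=n_components,
            vip_table=table,
            explained_ss=ss,
            y_variance_explained=ss / (len(self.y) - 1),
            cv_error_curve=cv_curve,
        )

    def _cv_rmsep(self) -> pd.DataFrame:
        """RMSEP per candidate component count, with a standard error.

        One CV pass fits the largest model per fold and reads predictions for
        every smaller count from its component sequence (PLS components are
        nested), which keeps the curve cheap and the folds identical across
        counts.
        """
        X, y = self.X.to_numpy(), self.y
        kf = KFold(n_splits=self.cv_folds, shuffle=True, random_state=self.seed)
        ncomp = self.max_components
        sq_err = np.zeros((ncomp, len(y)))
        for train, test in kf.split(X):
            n_c = min(ncomp, len(train) - 1)
            pls = PLSRegression(n_components=n_c, scale=True)
            pls.fit(X[train], y[train])
            Xc = (X[test] - pls._x_mean) / pls._x_std
            # cumulative prediction over the component sequence
            for a in range(1, n_c + 1):
                coef = pls.x_rotations_[:, :a] @ pls.y_loadings_[:, :a].T
                pred = Xc @ coef * pls._y_std + pls._y_mean
                sq_err[a - 1, test] = (pred.ravel() - y[test]) ** 2
            for a in range(n_c + 1, ncomp + 1):
                sq_err[a - 1, test] = sq_err[n_c - 1, test]
        rmsep = np.sqrt(sq_err.mean(axis=1))
        # SE of the mean squared error, pushed through the square root
        se_mse = sq_err.std(axis=1, ddof=1) / np.sqrt(len(y))
        se = se_mse / (2 * rmsep)
        return pd.DataFrame(
            {"n_components": np.arange(1, ncomp + 1), "rmsep": rmsep, "se": se}
        )


def _one_se_choice(curve: pd.DataFrame) -> int:
    i_min = int(curve["rmsep"].idxmin())
    cutoff = curve.loc[i_min, "rmsep"] + curve.loc[i_min, "se"]
    ok = curve[curve["rmsep"] <= cutoff]
    return int(ok["n_components"].iloc[0])


def _explained_ss(pls: PLSRegression) -> np.ndarray:
    """Response sum of squares explained per component (on the scaled y)."""
    T = pls.x_scores_
    q = pls.y_loadings_.ravel()
    return (T**2).sum(axis=0) * q**2


def _vip_scores(weights: np.ndarray, explained_ss: np.ndarray) -> np.ndarray:
    p, A = weights.shape
    wnorm2 = (weights**2) / np.maximum((weights**2).sum(axis=0, keepdims=True), 1e-300)
    total = explained_ss.sum()
    if total <= 0:
        raise ValueError("PLS explained zero response sum of squares")
    return np.sqrt(p * (wnorm2 @ explained_ss) / total)


class VIPResults:
    """Fitted PLS model with per-SNP VIP scores and the selection stages."""

    def __init__(self, model, pls, n_components, vip_table, explained_ss,
                 y_variance_explained, cv_error_curve):
        self.model = model
        self.pls = pls
        self.n_components = n_components
        self.vip_table = vip_table
        self.explained_ss = explained_ss
        self.y_variance_explained = y_variance_explained
        self.cv_error_curve = cv_error_curve

    @property
    def vip(self) -> pd.Series:
        return self.vip_table.set_index("snp_id")["vip"]

    def threshold(self, cutoff: float = 2.0) -> list:
        """SNPs with VIP >= cutoff, sorted by descending VIP."""
        return threshold_vip(self.vip_table, cutoff)

    def prune(self, cutoff: float = 2.0, r_cutoff: float = 0.7) -> list:
        """Threshold then correlation-prune; returns the selected SNP ids."""
        kept = self.threshold(cutoff)
        if not kept:
            return []
        return prune_correlated(self.model.X[kept], self.vip, r_cutoff=r_cutoff,
                                snp_meta=self.model.snp_meta)

    def summary(self) -> str:
        v = self.vip_table["vip"]
        lines = [
            "PLS/VIP fit",
            f"  predictors: {len(v)}    components: {self.n_components}",
            f"  response variance explained: {self.y_variance_explained.sum():.3f}",
            f"  VIP mean {v.mean():.3f}  min {v.min():.3f}  max {v.max():.3f}",
            f"  mean squared VIP: {np.mean(v**2):.6f}",
            f"  SNPs with VIP >= 2.0: {(v >= 2.0).sum()}",
        ]
        return "\n".join(lines)


def fit_pls(X, y, max_components: int = 10, cv_folds: int = 10, seed: int = 0,
            **kwargs) -> VIPResults:
    """Convenience wrapper: ``PLSVIP(X, y, ...).fit()``."""
    return PLSVIP(X, y, max_components=max_components, cv_folds=cv_folds,
                  seed=seed, **kwargs).fit()


def compute_vip(pls: PLSRegression) -> np.ndarray:
    """VIP scores from a fitted scikit-learn ``PLSRegression``."""
    return _vip_scores(pls.x_weights_, _explained_ss(pls))


def _genome_order_key(snp_ids, snp_meta):
    if snp_meta is None:
        return {s: (0, i) for i, s in enumerate(snp_ids)}

    def chrom_key(c):
        c = str(c)
        return (0, int(c)) if c.isdigit() else (1, c)

    return {
        s: (chrom_key(snp_meta.loc[s, "chrom"]), int(snp_meta.loc[s, "pos"]))
        for s in snp_ids
    }


def threshold_vip(vip_table: pd.DataFrame, cutoff: float = 2.0) -> list:
    """SNP ids with VIP >= cutoff, descending VIP, genome-order tie-break."""
    if len(vip_table) == 0:
        raise ValueError("empty VIP table")
    t = vip_table[vip_table["vip"] >= cutoff].copy()
    if len(t) == 0:
        logger.warning("no SNPs pass VIP >= %s; selection is empty", cutoff)
        return []
    meta = None
    if {"chrom", "pos"}.issubset(t.columns):
        meta = t.set_index("snp_id")[["chrom", "pos"]]
    order = _genome_order_key(t["snp_id"], meta)
    vips = dict(zip(t["snp_id"], t["vip"]))
    return sorted(t["snp_id"], key=lambda s: (-vips[s], order[s]))


def prune_correlated(X, vip: pd.Series, r_cutoff: float = 0.7,
                     snp_meta: pd.DataFrame = None) -> list:
    """Greedy correlation pruning in descending-VIP order.

    A SNP is kept iff its absolute Pearson correlation with every
    already-kept SNP is below ``r_cutoff``; when a pair is correlated the
    lower-VIP member is the one discarded.  The pass runs in descending VIP
    (ties broken by genome order), so the result does not depend on the
    input column order.  Zero-variance SNPs are dropped with a log entry.
    """
    X = pd.DataFrame(X)
    snps = [s for s in X.columns if s in vip.index]
    if len(snps) < len(X.columns):
        raise ValueError("every SNP in X must have a VIP score")
    order_key = _genome_order_key(snps, snp_meta)
    ranked = sorted(snps, key=lambda s: (-vip[s], order_key[s]))
    kept: list = []
    M = X[ranked].to_numpy(dtype=float)
    sd = M.std(axis=0)
    kept_idx = []
    for j, s in enumerate(ranked):
        if sd[j] == 0:
            logger.warning("SNP %s has zero variance; dropped from pruning", s)
            continue
        if kept_idx:
            r = np.array(
                [np.corrcoef(M[:, j], M[:, k])[0, 1] for k in kept_idx]
            )
            if np.any(np.abs(r) >= r_cutoff):
                continue
        kept_idx.append(j)
        kept.append(s)
    return kept
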