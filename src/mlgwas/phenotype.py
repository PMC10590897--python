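"""Adjusted genotype means across environments, and tolerance classification.

Plot-level ordinal damage ratings (1-4 scale, half-point steps) are adjusted
to per-genotype estimated marginal means with a linear mixed model: genotype
fixed; environment, genotype x environment, and replicate-within-environment
random.  Ratings are treated as numeric.  Genotypes are then classified as
tolerant (adjusted score <= 2), moderate (> 2, <= 3) or susceptible (> 3).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TOLERANT, MODERATE, SUSCEPTIBLE = "tolerant", "moderate", "susceptible"
CLASS_ORDER = [TOLERANT, MODERATE, SUSCEPTIBLE]


def classify_tolerance(adjusted_score: float) -> str:
    """Tolerance class from an adjusted damage score.

    Boundaries follow the damage-rating convention: a score of exactly 2 is
    tolerant, exactly 3 is moderate.  Scores outside [1, 4] are clamped with
    a warning (the classification is still returned).
    """
    s = float(adjusted_score)
    if not np.isfinite(s):
        raise ValueError("adjusted score must be finite")
    if s < 1.0 - 1e-9 or s > 4.0 + 1e-9:
        warnings.warn(f"adjusted score {s} outside the 1-4 rating scale; clamping")
    s = min(max(s, 1.0), 4.0)
    if s <= 2.0:
        return TOLERANT
    if s <= 3.0:
        return MODERATE
    return SUSCEPTIBLE


class AdjustedMeans:
    """Mixed-model adjustment of multi-environment plot ratings.

    Parameters
    ----------
    ratings : DataFrame
        Long format with columns ``genotype``, ``environment``, ``replicate``,
        ``score``.  Every genotype must be observed in at least one
        environment; genotypes seen in disjoint environment subsets remain
        comparable through the shared environment effects.

    The model is fitted by REML with genotype as a fixed effect and three
    variance components: environment, genotype x environment, and replicate
    nested in environment.  Because the only fixed effect is genotype, the
    equal-environment-weight marginal mean of genotype *g* is its fixed-effect
    estimate, which is what ``fit`` reports.
    """

    REQUIRED = ("genotype", "environment", "replicate", "score")

    def __init__(self, ratings: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in ratings.columns]
        if missing:
            raise ValueError(f"ratings table missing columns: {missing}")
        df = ratings.loc[:, list(self.REQUIRED)].copy()
        if df["score"].isna().any():
            raise ValueError("ratings contain missing scores")
        if df["genotype"].nunique() < 2:
            raise ValueError("need at least 2 genotypes")
        # sort so the fit is invariant to input row order
        self.data = df.sort_values(["genotype", "environment", "replicate"]).reset_index(
            drop=True
        )

    # -- design diagnostics -------------------------------------------------
    def is_balanced(self) -> bool:
        """True when every genotype x environment x replicate cell has one plot."""
        df = self.data
        counts = df.groupby(["genotype", "environment", "replicate"]).size()
        n_g = df["genotype"].nunique()
        n_e = df["environment"].nunique()
        n_r = df["replicate"].nunique()
        return len(counts) == n_g * n_e * n_r and (counts == 1).all()

    # -- fitting ------------------------------------------------------------
    def fit(self, method: str = "auto", maxiter: int = 200, tol: float = 1e-8):
        """Fit and return an :class:`AdjustedMeansResults`.

        method : {"auto", "reml", "means"}
            ``"reml"`` fits the mixed model; ``"means"`` is the balanced-design
            closed form (simple genotype means), valid when the design is
            complete and balanced.  ``"auto"`` uses REML and falls back to the
            closed form if the fit degenerates on balanced noise-free data.
        """
        if method not in ("auto", "reml", "means"):
            raise ValueError(f"unknown method {method!r}")
        if method == "means" or (method == "auto" and self._degenerate()):
            if not self.is_balanced():
                if method == "means":
                    raise ValueError("closed-form means require a balanced design")
            return self._fit_means()
        try:
            return self._fit_reml(maxiter=maxiter, tol=tol)
        except Exception as exc:
            if method == "auto" and self.is_balanced():
                logger.warning("REML fit failed (%s); using balanced closed form", exc)
                return self._fit_means()
            raise

    def _degenerate(self) -> bool:
        # noise-free balanced data (zero within-genotype spread) breaks REML
        if not self.is_balanced():
            return False
        within = self.data.groupby("genotype")["score"].var(ddof=0)
        return bool(np.all(within.fillna(0.0) < 1e-12))

    def _fit_means(self):
        means = self.data.groupby("genotype", sort=True)["score"].mean()
        vc = {"env": 0.0, "gxe": 0.0, "rep": 0.0, "residual": float("nan")}
        return AdjustedMeansResults(self, means, vc, method="means", converged=True)

    def _fit_reml(self, maxiter: int, tol: float):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = self.data.copy()
        df["rep_in_env"] = (
            df["environment"].astype(str) + ":" + df["replicate"].astype(str)
        )
        # environment as grouping factor: its random intercept is the env
        # effect; GxE and rep(env) enter as variance components within group
        vcf = {"gxe": "0 + C(genotype)", "rep": "0 + C(rep_in_env)"}
        model = smf.mixedlm(
            "score ~ 0 + C(genotype)",
            data=df,
            groups=df["environment"],
            re_formula="1",
            vc_formula=vcf,
        )
        res = None
        # boundary fits (a component at 0) make the default optimizer report
        # failure; retry with derivative-free methods before giving up
        for opt in ("lbfgs", "powell", "nm"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=True, maxiter=maxiter, method=opt)
            if res.converged:
                break
        if not res.converged:
            raise RuntimeError(
                "REML did not converge; iteration log:\n" + str(res.summary())
            )
        fe = res.fe_params
        genos = sorted(df["genotype"].unique())
        means = pd.Series(
            [fe[f"C(genotype)[{g}]"] for g in genos], index=genos, name="score"
        )
        means.index.name = "genotype"
        vc = {
            "env": float(res.cov_re.iloc[0, 0]),
            "gxe": float(res.vcomp[0]),
            "rep": float(res.vcomp[1]),
            "residual": float(res.scale),
        }
        for k, v in vc.items():
            if k != "residual" and v < 1e-10:
                logger.warning("variance component %r at boundary, pinned to 0", k)
                vc[k] = 0.0
        return AdjustedMeansResults(self, means, vc, method="reml", converged=True)


class AdjustedMeansResults:
    """Adjusted genotype means, variance components, and tolerance classes."""

    def __init__(self, model, means: pd.Series, variance_components: dict,
                 method: str, converged: bool):
        self.model = model
        self.adjusted_scores = means
        self.variance_components = variance_components
        self.method = method
        self.converged = converged
        self.classes = means.map(classify_tolerance)

    def frame(self) -> pd.DataFrame:
        """Per-genotype table: genotype, adjusted_score, tolerance_class."""
        return pd.DataFrame(
            {
                "genotype": self.adjusted_scores.index,
                "adjusted_score": self.adjusted_scores.to_numpy(),
                "tolerance_class": self.classes.to_numpy(),
            }
        )

    def class_counts(self) -> pd.Series:
        return self.classes.value_counts().reindex(CLASS_ORDER, fill_value=0)

    def summary(self) -> str:
        vc = self.variance_components
        counts = self.class_counts()
        n = len(self.adjusted_scores)
        lines = [
            "Adjusted genotype means (marginal means across environments)",
            f"  method: {self.method}    genotypes: {n}",
            "  variance components:",
        ]
        for k in ("env", "gxe", "rep", "residual"):
            lines.append(f"    {k:9s} {vc.get(k, float('nan')):10.4f}")
        lines.append("  tolerance classes:")
        for c in CLASS_ORDER:
            lines.append(f"    {c:12s} {counts[c]:5d}  ({100 * counts[c] / n:.1f}%)")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)


def fit_adjusted_means(ratings: pd.DataFrame, method: str = "auto") -> AdjustedMeansResults:
    """Convenience wrapper: ``AdjustedMeans(ratings).fit(method)``."""
    return AdjustedMeans(ratings).fit(method=method)
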