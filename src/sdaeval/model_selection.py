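"""Model-building procedure for seizure-detectability analysis.

The pipeline, run independently for each detector sensitivity threshold:

1. *Univariate screen* — one single-feature random-intercept logistic
   regression per feature; features significant at p < 0.05 become
   candidates for the multivariate model.
2. *Collinearity filter* — among collinear candidates, only the feature
   with the highest univariate AUC is retained.
3. *Backward stepwise deletion* — starting from the full candidate model,
   repeatedly drop the term with the largest p-value >= 0.05 (categorical
   terms tested as a likelihood-ratio block) until every remaining term is
   significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import (
    FixedEffect,
    RandomInterceptLogit,
    RandomInterceptLogitResults,
    _as_effects,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UnivariateResult",
    "univariate_screen",
    "collinearity_filter",
    "StepwiseResult",
    "backward_stepwise",
]


@dataclass
class UnivariateResult:
    """One row of the univariate screen."""

    feature: str
    fit: RandomInterceptLogitResults | None
    p_value: float
    auc: float
    auc_ci: tuple[float, float]
    significant: bool
    error: str | None = None

    def row(self) -> dict:
        return {
            "feature": self.feature,
            "p_value": self.p_value,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "significant": self.significant,
            "error": self.error or "",
        }


def univariate_screen(
    features,
    data: pd.DataFrame,
    outcome: str,
    group: str,
    alpha: float = 0.05,
    n_quad: int = 15,
) -> list[UnivariateResult]:
    """Fit one single-feature GLMM per feature.

    Fit failures are annotated per feature (``error`` set, ``p_value`` and
    ``auc`` NaN) rather than aborting the screen.
    """
    if not features:
        raise ValueError("need at least one feature to screen")
    effects = _as_effects(features, data)
    results: list[UnivariateResult] = []
    for eff in effects:
        try:
            fit = RandomInterceptLogit(
                data, outcome, [eff], group, n_quad=n_quad
            ).fit()
            p = fit.term_pvalue(eff.name)
            auc, lo, hi = fit.auc()
            results.append(
                UnivariateResult(eff.name, fit, p, auc, (lo, hi), p < alpha)
            )
        except Exception as exc:
            logger.warning("univariate fit failed for %s: %s", eff.name, exc)
            results.append(
                UnivariateResult(
                    eff.name, None, float("nan"), float("nan"),
                    (float("nan"), float("nan")), False, error=str(exc),
                )
            )
    return results


def screen_table(results: list[UnivariateResult]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in results])


def _numeric_codes(col: pd.Series) -> np.ndarray:
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        return pd.factorize(col, sort=True)[0].astype(float)
    return col.to_numpy(float)


def collinearity_filter(
    candidates: list[str],
    data: pd.DataFrame,
    univariate_aucs: dict[str, float],
    threshold: float = 0.8,
) -> tuple[list[str], list[dict]]:
    """Resolve collinear candidate features before the multivariate model.

    Features are visited in decreasing univariate AUC; a feature is dropped
    when its absolute Spearman correlation with an already-retained feature
    exceeds ``threshold`` (default 0.8). Categorical columns enter through
    their sorted level codes. Returns the retained features (original
    order) and a log of drop decisions.
    """
    if not 0 < threshold <= 1:
        raise ValueError("collinearity threshold must be in (0, 1]")
    order = sorted(candidates, key=lambda f: univariate_aucs.get(f, 0.0), reverse=True)
    retained: list[str] = []
    decisions: list[dict] = []
    for feat in order:
        x = _numeric_codes(data[feat])
        clash = None
        for kept in retained:
            rho = stats.spearmanr(x, _numeric_codes(data[kept])).statistic
            if abs(rho) > threshold:
                clash = (kept, float(rho))
                break
        if clash is None:
            retained.append(feat)
        else:
            decisions.append(
                {
                    "dropped": feat,
                    "kept": clash[0],
                    "spearman_rho": clash[1],
                    "dropped_auc": univariate_aucs.get(feat, float("nan")),
                    "kept_auc": univariate_aucs.get(clash[0], float("nan")),
                }
            )
            logger.info(
                "collinearity: dropped %s (AUC %.3f) in favour of %s "
                "(AUC %.3f), |rho| = %.3f",
                feat, univariate_aucs.get(feat, float("nan")),
                clash[0], univariate_aucs.get(clash[0], float("nan")),
                abs(clash[1]),
            )
    retained_in_input_order = [f for f in candidates if f in retained]
    return retained_in_input_order, decisions


@dataclass
class StepwiseResult:
    """Final multivariate model plus the deletion path."""

    fit: RandomInterceptLogitResults
    retained: list[str]
    removal_path: list[dict] = field(default_factory=list)
    intercept_only: bool = False


def backward_stepwise(
    candidates,
    data: pd.DataFrame,
    outcome: str,
    group: str,
    alpha: float = 0.05,
    n_quad: int = 15,
) -> StepwiseResult:
    """Backward stepwise deletion at significance level ``alpha``.

    Starting from the model with all candidates, repeatedly refit after
    removing the term with the largest p-value >= ``alpha`` (single-column
    terms by Wald z, multi-level categorical terms by likelihood-ratio
    block test). If every term is eventually removed, the intercept-only
    model is returned with a warning.
    """
    effects = _as_effects(candidates, data)
    if not effects:
        raise ValueError("need at least one candidate feature")
    path: list[dict] = []
    while effects:
        fit = RandomInterceptLogit(data, outcome, effects, group, n_quad=n_quad).fit()
        pvals = {e.name: fit.term_pvalue(e.name) for e in effects}
        worst = max(pvals, key=lambda k: (pvals[k] if np.isfinite(pvals[k]) else 1.0))
        if pvals[worst] < alpha:
            return StepwiseResult(fit, [e.name for e in effects], path)
        path.append({"removed": worst, "p_value": float(pvals[worst])})
        logger.info("stepwise: removed %s (p = %.4f)", worst, pvals[worst])
        effects = [e for e in effects if e.name != worst]

    warnings.warn(
        "backward stepwise removed every candidate; returning the "
        "intercept-only model",
        stacklevel=2,
    )
    # intercept-only random-intercept model: regress on a zero-variance-free
    # design with no fixed effects beyond the intercept
    fit = RandomInterceptLogit(data, outcome, [], group, n_quad=n_quad).fit()
    return StepwiseResult(fit, [], path, intercept_only=True)
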