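"""Random-intercept logistic regression (logistic GLMM) and the model
inference it supports.

The model for seizure *i* of baby *j* is

    logit P(detected_ij = 1 | b_j) = beta0 + x_ij' beta + b_j,
    b_j ~ Normal(0, sigma^2),

with seizure features as fixed effects and the baby as the grouping factor.
The marginal likelihood integrates the random intercept out of each baby's
contribution by adaptive Gauss–Hermite quadrature: the integrand is
re-centred at its mode (found by Newton's method) and re-scaled by its
curvature before applying the Gauss–Hermite rule, so a modest number of
nodes (15 by default) is accurate even for large cluster sizes. With one
node this reduces to the Laplace approximation.

Inference: Wald z tests per coefficient, likelihood-ratio block tests for
multi-level categorical terms, odds ratios with 95% CIs, AUC of the
fixed-effects (population-level) linear predictor with a DeLong CI, and the
DeLong paired test for comparing correlated AUCs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit, log_expit

logger = logging.getLogger(__name__)

__all__ = [
    "FixedEffect",
    "SeparationError",
    "ConvergenceError",
    "RandomInterceptLogit",
    "RandomInterceptLogitResults",
    "fit_glmm",
    "odds_ratio_ci",
    "delong_auc",
    "model_auc",
    "compare_auc",
    "mann_whitney",
]

_Z95 = 1.959963984540054  # Phi^{-1}(0.975)
_SIGMA_BOUNDARY = 1e-4    # below this the random intercept is on the boundary


class SeparationError(RuntimeError):
    """Raised when the likelihood is unbounded because a term perfectly
    separates the outcome."""


class ConvergenceError(RuntimeError):
    """Raised when the optimiser fails to converge; carries the trace."""


@dataclass(frozen=True)
class FixedEffect:
    """A fixed-effect term: a continuous column, or a categorical column
    expanded into indicator contrasts against ``reference``."""

    name: str
    categorical: bool = False
    reference: str | int | None = None

    @staticmethod
    def infer(name: str, data: pd.DataFrame) -> "FixedEffect":
        """Treat object/category/bool columns as categorical (reference =
        first level in sorted order), numeric columns as continuous."""
        col = data[name]
        if col.dtype == bool:
            return FixedEffect(name, categorical=True, reference=False)
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            return FixedEffect(name, categorical=True, reference=sorted(col.unique())[0])
        return FixedEffect(name)


def _as_effects(effects, data: pd.DataFrame) -> list[FixedEffect]:
    out = []
    for e in effects:
        out.append(e if isinstance(e, FixedEffect) else FixedEffect.infer(str(e), data))
    return out


@dataclass
class _Term:
    name: str
    columns: list[int]          # column indices in X (intercept excluded)
    labels: list[str]
    categorical: bool


def _build_design(
    data: pd.DataFrame, effects: list[FixedEffect]
) -> tuple[np.ndarray, list[str], list[_Term]]:
    """Design matrix with leading intercept; returns (X, names, terms)."""
    columns: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["intercept"]
    terms: list[_Term] = []
    for eff in effects:
        if eff.name not in data.columns:
            raise KeyError(f"feature column {eff.name!r} not in data")
        col = data[eff.name]
        if col.isna().any():
            raise ValueError(f"missing values in column {eff.name!r}")
        if eff.categorical:
            levels = sorted(col.unique())
            ref = eff.reference if eff.reference is not None else levels[0]
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} of {eff.name!r} not present in data"
                )
            idx, labels = [], []
            for lev in levels:
                if lev == ref:
                    continue
                columns.append((col == lev).to_numpy(float))
                names.append(f"{eff.name}[{lev}]")
                labels.append(f"{eff.name}[{lev}]")
                idx.append(len(columns) - 1)
            terms.append(_Term(eff.name, idx, labels, True))
        else:
            values = col.to_numpy(float)
            columns.append(values)
            names.append(eff.name)
            terms.append(_Term(eff.name, [len(columns) - 1], [eff.name], False))
    return np.column_stack(columns), names, terms


def _check_separation(X: np.ndarray, y: np.ndarray, names: list[str]) -> None:
    """Detect complete separation of the outcome by a single column: the
    column's ranges under y=0 and y=1 are disjoint."""
    for k in range(1, X.shape[1]):
        x0, x1 = X[y == 0, k], X[y == 1, k]
        if x0.size and x1.size and (x0.max() < x1.min() or x1.max() < x0.min()):
            raise SeparationError(
                f"term {names[k]!r} completely separates the outcome"
            )


class RandomInterceptLogit:
    """Logistic GLMM with a single random intercept.

    Parameters
    ----------
    data : DataFrame
        One row per observation (seizure).
    outcome : str
        Binary outcome column (e.g. detected at one threshold).
    effects : sequence of str or FixedEffect
        Fixed-effect terms; plain names are interpreted by
        :meth:`FixedEffect.infer`.
    group : str
        Grouping column (baby id).
    n_quad : int
        Number of adaptive Gauss–Hermite nodes; 1 gives the Laplace
        approximation.
    """

    def __init__(self, data, outcome, effects, group, n_quad=15):
        if n_quad < 1:
            raise ValueError("n_quad must be >= 1")
        self.data = data
        self.outcome = outcome
        self.effects = _as_effects(effects, data)
        self.group = group
        self.n_quad = int(n_quad)

        y = data[outcome]
        if y.isna().any():
            raise ValueError(f"missing values in outcome {outcome!r}")
        self.y = y.to_numpy(float)
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError(f"outcome {outcome!r} must be binary 0/1")
        if self.y.min() == self.y.max():
            raise ValueError(f"outcome {outcome!r} is constant; the model is degenerate")

        self.X, self.names, self.terms = _build_design(data, self.effects)
        codes, self.group_levels = pd.factorize(data[group])
        if (codes < 0).any():
            raise ValueError(f"missing values in group {group!r}")
        self.group_codes = codes.astype(np.intp)
        self.n_groups = len(self.group_levels)
        if self.n_groups < 2:
            raise ValueError("need >= 2 groups for a random intercept")
        _check_separation(self.X, self.y, self.names)

        z, w = hermgauss(self.n_quad)
        self._z = z
        self._logw = np.log(w) + z**2  # weights for the adapted rule

    # -- likelihood --------------------------------------------------------

    def _bernoulli_loglik(self, eta: np.ndarray) -> np.ndarray:
        # y*log p + (1-y)*log(1-p), numerically stable via log_expit
        return self.y * log_expit(eta) + (1.0 - self.y) * log_expit(-eta)

    def _group_sum(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.group_codes, weights=values, minlength=self.n_groups)

    def _posterior_modes(self, eta: np.ndarray, sigma: float):
        """Newton mode search for every group's random-intercept posterior,
        vectorised across groups. Returns (b_hat, curvature h > 0)."""
        inv_var = 1.0 / sigma**2
        b = np.zeros(self.n_groups)
        for _ in range(100):
            p = expit(eta + b[self.group_codes])
            grad = self._group_sum(self.y - p) - b * inv_var
            hess = self._group_sum(p * (1.0 - p)) + inv_var
            step = grad / hess
            b += step
            if np.max(np.abs(step)) < 1e-10:
                break
        p = expit(eta + b[self.group_codes])
        h = self._group_sum(p * (1.0 - p)) + inv_var
        return b, h

    def loglike(self, params: np.ndarray) -> float:
        """Marginal log-likelihood at ``params = [beta..., sigma]``."""
        beta, sigma = params[:-1], params[-1]
        eta = self.X @ beta
        if sigma < _SIGMA_BOUNDARY:
            return float(self._bernoulli_loglik(eta).sum())
        b_hat, h = self._posterior_modes(eta, sigma)
        scale = np.sqrt(2.0 / h)                       # (J,)
        nodes = b_hat[:, None] + scale[:, None] * self._z[None, :]   # (J, K)
        # log integrand at every node, summed within groups
        eta_nodes = eta[:, None] + nodes[self.group_codes, :]        # (n, K)
        ll_obs = (
            self.y[:, None] * log_expit(eta_nodes)
            + (1.0 - self.y[:, None]) * log_expit(-eta_nodes)
        )
        ll_groups = np.zeros((self.n_groups, ll_obs.shape[1]))
        np.add.at(ll_groups, self.group_codes, ll_obs)
        log_prior = -0.5 * nodes**2 / sigma**2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
        log_terms = self._logw[None, :] + ll_groups + log_prior
        m = log_terms.max(axis=1)
        integrals = m + np.log(np.exp(log_terms - m[:, None]).sum(axis=1))
        return float((integrals + np.log(scale)).sum())

    # -- fitting -----------------------------------------------------------

    def _start_params(self) -> np.ndarray:
        import statsmodels.api as sm

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(self.y, self.X).fit(disp=0, maxiter=100)
            beta0 = np.asarray(res.params, dtype=float)
            if not np.all(np.isfinite(beta0)) or np.abs(beta0).max() > 20:
                beta0 = np.zeros(self.X.shape[1])
        except Exception:
            beta0 = np.zeros(self.X.shape[1])
        return np.append(beta0, 0.5)

    def fit(
        self, start_params=None, maxiter=500, fixed_sigma: float | None = None
    ) -> "RandomInterceptLogitResults":
        """Maximise the marginal likelihood.

        ``fixed_sigma`` constrains the random-intercept SD instead of
        estimating it (``fixed_sigma=0`` fits the model on the ordinary
        logistic boundary).
        """
        x0 = np.asarray(start_params, float) if start_params is not None else self._start_params()
        if fixed_sigma is not None:
            if fixed_sigma < 0:
                raise ValueError("fixed_sigma must be >= 0")
            neg = lambda p: -self.loglike(np.append(p, fixed_sigma))
            x0 = x0[:-1]
            bounds = [(None, None)] * len(x0)
        else:
            neg = lambda p: -self.loglike(p)
            bounds = [(None, None)] * (len(x0) - 1) + [(0.0, None)]
        res = optimize.minimize(
            neg, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        if not res.success and "ROUNDOFF" not in str(res.message).upper():
            raise ConvergenceError(
                f"GLMM optimiser did not converge: {res.message} "
                f"(nit={res.nit}, final loglik={-res.fun:.4f})"
            )
        params = (
            np.append(res.x, fixed_sigma) if fixed_sigma is not None else res.x
        )
        beta, sigma = params[:-1], float(params[-1])
        if np.abs(beta).max() > 15:
            k = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"term {self.names[k]!r} appears to separate the outcome "
                f"(|coefficient| = {np.abs(beta[k]):.1f})"
            )
        cov = self._param_cov(params, sigma_fixed=fixed_sigma is not None)
        return RandomInterceptLogitResults(
            model=self, params=beta, random_intercept_sd=sigma,
            cov_params=cov, loglik=-float(res.fun), converged=bool(res.success),
            n_iter=int(res.nit),
        )

    def _param_cov(self, params: np.ndarray, sigma_fixed: bool = False) -> np.ndarray:
        """Observed-information covariance of the fixed effects. When the
        random-intercept SD is fixed or sits on the 0 boundary the Hessian
        is taken over beta only (the sigma direction is one-sided there)."""
        sigma = params[-1]
        if sigma_fixed or sigma < _SIGMA_BOUNDARY:
            f = lambda b: -self.loglike(np.append(b, sigma))
            H = _numerical_hessian(f, params[:-1])
        else:
            H = _numerical_hessian(lambda p: -self.loglike(p), params)[:-1, :-1]
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        return cov


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, float)
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


@dataclass
class RandomInterceptLogitResults:
    """Fitted logistic GLMM: estimates, Wald inference, odds ratios, AUC."""

    model: RandomInterceptLogit
    params: np.ndarray              # fixed effects, intercept first
    random_intercept_sd: float
    cov_params: np.ndarray
    loglik: float
    converged: bool
    n_iter: int = 0

    @property
    def names(self) -> list[str]:
        return self.model.names

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    @property
    def pvalues(self) -> np.ndarray:
        z = self.params / self.bse
        return 2.0 * stats.norm.sf(np.abs(z))

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def conf_int(self) -> np.ndarray:
        """95% Wald CI on the log-odds scale, shape (k, 2)."""
        half = _Z95 * self.bse
        return np.column_stack([self.params - half, self.params + half])

    def summary_frame(self) -> pd.DataFrame:
        ci = np.exp(self.conf_int())
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.params,
                "se": self.bse,
                "odds_ratio": self.odds_ratios,
                "or_ci_low": ci[:, 0],
                "or_ci_high": ci[:, 1],
                "p_value": self.pvalues,
            }
        )

    def linear_predictor(self, data: pd.DataFrame | None = None) -> np.ndarray:
        """Fixed-effects-only (population-level) linear predictor."""
        if data is None:
            return self.model.X @ self.params
        X, _, _ = _build_design(data, self.model.effects)
        return X @ self.params

    def conditional_linear_predictor(self) -> np.ndarray:
        """Linear predictor including the empirical-Bayes (posterior mode)
        random intercepts — only meaningful on the training babies."""
        eta = self.model.X @ self.params
        if self.random_intercept_sd < _SIGMA_BOUNDARY:
            return eta
        b_hat, _ = self.model._posterior_modes(eta, self.random_intercept_sd)
        return eta + b_hat[self.model.group_codes]

    def auc(self, conditional: bool = False) -> tuple[float, float, float]:
        """AUC of the linear predictor against the outcome, DeLong 95% CI."""
        score = (
            self.conditional_linear_predictor() if conditional
            else self.linear_predictor()
        )
        return delong_auc(self.model.y, score)

    def term_pvalue(self, term_name: str, method: str = "auto") -> float:
        """P-value for a whole term. Single-column terms use the Wald z test;
        multi-level categorical terms use a likelihood-ratio block test
        (refit without the term)."""
        term = next(t for t in self.model.terms if t.name == term_name)
        if method == "wald" or (method == "auto" and len(term.columns) == 1):
            return float(self.pvalues[term.columns[0]])
        reduced_effects = [e for e in self.model.effects if e.name != term_name]
        reduced = RandomInterceptLogit(
            self.model.data, self.model.outcome, reduced_effects,
            self.model.group, n_quad=self.model.n_quad,
        ).fit()
        lr = 2.0 * (self.loglik - reduced.loglik)
        df = len(term.columns)
        return float(stats.chi2.sf(max(lr, 0.0), df))


def fit_glmm(data, outcome, effects, group, n_quad=15) -> RandomInterceptLogitResults:
    """Fit a random-intercept logistic regression (thin wrapper over
    :class:`RandomInterceptLogit`)."""
    return RandomInterceptLogit(data, outcome, effects, group, n_quad=n_quad).fit()


def odds_ratio_ci(estimate: float, se: float) -> tuple[float, float, float]:
    """Odds ratio and 95% CI from a log-odds estimate and its SE:
    ``exp(estimate), exp(estimate ± 1.959964·se)``."""
    if not se > 0:
        raise ValueError(f"standard error must be > 0, got {se}")
    return (
        float(np.exp(estimate)),
        float(np.exp(estimate - _Z95 * se)),
        float(np.exp(estimate + _Z95 * se)),
    )


# --- AUC (DeLong) ---------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(y: np.ndarray, score: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative) of
    the Mann–Whitney AUC estimator."""
    y = np.asarray(y, float)
    score = np.asarray(score, float)
    pos, neg = score[y == 1], score[y == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("AUC requires both positive and negative outcomes")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_auc(y, score) -> tuple[float, float, float]:
    """AUC with DeLong 95% CI. Raises on a constant score (undefined AUC)."""
    score = np.asarray(score, float)
    if score.min() == score.max():
        raise ValueError("constant score: AUC is undefined")
    auc, v10, v01 = _delong_components(y, score)
    m, n = v10.size, v01.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = _Z95 * np.sqrt(var)
    return auc, max(auc - half, 0.0), min(auc + half, 1.0)


def model_auc(fit: RandomInterceptLogitResults, conditional: bool = False):
    """AUC (with DeLong 95% CI) of a fitted GLMM's linear predictor."""
    return fit.auc(conditional=conditional)


def compare_auc(y, score_a, score_b) -> tuple[float, float]:
    """DeLong paired test for the difference of two correlated AUCs scored
    on the same observations. Returns (auc_a − auc_b, two-sided p)."""
    score_a, score_b = np.asarray(score_a, float), np.asarray(score_b, float)
    y = np.asarray(y, float)
    if score_a.shape != y.shape or score_b.shape != y.shape:
        raise ValueError("both scores must cover the same observations")
    auc_a, v10_a, v01_a = _delong_components(y, score_a)
    auc_b, v10_b, v01_b = _delong_components(y, score_b)
    m, n = v10_a.size, v01_a.size
    diff = auc_a - auc_b
    var = 0.0
    if m > 1:
        s10 = np.cov(v10_a, v10_b, ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(v01_a, v01_b, ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 1e-16:
        return diff, 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return diff, float(2.0 * stats.norm.sf(abs(z)))


def compare_model_auc(
    fit_a: RandomInterceptLogitResults, fit_b: RandomInterceptLogitResults
) -> tuple[float, float]:
    """DeLong paired comparison of two fitted models on their (shared)
    training observations."""
    ya, yb = fit_a.model.y, fit_b.model.y
    if ya.shape != yb.shape or not np.array_equal(ya, yb):
        raise ValueError("models were fitted on different observation sets")
    return compare_auc(ya, fit_a.linear_predictor(), fit_b.linear_predictor())


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Mann–Whitney U test (two-sided) comparing two samples of per-patient
    false-detection rates.

    Exact p-value for small samples (both n <= 10, no ties across pooled
    data); the normal approximation with tie correction otherwise.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
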