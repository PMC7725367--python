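"""Count-model fitting and AICc-based model comparison.

Vocalization counts per trial are typically overdispersed relative to
Poisson, so the workhorse is the log-link negative-binomial GLM; competing
designs (intercept-only null, primed-vs-control treatment, and full
timepoints factor) are ranked by AICc, Akaike's information criterion
corrected for small samples,

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1),

and summarised as relative likelihoods exp(-0.5 * dAICc) against the best
model.  Factors always use treatment contrasts: the reference (control)
level sits on the intercept and each coefficient is a group-minus-control
difference — on the log scale, the log ratio of group means.

Also provided: gaussian OLS (for latency), a gaussian random-intercept
mixed model by maximum likelihood (repeated per-call measurements nested in
animals), the Levene-style absolute-deviation-from-median variability
response, Spearman rank correlation, and the Pearson chi^2/df dispersion
check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

__all__ = [
    "DesignSpec",
    "ModelFit",
    "ModelComparison",
    "fit_count_glm",
    "fit_lm",
    "fit_lmm",
    "aicc",
    "relative_likelihood",
    "compare_models",
    "variability_response",
    "spearman",
    "dispersion",
]


@dataclass(frozen=True)
class DesignSpec:
    """Response plus an optional grouping factor with a designated
    reference level (placed on the intercept) and optional subject ids for
    mixed models."""

    response: np.ndarray
    factor: np.ndarray | None = None
    reference: str | None = None
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "response", y)
        if self.factor is not None:
            f = np.asarray(self.factor)
            if f.size != y.size:
                raise ValueError("factor and response lengths differ")
            ref = self.reference if self.reference is not None else sorted(set(f))[0]
            if ref not in set(f.tolist()):
                raise ValueError(f"reference level {ref!r} not present in factor")
            object.__setattr__(self, "factor", f)
            object.__setattr__(self, "reference", ref)
        if self.subject_ids is not None:
            object.__setattr__(self, "subject_ids", np.asarray(self.subject_ids))

    def design_matrix(self) -> pd.DataFrame:
        """Intercept + treatment-contrast dummies (reference omitted)."""
        n = self.response.size
        cols = {"(Intercept)": np.ones(n)}
        if self.factor is not None:
            levels = [lv for lv in sorted(set(self.factor.tolist())) if lv != self.reference]
            for lv in levels:
                cols[str(lv)] = (self.factor == lv).astype(float)
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class ModelFit:
    coefficients: pd.Series
    standard_errors: pd.Series
    z_values: pd.Series
    p_values: pd.Series
    log_likelihood: float
    k: int
    n: int
    aicc: float
    family: str
    dispersion: float | None = None
    theta: float | None = None
    random_intercept_sd: float | None = None
    residual_sd: float | None = None
    fitted: np.ndarray | None = field(default=None, repr=False)
    response: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class ModelComparison:
    table: pd.DataFrame  # index: model name; columns aicc, delta_aicc, rel_lik

    @property
    def best(self) -> str:
        return str(self.table["delta_aicc"].idxmin())


def aicc(log_likelihood: float, k: int, n: int) -> float:
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * log_likelihood + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def relative_likelihood(delta_aicc: float | np.ndarray) -> float | np.ndarray:
    """exp(-0.5 * dAICc): support for a model relative to the best one."""
    return np.exp(-0.5 * np.asarray(delta_aicc, dtype=float))


def _check_counts(y: np.ndarray) -> None:
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("count response must be non-negative integers")


def _wald(params, bse, dist: str, df: float | None = None):
    z = params / bse
    if dist == "z":
        p = 2 * scipy.stats.norm.sf(np.abs(z))
    else:
        p = 2 * scipy.stats.t.sf(np.abs(z), df)
    return z, pd.Series(p, index=params.index)


def _glm_fit(y: np.ndarray, X: pd.DataFrame, family) -> sm.GLM:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(y, X, family=family).fit(maxiter=100, tol=1e-8)


def fit_count_glm(d: DesignSpec, family: str = "negbin") -> ModelFit:
    """Log-link Poisson or negative-binomial GLM.

    The NB size parameter theta is estimated by profile maximum likelihood:
    an outer 1-D optimisation of the NB log-likelihood over log(theta),
    refitting the IRLS coefficients at each candidate.  With a single
    saturated factor the fitted group means equal the sample means, so each
    coefficient is the log ratio of its group mean to the reference mean.
    """
    y = d.response
    _check_counts(y)
    X = d.design_matrix()
    if family == "poisson":
        res = _glm_fit(y, X, sm.families.Poisson())
        theta = None
        k = X.shape[1]
    elif family == "negbin":

        def nll(log_theta: float) -> float:
            fam = sm.families.NegativeBinomial(alpha=np.exp(-log_theta))
            return -_glm_fit(y, X, fam).llf

        opt = minimize_scalar(nll, bounds=(-5.0, 12.0), method="bounded",
                              options={"xatol": 1e-8})
        theta = float(np.exp(opt.x))
        res = _glm_fit(y, X, sm.families.NegativeBinomial(alpha=1.0 / theta))
        k = X.shape[1] + 1  # theta counts as a parameter
    else:
        raise ValueError(f"unknown count family: {family}")
    n = y.size
    disp = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else float("nan")
    z, p = _wald(res.params, res.bse, "z")
    return ModelFit(
        coefficients=res.params,
        standard_errors=res.bse,
        z_values=z,
        p_values=p,
        log_likelihood=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n),
        family=family,
        dispersion=disp,
        theta=theta,
        fitted=np.asarray(res.fittedvalues),
        response=y,
    )


def fit_lm(d: DesignSpec) -> ModelFit:
    """Gaussian OLS with treatment contrasts: the intercept is the
    reference-group mean, each coefficient a group mean minus it."""
    y = d.response
    X = d.design_matrix()
    if y.size < X.shape[1] + 2:
        raise ValueError("too few observations for OLS")
    res = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    k = X.shape[1] + 1  # + residual variance
    n = y.size
    z, p = _wald(res.params, res.bse, "t", df=res.df_resid)
    return ModelFit(
        coefficients=res.params,
        standard_errors=res.bse,
        z_values=z,
        p_values=p,
        log_likelihood=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n),
        family="gaussian",
        residual_sd=float(np.sqrt(res.scale)),
        fitted=np.asarray(res.fittedvalues),
        response=y,
    )


def fit_lmm(d: DesignSpec) -> ModelFit:
    """Gaussian random-intercept mixed model, maximum likelihood.

    Subjects (animals) contribute random intercepts; fixed effects use the
    same treatment contrasts as the other fitters.  k counts fixed effects
    plus the two variance components.
    """
    if d.subject_ids is None:
        raise ValueError("fit_lmm requires subject_ids")
    ids, counts = np.unique(d.subject_ids, return_counts=True)
    if ids.size < 2:
        raise ValueError("need >= 2 subjects for a random intercept")
    y = d.response
    X = d.design_matrix()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=d.subject_ids)
        try:
            res = model.fit(reml=False)
        except np.linalg.LinAlgError:
            res = model.fit(reml=False, method="powell")
    p_fixed = X.shape[1]
    k = p_fixed + 2
    n = y.size
    params = res.params[: p_fixed]
    bse = res.bse[: p_fixed]
    z, p = _wald(params, bse, "z")
    return ModelFit(
        coefficients=params,
        standard_errors=bse,
        z_values=z,
        p_values=p,
        log_likelihood=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n),
        family="lmm",
        random_intercept_sd=float(np.sqrt(res.cov_re.iloc[0, 0])),
        residual_sd=float(np.sqrt(res.scale)),
        fitted=np.asarray(res.fittedvalues),
        response=y,
    )


def compare_models(fits: dict[str, ModelFit]) -> ModelComparison:
    """Rank fitted models by AICc; the best model has relative likelihood 1."""
    ns = {f.n for f in fits.values()}
    if len(ns) != 1:
        raise ValueError("models compare only on the same response (equal n)")
    aiccs = pd.Series({name: f.aicc for name, f in fits.items()})
    delta = aiccs - aiccs.min()
    table = pd.DataFrame(
        {"aicc": aiccs, "delta_aicc": delta, "rel_lik": relative_likelihood(delta)}
    )
    return ModelComparison(table=table.sort_values("aicc"))


def variability_response(values: np.ndarray, center: float | None = None) -> np.ndarray:
    """Levene-style transform: |value - median| per observation, to model
    spread differences with the same machinery as means."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    c = float(np.median(v)) if center is None else center
    return np.abs(v - c)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for constant input")
    return float(scipy.stats.spearmanr(x, y).statistic)


def dispersion(fit: ModelFit) -> float:
    """Pearson chi^2 / residual df; ~1 for a well-specified count model."""
    if fit.fitted is None or fit.response is None:
        raise ValueError("fit carries no fitted values")
    if fit.family == "poisson":
        var = fit.fitted
    elif fit.family == "negbin":
        var = fit.fitted + fit.fitted**2 / fit.theta
    else:
        raise ValueError("dispersion applies to count models")
    chi2 = float(((fit.response - fit.fitted) ** 2 / var).sum())
    df = fit.n - (fit.k - (1 if fit.family == "negbin" else 0))
    return chi2 / df
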