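"""Fitted-model layer applied to derived quantities.

Beta regression (logit mean link, constant precision) with a likelihood
ratio test for species effects on pangenome distribution indices; Type-II
ANOVA with a phylogenetic-distance covariate for continuous genome
features; a quasibinomial logistic model with Wald chi-square omnibus
tests for GC-like proportions; and Pearson product-moment correlation.

The beta-regression likelihood is maximized through statsmodels'
BetaModel; everything else here wraps statsmodels/scipy fits into
:class:`pantrait.datatypes.TestResult` objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.othermod.betareg import BetaModel

from ._util import logger
from .datatypes import TestResult

_PHI_CAP = 1e7


def squeeze_unit_interval(y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Compress [0, 1] observations strictly inside (0, 1).

    y' = (y*(n-1) + 0.5)/n, the standard boundary transformation for beta
    likelihoods; applied (and flagged) only when some observation touches
    the boundary.
    """
    y = np.asarray(y, dtype=float)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("responses outside [0, 1]")
    if y.min() > 0 and y.max() < 1:
        return y, False
    n = len(y)
    return (y * (n - 1) + 0.5) / n, True


@dataclass
class BetaRegFit:
    """Maximum-likelihood beta regression fit (logit mean link)."""

    coefficients: pd.Series
    phi: float
    loglik: float
    cov: pd.DataFrame
    converged: bool
    n_obs: int
    df_model: int
    squeezed: bool = False

    @property
    def n_params(self) -> int:
        return len(self.coefficients) + 1  # + precision

    def fitted_means(self, X: np.ndarray) -> np.ndarray:
        eta = np.asarray(X, dtype=float) @ self.coefficients.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def _design(design, n: int) -> pd.DataFrame:
    """Build a design matrix (with intercept) from a factor, array or frame."""
    if design is None:
        return pd.DataFrame({"Intercept": np.ones(n)})
    if isinstance(design, pd.DataFrame):
        X = design.copy()
        if "Intercept" not in X.columns:
            X.insert(0, "Intercept", 1.0)
        return X
    arr = np.asarray(design)
    if arr.dtype.kind in "OU" or arr.dtype.kind == "S":  # a factor
        levels = sorted(set(map(str, arr)))
        X = pd.DataFrame({"Intercept": np.ones(n)})
        for lv in levels[1:]:
            X[f"group[{lv}]"] = (np.array(list(map(str, arr))) == lv).astype(float)
        return X
    if arr.ndim == 1:
        arr = arr[:, None]
    X = pd.DataFrame(arr, columns=[f"x{i + 1}" for i in range(arr.shape[1])])
    X.insert(0, "Intercept", 1.0)
    return X


def beta_regression(y, design=None) -> BetaRegFit:
    """Fit Beta(mu*phi, (1-mu)*phi) with logit(mu) = X beta, constant phi.

    Responses on the boundary are squeezed inside (0, 1) first (flagged on
    the fit).  Degenerate all-equal responses produce a capped-precision
    fit with a warning rather than an optimizer failure.
    """
    y = np.asarray(y, dtype=float)
    y, squeezed = squeeze_unit_interval(y)
    X = _design(design, len(y))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if np.allclose(y, y[0]):
        mu = float(np.clip(y[0], 1e-10, 1 - 1e-10))
        logger.warning("all responses equal after squeeze; precision capped")
        coef = pd.Series(np.zeros(X.shape[1]), index=X.columns)
        coef.iloc[0] = np.log(mu / (1 - mu))
        ll = float(np.sum(stats.beta.logpdf(y, mu * _PHI_CAP, (1 - mu) * _PHI_CAP)))
        return BetaRegFit(coef, _PHI_CAP, ll, pd.DataFrame(np.eye(X.shape[1]) * np.nan,
                          index=X.columns, columns=X.columns), False, len(y),
                          X.shape[1] - 1, squeezed)
    model = BetaModel(y, X.to_numpy(), exog_precision=np.ones((len(y), 1)))
    res = model.fit(disp=False, maxiter=500)
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged:
        res = model.fit(disp=False, maxiter=2000, method="bfgs",
                        start_params=res.params)
        converged = bool(res.mle_retvals.get("converged", True))
    if not converged:
        raise RuntimeError(f"beta regression failed to converge: {res.mle_retvals}")
    k = X.shape[1]
    coef = pd.Series(res.params[:k], index=X.columns)
    phi = float(np.exp(res.params[k]))
    cov = pd.DataFrame(res.cov_params()[:k, :k], index=X.columns, columns=X.columns)
    return BetaRegFit(coef, phi, float(res.llf), cov, converged, len(y), k - 1, squeezed)


def lrt(full: BetaRegFit, null: BetaRegFit) -> TestResult:
    """Likelihood-ratio test between nested beta-regression fits."""
    if full.n_obs != null.n_obs:
        raise ValueError("fits are on different numbers of observations")
    df = full.n_params - null.n_params
    if df < 0:
        raise ValueError("'full' model does not nest 'null'")
    chi2 = 2.0 * (full.loglik - null.loglik)
    if chi2 < -1e-6:
        raise RuntimeError(
            f"full-model log-likelihood below null ({chi2 / 2:.4g}); refit failed"
        )
    chi2 = max(0.0, chi2)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return TestResult(
        name="LRT",
        statistic=float(chi2),
        p_value=p,
        df=df,
        extra={"loglik_full": full.loglik, "loglik_null": null.loglik},
    )


def anova_with_covariate(
    y, group, covariate, transform: str | None = None
) -> list[TestResult]:
    """Least-squares fit y ~ group + covariate with Type-II F tests.

    ``transform='log10'`` log-transforms the response (for genome size and
    CDS counts).  Returns one TestResult per model term.
    """
    y = np.asarray(y, dtype=float)
    if transform == "log10":
        if (y <= 0).any():
            raise ValueError("log10 transform requires positive responses")
        y = np.log10(y)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    df = pd.DataFrame({
        "y": y,
        "group": list(map(str, group)),
        "covariate": np.asarray(covariate, dtype=float),
    })
    if df["group"].nunique() < 2:
        raise ValueError("group factor needs at least 2 levels")
    fit = smf.ols("y ~ C(group) + covariate", data=df).fit()
    if np.isnan(fit.params).any():
        raise ValueError("rank-deficient design (aliased term)")
    table = sm.stats.anova_lm(fit, typ=2)
    out = []
    for term in ("C(group)", "covariate"):
        row = table.loc[term]
        out.append(
            TestResult(
                name="group" if term == "C(group)" else "covariate",
                statistic=float(row["F"]),
                p_value=float(row["PR(>F)"]),
                df=(float(row["df"]), float(table.loc["Residual", "df"])),
                extra={"sum_sq": float(row["sum_sq"])},
            )
        )
    return out


def quasibinomial_glm(y, group, covariate=None) -> list[TestResult]:
    """Quasibinomial logistic regression with Wald chi-square omnibus tests.

    IRLS fit with logit link; the dispersion is estimated as Pearson
    chi-square / df and scales the Wald statistics.  Returns one TestResult
    per model term.
    """
    y = np.asarray(y, dtype=float)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("proportions must lie in [0, 1]")
    data = {"y": y, "group": list(map(str, group))}
    formula = "y ~ C(group)"
    if covariate is not None:
        data["covariate"] = np.asarray(covariate, dtype=float)
        formula += " + covariate"
    df = pd.DataFrame(data)
    if np.allclose(y, y[0]):
        # constant response: no information, all slopes zero
        terms = ["group"] + (["covariate"] if covariate is not None else [])
        return [TestResult(name=t, statistic=0.0, p_value=1.0) for t in terms]
    model = smf.glm(formula, data=df, family=sm.families.Binomial())
    res = model.fit(scale="X2")
    if not res.converged:
        raise RuntimeError("quasibinomial IRLS did not converge (separation?)")
    wt = res.wald_test_terms(skip_single=False, scalar=True)
    table = wt.table
    out = []
    for term in table.index:
        if term == "Intercept":
            continue
        name = "group" if term == "C(group)" else term
        out.append(
            TestResult(
                name=name,
                statistic=float(table.loc[term, "statistic"]),
                p_value=float(table.loc[term, "pvalue"]),
                df=float(table.loc[term, "df_constraint"]),
                extra={"dispersion": float(res.scale)},
            )
        )
    return out


def pearson_correlation(x, y) -> TestResult:
    """Pearson product-moment correlation with a t-test on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.allclose(x.var(), 0) or np.allclose(y.var(), 0):
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return TestResult(
        name="Pearson r",
        statistic=float(r),
        p_value=float(p),
        df=len(x) - 2,
        effect=float(r),
        effect_name="r",
    )
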