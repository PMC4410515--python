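"""Regression model comparison for the credence-update analysis.

The analysis fits linear models of the credence S on subsets of the
objective posterior O and explanatory-goodness scores, and compares them by

* AIC = 2k - 2LL, with k = number of regression coefficients (including the
  intercept) **plus one** for the Gaussian noise variance, and LL the
  maximised Gaussian log-likelihood (ML variance estimate RSS/n).  This is
  the bookkeeping convention under which the published comparison table is
  internally consistent (its Bayes-only row has k = 3, LL = 202.39,
  AIC = -398.77).
* likelihood-ratio tests for nested pairs: 2(LL_full - LL_nested) against
  chi-squared with df = k_full - k_nested;
* Vuong's and Clarke's tests for non-nested pairs, both built from the
  pointwise log-likelihood differences d_i = ll_i(A) - ll_i(B):
  Vuong's z = sum(d) / (sqrt(n) * sd(d)) with a standard-normal reference,
  Clarke's B = #{d_i > 0} (zeros dropped) with an exact binomial(n', 1/2)
  reference, both two-sided.

Fits go through statsmodels OLS; the k/LL/AIC conventions, standardized
coefficients and the non-nested tests are computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, DegenerateFitError, NestingError


def aic_from_ll(k: int, ll: float) -> float:
    """AIC = 2k - 2LL under this package's parameter-count convention."""
    return 2.0 * k - 2.0 * ll


def lr_statistic_from_ll(ll_nested: float, ll_full: float) -> float:
    """Likelihood-ratio statistic 2 * (LL_full - LL_nested)."""
    return 2.0 * (ll_full - ll_nested)


@dataclass(frozen=True)
class FitResult:
    """A fitted Gaussian linear model with comparison bookkeeping.

    ``k`` counts the regression coefficients (intercept included) plus one
    for the noise variance.  ``pointwise_ll`` holds the per-observation
    Gaussian log-likelihood at the ML estimates, for non-nested tests.
    """

    name: str
    predictors: Tuple[str, ...]
    coef: pd.DataFrame  # index: term; columns B, se, beta, t, p
    n: int
    k: int
    ll: float
    aic: float
    r2: float
    pointwise_ll: np.ndarray

    def summary_row(self) -> dict:
        return {"model": self.name, "k": self.k, "LL": self.ll,
                "AIC": self.aic, "R2": self.r2}


@dataclass(frozen=True)
class NonNestedTestResult:
    """Outcome of a Vuong or Clarke comparison of two non-nested models."""

    test: str  # "vuong" | "clarke"
    model_a: str
    model_b: str
    statistic: float
    p: float
    preferred: Optional[str]
    degenerate: bool = False


def fit_linear_model(table: pd.DataFrame, predictors: Sequence[str],
                     response: str = "S", name: Optional[str] = None) -> FitResult:
    """OLS (= Gaussian ML) fit of ``response`` on ``predictors`` + intercept."""
    predictors = tuple(predictors)
    y = table[response].to_numpy(dtype=float)
    X = table[list(predictors)].to_numpy(dtype=float) if predictors else \
        np.empty((len(y), 0))
    n, p = X.shape
    design = sm.add_constant(X, has_constant="add")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows to fit {p} predictors")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(f"design matrix for {predictors} is rank deficient")
    res = sm.OLS(y, design).fit()
    resid = res.resid
    rss = float(resid @ resid)
    if rss <= 0.0:
        raise DegenerateFitError("zero residual variance: log-likelihood diverges")
    sigma2 = rss / n  # ML estimate
    pointwise = -0.5 * (np.log(2.0 * np.pi * sigma2) + resid ** 2 / sigma2)
    ll = float(pointwise.sum())
    k = (p + 1) + 1  # coefficients incl. intercept, plus noise variance

    sd_y = y.std(ddof=1)
    betas = [np.nan]  # intercept has no standardized coefficient
    for j in range(p):
        betas.append(res.params[j + 1] * X[:, j].std(ddof=1) / sd_y)
    coef = pd.DataFrame({
        "B": res.params, "se": res.bse, "beta": betas,
        "t": res.tvalues, "p": res.pvalues,
    }, index=["Intercept", *predictors])
    return FitResult(
        name=name or ("M" + "".join(predictors) if predictors else "Mnull"),
        predictors=predictors, coef=coef, n=n, k=k, ll=ll,
        aic=aic_from_ll(k, ll), r2=float(res.rsquared), pointwise_ll=pointwise,
    )


def lr_test(nested: FitResult, full: FitResult) -> Tuple[float, int, float]:
    """Likelihood-ratio test of a nested model against a richer one."""
    if nested.n != full.n:
        raise NestingError("models were fitted on different numbers of rows")
    if not set(nested.predictors) < set(full.predictors):
        if set(nested.predictors) == set(full.predictors):
            return 0.0, 0, 1.0
        raise NestingError(
            f"{nested.predictors} is not nested in {full.predictors}")
    stat = lr_statistic_from_ll(nested.ll, full.ll)
    df = full.k - nested.k
    return stat, df, float(stats.chi2.sf(stat, df))


def vuong_test(fit_a: FitResult, fit_b: FitResult, alpha: float = 0.05,
               corrected: bool = False) -> NonNestedTestResult:
    """Vuong's normal-reference test on pointwise log-likelihood differences.

    ``corrected=True`` applies the Schwarz model-size correction
    (each d_i shifted by -(k_a - k_b) * ln(n) / (2n)); the basic statistic is
    the default since the compared score models have equal parameter counts.
    """
    if fit_a.n != fit_b.n:
        raise NestingError("models were fitted on different numbers of rows")
    d = fit_a.pointwise_ll - fit_b.pointwise_ll
    n = len(d)
    if corrected:
        d = d - (fit_a.k - fit_b.k) * np.log(n) / (2.0 * n)
    sd = float(d.std(ddof=0))
    if sd == 0.0:
        return NonNestedTestResult("vuong", fit_a.name, fit_b.name,
                                   0.0, 1.0, None, degenerate=True)
    z = float(d.sum() / (np.sqrt(n) * sd))
    p = float(2.0 * stats.norm.sf(abs(z)))
    preferred = None
    if p < alpha:
        preferred = fit_a.name if z > 0 else fit_b.name
    return NonNestedTestResult("vuong", fit_a.name, fit_b.name, z, p, preferred)


def clarke_test(fit_a: FitResult, fit_b: FitResult,
                alpha: float = 0.05) -> NonNestedTestResult:
    """Clarke's distribution-free sign test on log-likelihood differences.

    Exact zeros are dropped; the statistic is the count of positive
    differences, referred to a two-sided exact binomial(n', 1/2).
    """
    if fit_a.n != fit_b.n:
        raise NestingError("models were fitted on different numbers of rows")
    d = fit_a.pointwise_ll - fit_b.pointwise_ll
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return NonNestedTestResult("clarke", fit_a.name, fit_b.name,
                                   0.0, 1.0, None, degenerate=True)
    b = int((d > 0).sum())
    p = float(stats.binomtest(b, n, 0.5).pvalue)
    preferred = None
    if p < alpha and b != n - b:
        preferred = fit_a.name if b > n - b else fit_b.name
    return NonNestedTestResult("clarke", fit_a.name, fit_b.name, float(b), p, preferred)


@dataclass(frozen=True)
class ComparisonReport:
    """A comparison-table of fitted models plus pairwise non-nested tests."""

    table: pd.DataFrame  # columns model, k, LL, AIC, dAIC, chi2, df, p, R2
    fits: Dict[str, FitResult]
    pairwise: List[NonNestedTestResult]
    best: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def compare_models(table: pd.DataFrame, model_specs: Dict[str, Sequence[str]],
                   baseline: str, response: str = "S") -> ComparisonReport:
    """Fit a family of models and build the comparison report.

    ``model_specs`` maps model names to predictor-column lists; ``baseline``
    names the model nested in every other (it anchors the LR-test column).
    Vuong and Clarke tests are run for every non-nested pair.
    """
    if baseline not in model_specs:
        raise ValueError(f"baseline {baseline!r} is not among the model specs")
    fits = {nm: fit_linear_model(table, preds, response=response, name=nm)
            for nm, preds in model_specs.items()}
    best_aic = min(f.aic for f in fits.values())
    winners = sorted(nm for nm, f in fits.items() if f.aic == best_aic)
    if len(winners) > 1:
        warnings.warn(f"AIC tie among {winners}; reporting {winners[0]} as best",
                      stacklevel=2)
    best = winners[0]

    rows = []
    for nm, fit in fits.items():
        row = fit.summary_row()
        row["dAIC"] = fit.aic - best_aic
        if nm == baseline:
            row.update(chi2=np.nan, df=np.nan, p=np.nan)
        else:
            chi2, df, p = lr_test(fits[baseline], fit)
            row.update(chi2=chi2, df=df, p=p)
        rows.append(row)
    out = pd.DataFrame(rows)[["model", "k", "LL", "AIC", "dAIC", "chi2", "df", "p", "R2"]]

    pairwise: List[NonNestedTestResult] = []
    names = list(model_specs)
    for i, nm_a in enumerate(names):
        for nm_b in names[i + 1:]:
            pa, pb = set(model_specs[nm_a]), set(model_specs[nm_b])
            if pa <= pb or pb <= pa:
                continue
            pairwise.append(vuong_test(fits[nm_a], fits[nm_b]))
            pairwise.append(clarke_test(fits[nm_a], fits[nm_b]))
    return ComparisonReport(table=out, fits=fits, pairwise=pairwise, best=best)


def study_model_family(measure_keys: Sequence[str] = ("P", "G1", "G2", "G3", "SS"),
                       include_judged: bool = True) -> Dict[str, List[str]]:
    """The analysis's model family over a trial table's columns.

    ``MO`` regresses S on the objective posterior alone; each ``MOA_XB_X``
    adds the computed scores under measure X; ``MOAB`` uses the judged
    scores; ``MOABA_G3B_G3`` combines judged and computed (G3) scores.
    """
    family: Dict[str, List[str]] = {"MO": ["O"]}
    for key in measure_keys:
        family[f"MOA_{key}B_{key}"] = ["O", f"A_{key}", f"B_{key}"]
    if include_judged:
        family["MOAB"] = ["O", "judged_A", "judged_B"]
    return family
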