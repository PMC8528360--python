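"""Maximum-likelihood logistic regression with Wald inference and
SAS-convention standardized coefficients.

The fit itself is delegated to ``statsmodels`` (Newton-Raphson on the
Bernoulli log-likelihood, parameter tolerance 1e-8, at most 100
iterations); this module owns the inference surface used downstream:
odds ratios with Wald 95% CIs (z = 1.96 exactly), predicted
probabilities, and standardized coefficients

    SC_i = beta_i * SD(x_i) / (pi / sqrt(3)),

where SD is the sample standard deviation of the predictor in the fitting
table and pi/sqrt(3) is the standard deviation of the standard logistic
distribution.  This is the convention of SAS PROC LOGISTIC's standardized
estimate, and the convention under which the published score weights are
reproducible from the published odds ratios and covariate SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortError, CohortTable

__all__ = ["FitResult", "fit_logistic", "standardized_coefficients", "predict_probabilities"]

Z95 = 1.96                        # Wald normal quantile, used exactly
LOGISTIC_SD = np.pi / np.sqrt(3)  # ~1.8138
SEPARATION_BETA = 15.0            # |beta| beyond this flags (quasi-)separation


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


@dataclass
class FitResult:
    """Logistic-regression fit: coefficients, Wald inference, likelihoods.

    ``params``/``bse`` are indexed by predictor name with ``const`` first.
    ``llf``/``llnull`` are the log-likelihoods of the fitted and
    intercept-only models.
    """

    predictors: list[str]
    outcome: str
    params: pd.Series
    bse: pd.Series
    llf: float
    llnull: float
    n: int
    converged: bool
    n_iter: int = 0
    sc: pd.Series | None = field(default=None, repr=False)

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    @property
    def coef(self) -> pd.Series:
        return self.params.drop("const")

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.coef)

    def conf_int(self) -> pd.DataFrame:
        """Wald 95% CI for the odds ratios: exp(beta +/- 1.96 SE)."""
        se = self.bse.drop("const")
        lo = np.exp(self.coef - Z95 * se)
        hi = np.exp(self.coef + Z95 * se)
        return pd.DataFrame({"or_lower": lo, "or_upper": hi})

    def summary_frame(self) -> pd.DataFrame:
        """Per-predictor table: beta, SE, OR, 95% CI, standardized coefficient."""
        out = pd.DataFrame({
            "coef": self.coef,
            "se": self.bse.drop("const"),
            "odds_ratio": self.odds_ratios,
        }).join(self.conf_int())
        if self.sc is not None:
            out["std_coef"] = self.sc
        return out


def _design(table: CohortTable, predictors: list[str]) -> np.ndarray:
    X = table.df[predictors].to_numpy(float)
    if np.isnan(X).any():
        j = int(np.argwhere(np.isnan(X))[0, 1])
        raise CohortError(
            f"predictor {predictors[j]!r} has missing values; impute first")
    return sm.add_constant(X, has_constant="add")


def fit_logistic(table: CohortTable, predictors: list[str], outcome: str | None = None) -> FitResult:
    """Fit a multivariable logistic model by maximum likelihood.

    Raises on a single-class outcome or a rank-deficient design; a fit
    that diverges (|beta| > 15 without convergence) is returned with
    ``converged=False`` so callers can discard it.
    """
    outcome = outcome or table.outcome
    y = table.df[outcome].to_numpy(float)
    if np.isnan(y).any():
        raise CohortError("outcome has missing values")
    if len(np.unique(y)) < 2:
        raise CohortError("outcome has a single class; cannot fit")
    X = _design(table, predictors)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CohortError(f"rank-deficient design for predictors {predictors}")
    names = ["const"] + list(predictors)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except np.linalg.LinAlgError:
        # singular Hessian mid-iteration: complete/quasi-complete separation
        nan = pd.Series(np.nan, index=names)
        return FitResult(predictors=list(predictors), outcome=outcome,
                         params=nan, bse=nan.copy(), llf=np.nan, llnull=np.nan,
                         n=len(y), converged=False)
    params = pd.Series(res.params, index=names)
    converged = bool(res.mle_retvals.get("converged", False))
    if np.abs(params.drop("const")).max() > SEPARATION_BETA:
        # diverging coefficients: complete/quasi-complete separation
        converged = False
    return FitResult(
        predictors=list(predictors), outcome=outcome,
        params=params, bse=pd.Series(res.bse, index=names),
        llf=float(res.llf), llnull=float(res.llnull),
        n=len(y), converged=converged,
        n_iter=int(res.mle_retvals.get("iterations", 0)),
    )


def standardized_coefficients(fit: FitResult, table: CohortTable) -> pd.Series:
    """SAS-convention standardized coefficients, SC_i = beta_i SD_i / (pi/sqrt(3)).

    SD is the sample (ddof=1) standard deviation of each predictor in the
    fitting table; the result is attached to ``fit.sc`` and returned.
    """
    if not fit.converged:
        raise RuntimeError("fit did not converge; standardized coefficients undefined")
    sds = table.df[fit.predictors].std(ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise CohortError(f"zero-variance predictor {bad!r}")
    sc = fit.coef * sds.to_numpy() / LOGISTIC_SD
    fit.sc = sc
    return sc


def predict_probabilities(fit: FitResult, table: CohortTable) -> np.ndarray:
    """Per-row event probability, expit of the fitted linear predictor."""
    X = _design(table, fit.predictors)
    from scipy.special import expit
    return expit(X @ fit.params.to_numpy())
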