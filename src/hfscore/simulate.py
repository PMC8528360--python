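"""Synthetic heart-failure cohort generator.

The real Beijing multi-hospital cohort is not publicly deposited, so the
package ships a generator that emulates its published marginal structure:
continuous covariates drawn from the reported normal distributions (age
truncated at >=20 years, the study's eligibility floor), binary covariates
at the reported prevalences, a binary one-year mortality outcome drawn from
a logistic model with the reported effect sizes, and MCAR missingness at
the reported per-variable rates (covariates only, never the outcome).

Covariates are mutually independent by default — only marginals were
published.  A Gaussian-copula correlation hook is provided for sensitivity
work but defaults to the identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .cohort import CohortTable, default_schema

__all__ = ["GeneratorParams", "SyntheticCohort", "calibrate_intercept", "generate_cohort"]

# Published marginal distributions of the study cohort (n=1742):
# continuous as (mean, SD), binaries as prevalence, MCAR rates per variable.
CONTINUOUS_MARGINALS = {
    "age": (57.1, 12.4),
    "bmi": (25.1, 3.4),
    "la_diam": (39.9, 7.9),
    "heart_rate": (73.0, 14.0),
}
BINARY_PREVALENCES = {
    "female": 0.199,
    "lvef_lt40": 0.355,
    "nyha_gt3": 0.427,
    "hf_history": 0.181,
    "ami_history": 0.226,
    "chd": 0.712,
    "diabetes": 0.278,
    "hypertension": 0.636,
    "valve_surgery": 0.061,
    "smoking": 0.578,
    "alcohol": 0.351,
}
MISSING_RATES = {"la_diam": 0.038, "heart_rate": 0.007, "age": 0.002}

#: Reported odds ratios of the five selected risk factors; all other
#: covariates carry zero effect by default.
TRUE_ODDS_RATIOS = {
    "age": 1.03,       # per year
    "female": 0.44,
    "la_diam": 1.05,   # per mm
    "bmi": 0.89,       # per kg/m2
    "nyha_gt3": 4.2,
}

AGE_FLOOR = 20.0  # eligibility: hospitalized patients aged >= 20 years


def _default_log_odds() -> dict[str, float]:
    return {k: math.log(v) for k, v in TRUE_ODDS_RATIOS.items()}


@dataclass
class GeneratorParams:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    continuous : dict
        name -> (mean, SD); SDs must be positive.
    prevalence : dict
        name -> Bernoulli prevalence in (0, 1).
    log_odds : dict
        name -> true log odds ratio of the outcome model; variables absent
        from this dict carry zero effect.
    intercept : float or None
        Outcome-model intercept (log-odds).  ``None`` means "calibrate to
        ``target_rate`` before generating".
    target_rate : float
        Marginal one-year mortality proportion the intercept is calibrated
        to (study value 0.065).
    missing_rates : dict
        name -> MCAR missingness proportion, applied to covariates only.
    correlation : ndarray or None
        Optional Gaussian-copula correlation matrix over the covariates in
        generation order; ``None`` means independent.
    """

    continuous: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CONTINUOUS_MARGINALS))
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(BINARY_PREVALENCES))
    log_odds: dict[str, float] = field(default_factory=_default_log_odds)
    intercept: float | None = None
    target_rate: float = 0.065
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(MISSING_RATES))
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, (_, sd) in self.continuous.items():
            if not sd > 0:
                raise ValueError(f"{name}: SD must be > 0, got {sd}")
        for name, p in self.prevalence.items():
            if not 0 < p < 1:
                raise ValueError(f"{name}: prevalence must be in (0,1), got {p}")
        for name, r in self.missing_rates.items():
            if not 0 <= r < 1:
                raise ValueError(f"{name}: missing rate must be in [0,1), got {r}")
        if not 0 < self.target_rate < 1:
            raise ValueError(f"target rate must be in (0,1), got {self.target_rate}")
        for name, b in self.log_odds.items():
            if not np.isfinite(b):
                raise ValueError(f"{name}: log odds ratio must be finite, got {b}")

    @property
    def covariate_order(self) -> list[str]:
        """Generation order: schema order restricted to generated covariates."""
        names = list(self.continuous) + list(self.prevalence)
        schema_order = [v.name for v in default_schema() if v.name in names]
        # keep any extra (non-schema) covariates in declaration order
        return schema_order + [n for n in names if n not in schema_order]


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth.

    ``linear_predictor`` is the true per-row log-odds (intercept included)
    from which the outcome was drawn, stored before missingness was applied.
    """

    cohort: CohortTable
    linear_predictor: np.ndarray
    params: GeneratorParams


def _draw_covariates(params: GeneratorParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    order = params.covariate_order
    k = len(order)
    if params.correlation is None:
        z = rng.standard_normal((n, k))
    else:
        R = np.asarray(params.correlation, float)
        if R.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k} for covariates {order}")
        z = rng.standard_normal((n, k)) @ np.linalg.cholesky(R).T
    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(order):
        if name in params.continuous:
            mean, sd = params.continuous[name]
            x = mean + sd * z[:, j]
            if name == "age":
                # rejection sampling of the eligibility floor; negligible mass
                bad = x < AGE_FLOOR
                while bad.any():
                    x[bad] = mean + sd * rng.standard_normal(bad.sum())
                    bad = x < AGE_FLOOR
            cols[name] = x
        else:
            # copula margin: P(Phi(z) < p) = p, monotone in z
            cols[name] = (ndtr(z[:, j]) < params.prevalence[name]).astype(float)
    return pd.DataFrame(cols)


def _linear_predictor(params: GeneratorParams, X: pd.DataFrame) -> np.ndarray:
    eta = np.zeros(len(X))
    for name, beta in params.log_odds.items():
        if beta != 0.0:
            eta += beta * X[name].to_numpy()
    return eta


def calibrate_intercept(
    params: GeneratorParams,
    target_rate: float | None = None,
    n_mc: int = 200_000,
    seed: int = 0,
    tol: float = 5e-4,
) -> float:
    """Solve for the outcome-model intercept hitting a marginal event rate.

    Draws ``n_mc`` covariate vectors once and bisects on the intercept b0
    until the Monte-Carlo mean of ``expit(b0 + eta)`` is within ``tol`` of
    the target (the mean is strictly increasing in b0).  With all effects
    zero this reduces to ``logit(target)``.
    """
    target = params.target_rate if target_rate is None else target_rate
    if not 0 < target < 1:
        raise ValueError("target rate must be in (0,1)")
    if n_mc < 10_000:
        raise ValueError("n_mc must be at least 10,000 for a stable calibration")
    rng = np.random.default_rng(seed)
    eta = _linear_predictor(params, _draw_covariates(params, n_mc, rng))
    lo, hi = -40.0, 15.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rate = float(expit(mid + eta).mean())
        if abs(rate - target) <= tol and hi - lo < 1e-6:
            return mid
        if rate < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            return 0.5 * (lo + hi)
    raise RuntimeError("intercept calibration did not converge")


def generate_cohort(params: GeneratorParams, n: int, seed: int) -> SyntheticCohort:
    """Generate a synthetic cohort of ``n`` patients.

    The outcome is drawn Bernoulli(expit(intercept + sum(beta_i x_i))) from
    the complete covariates; MCAR missingness is then applied to covariates
    at the configured rates.  Same ``seed`` gives a bit-identical cohort.
    If ``params.intercept`` is None it is calibrated first (seeded off
    ``seed`` so the whole call is reproducible).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    intercept = params.intercept
    if intercept is None:
        intercept = calibrate_intercept(params, seed=seed ^ 0x5EED)
    rng = np.random.default_rng(seed)
    X = _draw_covariates(params, n, rng)
    eta = intercept + _linear_predictor(params, X)
    y = (rng.random(n) < expit(eta)).astype(float)

    df = X.copy()
    for name, rate in params.missing_rates.items():
        if rate > 0 and name in df:
            df.loc[rng.random(n) < rate, name] = np.nan
    df["death_1y"] = y

    schema = [v for v in default_schema() if v.name in df.columns]
    extra = [c for c in df.columns if c not in {v.name for v in schema}]
    if extra:
        from .cohort import VariableSpec
        for c in extra:
            vals = df[c].dropna().unique()
            kind = "binary" if set(vals) <= {0.0, 1.0} else "continuous"
            schema.append(VariableSpec(c, kind, "candidate"))
    order = [v.name for v in schema]
    table = CohortTable(df[order], schema)
    return SyntheticCohort(table, eta, params)
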