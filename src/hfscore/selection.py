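"""Resampling-based variable selection by posterior selection probability.

The selection engine repeatedly refits the full multivariable logistic
model on nonparametric bootstrap resamples of the derivation sample (n
rows drawn with replacement per iteration).  For each candidate it records
whether the Wald 95% CI for the odds ratio excludes 1 in that refit; the
*posterior selection probability* of a candidate is the fraction of
completed iterations in which its CI excluded 1.  Candidates at or above a
probability threshold (default 0.9) are selected as robust risk factors.

This is a frequentist case-resampling scheme — there are no priors,
proposals, or chains — sometimes advertised under a "Markov chain Monte
Carlo simulation" label in the clinical-score literature.  Alongside the
two-sided exclusion probability, the one-sided probability that the
candidate *increases* risk (CI excludes 1 on the harmful side) is
reported, so protective factors show a near-zero harmful-direction
probability while still being selected by the two-sided rule.

Each iteration also records the in-resample ROC AUC of the refitted model
as a discrimination diagnostic.  Iterations whose refit fails to converge
(e.g. separation in the resample) are discarded and counted; the
probability denominator is the number of completed iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortError, CohortTable
from .evaluation import roc_auc
from .logistic import SEPARATION_BETA, Z95

__all__ = ["SelectionResult", "run_selection", "select_variables"]


@dataclass
class SelectionResult:
    """Outcome of a resampling selection run."""

    candidates: list[str]
    posterior: pd.Series          # two-sided CI-excludes-1 probability
    prob_increase: pd.Series      # one-sided: CI excludes 1 on the harmful side
    aucs: np.ndarray = field(repr=False)
    n_iter: int = 0
    n_completed: int = 0
    n_discarded: int = 0
    threshold: float = 0.9

    @property
    def selected(self) -> list[str]:
        return select_variables(self, self.threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "posterior": self.posterior,
            "prob_increase": self.prob_increase,
            "selected": self.posterior >= self.threshold,
        })


def run_selection(
    table: CohortTable,
    candidates: list[str],
    outcome: str | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    threshold: float = 0.9,
    extra_covariates: list[str] | None = None,
) -> SelectionResult:
    """Run the bootstrap selection on a (screened, imputed) cohort.

    All candidates enter every iteration's model jointly;
    ``extra_covariates`` (e.g. missingness indicators) are included in
    each model but are not themselves scored for selection.  Fails hard if
    fewer than half the iterations complete, which signals pathological
    data rather than sampling noise.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    outcome = outcome or table.outcome
    extra = list(extra_covariates or [])
    cols = list(candidates) + extra
    X = table.df[cols].to_numpy(float)
    if np.isnan(X).any():
        raise CohortError("candidates contain missing values; impute first")
    y = table.df[outcome].to_numpy(float)
    n, k = X.shape
    Xc = np.column_stack([np.ones(n), X])

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(candidates))
    hits_up = np.zeros(len(candidates))
    aucs: list[float] = []
    completed = discarded = 0
    sl = slice(1, 1 + len(candidates))  # candidate coefficients in the design

    for _ in range(n_iter):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            discarded += 1
            continue
        Xb = Xc[idx]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(yb, Xb).fit(method="newton", maxiter=100,
                                           tol=1e-8, disp=0)
            ok = bool(res.mle_retvals.get("converged", False))
        except Exception:
            ok = False
        if not ok or np.abs(res.params[1:]).max() > SEPARATION_BETA or \
                not np.all(np.isfinite(res.bse)):
            discarded += 1
            continue
        b, se = res.params[sl], res.bse[sl]
        excl = np.abs(b) > Z95 * se          # Wald 95% CI for OR excludes 1
        hits += excl
        hits_up += excl & (b > 0)
        aucs.append(roc_auc(res.predict(Xb), yb))
        completed += 1

    if completed < 0.5 * n_iter:
        raise RuntimeError(
            f"only {completed}/{n_iter} bootstrap iterations converged; "
            "data look pathological (separation or too few events)"
        )
    post = pd.Series(hits / completed, index=list(candidates))
    post_up = pd.Series(hits_up / completed, index=list(candidates))
    return SelectionResult(
        candidates=list(candidates), posterior=post, prob_increase=post_up,
        aucs=np.asarray(aucs), n_iter=n_iter, n_completed=completed,
        n_discarded=discarded, threshold=threshold,
    )


def select_variables(result: SelectionResult, threshold: float | None = None) -> list[str]:
    """Candidates whose posterior probability meets the threshold,
    in descending probability order (ties keep candidate order)."""
    thr = result.threshold if threshold is None else threshold
    keep = result.posterior[result.posterior >= thr]
    return list(keep.sort_values(ascending=False, kind="stable").index)
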