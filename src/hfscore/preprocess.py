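"""Missing-data handling and candidate screening.

Missing continuous covariates are handled by the dummy-indicator method: a
0/1 was-missing indicator column is appended and the missing cells are
replaced by the median of the observed values, so every patient stays in
the analysis.  This assumes missingness completely at random and is less
efficient than multiple imputation, which is deliberately out of scope.

Candidate risk factors are screened before modelling: binary candidates
must exceed a prevalence floor (default 1%), and candidates qualify when
their bivariate Spearman correlation with the outcome is significant at
``alpha`` — or when they are forced in on clinical-judgment grounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortError, CohortTable, VariableSpec

__all__ = ["ImputationRecord", "impute_with_indicators", "screen_candidates"]


@dataclass(frozen=True)
class ImputationRecord:
    variable: str
    median: float
    indicator: str
    count_imputed: int


def indicator_name(variable: str) -> str:
    return f"{variable}_missing"


def impute_with_indicators(
    table: CohortTable, variables: list[str]
) -> tuple[CohortTable, list[ImputationRecord]]:
    """Median-impute continuous variables, appending was-missing indicators.

    For each named variable a ``<name>_missing`` indicator column (1 where
    the value was absent, else 0) is appended with role ``auxiliary`` and
    missing cells are replaced by the median of the observed values.
    Observed values are never altered, and re-running on an already imputed
    table is a no-op.
    """
    df = table.df.copy()
    schema = list(table.schema)
    records: list[ImputationRecord] = []
    for name in variables:
        spec = table.spec(name)
        if spec.kind != "continuous":
            raise CohortError(
                f"{name!r} is binary; the dummy-indicator median method applies "
                "to continuous variables only"
            )
        mask = df[name].isna()
        observed = df[name][~mask]
        if observed.empty:
            raise CohortError(f"{name!r}: all values missing, cannot impute")
        med = float(observed.median())
        ind = indicator_name(name)
        if ind in df.columns:  # idempotent re-run: merge with prior indicator
            df[ind] = np.maximum(df[ind].to_numpy(), mask.to_numpy(float))
        else:
            df[ind] = mask.to_numpy(float)
            schema.append(VariableSpec(ind, "binary", "auxiliary", "flag"))
        df.loc[mask, name] = med
        records.append(ImputationRecord(name, med, ind, int(mask.sum())))
    return CohortTable(df, schema), records


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p; exact permutation p for n <= 10."""
    n = len(x)
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= 10:
        res = stats.permutation_test(
            (x,), lambda xs: stats.spearmanr(xs, y).statistic,
            permutation_type="pairings", alternative="two-sided",
            n_resamples=np.inf,
        )
        return rho, float(res.pvalue)
    return rho, float(stats.spearmanr(x, y).pvalue)


def screen_candidates(
    table: CohortTable,
    candidates: list[str] | None = None,
    alpha: float = 0.05,
    forced: tuple[str, ...] = (),
    prevalence_floor: float = 0.01,
) -> pd.DataFrame:
    """Bivariate screening of candidate risk factors against the outcome.

    Rules, applied per candidate:

    * binary candidates with prevalence <= ``prevalence_floor`` are
      disqualified regardless of significance (too rare to model);
    * remaining candidates qualify when the Spearman correlation with the
      outcome has p < ``alpha``, or when listed in ``forced`` (the clinical
      judgment hook);
    * a candidate constant across rows has undefined rho and is
      disqualified with reason ``"constant"``.

    Returns a DataFrame with columns: variable, prevalence (binary
    prevalence, or non-missing fraction for continuous), rho, p_value,
    qualified, forced, reason.  Missing candidate values are pairwise
    dropped (screen after imputation to use all rows).
    """
    if candidates is None:
        candidates = table.candidates
    y_all = table.df[table.outcome].to_numpy(float)
    rows = []
    for name in candidates:
        spec = table.spec(name)
        col = table.df[name]
        obs = col.notna().to_numpy()
        x, y = col[obs].to_numpy(float), y_all[obs]
        prev = float(np.mean(x == 1)) if spec.kind == "binary" else float(obs.mean())
        is_forced = name in forced
        if spec.kind == "binary" and prev <= prevalence_floor:
            rows.append(dict(variable=name, prevalence=prev, rho=np.nan,
                             p_value=np.nan, qualified=False, forced=is_forced,
                             reason=f"prevalence <= {prevalence_floor:g}"))
            continue
        if np.ptp(x) == 0:
            rows.append(dict(variable=name, prevalence=prev, rho=np.nan,
                             p_value=np.nan, qualified=False, forced=is_forced,
                             reason="constant"))
            continue
        rho, p = _spearman(x, y)
        qualified = bool(p < alpha or is_forced)
        reason = "forced" if (is_forced and not p < alpha) else (
            f"p < {alpha:g}" if qualified else f"p >= {alpha:g}")
        rows.append(dict(variable=name, prevalence=prev, rho=rho, p_value=p,
                         qualified=qualified, forced=is_forced, reason=reason))
    return pd.DataFrame(rows)
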