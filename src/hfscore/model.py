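"""Risk-score derivation as a model/results pair.

``RiskScoreModel`` wraps a derivation cohort together with the screening
and selection configuration; ``fit()`` runs the full derivation —
imputation, prevalence/Spearman screening, bootstrap posterior-probability
selection, the final multivariable logistic fit with standardized
coefficients, and score construction — and returns a
``RiskScoreResults`` carrying the estimates, the selection diagnostics,
the :class:`~hfscore.score.ScoreSpec`, and evaluation helpers.

Typical use::

    model = RiskScoreModel(derivation_cohort)
    results = model.fit(n_iter=10_000, seed=42)
    print(results.summary())
    report = results.evaluate(test_cohort, sample="test")
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableSpec, default_schema
from .evaluation import (EvaluationReport, decile_calibration, hosmer_lemeshow,
                         nagelkerke_r2, roc_auc, tier_mortality)
from .logistic import FitResult, fit_logistic, predict_probabilities, standardized_coefficients
from .preprocess import ImputationRecord, impute_with_indicators, screen_candidates
from .score import ScoreSpec, assign_tier, build_score_spec, evaluate_score
from .selection import SelectionResult, run_selection

__all__ = ["RiskScoreModel", "RiskScoreResults"]


class RiskScoreModel:
    """Derive an integer-grid clinical risk score from a patient cohort.

    Parameters
    ----------
    cohort : CohortTable
        The derivation sample (split the full cohort first).
    candidates : list of str, optional
        Candidate risk factors; defaults to every schema variable with the
        ``candidate`` role.
    alpha : float
        Two-sided significance level for Spearman screening (default 0.05).
    prevalence_floor : float
        Binary candidates at or below this prevalence are disqualified
        (default 0.01, the ">1% frequency" rule).
    forced : tuple of str
        Candidates forced through screening on clinical-judgment grounds.
    age_variable : str
        Which selected variable takes the finer x10 / floor-one-decimal
        rescale rule (default ``"age"``).
    indicators_in_selection : bool
        Include was-missing indicator columns as covariates during
        selection (default True); the final model uses the risk factors
        only.
    """

    def __init__(
        self,
        cohort: CohortTable,
        candidates: list[str] | None = None,
        alpha: float = 0.05,
        prevalence_floor: float = 0.01,
        forced: tuple[str, ...] = (),
        age_variable: str = "age",
        indicators_in_selection: bool = True,
    ):
        self.cohort = cohort
        self.candidates = list(candidates) if candidates else cohort.candidates
        self.alpha = alpha
        self.prevalence_floor = prevalence_floor
        self.forced = tuple(forced)
        self.age_variable = age_variable
        self.indicators_in_selection = indicators_in_selection

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: list[VariableSpec] | None = None,
                       **kwargs) -> "RiskScoreModel":
        schema = schema or [v for v in default_schema() if v.name in df.columns]
        return cls(CohortTable(df.copy(), schema), **kwargs)

    def fit(self, n_iter: int = 10_000, threshold: float = 0.9,
            seed: int | None = None) -> "RiskScoreResults":
        """Run the full derivation and return the results object."""
        if not 0 < threshold <= 1:
            raise ValueError("selection threshold must be in (0, 1]")
        seed = 0 if seed is None else seed
        # 1. dummy-indicator median imputation of incomplete continuous candidates
        to_impute = [
            name for name in self.candidates
            if self.cohort.spec(name).kind == "continuous"
            and self.cohort.df[name].isna().any()
        ]
        imputed, records = impute_with_indicators(self.cohort, to_impute)
        # 2. prevalence + Spearman screening
        screening = screen_candidates(
            imputed, self.candidates, alpha=self.alpha,
            forced=self.forced, prevalence_floor=self.prevalence_floor,
        )
        qualified = list(screening.loc[screening.qualified, "variable"])
        if not qualified:
            raise RuntimeError("no candidate qualified at screening")
        # 3. bootstrap posterior-probability selection
        # indicator covariates obey the same prevalence floor as candidates:
        # near-empty indicators quasi-separate in bootstrap resamples
        indicators = [
            r.indicator for r in records
            if imputed.df[r.indicator].mean() > self.prevalence_floor
        ] if self.indicators_in_selection else []
        selection = run_selection(
            imputed, qualified, n_iter=n_iter, seed=seed,
            threshold=threshold, extra_covariates=indicators,
        )
        selected = selection.selected
        if not selected:
            raise RuntimeError("no variable reached the posterior-probability threshold")
        # keep a stable clinical ordering (schema order) for the final model
        order = [v.name for v in imputed.schema]
        selected = sorted(selected, key=order.index)
        # 4. final multivariable fit on the original derivation sample
        fit = fit_logistic(imputed, selected)
        if not fit.converged:
            raise RuntimeError("final model failed to converge")
        sc = standardized_coefficients(fit, imputed)
        # 5. score construction
        spec = build_score_spec(sc, age_variable=self.age_variable)
        return RiskScoreResults(
            model=self, imputation=records, screening=screening,
            selection=selection, fit=fit, score_spec=spec,
            imputed_cohort=imputed,
        )


@dataclass
class RiskScoreResults:
    """Fitted derivation results: estimates, diagnostics, and the score."""

    model: RiskScoreModel
    imputation: list[ImputationRecord]
    screening: pd.DataFrame
    selection: SelectionResult
    fit: FitResult
    score_spec: ScoreSpec
    imputed_cohort: CohortTable = field(repr=False)

    @property
    def selected(self) -> list[str]:
        return self.fit.predictors

    def risk_factor_table(self) -> pd.DataFrame:
        """Per-selected-variable table: posterior probability, OR (95% CI),
        standardized coefficient, initial and rescaled weight."""
        tab = self.fit.summary_frame()
        tab.insert(0, "posterior", self.selection.posterior.reindex(tab.index))
        tab["initial_weight"] = pd.Series(self.score_spec.initial)
        tab["rescaled_weight"] = pd.Series(self.score_spec.weights)
        return tab

    def summary(self) -> str:
        """Human-readable derivation summary."""
        t = self.risk_factor_table().copy()
        t["or_95ci"] = [
            f"{o:.2f} ({l:.2f}-{u:.2f})"
            for o, l, u in zip(t.odds_ratio, t.or_lower, t.or_upper)
        ]
        cols = ["posterior", "or_95ci", "std_coef", "initial_weight", "rescaled_weight"]
        lines = [
            "Five-variable risk score derivation"
            if len(self.selected) == 5 else
            f"{len(self.selected)}-variable risk score derivation",
            f"n = {self.fit.n}, events = {int(self.imputed_cohort.df[self.fit.outcome].sum())}",
            f"bootstrap iterations: {self.selection.n_completed} completed, "
            f"{self.selection.n_discarded} discarded "
            f"(threshold {self.selection.threshold:g})",
            "",
            t[cols].round(4).to_string(),
            "",
            self.score_spec.formula(),
            f"tiers: low < {self.score_spec.low_cut:g} <= moderate <= "
            f"{self.score_spec.high_cut:g} < high",
        ]
        return "\n".join(lines)

    # -- application -----------------------------------------------------
    def _prepared(self, cohort: CohortTable) -> CohortTable:
        """Impute any incomplete continuous score/model variable."""
        need = [
            v for v in self.selected
            if cohort.spec(v).kind == "continuous" and cohort.df[v].isna().any()
        ]
        return impute_with_indicators(cohort, need)[0] if need else cohort

    def score(self, cohort: CohortTable) -> pd.DataFrame:
        """Scored copy of a cohort: appends ``score`` and ``tier`` columns."""
        prepared = self._prepared(cohort)
        out = cohort.df.copy()
        out["score"] = evaluate_score(self.score_spec, prepared)
        out["tier"] = assign_tier(self.score_spec, out["score"].to_numpy())
        return out

    def evaluate(self, cohort: CohortTable | None = None, sample: str = "derivation",
                 groups: int = 10) -> EvaluationReport:
        """Discrimination/calibration report on a sample.

        Both validation models are refitted on the evaluated sample: the
        multivariable model on the selected risk factors, and a
        univariable logistic model on the integer score.
        """
        table = self.imputed_cohort if cohort is None else self._prepared(cohort)
        y = table.df[table.outcome].to_numpy(float)

        mfit = fit_logistic(table, self.selected)
        mprob = predict_probabilities(mfit, table)

        scores = evaluate_score(self.score_spec, table)
        stable = table.with_columns(
            pd.DataFrame({"score": scores}, index=table.df.index),
            [VariableSpec("score", "continuous", "auxiliary", "points")],
        )
        sfit = fit_logistic(stable, ["score"])
        sprob = predict_probabilities(sfit, stable)

        tiers = assign_tier(self.score_spec, scores)
        return EvaluationReport(
            sample=sample, n=table.n, events=int(y.sum()),
            model_auc=roc_auc(mprob, y),
            model_r2=nagelkerke_r2(mfit.llf, mfit.llnull, mfit.n),
            model_hl=hosmer_lemeshow(mprob, y, groups),
            score_auc=roc_auc(sprob, y),
            score_r2=nagelkerke_r2(sfit.llf, sfit.llnull, sfit.n),
            score_hl=hosmer_lemeshow(sprob, y, groups),
            score_mean=float(np.mean(scores)), score_sd=float(np.std(scores, ddof=1)),
            deciles=decile_calibration(mprob, y, groups),
            tiers=tier_mortality(tiers, y),
        )
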