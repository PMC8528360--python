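"""Discrimination and calibration metrics for binary risk models.

* ROC AUC via the Mann-Whitney pairwise estimator (ties count one half).
* Max-rescaled (Nagelkerke) R-squared from the fitted and null
  log-likelihoods.
* Hosmer-Lemeshow goodness-of-fit over equal-frequency predicted-risk
  groups (default deciles), with tied predictions kept in one group.
* Decile calibration (mean predicted probability vs observed event rate)
  and tier-wise mortality for the low/moderate/high score bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "roc_auc",
    "nagelkerke_r2",
    "hosmer_lemeshow",
    "decile_calibration",
    "tier_mortality",
    "EvaluationReport",
]


def roc_auc(scores, outcomes) -> float:
    """Mann-Whitney AUC: P(case score > control score) + 0.5 P(tie).

    Equivalent to the area under the empirical ROC curve; invariant under
    strictly monotone transformations of the scores.
    """
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    r = stats.rankdata(s)  # average ranks handle ties as half-wins
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Max-rescaled R²: Cox-Snell R² divided by its attainable maximum.

    R²_CS = 1 - exp(2 (L0 - L1)/n);  R²_max = 1 - exp(2 L0 / n).
    """
    if llf < llnull - 1e-8:
        raise ValueError("fitted log-likelihood below null; not a nested MLE")
    r2_cs = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    r2_max = 1.0 - np.exp(2.0 * llnull / n)
    return float(r2_cs / r2_max)


def _hl_groups(p: np.ndarray, groups: int) -> np.ndarray:
    """Equal-frequency group labels with tied probabilities kept together."""
    order = np.argsort(p, kind="stable")
    labels = np.empty(len(p), dtype=int)
    labels[order] = np.arange(len(p)) * groups // len(p)
    # rows sharing a predicted probability take the lowest label among them
    frame = pd.Series(labels).groupby(pd.Series(p)).transform("min")
    return frame.to_numpy()


def hosmer_lemeshow(probabilities, outcomes, groups: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow calibration chi-square.

    Rows are sorted by predicted probability and cut into ``groups``
    near-equal-size groups (ties kept together); the statistic sums
    (O - E)^2 / E over both outcome classes in every group, with
    df = (#groups) - 2.  Groups whose expected event count is zero are
    merged into a neighbour with a warning.

    Returns ``(statistic, df, p_value)``.
    """
    p = np.asarray(probabilities, float)
    y = np.asarray(outcomes, float)
    if groups < 3:
        raise ValueError("need at least 3 groups")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    labels = _hl_groups(p, groups)
    df_ = pd.DataFrame({"g": labels, "p": p, "y": y})
    agg = df_.groupby("g").agg(n=("y", "size"), obs=("y", "sum"), exp=("p", "sum"))
    # merge groups with a degenerate expected count into the next one up
    while len(agg) > 2 and ((agg["exp"] <= 0) | (agg["exp"] >= agg["n"])).any():
        warnings.warn("merging Hosmer-Lemeshow groups with empty expected cells")
        i = int(np.argmax((agg["exp"] <= 0) | (agg["exp"] >= agg["n"]).to_numpy()))
        j = i + 1 if i + 1 < len(agg) else i - 1
        agg.iloc[j] += agg.iloc[i]
        agg = agg.drop(agg.index[i])
    o1, e1, n_g = agg["obs"], agg["exp"], agg["n"]
    stat = float((((o1 - e1) ** 2 / e1) + (((n_g - o1) - (n_g - e1)) ** 2 / (n_g - e1))).sum())
    dof = len(agg) - 2
    pval = float(stats.chi2.sf(stat, dof))
    return stat, dof, pval


def decile_calibration(probabilities, outcomes, groups: int = 10) -> pd.DataFrame:
    """Per-decile mean predicted probability and observed event rate."""
    p = np.asarray(probabilities, float)
    y = np.asarray(outcomes, float)
    labels = _hl_groups(p, groups)
    out = (
        pd.DataFrame({"decile": labels, "p": p, "y": y})
        .groupby("decile")
        .agg(n=("y", "size"), mean_predicted=("p", "mean"), observed_rate=("y", "mean"))
        .reset_index()
    )
    out["decile"] = np.arange(1, len(out) + 1)
    return out


def tier_mortality(tiers, outcomes) -> pd.DataFrame:
    """Per-risk-tier patient count, deaths, and mortality rate.

    Tiers absent from the data are reported with n=0 and an undefined
    (NaN) rate.  Row order is low, moderate, high.
    """
    t = pd.Series(list(tiers), dtype="object")
    y = np.asarray(outcomes, float)
    rows = []
    for tier in ("low", "moderate", "high"):
        mask = (t == tier).to_numpy()
        n = int(mask.sum())
        deaths = int(y[mask].sum()) if n else 0
        rows.append(dict(tier=tier, n=n, deaths=deaths,
                         mortality=deaths / n if n else np.nan))
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Discrimination and calibration summary for one evaluated sample.

    ``model_*`` metrics come from the multivariable risk-factor model,
    ``score_*`` metrics from a univariable logistic refit on the integer
    risk score, mirroring the two validation models of the derivation
    procedure.
    """

    sample: str
    n: int
    events: int
    model_auc: float
    model_r2: float
    model_hl: tuple[float, int, float]
    score_auc: float
    score_r2: float
    score_hl: tuple[float, int, float]
    score_mean: float
    score_sd: float
    deciles: pd.DataFrame
    tiers: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, auc, r2, hl in (
            ("risk-factor model", self.model_auc, self.model_r2, self.model_hl),
            ("score model", self.score_auc, self.score_r2, self.score_hl),
        ):
            rows.append(dict(sample=self.sample, model=label, roc_auc=auc,
                             max_rescaled_r2=r2, hl_statistic=hl[0],
                             hl_df=hl[1], hl_p=hl[2]))
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        lines = [
            f"Sample: {self.sample}  (n={self.n}, events={self.events})",
            f"Score mean (SD): {self.score_mean:.1f} ({self.score_sd:.1f})",
            self.to_frame().drop(columns="sample").to_string(index=False),
            "Tier mortality:",
            self.tiers.to_string(index=False),
        ]
        return "\n".join(lines)
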