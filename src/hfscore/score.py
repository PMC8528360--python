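"""Integer-grid clinical risk score built from standardized coefficients.

Construction, given the standardized coefficients SC_i of the selected
risk factors:

1. initial weight  w_i = |SC_i| / sum_j |SC_j|  with sign(SC_i) kept
   separately (weights sum to 1);
2. rescale: w_i x 100, rounded to the nearest multiple of 5 with exact
   half-grid ties rounded toward zero (32.5 -> 30) — except age, which is
   rescaled by 10 only and floored to one decimal place (a per-year weight
   on a finer grid);
3. signed rescaled weights enter   score = base + sum_i sign_i w*_i x_i
   with base 100 so typical profiles stay positive (no clipping: strongly
   protective profiles may still fall below the base).

Risk tiers: low (< 300), moderate (300 to 800 inclusive), high (> 800).

``published_score_spec`` returns the published five-variable score for
one-year post-discharge mortality in hospitalized heart-failure patients:
100 + 1.5*age - 15*female + 20*LA-diameter - 20*BMI + 30*NYHA>3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable

__all__ = [
    "ScoreSpec",
    "initial_weights",
    "rescale_weight",
    "evaluate_score",
    "assign_tier",
    "build_score_spec",
    "published_score_spec",
]

_TIE_EPS = 1e-9  # half-grid tie detection under floating point


def initial_weights(scs: pd.Series | dict) -> tuple[pd.Series, pd.Series]:
    """Normalized magnitude weights and signs from standardized coefficients.

    weight_i = |SC_i| / sum|SC|; returns ``(weights, signs)`` with weights
    summing to 1 and signs in {-1, +1} (sign of SC, +1 for SC == 0).
    """
    sc = pd.Series(scs, dtype=float)
    total = sc.abs().sum()
    if total == 0:
        raise ValueError("all standardized coefficients are zero")
    weights = sc.abs() / total
    signs = pd.Series(np.where(sc < 0, -1.0, 1.0), index=sc.index)
    return weights, signs


def rescale_weight(weight: float, is_age: bool = False, ties: str = "toward-zero") -> float:
    """Map an initial weight onto the practical scoring grid.

    Non-age: multiply by 100 and round to the nearest multiple of 5; an
    exact half-grid tie (x5 remainder 2.5) rounds toward zero, the rule
    consistent with the reference 32.5 -> 30 mapping.  ``ties="up"``
    switches to round-half-up with a warning that it departs from that
    mapping.  Age: multiply by 10 and floor to one decimal place.
    """
    if is_age:
        return math.floor(weight * 10 * 10 + _TIE_EPS) / 10
    if ties not in ("toward-zero", "up"):
        raise ValueError(f"unknown tie rule {ties!r}")
    x = weight * 100 / 5
    frac = x - math.floor(x)
    if abs(frac - 0.5) <= _TIE_EPS and ties == "up":
        warnings.warn("half-grid tie rounded up; departs from the toward-zero "
                      "convention of the reference weight table")
        return 5.0 * math.ceil(x)
    if frac > 0.5 + _TIE_EPS:
        return 5.0 * math.ceil(x)
    return 5.0 * math.floor(x)


@dataclass
class ScoreSpec:
    """A fixed-weight clinical score: signed grid weights, base, tiers.

    ``weights`` maps variable name -> signed rescaled weight (score points
    per unit of the variable).  ``low_cut``/``high_cut`` bound the moderate
    tier: score < low_cut is low risk, score > high_cut is high risk, the
    closed interval between them is moderate.
    """

    weights: dict[str, float]
    base: float = 100.0
    low_cut: float = 300.0
    high_cut: float = 800.0
    initial: dict[str, float] = field(default_factory=dict)
    std_coefs: dict[str, float] = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return list(self.weights)

    def to_dict(self) -> dict:
        return {
            "base": self.base,
            "weights": {k: float(v) for k, v in self.weights.items()},
            "tiers": {"low_below": self.low_cut, "high_above": self.high_cut},
            "initial_weights": {k: float(v) for k, v in self.initial.items()},
            "std_coefs": {k: float(v) for k, v in self.std_coefs.items()},
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScoreSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            weights=dict(d["weights"]), base=float(d["base"]),
            low_cut=float(d["tiers"]["low_below"]),
            high_cut=float(d["tiers"]["high_above"]),
            initial=dict(d.get("initial_weights", {})),
            std_coefs=dict(d.get("std_coefs", {})),
        )

    def formula(self) -> str:
        terms = " ".join(
            f"{'+' if w >= 0 else '-'} {abs(w):g}*{name}"
            for name, w in self.weights.items()
        )
        return f"score = {self.base:g} {terms}"


def build_score_spec(scs: pd.Series | dict, age_variable: str = "age") -> ScoreSpec:
    """Build a ScoreSpec from standardized coefficients via the grid rules."""
    weights, signs = initial_weights(scs)
    rescaled = {
        name: float(signs[name] * rescale_weight(float(weights[name]),
                                                 is_age=(name == age_variable)))
        for name in weights.index
    }
    return ScoreSpec(
        weights=rescaled,
        initial={k: float(v) for k, v in weights.items()},
        std_coefs={k: float(v) for k, v in pd.Series(scs, dtype=float).items()},
    )


def published_score_spec() -> ScoreSpec:
    """The published five-variable one-year mortality score (fixed weights)."""
    return ScoreSpec(weights={
        "age": 1.5, "female": -15.0, "la_diam": 20.0, "bmi": -20.0,
        "nyha_gt3": 30.0,
    })


def evaluate_score(spec: ScoreSpec, patients: CohortTable | pd.DataFrame) -> np.ndarray:
    """Per-patient score: base + signed weighted sum of the score variables.

    Continuous output, no capping.  Raises if a score variable is missing
    a value (impute first) or absent from the table.
    """
    df = patients.df if isinstance(patients, CohortTable) else patients
    absent = [v for v in spec.variables if v not in df.columns]
    if absent:
        raise KeyError(f"score variable(s) absent: {absent}")
    X = df[spec.variables].to_numpy(float)
    if np.isnan(X).any():
        j = int(np.argwhere(np.isnan(X))[0, 1])
        raise ValueError(f"missing value in score variable {spec.variables[j]!r}; impute first")
    w = np.array([spec.weights[v] for v in spec.variables])
    return spec.base + X @ w


def assign_tier(spec: ScoreSpec, score) -> np.ndarray | str:
    """Risk tier for a score or array of scores: low / moderate / high."""
    s = np.asarray(score, float)
    out = np.where(s < spec.low_cut, "low",
                   np.where(s > spec.high_cut, "high", "moderate"))
    return out.item() if np.isscalar(score) or s.ndim == 0 else out
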