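import numpy as np
import pandas as pd
import pytest

from hfscore import CohortTable, GeneratorParams, VariableSpec, generate_cohort

# Published standardized coefficients of the five selected risk factors,
# used throughout as frozen reference inputs.
REFERENCE_SCS = {
    "age": 0.1864,
    "female": -0.1796,
    "la_diam": 0.2157,
    "bmi": -0.2254,
    "nyha_gt3": 0.3886,
}

REFERENCE_INITIAL_WEIGHTS = {
    "age": 0.155891946,
    "female": 0.150204901,
    "la_diam": 0.180396421,
    "bmi": 0.188508823,
    "nyha_gt3": 0.324997909,
}

REFERENCE_RESCALED = {
    "age": 1.5,
    "female": -15.0,
    "la_diam": 20.0,
    "bmi": -20.0,
    "nyha_gt3": 30.0,
}


def make_cohort(columns: dict, kinds: dict | None = None, outcome: str = "y") -> CohortTable:
    """Build a small cohort from raw columns; kinds default to binary for
    0/1-valued columns and continuous otherwise."""
    df = pd.DataFrame({k: pd.array(v, dtype=float) for k, v in columns.items()})
    kinds = kinds or {}
    schema = []
    for name in df.columns:
        vals = set(df[name].dropna().unique())
        kind = kinds.get(name, "binary" if vals <= {0.0, 1.0} else "continuous")
        role = "outcome" if name == outcome else "candidate"
        schema.append(VariableSpec(name, kind, role))
    return CohortTable(df, schema)


@pytest.fixture(scope="session")
def score_params() -> GeneratorParams:
    """Generator restricted to the five score covariates, no missingness."""
    return GeneratorParams(
        continuous={"age": (57.1, 12.4), "bmi": (25.1, 3.4), "la_diam": (39.9, 7.9)},
        prevalence={"female": 0.199, "nyha_gt3": 0.427},
        missing_rates={},
    )


@pytest.fixture(scope="session")
def big_cohort(score_params):
    """n=50,000 five-covariate cohort with a calibrated intercept; shared by
    the law-of-large-numbers, parameter-recovery and discrimination tests."""
    return generate_cohort(score_params, 50_000, seed=7)


@pytest.fixture(scope="session")
def full_cohort_5k():
    """n=5,000 cohort with the full covariate panel and missingness."""
    return generate_cohort(GeneratorParams(), 5_000, seed=42)
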