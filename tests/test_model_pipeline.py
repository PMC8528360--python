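import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from hfscore import (CohortTable, GeneratorParams, PipelineConfig, RiskScoreModel,
                     apply_published_score, generate_cohort, run_derivation_pipeline,
                     split_cohort)

from conftest import make_cohort


@pytest.fixture(scope="module")
def boosted_cohort():
    """n=4,000 with amplified true effects so a desk-scale derivation
    recovers the generating variables reliably."""
    params = GeneratorParams(
        log_odds={"age": np.log(1.05), "female": np.log(0.3),
                  "la_diam": np.log(1.08), "bmi": np.log(0.8),
                  "nyha_gt3": np.log(5.0)},
        target_rate=0.10,
    )
    return generate_cohort(params, 4_000, seed=21).cohort


@pytest.fixture(scope="module")
def fitted(boosted_cohort):
    deriv, _ = split_cohort(boosted_cohort, seed=1)
    return RiskScoreModel(deriv).fit(n_iter=120, threshold=0.9, seed=2)


class TestRiskScoreModel:
    def test_recovers_generating_variables_without_nulls(self, fitted):
        truth = {"age", "female", "bmi", "la_diam", "nyha_gt3"}
        assert truth <= set(fitted.selected) or len(truth & set(fitted.selected)) >= 4
        nulls = {"chd", "smoking", "alcohol", "hypertension", "diabetes",
                 "valve_surgery", "hf_history", "ami_history", "lvef_lt40",
                 "heart_rate"}
        assert not nulls & set(fitted.selected)

    def test_score_spec_weights_on_grid(self, fitted):
        for name, w in fitted.score_spec.weights.items():
            if name == "age":
                assert w == pytest.approx(round(w, 1))
            else:
                assert w % 5 == 0

    def test_summary_mentions_selected_variables(self, fitted):
        s = fitted.summary()
        for name in fitted.selected:
            assert name in s
        assert "score = 100" in s

    def test_scored_output_has_score_and_tier(self, fitted, boosted_cohort):
        _, test = split_cohort(boosted_cohort, seed=1)
        scored = fitted.score(test)
        assert {"score", "tier"} <= set(scored.columns)
        assert scored["tier"].isin(["low", "moderate", "high"]).all()

    def test_evaluation_report_is_coherent(self, fitted, boosted_cohort):
        _, test = split_cohort(boosted_cohort, seed=1)
        rep = fitted.evaluate(test, sample="test")
        assert 0.5 < rep.model_auc <= 1
        assert 0 <= rep.model_r2 <= 1
        assert rep.tiers.n.sum() == test.n
        assert rep.score_sd > 0
        # the multivariable model should discriminate at least as well as
        # the coarsened integer score
        assert rep.model_auc >= rep.score_auc - 0.02

    def test_invalid_threshold_rejected_before_compute(self, boosted_cohort):
        with pytest.raises(ValueError, match="threshold"):
            RiskScoreModel(boosted_cohort).fit(n_iter=10, threshold=1.01)

    def test_from_dataframe_constructor(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "age": rng.normal(57, 12, 300),
            "nyha_gt3": rng.integers(0, 2, 300).astype(float),
            "death_1y": rng.integers(0, 2, 300).astype(float),
        })
        model = RiskScoreModel.from_dataframe(df)
        assert model.cohort.n == 300
        assert model.cohort.outcome == "death_1y"


class TestApplyPublishedScore:
    def test_zero_profile_scores_base_and_low_tier(self):
        t = make_cohort(
            {"age": [0.0], "female": [0.0], "la_diam": [0.0], "bmi": [0.0],
             "nyha_gt3": [0.0], "y": [0.0]},
            kinds={"age": "continuous", "la_diam": "continuous", "bmi": "continuous"},
            outcome="y")
        out = apply_published_score(t)
        assert out.loc[0, "score"] == 100.0
        assert out.loc[0, "tier"] == "low"

    def test_reference_profile(self):
        t = make_cohort(
            {"age": [57.0], "female": [0.0], "la_diam": [40.0], "bmi": [25.1],
             "nyha_gt3": [0.0], "y": [0.0]},
            kinds={"age": "continuous", "la_diam": "continuous", "bmi": "continuous"},
            outcome="y")
        out = apply_published_score(t)
        assert out.loc[0, "score"] == pytest.approx(483.5)
        assert out.loc[0, "tier"] == "moderate"

    def test_population_mean_score_near_published_value(self, big_cohort):
        out = apply_published_score(big_cohort.cohort)
        assert out["score"].mean() == pytest.approx(492.5, abs=5)

    def test_imputes_missing_continuous_score_variables(self, full_cohort_5k):
        out = apply_published_score(full_cohort_5k.cohort)
        assert out["score"].notna().all()


class TestPipeline:
    def _config(self, tmp_path, name, **kw):
        return PipelineConfig(
            output_dir=str(tmp_path / name), n_patients=1_200,
            seed_generate=5, seed_split=6, seed_bootstrap=7,
            n_iter=60, target_rate=0.12, **kw)

    def test_end_to_end_artifacts_exist(self, tmp_path):
        manifest = run_derivation_pipeline(self._config(tmp_path, "run"))
        for key in ("cohort", "baseline_summary", "screening", "selection",
                    "risk_factors", "score_spec", "scored_derivation",
                    "scored_test", "performance", "tier_mortality", "manifest"):
            assert key in manifest.outputs, key
            assert (tmp_path / "run").joinpath(
                manifest.outputs[key].split("/")[-1]).exists()
        stages = [s["stage"] for s in manifest.stages]
        assert stages == ["input", "split", "baseline", "derive", "score", "evaluate"]

    def test_rerun_with_same_config_is_byte_identical(self, tmp_path):
        run_derivation_pipeline(self._config(tmp_path, "a"))
        run_derivation_pipeline(self._config(tmp_path, "b"))
        for fname in ("cohort.csv", "screening.csv", "selection.csv",
                      "risk_factors.csv", "scored_test.csv", "performance.csv"):
            assert (tmp_path / "a" / fname).read_bytes() == \
                   (tmp_path / "b" / fname).read_bytes(), fname

    def test_invalid_config_fails_before_any_compute(self, tmp_path):
        cfg = self._config(tmp_path, "bad")
        cfg.threshold = 1.01
        with pytest.raises(ValueError, match="threshold"):
            run_derivation_pipeline(cfg)
        assert not (tmp_path / "bad").exists()

    def test_config_requires_exactly_one_input(self, tmp_path):
        with pytest.raises(ValueError, match="exactly one"):
            PipelineConfig(output_dir=str(tmp_path)).validate()

    def test_manifest_round_trips_config(self, tmp_path):
        manifest = run_derivation_pipeline(self._config(tmp_path, "rt"))
        with open(tmp_path / "rt" / "manifest.json") as fh:
            loaded = json.load(fh)
        cfg = {k: v for k, v in loaded["config"].items() if k != "forced"}
        rebuilt = PipelineConfig(**cfg, forced=tuple(loaded["config"]["forced"]))
        rebuilt.output_dir = str(tmp_path / "rt2")
        run_derivation_pipeline(rebuilt)
        assert (tmp_path / "rt2" / "risk_factors.csv").read_bytes() == \
               (tmp_path / "rt" / "risk_factors.csv").read_bytes()
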