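import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfscore import (assign_tier, build_score_spec, evaluate_score, initial_weights,
                     published_score_spec, rescale_weight)
from hfscore.score import ScoreSpec

from conftest import (REFERENCE_INITIAL_WEIGHTS, REFERENCE_RESCALED, REFERENCE_SCS,
                      make_cohort)


class TestInitialWeights:
    def test_reference_scs_reproduce_printed_weights_to_nine_decimals(self):
        weights, signs = initial_weights(REFERENCE_SCS)
        for name, expected in REFERENCE_INITIAL_WEIGHTS.items():
            assert abs(weights[name] - expected) < 1e-9
        assert signs.to_dict() == {"age": 1, "female": -1, "la_diam": 1,
                                   "bmi": -1, "nyha_gt3": 1}

    def test_single_sc_normalizes_to_one(self):
        w, s = initial_weights({"only": -0.37})
        assert w["only"] == 1.0 and s["only"] == -1.0

    def test_symmetric_pair(self):
        w, s = initial_weights({"a": 1.0, "b": -1.0})
        assert w.tolist() == [0.5, 0.5]
        assert s.tolist() == [1.0, -1.0]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            initial_weights({"a": 0.0, "b": 0.0})

    @given(st.lists(st.floats(min_value=-5, max_value=5).filter(lambda v: abs(v) > 1e-6),
                    min_size=1, max_size=8))
    @settings(derandomize=True, max_examples=100)
    def test_weights_always_sum_to_one(self, scs):
        w, _ = initial_weights({f"v{i}": v for i, v in enumerate(scs)})
        assert abs(w.sum() - 1.0) < 1e-12


class TestRescaleWeight:
    @pytest.mark.parametrize("name", list(REFERENCE_INITIAL_WEIGHTS))
    def test_reference_weights_map_to_printed_grid(self, name):
        got = rescale_weight(REFERENCE_INITIAL_WEIGHTS[name], is_age=(name == "age"))
        assert got == abs(REFERENCE_RESCALED[name])

    def test_exact_half_grid_tie_rounds_toward_zero(self):
        assert rescale_weight(0.325) == 30.0

    def test_half_up_tie_rule_opt_in_with_warning(self):
        with pytest.warns(UserWarning, match="departs"):
            assert rescale_weight(0.325, ties="up") == 35.0
        with pytest.raises(ValueError):
            rescale_weight(0.3, ties="bogus")

    def test_simple_examples(self):
        assert rescale_weight(0.18) == 20.0   # 18.0 is nearer 20 than 15
        assert rescale_weight(0.17) == 15.0
        assert rescale_weight(0.0) == 0.0

    def test_age_rule_floors_to_one_decimal(self):
        assert rescale_weight(0.155891946, is_age=True) == 1.5
        assert rescale_weight(0.1999, is_age=True) == 1.9
        assert rescale_weight(0.15, is_age=True) == 1.5

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    @settings(derandomize=True, max_examples=200)
    def test_monotone_and_on_grid(self, w1, w2):
        lo, hi = sorted((w1, w2))
        r_lo, r_hi = rescale_weight(lo), rescale_weight(hi)
        assert r_lo <= r_hi
        assert r_lo % 5 == 0 and r_hi % 5 == 0

    @given(st.floats(min_value=0, max_value=1))
    @settings(derandomize=True, max_examples=200)
    def test_age_output_has_one_decimal(self, w):
        r = rescale_weight(w, is_age=True)
        assert r == pytest.approx(round(r, 1))
        assert r <= w * 10 + 1e-9  # floored, never rounded up


class TestScoreSpecConstruction:
    def test_reference_scs_rebuild_printed_weight_vector(self):
        spec = build_score_spec(REFERENCE_SCS)
        assert spec.weights == REFERENCE_RESCALED
        assert spec.base == 100.0

    def test_yaml_round_trip(self, tmp_path):
        spec = build_score_spec(REFERENCE_SCS)
        p = tmp_path / "spec.yaml"
        spec.to_yaml(p)
        back = ScoreSpec.from_yaml(p)
        assert back.weights == spec.weights
        assert back.base == spec.base
        assert (back.low_cut, back.high_cut) == (spec.low_cut, spec.high_cut)

    def test_formula_string_lists_signed_terms(self):
        f = published_score_spec().formula()
        assert f.startswith("score = 100")
        assert "- 15*female" in f and "+ 30*nyha_gt3" in f


class TestEvaluateScore:
    def _patients(self, rows):
        cols = {k: [r[k] for r in rows] for k in rows[0]}
        cols["y"] = [0.0] * len(rows)
        return make_cohort(cols, kinds={"age": "continuous", "bmi": "continuous",
                                        "la_diam": "continuous"})

    def test_all_zero_covariates_give_base_offset(self):
        t = self._patients([dict(age=0.0, female=0.0, la_diam=0.0, bmi=0.0,
                                 nyha_gt3=0.0)])
        s = evaluate_score(published_score_spec(), t)
        assert s[0] == 100.0

    def test_reference_profile_arithmetic(self):
        # 100 + 1.5*57 + 20*40 - 20*25.1 = 483.5 (male, NYHA<=3)
        t = self._patients([dict(age=57.0, female=0.0, la_diam=40.0, bmi=25.1,
                                 nyha_gt3=0.0)])
        s = evaluate_score(published_score_spec(), t)
        assert s[0] == pytest.approx(483.5, abs=1e-9)

    def test_worked_profile_follows_formula(self):
        # 45y female, LA 30 mm, BMI 23, NYHA<=3:
        # 100 + 67.5 - 15 + 600 - 460 + 0 = 292.5 by direct arithmetic
        t = self._patients([dict(age=45.0, female=1.0, la_diam=30.0, bmi=23.0,
                                 nyha_gt3=0.0)])
        s = evaluate_score(published_score_spec(), t)
        assert s[0] == pytest.approx(292.5, abs=1e-9)

    def test_affine_in_each_covariate_and_swap_symmetry(self):
        spec = published_score_spec()
        a = dict(age=50.0, female=1.0, la_diam=35.0, bmi=22.0, nyha_gt3=1.0)
        b = dict(age=70.0, female=0.0, la_diam=45.0, bmi=30.0, nyha_gt3=0.0)
        s = evaluate_score(spec, self._patients([a, b]))
        swapped = evaluate_score(spec, self._patients([b, a]))
        assert s[0] == swapped[1] and s[1] == swapped[0]
        bumped = dict(a, la_diam=a["la_diam"] + 1)
        s2 = evaluate_score(spec, self._patients([bumped]))
        assert s2[0] - s[0] == pytest.approx(20.0)

    def test_missing_score_variable_rejected(self):
        t = self._patients([dict(age=50.0, female=0.0, la_diam=np.nan, bmi=22.0,
                                 nyha_gt3=0.0)])
        with pytest.raises(ValueError, match="impute"):
            evaluate_score(published_score_spec(), t)

    def test_absent_column_rejected(self):
        t = make_cohort({"age": [50.0], "y": [0.0]}, kinds={"age": "continuous"})
        with pytest.raises(KeyError):
            evaluate_score(published_score_spec(), t)


class TestAssignTier:
    @pytest.mark.parametrize("score,tier", [
        (299.99, "low"), (300.0, "moderate"), (500.0, "moderate"),
        (800.0, "moderate"), (800.01, "high"), (89.9, "low"), (1195.63, "high"),
    ])
    def test_boundaries(self, score, tier):
        assert assign_tier(published_score_spec(), score) == tier

    def test_vectorized_assignment_partitions(self):
        spec = published_score_spec()
        s = np.linspace(0, 1200, 1001)
        tiers = assign_tier(spec, s)
        assert set(tiers) == {"low", "moderate", "high"}
        assert ((tiers == "low") | (tiers == "moderate") | (tiers == "high")).all()
        assert (s[tiers == "low"] < 300).all()
        assert (s[tiers == "high"] > 800).all()
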