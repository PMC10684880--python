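"""Nutrition scoring: profile aggregation, HENI, Food Compass ladders."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sustdiet as sd
from sustdiet.errors import (
    AllZeroError,
    KeyMismatchError,
    MissingFoodError,
    NonMonotoneCutpointsError,
    ZeroEnergyError,
)
from sustdiet.nutrition_scores import (
    DOMAINS,
    RISKS,
    FcsAttribute,
    FcsConfig,
    raw_fcs,
    scale_fcs,
    score_attributes,
)


def _factor_table(**overrides):
    factor = {r: 0.0 for r in RISKS}
    factor["seafood"] = -81.0
    factor.update(overrides)
    return sd.HeniFactorTable(factor=factor)


def _risk_vector(**values):
    d = {r: 0.0 for r in RISKS}
    d.update(values)
    return sd.RiskIntakeVector(d=d)


class TestAggregateProfile:
    def test_single_food_rescales_to_100_kcal(self):
        foods = pd.DataFrame(
            [dict(food_id="veg", group="vegetables", kcal_per_100g=50.0, fiber=2.0)]
        )
        c = sd.DietComposition({"vegetables": 1.0})
        profile, risks = sd.aggregate_profile(c, foods)
        # 2 g fiber per 100 g at 50 kcal/100 g -> 4 g fiber per 100 kcal
        assert profile.amounts["fiber"] == pytest.approx(4.0)
        assert risks.d["fiber"] == pytest.approx(4.0)
        assert profile.total_kcal_per_day == pytest.approx(1800 * 0.5)

    def test_mixture_matches_brute_force_per_ingredient_sum(self):
        foods = pd.DataFrame(
            [
                dict(food_id="leg", group="legumes", kcal_per_100g=340.0, fiber=15.0, protein=22.0),
                dict(food_id="fru", group="fruits", kcal_per_100g=55.0, fiber=2.2, protein=0.8),
            ]
        )
        c = sd.DietComposition({"legumes": 0.3, "fruits": 0.7})
        profile, _ = sd.aggregate_profile(c, foods)
        # explicit loop oracle
        grams = {"legumes": 0.3 * 1800, "fruits": 0.7 * 1800}
        kcal = grams["legumes"] * 3.40 + grams["fruits"] * 0.55
        for col, per100g in [("fiber", (15.0, 2.2)), ("protein", (22.0, 0.8))]:
            per_day = grams["legumes"] * per100g[0] / 100 + grams["fruits"] * per100g[1] / 100
            assert profile.amounts[col] == pytest.approx(per_day * 100 / kcal)

    def test_zero_energy_diet_rejected(self):
        foods = pd.DataFrame(
            [dict(food_id="water", group="sugar-sweetened beverages", kcal_per_100g=0.0)]
        )
        c = sd.DietComposition({"sugar-sweetened beverages": 1.0})
        with pytest.raises(ZeroEnergyError) as exc:
            sd.aggregate_profile(c, foods)
        assert exc.value.code == "ZERO_ENERGY_DIET"

    def test_unrepresented_group_rejected(self):
        foods = pd.DataFrame(
            [dict(food_id="leg", group="legumes", kcal_per_100g=340.0)]
        )
        c = sd.DietComposition({"legumes": 0.5, "eggs": 0.5})
        with pytest.raises(MissingFoodError):
            sd.aggregate_profile(c, foods)

    def test_zero_share_groups_enter_profile_as_zero_grams(self):
        foods = pd.DataFrame(
            [dict(food_id="leg", group="legumes", kcal_per_100g=340.0)]
        )
        c = sd.DietComposition({"legumes": 1.0, "red meat": 0.0})
        profile, risks = sd.aggregate_profile(c, foods)
        assert profile.amounts["red meat"] == 0.0
        assert risks.d["red meats"] == 0.0


class TestHeniScore:
    def test_zero_intake_scores_zero(self):
        assert sd.heni_score(_risk_vector(), _factor_table()) == 0.0

    def test_red_meat_unit_intake(self):
        t = _factor_table(**{"red meats": 0.0990})
        got = sd.heni_score(_risk_vector(**{"red meats": 1.0}), t)
        assert got == pytest.approx(-0.53 * 0.0990)
        assert got == pytest.approx(-0.052, abs=5e-4)

    def test_seafood_unit_intake_yields_positive_minutes(self, fixtures):
        got = sd.heni_score(_risk_vector(seafood=1.0), fixtures.table2)
        assert got == pytest.approx(42.93)

    def test_key_mismatch_rejected(self):
        with pytest.raises(KeyMismatchError):
            sd.RiskIntakeVector(d={"seafood": 1.0})

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        intakes=st.lists(
            st.floats(min_value=0, max_value=50), min_size=15, max_size=15
        ),
        alpha=st.floats(min_value=0, max_value=10),
    )
    def test_linearity_and_additivity(self, fixtures, intakes, alpha):
        t = fixtures.table2
        d = _risk_vector(**dict(zip(RISKS, intakes)))
        scaled = _risk_vector(**{r: alpha * v for r, v in d.d.items()})
        assert sd.heni_score(scaled, t) == pytest.approx(
            alpha * sd.heni_score(d, t), rel=1e-9, abs=1e-9
        )
        # additivity over disjoint halves
        half1 = _risk_vector(**{r: d.d[r] for r in RISKS[:7]})
        half2 = _risk_vector(**{r: d.d[r] for r in RISKS[7:]})
        assert sd.heni_score(half1, t) + sd.heni_score(half2, t) == pytest.approx(
            sd.heni_score(d, t), rel=1e-9, abs=1e-9
        )

    def test_processed_meat_to_legume_swap_gains_half_minute(self, fixtures):
        """1 g processed meat -> 1 g legumes per 100 kcal gains 0.578 min."""
        base = _risk_vector(**{"processed meats": 1.0})
        swapped = _risk_vector(legumes=1.0)
        delta = sd.heni_score(swapped, fixtures.table2) - sd.heni_score(
            base, fixtures.table2
        )
        assert delta == pytest.approx(-0.53 * (-0.23 - 0.86), abs=1e-9)
        assert delta == pytest.approx(0.578, abs=1e-3)
        assert delta > 0


class TestRiskContributions:
    def test_single_component_is_100_percent(self, fixtures):
        contrib = sd.risk_contributions(_risk_vector(fruits=3.0), fixtures.table2)
        assert contrib["fruits"] == pytest.approx(100.0)

    def test_hand_computed_split(self):
        t = _factor_table(legumes=-1.0, fruits=2.0, sodium=-2.0)
        d = _risk_vector(legumes=1.0, fruits=1.0, sodium=1.0)
        contrib = sd.risk_contributions(d, t)
        assert contrib["legumes"] == pytest.approx(20.0)
        assert contrib["fruits"] == pytest.approx(40.0)
        assert contrib["sodium"] == pytest.approx(40.0)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=0.01)

    def test_all_zero_rejected(self, fixtures):
        with pytest.raises(AllZeroError):
            sd.risk_contributions(_risk_vector(), fixtures.table2)


class TestAttributeLadders:
    def test_hand_ladder_lookup(self):
        attr = FcsAttribute(
            "fiber", "protein & fiber", "beneficial", (1.0, 2.0), (0, 5, 10)
        )
        assert attr.score(0.5) == 0
        assert attr.score(1.5) == 5
        assert attr.score(3.0) == 10

    def test_tie_goes_to_the_healthier_side(self):
        beneficial = FcsAttribute(
            "fiber", "protein & fiber", "beneficial", (1.0, 2.0), (0, 5, 10)
        )
        harmful = FcsAttribute(
            "sugar_carb_ratio", "nutrient ratios", "harmful", (1.0, 2.0), (10, 5, 0)
        )
        assert beneficial.score(2.0) == 10  # upper rung
        assert harmful.score(2.0) == 5  # lower rung (healthier for harmful)

    def test_non_monotone_scores_rejected(self):
        with pytest.raises(NonMonotoneCutpointsError):
            FcsAttribute("x", "vitamins", "beneficial", (1.0, 2.0), (0, 5, 3))

    def test_missing_attribute_scores_zero(self, fcs_config):
        profile = sd.NutrientProfile(amounts={}, total_kcal_per_day=2000.0)
        scores = score_attributes(profile, fcs_config)
        assert set(scores.values()) == {0.0}


def _tiny_config():
    attrs = [
        FcsAttribute("a_ratio", "nutrient ratios", "beneficial", (1.0,), (0, 1)),
        FcsAttribute("a_vit", "vitamins", "beneficial", (1.0,), (0, 1)),
        FcsAttribute("a_min", "minerals", "beneficial", (1.0,), (0, 1)),
        FcsAttribute("a_add", "additives", "harmful", (1.0,), (1, 0)),
        FcsAttribute("a_lip", "specific lipids", "beneficial", (1.0,), (0, 1)),
        FcsAttribute("a_pf", "protein & fiber", "beneficial", (1.0,), (0, 1)),
        FcsAttribute("ing1", "food ingredients", "beneficial", (1.0,), (0, 5)),
        FcsAttribute("ing2", "food ingredients", "beneficial", (1.0,), (0, 5)),
    ]
    return FcsConfig(attributes=tuple(attrs))


class TestRawFcs:
    def test_all_zero_scores_give_zero(self):
        cfg = _tiny_config()
        raw, _ = raw_fcs({a.name: 0.0 for a in cfg.attributes}, cfg)
        assert raw == 0.0

    def test_domain_mean_plus_ingredient_sum(self):
        cfg = _tiny_config()
        scores = {a.name: 1.0 for a in cfg.attributes}
        scores["ing1"], scores["ing2"] = 2.0, 3.0
        raw, domain_scores = raw_fcs(scores, cfg)
        # six non-ingredient domains at 1 each -> mean 1; ingredients sum 5
        assert raw == pytest.approx(6.0)
        assert domain_scores["food ingredients"] == pytest.approx(2.5)

    def test_single_ingredient_attribute_passes_through(self):
        cfg = _tiny_config()
        scores = {a.name: 0.0 for a in cfg.attributes}
        scores["ing1"] = 4.0
        raw, _ = raw_fcs(scores, cfg)
        assert raw == pytest.approx(4.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=10), min_size=8, max_size=8))
    def test_matches_explicit_loop_oracle(self, values):
        cfg = _tiny_config()
        scores = dict(zip((a.name for a in cfg.attributes), map(float, values)))
        raw, _ = raw_fcs(scores, cfg)
        # brute force: explicit loops over domains and attributes
        by_domain = {}
        for a in cfg.attributes:
            by_domain.setdefault(a.domain, []).append(scores[a.name])
        non_ing = [
            sum(v) / len(v) for d, v in by_domain.items() if d != "food ingredients"
        ]
        expected = sum(non_ing) / len(non_ing) + sum(by_domain["food ingredients"])
        assert raw == pytest.approx(expected, abs=1e-12)


class TestScaleFcs:
    def test_fixed_points(self):
        assert scale_fcs(26.1) == pytest.approx(100.0, abs=1e-12)
        assert scale_fcs(-10.6) == pytest.approx(1.0, abs=1e-12)

    def test_published_current_diet_raw_score_maps_to_65_46(self):
        # invert the affine map at scaled 65.46, then confirm forward
        raw = 26.1 - 36.7 * (100 - 65.46) / 99
        assert scale_fcs(raw) == pytest.approx(65.46, abs=1e-9)
        assert raw == pytest.approx(13.296, abs=1e-3)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(min_value=-10.6, max_value=26.1))
    def test_affine_and_invertible(self, raw):
        scaled = scale_fcs(raw)
        # strictly increasing affine map, inverse recovers raw
        assert scale_fcs(raw + 0.1) > scaled
        recovered = 26.1 - (100 - scaled) * 36.7 / 99
        assert recovered == pytest.approx(raw, abs=1e-9)

    def test_out_of_range_raw_warns_but_does_not_clamp(self):
        with pytest.warns(UserWarning):
            assert scale_fcs(100.0) > 100.0


class TestShippedConfig:
    def test_structure_is_the_adapted_46_attribute_7_domain_layout(self, fcs_config):
        assert len(fcs_config.attributes) == 46
        assert fcs_config.domains == DOMAINS
        names = {a.name for a in fcs_config.attributes}
        assert {"red meat", "processed meat"} <= names
        assert "iodine" not in names
        by_domain = {}
        for a in fcs_config.attributes:
            by_domain[a.domain] = by_domain.get(a.domain, 0) + 1
        assert by_domain["food ingredients"] == 13
        assert by_domain["vitamins"] == 12
        assert by_domain["minerals"] == 9
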