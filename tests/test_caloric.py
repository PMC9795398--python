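"""Density estimation, weighted state scores, and the region z comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from foodenv.availability import compute_availability
from foodenv.caloric import (
    DensityRegistry,
    build_density_registry,
    business_density,
    category_density,
    compare_regions_ztest,
    dish_density,
    is_gram_unit,
    score_obesity_correlation,
    state_scores,
    state_weighted_score,
)
from foodenv.records import (
    BusinessRecord,
    NutritionRecord,
    ObesityTable,
    PopularDishTable,
)
from foodenv.synthetic import generate_world

from conftest import tiny_config


class TestGramUnit:
    @pytest.mark.parametrize("unit", ["g", "gr", "gram", "grams", " Grams ", "G"])
    def test_gram_variants_accepted(self, unit):
        assert is_gram_unit(unit)

    @pytest.mark.parametrize(
        "unit", ["oz", "slice", "piece", "package", "breast", "", "kg", "mg"]
    )
    def test_non_gram_units_rejected(self, unit):
        assert not is_gram_unit(unit)


class TestDishDensity:
    def test_single_gram_record(self):
        recs = [NutritionRecord("pizza", 230.0, 100.0, "g")]
        assert dish_density(recs) == pytest.approx(2.30)

    def test_mean_over_gram_records_ignores_others(self):
        recs = [
            NutritionRecord("pizza", 200.0, 100.0, "g"),
            NutritionRecord("pizza", 300.0, 100.0, "grams"),
            NutritionRecord("pizza", 500.0, 1.0, "piece"),
        ]
        assert dish_density(recs) == pytest.approx(2.50)

    def test_no_gram_records_gives_none(self):
        recs = [NutritionRecord("pizza", 500.0, 2.0, "oz")]
        assert dish_density(recs) is None

    def test_optional_density_cap_drops_outliers(self):
        recs = [
            NutritionRecord("pizza", 200.0, 100.0, "g"),
            NutritionRecord("pizza", 5000.0, 1.0, "g"),
        ]
        assert dish_density(recs) == pytest.approx(2501.0)  # raw by default
        assert dish_density(recs, max_density=100.0) == pytest.approx(2.0)


class TestCategoryDensity:
    def test_mean_over_dishes(self):
        assert category_density(["a", "b"], {"a": 2.0, "b": 4.0}) == pytest.approx(3.0)

    def test_single_dish(self):
        assert category_density(["a"], {"a": 1.7}) == pytest.approx(1.7)

    def test_duplicate_dish_counted_once(self):
        assert category_density(
            ["a", "a", "b"], {"a": 2.0, "b": 4.0}
        ) == pytest.approx(3.0)

    def test_no_dish_with_density_gives_none(self):
        assert category_density(["a"], {}) is None


class TestDensityRegistry:
    def test_registry_from_records(self, sample_nutrition):
        popular = PopularDishTable(
            {"Pizza": ["margherita pizza"], "Salad": ["caesar salad"],
             "Sandwiches": ["chicken sandwich"]}
        )
        reg = build_density_registry(sample_nutrition, popular)
        assert reg.dish_density_of("margherita pizza") == pytest.approx(2.65)
        assert reg.dish.loc["margherita pizza", "n_gram_records"] == 2
        # piece-only dish has no density; its category is excluded
        assert reg.dish_density_of("chicken sandwich") is None
        assert "Sandwiches" not in reg.category.index
        assert reg.category_density_of("Salad") == pytest.approx(0.9)


class TestStateWeightedScore:
    def test_constant_density_yields_that_density(self):
        reg = DensityRegistry(
            category=pd.DataFrame({"density": [3.0, 3.0]}, index=["a", "b"])
        )
        row = pd.Series({"a": 0.7, "b": 0.1})
        assert state_weighted_score(row, reg) == pytest.approx(3.0)

    def test_hand_weighted_mean(self):
        reg = DensityRegistry(
            category=pd.DataFrame({"density": [2.0, 6.0]}, index=["a", "b"])
        )
        row = pd.Series({"a": 0.5, "b": 0.25})
        assert state_weighted_score(row, reg) == pytest.approx(10.0 / 3.0)

    def test_scale_invariance_of_weights(self):
        reg = DensityRegistry(
            category=pd.DataFrame({"density": [2.0, 6.0, 1.0]}, index=list("abc"))
        )
        row = pd.Series({"a": 0.5, "b": 0.25, "c": 0.05})
        doubled = 2 * row
        assert state_weighted_score(row, reg) == pytest.approx(
            state_weighted_score(doubled, reg)
        )

    def test_categories_without_density_dropped_from_both_sides(self):
        reg = DensityRegistry(
            category=pd.DataFrame({"density": [2.0]}, index=["a"])
        )
        row = pd.Series({"a": 0.5, "mystery": 0.9})
        assert state_weighted_score(row, reg) == pytest.approx(2.0)

    def test_empty_intersection_names_region(self):
        reg = DensityRegistry()
        with pytest.raises(ValueError, match="XX"):
            state_weighted_score(pd.Series({"a": 0.5}), reg, region="XX")

    @given(
        st.lists(
            st.tuples(st.floats(0.01, 1.0), st.floats(0.5, 10.0)),
            min_size=1, max_size=6,
        )
    )
    def test_score_bounded_by_contributing_densities(self, pairs):
        labels = [f"c{i}" for i in range(len(pairs))]
        avail = pd.Series({l: a for l, (a, _) in zip(labels, pairs)})
        reg = DensityRegistry(
            category=pd.DataFrame(
                {"density": [d for _, d in pairs]}, index=labels
            )
        )
        score = state_weighted_score(avail, reg)
        dens = [d for _, d in pairs]
        assert min(dens) - 1e-9 <= score <= max(dens) + 1e-9


class TestNoiselessRecovery:
    def test_planted_densities_and_scores_recovered_exactly(self):
        cfg = tiny_config(seed=3, calorie_noise_cv=0.0, non_gram_fraction=0.0)
        world = generate_world(cfg)
        reg = build_density_registry(world.nutrition, world.popular_dishes)
        truth = {c.label: c.true_density for c in cfg.categories}
        for dish in reg.dish.index:
            cat = next(c for c in truth if dish.startswith(c.lower()))
            assert reg.dish.loc[dish, "density"] == pytest.approx(
                truth[cat], abs=1e-12
            )
        for cat in reg.category.index:
            assert reg.category_density_of(cat) == pytest.approx(
                truth[cat], abs=1e-12
            )
        # region scores are availability-weighted means of exact densities,
        # hence bracketed by the planted range and close to mix-weighted truth
        table = compute_availability(world.businesses)
        scores = state_scores(table, reg)
        for region, score in scores.scores.items():
            assert min(truth.values()) <= score <= max(truth.values())


class TestScoreObesityCorrelation:
    def test_exact_linear_relation(self):
        from foodenv.caloric import StateScoreTable

        scores = StateScoreTable({"A": 1.0, "B": 2.0, "C": 3.0})
        obesity = ObesityTable({"A": 20.0, "B": 25.0, "C": 30.0})
        r, p = score_obesity_correlation(scores, obesity)
        assert r == pytest.approx(1.0)

    def test_hand_computed_r_with_sign_flip(self):
        from foodenv.caloric import StateScoreTable

        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 6.0, -8.0])
        scores = StateScoreTable(dict(zip("ABCD", x)))
        obesity = ObesityTable(dict(zip("ABCD", y + 20)))
        r, _ = score_obesity_correlation(scores, obesity)
        xc, yc = x - x.mean(), y - y.mean()
        expect = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(expect, abs=1e-12)

    def test_affine_invariance(self):
        from foodenv.caloric import StateScoreTable

        base = {"A": 1.0, "B": 2.5, "C": 2.0, "D": 4.0}
        obesity = ObesityTable({"A": 20.0, "B": 31.0, "C": 25.0, "D": 39.0})
        r1, _ = score_obesity_correlation(StateScoreTable(base), obesity)
        shifted = {k: 3.0 * v + 7.0 for k, v in base.items()}
        r2, _ = score_obesity_correlation(StateScoreTable(shifted), obesity)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_raises(self):
        from foodenv.caloric import StateScoreTable

        scores = StateScoreTable({"A": 1.0, "B": 1.0, "C": 1.0})
        obesity = ObesityTable({"A": 20.0, "B": 25.0, "C": 30.0})
        with pytest.raises(ValueError):
            score_obesity_correlation(scores, obesity)

    def test_too_few_regions_raises(self):
        from foodenv.caloric import StateScoreTable

        with pytest.raises(ValueError):
            score_obesity_correlation(
                StateScoreTable({"A": 1.0, "B": 2.0}),
                ObesityTable({"A": 20.0, "B": 25.0}),
            )


class TestCompareRegionsZTest:
    def _registry(self):
        return DensityRegistry(
            category=pd.DataFrame({"density": [2.0, 3.0]}, index=["lo", "hi"])
        )

    def _biz(self, i, region, cats):
        return BusinessRecord(f"b{i}", region, tuple(cats), 1, 4.0, 1)

    def test_identical_samples_give_zero(self):
        reg = self._registry()
        biz = [self._biz(i, r, ["lo"]) for r in ("CO", "MS") for i in range(3)]
        z, p = compare_regions_ztest("CO", "MS", biz, reg)
        assert z == 0.0 and p == 1.0

    def test_separated_samples_give_large_z_with_sign(self):
        reg = self._registry()
        biz = [self._biz(i, "MS", ["hi"]) for i in range(4)] + [
            self._biz(10 + i, "CO", ["lo"]) for i in range(4)
        ]
        # zero within-group variance: separation is infinite in the limit,
        # so perturb one business per region via mixed categories
        biz[0] = self._biz(0, "MS", ["hi", "lo"])
        biz[4] = self._biz(10, "CO", ["lo", "hi"])
        z, _ = compare_regions_ztest("MS", "CO", biz, reg)
        assert z > 3
        z_rev, _ = compare_regions_ztest("CO", "MS", biz, reg)
        assert z_rev == pytest.approx(-z)

    def test_matches_unpooled_formula_on_fixture(self):
        rng = np.random.default_rng(5)
        reg = DensityRegistry(
            category=pd.DataFrame(
                {"density": rng.uniform(1, 5, size=4)}, index=list("abcd")
            )
        )
        biz = []
        for i in range(10):
            biz.append(self._biz(i, "MS", [rng.choice(list("abcd"))]))
            biz.append(self._biz(100 + i, "CO", [rng.choice(list("abcd"))]))
        z, p = compare_regions_ztest("MS", "CO", biz, reg)
        a = np.array([business_density(b, reg) for b in biz if b.region == "MS"])
        b = np.array([business_density(x, reg) for x in biz if x.region == "CO"])
        expect = (a.mean() - b.mean()) / math.sqrt(
            a.var(ddof=1) / 10 + b.var(ddof=1) / 10
        )
        assert z == pytest.approx(expect, abs=1e-12)

    def test_undefined_densities_raise(self):
        reg = DensityRegistry()
        biz = [self._biz(i, r, ["x"]) for r in ("CO", "MS") for i in range(3)]
        with pytest.raises(ValueError):
            compare_regions_ztest("CO", "MS", biz, reg)
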