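import itertools

import numpy as np
import pandas as pd
import pytest

from sugarsteps import (
    Category,
    FoodDB,
    FoodFlags,
    FoodItem,
    Kind,
    NutrientProfile,
    ValidationError,
    assign_and_estimate,
    daily_intake,
    energy_percent,
    mann_whitney,
    summarize,
)
from sugarsteps.intake import _adherence_pct


def drink_db():
    drink = FoodItem(
        "drink", "sweet drink", Kind.SINGLE, Category.BEVERAGE_SOFT,
        profile=NutrientProfile(5, 5, 10, 180),
        flags=FoodFlags(sugars_all_added=True),
    )
    water = FoodItem(
        "water", "water", Kind.SINGLE, Category.OTHER_SINGLE,
        profile=NutrientProfile(0, 0, 0, 0),
    )
    return FoodDB({"drink": drink, "water": water}, {})


def records_frame(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "day_index", "day_class", "food_id", "amount_g"]
    )


def test_single_drink_day():
    db = drink_db()
    est = assign_and_estimate(db)
    recs = records_frame([("P1", 1, "weekday", "drink", 250.0)])
    out = daily_intake(recs, est, db)
    assert len(out) == 1
    assert out.loc[0, "added_g"] == pytest.approx(25.0)
    assert out.loc[0, "energy_kJ"] == pytest.approx(450.0)


def test_empty_day_is_all_zeros():
    db = drink_db()
    est = assign_and_estimate(db)
    recs = records_frame([("P1", 1, "weekday", "water", 0.0)])
    out = daily_intake(recs, est, db)
    assert out[["added_g", "free_g", "total_g", "energy_kJ"]].to_numpy().sum() == 0.0


def test_unknown_food_id_names_record():
    db = drink_db()
    est = assign_and_estimate(db)
    recs = records_frame([("P9", 2, "weekend", "nope", 100.0)])
    with pytest.raises(ValidationError, match="P9.*nope"):
        daily_intake(recs, est, db)


def test_brute_force_summation_oracle(small_world):
    from sugarsteps import generate_survey

    cfg, db, truth, proc = small_world
    est = assign_and_estimate(db, proc)
    _, recs, _ = generate_survey(cfg, db, truth)
    sample = recs[recs["participant_id"] == recs["participant_id"].iloc[0]]
    out = daily_intake(sample, est, db)
    day1 = sample[sample["day_index"] == 1]
    expected = sum(
        row.amount_g * est[row.food_id].added_sugars / 100.0 for row in day1.itertuples()
    )
    got = out.loc[out["day_index"] == 1, "added_g"].iloc[0]
    assert got == pytest.approx(expected, rel=1e-12)


def test_additivity_and_scaling(small_world):
    from sugarsteps import generate_survey

    cfg, db, truth, proc = small_world
    est = assign_and_estimate(db, proc)
    _, recs, _ = generate_survey(cfg, db, truth)
    recs = recs.head(200)
    base = daily_intake(recs, est, db)
    doubled = daily_intake(recs.assign(amount_g=recs["amount_g"] * 2), est, db)
    np.testing.assert_allclose(
        doubled[["added_g", "energy_kJ"]].to_numpy(),
        2 * base[["added_g", "energy_kJ"]].to_numpy(),
    )
    # additivity: splitting the record set and summing matches one pass
    half1, half2 = recs.iloc[::2], recs.iloc[1::2]
    merged = (
        pd.concat([daily_intake(half1, est, db), daily_intake(half2, est, db)])
        .groupby(["participant_id", "day_index", "day_class"], as_index=False)
        .sum()
        .sort_values(["participant_id", "day_index"])
        .reset_index(drop=True)
    )
    np.testing.assert_allclose(
        merged[["added_g", "free_g", "total_g", "energy_kJ"]].to_numpy(),
        base[["added_g", "free_g", "total_g", "energy_kJ"]].to_numpy(),
    )


class TestEnergyPercent:
    def test_arithmetic(self):
        assert energy_percent(50.0, 8500.0) == pytest.approx(10.0)

    def test_zero_sugars(self):
        assert energy_percent(0.0, 8500.0) == 0.0

    def test_median_scale_consistency(self):
        assert energy_percent(59.0, 8358.0) == pytest.approx(12.0, abs=0.01)

    def test_zero_energy_flagged_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(energy_percent(10.0, 0.0))


class TestMannWhitney:
    def test_exact_enumeration_oracle(self):
        """p for {1,2,3} vs {4,5,6} equals brute force over all 20 orderings."""
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]

        def u_stat(a, b):
            return sum(1 for i in a for j in b if i > j)

        observed = u_stat(x, y)
        pooled = x + y
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            a = [pooled[i] for i in combo]
            b = [pooled[i] for i in range(6) if i not in combo]
            u = u_stat(a, b)
            total += 1
            if min(u, 9 - u) <= min(observed, 9 - observed):
                count += 1
        brute_p = count / total  # = 2/20 = 0.1 two-sided
        assert mann_whitney(x, y) == pytest.approx(brute_p)
        assert brute_p == pytest.approx(0.1)

    def test_identical_distributions_null(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        assert mann_whitney(x, x) == pytest.approx(1.0, abs=0.01)


class TestSummarize:
    def test_adherence_strictly_below(self):
        assert _adherence_pct(np.array([8.0, 9.0, 10.0, 11.0, 12.0]), 10.0) == 40

    def test_threshold_monotonicity(self):
        values = np.linspace(2, 18, 101)
        shares = [_adherence_pct(values, thr) for thr in (5.0, 10.0, 15.0)]
        assert shares == sorted(shares)

    def _usual(self, n=60):
        rng = np.random.default_rng(1)
        ids = [f"P{i:03d}" for i in range(n)]
        added = rng.lognormal(3.9, 0.3, n)
        extra = rng.lognormal(2.0, 0.3, n)
        intr = rng.lognormal(3.5, 0.3, n)
        usual = pd.DataFrame(
            {
                "participant_id": ids,
                "added_g": added,
                "free_g": added + extra,
                "total_g": added + extra + intr,
                "energy_kJ": rng.lognormal(9.0, 0.2, n),
            }
        )
        parts = pd.DataFrame(
            {
                "participant_id": ids,
                "sex": ["girl", "boy"] * (n // 2),
                "school_year": ([5] * (n // 3) + [8] * (n // 3) + [11] * (n // 3)),
            }
        )
        return usual, parts

    def test_table_shape_and_counts(self):
        usual, parts = self._usual()
        out = summarize(usual, parts)
        assert len(out) == 10  # 3 years x (all, girl, boy) + overall
        assert out.iloc[-1]["n"] == 60
        assert (out["added_E_median"] <= out["free_E_median"]).all()
        assert (out["free_E_median"] <= out["total_E_median"]).all()

    def test_hand_computed_medians_two_participants(self):
        usual = pd.DataFrame(
            {
                "participant_id": ["A", "B"],
                "added_g": [40.0, 60.0],
                "free_g": [50.0, 70.0],
                "total_g": [90.0, 110.0],
                "energy_kJ": [8500.0, 8500.0],
            }
        )
        parts = pd.DataFrame(
            {"participant_id": ["A", "B"], "sex": ["girl", "boy"], "school_year": [5, 5]}
        )
        out = summarize(usual, parts)
        top = out.iloc[0]
        assert top["added_g_median"] == pytest.approx(50.0)
        assert top["added_g_p25"] == pytest.approx(45.0)
        assert top["added_E_median"] == pytest.approx(50 * 17 / 8500 * 100)

    def test_missing_participant_in_roster(self):
        usual, parts = self._usual()
        with pytest.raises(ValidationError, match="missing from roster"):
            summarize(usual, parts.iloc[:-1])
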