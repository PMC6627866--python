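"""Synthetic food databases and two-day dietary surveys with planted truth.

No real food-composition or survey data is redistributable, so every other
module is exercised against generated data whose correct answers are known by
construction:

* :func:`generate_food_db` builds a database of single and composite items
  (composites arranged in a bounded-depth DAG) with category-consistent
  nutrient profiles, flags and subjective-step inputs, together with the
  analytically planted added/free sugars truth for every item.
* :func:`generate_survey` builds a participant roster shaped like a national
  school survey (three school years × two sexes) and two recall days per
  participant whose nutrient totals follow a lognormal model with specified
  between-/within-person variance components and a weekend effect.  Day
  totals are drawn first and then realised exactly as food records via four
  staple foods, so the variance structure is exact by construction.

All randomness flows from ``SynthConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .food_model import (
    Category,
    FoodDB,
    FoodFlags,
    FoodItem,
    Kind,
    NutrientProfile,
    Recipe,
    RecipeComponent,
    ValidationError,
)
from .sugar_steps import ProcedureConfig, composite_step

__all__ = ["SynthConfig", "NutrientParams", "generate_food_db", "generate_survey"]


def _q(x: float) -> float:
    """Quantize to the 6-decimal fixed point used by the file format."""
    return round(float(x), 6)


#: Staple items guaranteed to exist in every generated database.  The survey
#: generator solves day records exactly against the first four.
STAPLES = ("S_SUGAR", "S_JUICE", "S_FRUIT", "S_OIL", "S_WATER", "S_FLOUR", "S_MILK")


@dataclass(frozen=True)
class NutrientParams:
    """Log-scale mean and variance components of one nutrient's daily intake."""

    mu: float
    sigma2_between: float
    sigma2_within: float


def _default_category_mix() -> dict[Category, float]:
    return {
        Category.OTHER_SINGLE: 0.13,
        Category.FRUIT_RAW: 0.10,
        Category.VEGETABLE_RAW: 0.10,
        Category.DAIRY_PLAIN: 0.06,
        Category.DAIRY_SWEETENED: 0.06,
        Category.BREAD_PLAIN: 0.05,
        Category.BAKED_SWEET: 0.08,
        Category.CEREAL_BREAKFAST: 0.04,
        Category.CONFECTIONERY: 0.08,
        Category.BEVERAGE_SOFT: 0.06,
        Category.JUICE_FRUIT: 0.04,
        Category.JUICE_VEGETABLE: 0.01,
        Category.HONEY: 0.01,
        Category.SYRUP: 0.01,
        Category.PICKLED_SWEETENED: 0.03,
        Category.PSEUDOCEREAL: 0.02,
        Category.MEAT_FISH_PLAIN: 0.08,
        Category.FAT_OIL: 0.04,
    }


def _default_participants() -> dict[tuple[int, str], int]:
    # national-survey-like strata: school years 5/8/11 × girl/boy
    return {
        (5, "girl"): 559,
        (5, "boy"): 490,
        (8, "girl"): 574,
        (8, "boy"): 476,
        (11, "girl"): 577,
        (11, "boy"): 423,
    }


def _default_nutrients() -> dict[str, NutrientParams]:
    # chosen so habitual medians land near 51/59/100 g/day and ~10/12/20 E%
    return {
        "added_g": NutrientParams(3.765, 0.16, 0.25),
        "free_g": NutrientParams(3.911, 0.16, 0.25),
        "total_g": NutrientParams(4.438, 0.16, 0.25),
        "energy_kJ": NutrientParams(9.008, 0.05, 0.12),
    }


@dataclass
class SynthConfig:
    n_single: int = 844
    n_composite: int = 639
    max_dag_depth: int = 4
    category_mix: dict[Category, float] = field(default_factory=_default_category_mix)
    participant_counts: dict[tuple[int, str], int] = field(default_factory=_default_participants)
    nutrients: dict[str, NutrientParams] = field(default_factory=_default_nutrients)
    weekend_effect: float = 1.1  # multiplicative, sugars only
    energy_sugars_correlation: float = 0.6
    weekend_probability: float = 3.0 / 7.0  # Friday-Sunday share of the week
    seed: int = 0

    def validate(self) -> None:
        if self.max_dag_depth < 1:
            raise ValidationError("max_dag_depth must be >= 1")
        if self.n_single < len(STAPLES):
            raise ValidationError(f"n_single must be >= {len(STAPLES)} (staple items)")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"category_mix probabilities sum to {total}, not 1")
        for p in self.nutrients.values():
            if p.sigma2_between < 0 or p.sigma2_within < 0:
                raise ValidationError("variance components must be >= 0")
        if self.weekend_effect <= 0:
            raise ValidationError("weekend_effect must be > 0")


def _staple_items() -> list[tuple[FoodItem, int, int, float, float]]:
    """(item, step_added, step_free, added_truth, free_truth) for the staples."""

    def item(iid, name, cat, mono, di, energy, fructose=None, **flags):
        return FoodItem(
            item_id=iid,
            name=name,
            kind=Kind.SINGLE,
            category=cat,
            profile=NutrientProfile(
                monosaccharides=_q(mono),
                disaccharides=_q(di),
                total_sugars=_q(mono + di),
                energy=_q(energy),
                fructose=fructose,
            ),
            flags=FoodFlags(**flags),
        )

    return [
        (item("S_SUGAR", "white sugar", Category.CONFECTIONERY, 0, 100, 1700,
              sugars_all_added=True), 3, 3, 100.0, 100.0),
        (item("S_JUICE", "orange juice, unsweetened", Category.JUICE_FRUIT, 7, 3, 180,
              fructose=3.5), 2, 3, 0.0, 10.0),
        (item("S_FRUIT", "banana", Category.FRUIT_RAW, 6, 6, 400, fructose=3.0), 2, 2, 0.0, 0.0),
        (item("S_OIL", "rapeseed oil", Category.FAT_OIL, 0, 0, 3700), 1, 1, 0.0, 0.0),
        (item("S_WATER", "water", Category.OTHER_SINGLE, 0, 0, 0), 1, 1, 0.0, 0.0),
        (item("S_FLOUR", "wheat flour", Category.OTHER_SINGLE, 0, 0, 1450), 1, 1, 0.0, 0.0),
        (item("S_MILK", "milk, plain", Category.DAIRY_PLAIN, 0, 4.8, 270), 2, 2, 0.0, 0.0),
    ]


def _make_single(iid: str, cat: Category, rng: np.random.Generator,
                 plain_dairy_ids: list[str], sugar_source_ids: list[str],
                 config: ProcedureConfig, db_items: dict[str, FoodItem],
                 ) -> tuple[FoodItem, int, int, float, float]:
    """One synthetic single item plus its planted steps and truth."""

    def build(mono, di, energy, fructose=None, flags=None, counterpart=None,
              provenance=""):
        total = _q(_q(mono) + _q(di))
        return FoodItem(
            item_id=iid,
            name=f"{cat.value} {iid}",
            kind=Kind.SINGLE,
            category=cat,
            profile=NutrientProfile(_q(mono), _q(di), total, _q(energy), fructose),
            flags=flags or FoodFlags(),
            unsweetened_counterpart_id=counterpart,
            provenance=provenance,
        )

    U = rng.uniform
    if cat is Category.BEVERAGE_SOFT:
        t = U(4, 12)
        it = build(t * 0.5, t * 0.5, 17 * t + U(0, 30), flags=FoodFlags(sugars_all_added=True))
        return it, 3, 3, it.profile.total_sugars, it.profile.total_sugars
    if cat is Category.JUICE_FRUIT:
        t = U(8, 12)
        mono = t * 0.7
        fr = _q(min(U(0.3, 0.6) * mono, mono))
        it = build(mono, t * 0.3, 17 * t + U(0, 30), fructose=fr)
        return it, 2, 3, 0.0, it.profile.total_sugars
    if cat is Category.JUICE_VEGETABLE:
        t = U(3, 8)
        it = build(t * 0.6, t * 0.4, 17 * t + U(0, 30))
        return it, 2, 2, 0.0, 0.0
    if cat in (Category.HONEY, Category.SYRUP):
        t = U(60, 82)
        it = build(t * 0.6, t * 0.4, 17 * t + U(0, 100))
        return it, 2, 3, 0.0, it.profile.total_sugars
    if cat is Category.FRUIT_RAW:
        t = U(5, 15)
        mono = t * 0.6
        fr = _q(min(U(0.3, 0.6) * mono, mono))
        it = build(mono, t * 0.4, 17 * t + U(50, 300), fructose=fr)
        return it, 2, 2, 0.0, 0.0
    if cat is Category.VEGETABLE_RAW:
        t = U(1, 6)
        it = build(t * 0.5, t * 0.5, 17 * t + U(20, 150))
        return it, 2, 2, 0.0, 0.0
    if cat is Category.DAIRY_PLAIN:
        t = U(3, 5)
        it = build(0, t, 17 * t + U(100, 300))
        return it, 2, 2, 0.0, 0.0
    if cat is Category.DAIRY_SWEETENED:
        cp = plain_dairy_ids[rng.integers(len(plain_dairy_ids))]
        cp_total = db_items[cp].profile.total_sugars
        extra = _q(U(5, 12))
        it = build(extra * 0.3, cp_total + extra * 0.7,
                   17 * (cp_total + extra) + U(100, 300), counterpart=cp)
        truth = _q(it.profile.total_sugars - cp_total)
        return it, 5, 5, truth, truth
    if cat is Category.BREAD_PLAIN:
        t = U(1, 4)
        it = build(t * 0.3, t * 0.7, 1000 + U(0, 200), flags=FoodFlags(sugars_all_added=True))
        return it, 3, 3, it.profile.total_sugars, it.profile.total_sugars
    if cat in (Category.BAKED_SWEET, Category.CEREAL_BREAKFAST):
        t = U(10, 35) if cat is Category.BAKED_SWEET else U(8, 25)
        if rng.random() < 0.5:
            mono = t * 0.5
            fr = _q(min(U(0.1, 0.4) * mono, mono))
            it = build(mono, t * 0.5, 17 * t + U(500, 1200), fructose=fr,
                       flags=FoodFlags(contains_fruit_or_veg=True))
            truth = _q(it.profile.total_sugars - fr)
            return it, 6, 6, truth, truth
        it = build(t * 0.4, t * 0.6, 17 * t + U(500, 1200),
                   flags=FoodFlags(sugars_all_added=True))
        return it, 3, 3, it.profile.total_sugars, it.profile.total_sugars
    if cat is Category.CONFECTIONERY:
        t = U(40, 70)
        it = build(t * 0.4, t * 0.6, 17 * t + U(200, 800),
                   flags=FoodFlags(sugars_all_added=True))
        return it, 3, 3, it.profile.total_sugars, it.profile.total_sugars
    if cat is Category.PICKLED_SWEETENED:
        t = U(5, 15)
        it = build(t * 0.5, t * 0.5, 17 * t + U(50, 400),
                   flags=FoodFlags(sugars_all_added=True))
        return it, 3, 3, it.profile.total_sugars, it.profile.total_sugars
    if cat is Category.PSEUDOCEREAL:
        t = U(0.5, 2)
        it = build(t * 0.5, t * 0.5, 1400 + U(0, 200))
        return it, 2, 2, 0.0, 0.0
    if cat is Category.MEAT_FISH_PLAIN:
        if rng.random() < 0.5:
            it = build(0, 0, U(400, 1200))
            return it, 1, 1, 0.0, 0.0
        t = U(0.1, 0.5)
        it = build(t, 0, U(400, 1200))
        return it, 2, 2, 0.0, 0.0
    if cat is Category.FAT_OIL:
        it = build(0, 0, U(2500, 3700))
        return it, 1, 1, 0.0, 0.0

    # other_single: mixed bag exercising steps 1, 3, 7, 8 and 10
    r = rng.random()
    if r < 0.55:
        it = build(0, 0, U(0, 1500))
        return it, 1, 1, 0.0, 0.0
    if r < 0.80:
        t = U(2, 20)
        it = build(t * 0.5, t * 0.5, 17 * t + U(0, 1000),
                   flags=FoodFlags(sugars_all_added=True))
        return it, 3, 3, it.profile.total_sugars, it.profile.total_sugars
    if r < 0.88:
        t = _q(U(5, 20))
        added = _q(U(0.2, 0.8) * t)
        free = _q(min(added + U(0, 0.5) * (t - added), t))
        it = build(t * 0.5, t * 0.5, 17 * t + U(0, 1000),
                   flags=FoodFlags(label_derived=True),
                   provenance="average of 3+ supermarket labels")
        config.override_map[iid] = (added, free)
        return it, 7, 7, added, free
    if r < 0.94:
        ref = sugar_source_ids[rng.integers(len(sugar_source_ids))]
        ratio = _q(U(0.05, 0.3))
        ref_profile = db_items[ref].profile
        truth = _q(ratio * ref_profile.total_sugars)  # references are all-added items
        t = min(100.0, _q(truth + U(0, 3)))
        it = build(t * 0.5, t * 0.5, 17 * t + U(0, 1000))
        config.proportional_reference_map[iid] = (ref, ratio)
        return it, 8, 8, truth, truth
    t = U(2, 10)
    it = build(t * 0.5, t * 0.5, 17 * t + U(0, 1000))
    truth = _q(0.5 * it.profile.total_sugars)
    return it, 10, 10, truth, truth


def generate_food_db(config: SynthConfig) -> tuple[FoodDB, pd.DataFrame, ProcedureConfig]:
    """Generate a database with planted ground truth.

    Returns ``(db, truth, procedure_config)`` where ``truth`` has one row per
    item: planted step numbers and added/free g/100 g, and
    ``procedure_config`` carries the step-7 overrides and step-8 references
    the planted truth assumes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    proc = ProcedureConfig()

    items: dict[str, FoodItem] = {}
    recipes: dict[str, Recipe] = {}
    truth_rows: list[dict] = []

    def record(item: FoodItem, sa: int, sf: int, added: float, free: float) -> None:
        items[item.item_id] = item
        truth_rows.append(
            {
                "item_id": item.item_id,
                "step_added": sa,
                "step_free": sf,
                "added_g_per100": _q(added),
                "free_g_per100": _q(free),
            }
        )

    for item, sa, sf, a, f in _staple_items():
        record(item, sa, sf, a, f)

    plain_dairy = ["S_MILK"]
    sugar_sources = ["S_SUGAR"]
    cats = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in cats])
    n_extra = config.n_single - len(STAPLES)
    draws = rng.choice(len(cats), size=n_extra, p=probs)
    # plain dairy first so sweetened counterparts always have a target
    order = np.argsort([0 if cats[d] is Category.DAIRY_PLAIN else 1 for d in draws],
                       kind="stable")
    for j, pos in enumerate(order):
        cat = cats[draws[pos]]
        iid = f"S{j + 1:04d}"
        item, sa, sf, a, f = _make_single(
            iid, cat, rng, plain_dairy, sugar_sources, proc, items
        )
        record(item, sa, sf, a, f)
        if cat is Category.DAIRY_PLAIN:
            plain_dairy.append(iid)
        if cat is Category.CONFECTIONERY:
            sugar_sources.append(iid)

    # --- composites over a bounded-depth DAG -------------------------------
    truth_by_id = {r["item_id"]: r for r in truth_rows}
    levels: dict[str, int] = {iid: 0 for iid in items}
    by_level: dict[int, list[str]] = {0: sorted(items)}

    n_bread = max(1, config.n_composite // 20)
    for j in range(config.n_composite):
        cid = f"C{j + 1:04d}"
        if j < n_bread:
            # plain-bread dough: flour + water + sucrose, baked with water loss
            sugar_g = _q(rng.uniform(1, 8)) if j % 2 == 0 else _q(rng.uniform(10, 25))
            comps = [
                RecipeComponent(cid, "S_FLOUR", 600.0),
                RecipeComponent(cid, "S_WATER", 350.0),
                RecipeComponent(cid, "S_SUGAR", sugar_g),
            ]
            pre = 950.0 + sugar_g
            post = _q(pre * 0.85)
            cat = Category.BREAD_PLAIN
            level = 1
        else:
            level = 1 + int(rng.integers(config.max_dag_depth))
            pool: list[str] = []
            for l in range(level):
                pool.extend(by_level.get(l, []))
            k = int(rng.integers(2, 6))
            chosen = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
            comps = [
                RecipeComponent(cid, pool[c], _q(rng.uniform(20, 400))) for c in sorted(chosen)
            ]
            pre = sum(c.raw_weight for c in comps)
            post = _q(pre * rng.uniform(0.85, 1.0))
            cat = Category.COMPOSITE
        recipe = Recipe(cid, tuple(sorted(comps, key=lambda c: c.ingredient_id)),
                        batch_post_weight=post)
        item = FoodItem(item_id=cid, name=f"composite {cid}", kind=Kind.COMPOSITE,
                        category=cat)
        # planted truth: recipe-weighted ingredient truth, step by the 4/9 rule
        added = sum(c.raw_weight * truth_by_id[c.ingredient_id]["added_g_per100"] / 100.0
                    for c in recipe.components) / post * 100.0
        free = sum(c.raw_weight * truth_by_id[c.ingredient_id]["free_g_per100"] / 100.0
                   for c in recipe.components) / post * 100.0
        sa = composite_step({truth_by_id[c.ingredient_id]["step_added"] for c in recipe.components})
        sf = composite_step({truth_by_id[c.ingredient_id]["step_free"] for c in recipe.components})
        if cat is Category.BREAD_PLAIN:
            added_in_batch = sum(
                c.raw_weight * truth_by_id[c.ingredient_id]["added_g_per100"] / 100.0
                for c in recipe.components
            )
            if added_in_batch / recipe.batch_pre_weight * 1000.0 < proc.bread_discount_threshold:
                added = free = 0.0
        items[cid] = item
        recipes[cid] = recipe
        truth_rows.append(
            {
                "item_id": cid,
                "step_added": sa,
                "step_free": sf,
                "added_g_per100": added,
                "free_g_per100": free,
            }
        )
        truth_by_id[cid] = truth_rows[-1]
        levels[cid] = level
        by_level.setdefault(level, []).append(cid)

    db = FoodDB(items=items, recipes=recipes)
    db.validate()
    proc.validate()
    truth = pd.DataFrame(truth_rows).sort_values("item_id").reset_index(drop=True)
    truth["objective_added"] = truth["step_added"] <= 6
    truth["objective_free"] = truth["step_free"] <= 6
    return db, truth, proc


# ---------------------------------------------------------------------------
# Survey generation
# ---------------------------------------------------------------------------

def _staple_solver(db: FoodDB):
    """Exact food-record realisation of (added, free, total, energy) targets.

    Back-substitution: sugar supplies the added target, juice the free-only
    margin, fruit the intrinsic margin, oil the remaining energy.  The first
    three amounts are non-negative whenever added <= free <= total; oil is
    clamped at zero when the energy target falls below the energy already
    carried by the sugar-bearing staples, and the relative energy deviation
    is returned.
    """
    ps = db.items["S_SUGAR"].profile
    pj = db.items["S_JUICE"].profile
    pf = db.items["S_FRUIT"].profile
    po = db.items["S_OIL"].profile
    tj = pj.total_sugars / 100.0
    tf = pf.total_sugars / 100.0
    es, ej, ef, eo = (p.energy / 100.0 for p in (ps, pj, pf, po))

    def required_energy(a: float, f: float, t: float) -> float:
        return es * a + ej * (f - a) / tj + ef * (t - f) / tf

    def solve(a: float, f: float, t: float, e: float) -> tuple[dict[str, float], float]:
        g_sugar = a  # per-100 g added = 100
        g_juice = (f - a) / tj
        g_fruit = (t - f) / tf
        e_req = es * g_sugar + ej * g_juice + ef * g_fruit
        g_oil = max(0.0, (e - e_req) / eo)
        deviation = max(0.0, (e_req - e) / e) if e > 0 else 0.0
        amounts = {"S_SUGAR": g_sugar, "S_JUICE": g_juice, "S_FRUIT": g_fruit, "S_OIL": g_oil}
        return {k: v for k, v in amounts.items() if v > 1e-9}, deviation

    return solve, required_energy


def generate_survey(config: SynthConfig, db: FoodDB, truth: pd.DataFrame,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two-day dietary records with exact, known variance structure.

    Returns ``(participants, records, true_habitual)``.  Day totals per
    nutrient follow a lognormal model: person effect with σ²_between, day
    residual with σ²_within, a multiplicative weekend effect on the sugar
    nutrients, and correlated energy.  Totals are realised exactly through
    the staple foods (plus random garnish foods rescaled to fit), so observed
    record sums equal the drawn targets.

    ``true_habitual`` holds each participant's true long-term mean daily
    intake (expectation over day residuals and the week's 4/7-3/7
    weekday/weekend composition).
    """
    config.validate()
    if len(db) == 0:
        raise ValidationError("empty food database")
    for s in ("S_SUGAR", "S_JUICE", "S_FRUIT", "S_OIL"):
        if s not in db.items:
            raise ValidationError(f"staple item {s} missing from database")
    rng = np.random.default_rng(config.seed + 1)
    solve, required_energy = _staple_solver(db)

    p_add = config.nutrients["added_g"]
    p_free = config.nutrients["free_g"]
    p_tot = config.nutrients["total_g"]
    p_en = config.nutrients["energy_kJ"]
    rho = config.energy_sugars_correlation
    log_wf = math.log(config.weekend_effect)
    ws = config.weekend_probability
    week_mix = (1.0 - ws) + ws * config.weekend_effect

    from .recipe_engine import resolve_all_profiles

    profiles = resolve_all_profiles(db)
    added_per100 = dict(zip(truth["item_id"], truth["added_g_per100"]))
    free_per100 = dict(zip(truth["item_id"], truth["free_g_per100"]))
    garnish_pool = sorted(set(db.items) - {"S_SUGAR", "S_JUICE", "S_FRUIT", "S_OIL"})

    part_rows: list[dict] = []
    rec_rows: list[dict] = []
    truth_rows: list[dict] = []
    dev_rows: list[dict] = []
    pidx = 0
    for (year, sex), count in sorted(config.participant_counts.items()):
        for _ in range(count):
            pidx += 1
            pid = f"P{pidx:05d}"
            part_rows.append({"participant_id": pid, "sex": sex, "school_year": year})

            u = rng.standard_normal()
            v = rng.standard_normal()
            u_e = rho * u + math.sqrt(1 - rho * rho) * v

            def habitual(p: NutrientParams, person: float, sugars: bool) -> float:
                mix = week_mix if sugars else 1.0
                return math.exp(p.mu + math.sqrt(p.sigma2_between) * person
                                + p.sigma2_within / 2.0) * mix

            truth_rows.append(
                {
                    "participant_id": pid,
                    "added_g": habitual(p_add, u, True),
                    "free_g": habitual(p_free, u, True),
                    "total_g": habitual(p_tot, u, True),
                    "energy_kJ": habitual(p_en, u_e, False),
                }
            )

            for day in (1, 2):
                weekend = rng.random() < ws
                e1 = rng.standard_normal()
                e2 = rng.standard_normal()
                e_en = rho * e1 + math.sqrt(1 - rho * rho) * e2
                wterm = log_wf if weekend else 0.0

                def draw(p: NutrientParams, person: float, resid: float, sugars: bool) -> float:
                    return math.exp(
                        p.mu + math.sqrt(p.sigma2_between) * person
                        + (wterm if sugars else 0.0)
                        + math.sqrt(p.sigma2_within) * resid
                    )

                a = draw(p_add, u, e1, True)
                f = draw(p_free, u, e1, True)
                t = draw(p_tot, u, e1, True)
                e = draw(p_en, u_e, e_en, False)
                # independent parametrisations can break the ordering; repair
                f = max(f, a)
                t = max(t, f)
                # an energy draw below the energy the sugars themselves carry
                # cannot be realised as foods; raise it to the feasible floor
                # and record the adjustment (rare tail events)
                e_floor = required_energy(a, f, t)
                if e < e_floor:
                    dev_rows.append(
                        {
                            "participant_id": pid,
                            "day_index": day,
                            "energy_rel_deviation": (e_floor - e) / e,
                        }
                    )
                    e = e_floor

                # garnish foods for realism, rescaled so the staple solve
                # stays feasible (at most half of every target margin)
                n_g = int(rng.integers(2, 6))
                g_ids = [garnish_pool[i] for i in rng.integers(0, len(garnish_pool), n_g)]
                g_amt = rng.uniform(10, 80, n_g)
                ga = gf = gt = ge = 0.0
                for gid, amt in zip(g_ids, g_amt):
                    ga += amt * added_per100[gid] / 100.0
                    gf += amt * free_per100[gid] / 100.0
                    gt += amt * profiles[gid].total_sugars / 100.0
                    ge += amt * profiles[gid].energy / 100.0
                margins = (a, f - a, t - f, max(0.0, e - required_energy(a, f, t)))
                used = (ga, gf - ga, gt - gf, ge)
                scale = 1.0
                for m, g in zip(margins, used):
                    if g > 1e-12:
                        scale = min(scale, 0.5 * m / g)
                scale = max(scale, 0.0)
                amounts, deviation = solve(a - ga * scale, f - gf * scale,
                                           t - gt * scale, e - ge * scale)
                assert deviation < 1e-9  # targets are feasible by construction
                day_class = "weekend" if weekend else "weekday"
                merged: dict[str, float] = {}
                if scale > 0:
                    for gid, amt in zip(g_ids, g_amt):
                        merged[gid] = merged.get(gid, 0.0) + amt * scale
                for fid, amt in amounts.items():
                    if amt > 1e-9:
                        merged[fid] = merged.get(fid, 0.0) + amt
                for fid in sorted(merged):
                    rec_rows.append(
                        {
                            "participant_id": pid,
                            "day_index": day,
                            "day_class": day_class,
                            "food_id": fid,
                            "amount_g": merged[fid],
                        }
                    )

    participants = pd.DataFrame(part_rows)
    records = pd.DataFrame(rec_rows)
    records.attrs["realization_deviations"] = pd.DataFrame(
        dev_rows, columns=["participant_id", "day_index", "energy_rel_deviation"]
    )
    true_habitual = pd.DataFrame(truth_rows)
    return participants, records, true_habitual
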