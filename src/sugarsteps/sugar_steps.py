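"""Ten-step decision procedure for added and free sugars content.

Every food item receives, per sugar type (added and free), a step number in
1–10 and a content value in g per 100 g.  Steps 1–6 are objective (rule- and
data-driven), steps 7–10 subjective (judgement-based, their inputs arriving
as provenance-tagged data).  Single items are estimated through steps
1–3, 5–8 and 10; composite items receive step 4 (all components in steps 1–4)
or step 9 (any component in steps 5–10) with recipe-weighted content.

Definitions used (configurable through :class:`ProcedureConfig`):

* **added sugars** — refined sugars added during cooking or manufacturing
  (honey and unsweetened fruit-juice sugars excluded);
* **free sugars** — all added sugars plus sugars naturally present in honey,
  syrups, fruit juice and fruit-juice concentrate (vegetable-juice sugars
  excluded by default).

Hence free sugars is a superset of added sugars and
``0 <= added <= free <= total`` holds for every estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .food_model import Category, FoodDB, FoodItem, Kind, NutrientProfile, ValidationError
from .recipe_engine import resolve_all_profiles, topological_order

__all__ = [
    "SugarEstimate",
    "ProcedureConfig",
    "assign_and_estimate",
    "bread_rule",
    "fructose_subtraction",
    "composite_step",
    "composite_content",
    "step_distribution",
    "distribution_from_counts",
    "sugar_containing_share",
    "estimates_to_frame",
    "write_estimates",
    "load_estimates",
]

_TOL = 1e-9

OBJECTIVE_STEPS = frozenset({1, 2, 3, 4, 5, 6})

#: Categories whose sugars are entirely intrinsic (unprocessed/plain foods).
INTRINSIC_CATEGORIES = frozenset(
    {
        Category.FRUIT_RAW,
        Category.VEGETABLE_RAW,
        Category.DAIRY_PLAIN,
        Category.MEAT_FISH_PLAIN,
        Category.FAT_OIL,
        Category.PSEUDOCEREAL,
    }
)

#: Categories whose sugars are free but not added (WHO vs. NNR split).
FREE_ONLY_CATEGORIES = frozenset({Category.JUICE_FRUIT, Category.HONEY, Category.SYRUP})


@dataclass(frozen=True)
class SugarEstimate:
    """Procedure output for one item: step numbers and g/100 g contents."""

    item_id: str
    step_added: int
    step_free: int
    added_sugars: float
    free_sugars: float
    notes: str = ""

    @property
    def objective_added(self) -> bool:
        return self.step_added in OBJECTIVE_STEPS

    @property
    def objective_free(self) -> bool:
        return self.step_free in OBJECTIVE_STEPS


@dataclass
class ProcedureConfig:
    """Tunable definition switches and subjective-step inputs.

    ``bread_discount_threshold`` is grams of added sugars per 1000 g
    pre-baking batch weight below which (strictly) bread sugars are
    discounted.  ``override_map`` supplies manufacturer/recipe information
    for step 7 as ``item_id -> (added, free)`` g/100 g;
    ``proportional_reference_map`` supplies step-8 scaling as
    ``item_id -> (reference_id, ratio)``.
    """

    bread_discount_threshold: float = 9.0
    honey_in_added: bool = False
    fruit_puree_in_free: bool = False
    vegetable_juice_in_free: bool = False
    proportional_reference_map: dict[str, tuple[str, float]] = field(default_factory=dict)
    override_map: dict[str, tuple[float, float]] = field(default_factory=dict)
    fruit_puree_ids: set[str] = field(default_factory=set)
    step10_fallback: bool = True
    step10_fraction: float = 0.5

    def validate(self) -> None:
        if self.bread_discount_threshold <= 0:
            raise ValidationError("bread_discount_threshold must be > 0")
        if not (0.0 <= self.step10_fraction <= 1.0):
            raise ValidationError("step10_fraction must lie in [0, 1]")
        for iid, (a, f) in self.override_map.items():
            if a < 0 or f < a:
                raise ValidationError(
                    f"override for {iid}: need 0 <= added <= free, got ({a}, {f})"
                )
        for iid, (ref, ratio) in self.proportional_reference_map.items():
            if ratio < 0:
                raise ValidationError(f"reference ratio for {iid} must be >= 0")

    def to_yaml(self, path) -> None:
        data = {
            "bread_discount_threshold": self.bread_discount_threshold,
            "honey_in_added": self.honey_in_added,
            "fruit_puree_in_free": self.fruit_puree_in_free,
            "vegetable_juice_in_free": self.vegetable_juice_in_free,
            "proportional_reference_map": {
                k: list(v) for k, v in sorted(self.proportional_reference_map.items())
            },
            "override_map": {k: list(v) for k, v in sorted(self.override_map.items())},
            "fruit_puree_ids": sorted(self.fruit_puree_ids),
            "step10_fallback": self.step10_fallback,
            "step10_fraction": self.step10_fraction,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ProcedureConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(
            bread_discount_threshold=data.get("bread_discount_threshold", 9.0),
            honey_in_added=data.get("honey_in_added", False),
            fruit_puree_in_free=data.get("fruit_puree_in_free", False),
            vegetable_juice_in_free=data.get("vegetable_juice_in_free", False),
            proportional_reference_map={
                k: (v[0], float(v[1]))
                for k, v in (data.get("proportional_reference_map") or {}).items()
            },
            override_map={
                k: (float(v[0]), float(v[1]))
                for k, v in (data.get("override_map") or {}).items()
            },
            fruit_puree_ids=set(data.get("fruit_puree_ids") or []),
            step10_fallback=data.get("step10_fallback", True),
            step10_fraction=data.get("step10_fraction", 0.5),
        )
        cfg.validate()
        return cfg


def bread_rule(item: FoodItem, pre_baking_weight: float, sugars_in_batch: float,
               config: ProcedureConfig) -> bool:
    """Decide whether a plain bread's added sugars are discounted.

    True iff the added sugars per 1000 g pre-baking weight fall strictly
    below the configured threshold (default 9 g / 1000 g); the boundary value
    itself is *not* discounted.
    """
    if item.category is not Category.BREAD_PLAIN:
        raise ValidationError(f"bread rule applied to non-bread item {item.item_id}")
    if pre_baking_weight <= 0:
        raise ValidationError(f"item {item.item_id}: non-positive pre-baking weight")
    per_1000 = sugars_in_batch / pre_baking_weight * 1000.0
    return per_1000 < config.bread_discount_threshold


def fructose_subtraction(profile: NutrientProfile) -> float:
    """Added/free sugars candidate by subtracting analytical fructose.

    Only fructose is subtracted from total sugars (other intrinsic sugars are
    not accounted for); negative results are clamped to zero.
    """
    if profile.fructose is None:
        raise ValidationError("fructose subtraction requires an analytical fructose value")
    return max(0.0, profile.total_sugars - profile.fructose)


def composite_step(component_steps: set[int] | frozenset[int]) -> int:
    """Step for a composite: 4 if all components sit in steps 1–4, else 9."""
    if not component_steps:
        raise ValidationError("composite with no component steps")
    return 4 if max(component_steps) <= 4 else 9


def composite_content(db: FoodDB, composite_id: str,
                      estimates: dict[str, SugarEstimate]) -> tuple[float, float]:
    """Recipe-weighted (added, free) g/100 g of a finished composite food."""
    recipe = db.recipes.get(composite_id)
    if recipe is None:
        raise ValidationError(f"item {composite_id} has no recipe")
    added = free = 0.0
    for c in recipe.components:
        est = estimates.get(c.ingredient_id)
        if est is None:
            raise ValidationError(
                f"composite {composite_id}: ingredient {c.ingredient_id} not yet estimated"
            )
        added += c.raw_weight * est.added_sugars / 100.0
        free += c.raw_weight * est.free_sugars / 100.0
    scale = 100.0 / recipe.post_weight
    return added * scale, free * scale


def _single_added(item: FoodItem, profile: NutrientProfile, db: FoodDB,
                  profiles: dict[str, NutrientProfile], config: ProcedureConfig,
                  estimates: dict[str, SugarEstimate], notes: list[str]) -> tuple[int, float]:
    cat = item.category
    if profile.total_sugars <= _TOL:
        return 1, 0.0
    if cat is Category.HONEY and config.honey_in_added:
        notes.append("honey counted as added per config")
        return 3, profile.total_sugars
    if cat in INTRINSIC_CATEGORIES or cat in FREE_ONLY_CATEGORIES or cat is Category.JUICE_VEGETABLE:
        return 2, 0.0
    if item.flags.sugars_all_added:
        return 3, profile.total_sugars
    if item.unsweetened_counterpart_id is not None:
        counter = profiles[item.unsweetened_counterpart_id]
        value = profile.total_sugars - counter.total_sugars
        if value < 0:
            notes.append("step 5 subtraction clamped to 0")
            value = 0.0
        return 5, value
    if item.flags.contains_fruit_or_veg and profile.fructose is not None:
        value = fructose_subtraction(profile)
        if profile.total_sugars - profile.fructose < 0:
            notes.append("step 6 subtraction clamped to 0")
        return 6, value
    if item.item_id in config.override_map:
        return 7, config.override_map[item.item_id][0]
    if item.item_id in config.proportional_reference_map:
        ref_id, ratio = config.proportional_reference_map[item.item_id]
        ref = estimates.get(ref_id)
        if ref is None:
            raise ValidationError(
                f"item {item.item_id}: step-8 reference {ref_id} not yet estimated"
            )
        return 8, ratio * ref.added_sugars
    if config.step10_fallback:
        notes.append("step 10 fallback: 50% of total sugars")
        return 10, config.step10_fraction * profile.total_sugars
    raise ValidationError(
        f"item {item.item_id}: no added-sugars rule applies (category {cat.value})"
    )


def _single_free(item: FoodItem, profile: NutrientProfile, db: FoodDB,
                 profiles: dict[str, NutrientProfile], config: ProcedureConfig,
                 estimates: dict[str, SugarEstimate], notes: list[str]) -> tuple[int, float]:
    cat = item.category
    if profile.total_sugars <= _TOL:
        return 1, 0.0
    if cat is Category.JUICE_VEGETABLE:
        if config.vegetable_juice_in_free:
            notes.append("vegetable-juice sugars counted as free per config")
            return 3, profile.total_sugars
        return 2, 0.0
    if cat in FREE_ONLY_CATEGORIES:
        return 3, profile.total_sugars
    if item.item_id in config.fruit_puree_ids and config.fruit_puree_in_free:
        notes.append("fruit-purée sugars counted as free per config")
        return 3, profile.total_sugars
    if cat in INTRINSIC_CATEGORIES:
        return 2, 0.0
    if item.flags.sugars_all_added or item.flags.sugars_all_free:
        return 3, profile.total_sugars
    if item.unsweetened_counterpart_id is not None:
        counter = profiles[item.unsweetened_counterpart_id]
        value = max(0.0, profile.total_sugars - counter.total_sugars)
        return 5, value
    if item.flags.contains_fruit_or_veg and profile.fructose is not None:
        return 6, fructose_subtraction(profile)
    if item.item_id in config.override_map:
        return 7, config.override_map[item.item_id][1]
    if item.item_id in config.proportional_reference_map:
        ref_id, ratio = config.proportional_reference_map[item.item_id]
        ref = estimates.get(ref_id)
        if ref is None:
            raise ValidationError(
                f"item {item.item_id}: step-8 reference {ref_id} not yet estimated"
            )
        return 8, ratio * ref.free_sugars
    if config.step10_fallback:
        return 10, config.step10_fraction * profile.total_sugars
    raise ValidationError(
        f"item {item.item_id}: no free-sugars rule applies (category {cat.value})"
    )


def _single_order(db: FoodDB, config: ProcedureConfig) -> list[str]:
    """Singles ordered so step-8 references precede their dependents."""
    singles = db.single_ids
    ref = config.proportional_reference_map
    order: list[str] = []
    seen: set[str] = set()
    in_progress: set[str] = set()

    def visit(iid: str) -> None:
        if iid in seen:
            return
        if iid in in_progress:
            raise ValidationError(f"cyclic step-8 reference chain involving {iid}")
        in_progress.add(iid)
        if iid in ref and ref[iid][0] in db.items and db.items[ref[iid][0]].kind is Kind.SINGLE:
            visit(ref[iid][0])
        in_progress.discard(iid)
        seen.add(iid)
        order.append(iid)

    for iid in singles:
        visit(iid)
    return order


def assign_and_estimate(db: FoodDB, config: ProcedureConfig | None = None) -> dict[str, SugarEstimate]:
    """Run the ten-step procedure over an entire database.

    Every item receives exactly one step per sugar type and a content value;
    evaluation is deterministic.  Singles go through steps 1–3, 5–8 and 10;
    composites receive step 4 or 9 with recipe-weighted content.  Plain-bread
    composites additionally pass the bread discount rule.
    """
    config = config or ProcedureConfig()
    config.validate()
    db.validate()
    profiles = resolve_all_profiles(db)
    estimates: dict[str, SugarEstimate] = {}

    for iid in _single_order(db, config):
        item = db.items[iid]
        profile = profiles[iid]
        notes: list[str] = []
        step_a, added = _single_added(item, profile, db, profiles, config, estimates, notes)
        step_f, free = _single_free(item, profile, db, profiles, config, estimates, notes)
        free = min(free, profile.total_sugars + _TOL)
        if added > free + 1e-6:
            raise ValidationError(
                f"item {iid}: added {added} exceeds free {free}; inconsistent inputs"
            )
        free = max(free, added)
        estimates[iid] = SugarEstimate(iid, step_a, step_f, added, free, "; ".join(notes))

    for iid in topological_order(db):
        item = db.items[iid]
        if item.kind is not Kind.COMPOSITE:
            continue
        recipe = db.recipes[iid]
        steps_a = {estimates[c.ingredient_id].step_added for c in recipe.components}
        steps_f = {estimates[c.ingredient_id].step_free for c in recipe.components}
        step_a = composite_step(steps_a)
        step_f = composite_step(steps_f)
        added, free = composite_content(db, iid, estimates)
        notes = []
        if item.category is Category.BREAD_PLAIN:
            pre = recipe.batch_pre_weight
            added_in_batch = sum(
                c.raw_weight * estimates[c.ingredient_id].added_sugars / 100.0
                for c in recipe.components
            )
            if bread_rule(item, pre, added_in_batch, config):
                notes.append(
                    f"bread discount: {added_in_batch / pre * 1000:.2f} g/1000 g "
                    f"< {config.bread_discount_threshold} g/1000 g"
                )
                added = free = 0.0
        estimates[iid] = SugarEstimate(iid, step_a, step_f, added, free, "; ".join(notes))

    for iid, est in estimates.items():
        total = profiles[iid].total_sugars
        if not (est.added_sugars >= -_TOL
                and est.added_sugars <= est.free_sugars + 1e-6
                and est.free_sugars <= total + 1e-6):
            raise ValidationError(
                f"item {iid}: estimate violates 0 <= added <= free <= total "
                f"({est.added_sugars}, {est.free_sugars}, {total})"
            )
    return estimates


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def _round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10 ** ndigits
    return math.floor(x * scale + 0.5) / scale


def distribution_from_counts(added_counts: list[int], free_counts: list[int]) -> pd.DataFrame:
    """Step-distribution table from raw per-step counts (steps 1–10).

    Returns one row per step plus a ``total`` row, with counts, percentages
    (one decimal) and, as frame attrs, the objective-step fractions rounded
    to the nearest integer percent.
    """
    if len(added_counts) != 10 or len(free_counts) != 10:
        raise ValidationError("expected counts for steps 1..10")
    n_added, n_free = sum(added_counts), sum(free_counts)
    if n_added != n_free:
        raise ValidationError("added and free counts cover different item totals")
    rows = []
    for step in range(1, 11):
        rows.append(
            {
                "step": str(step),
                "count_added": added_counts[step - 1],
                "pct_added": _round_half_up(added_counts[step - 1] / n_added * 100, 1),
                "count_free": free_counts[step - 1],
                "pct_free": _round_half_up(free_counts[step - 1] / n_free * 100, 1),
            }
        )
    rows.append(
        {
            "step": "total",
            "count_added": n_added,
            "pct_added": 100.0,
            "count_free": n_free,
            "pct_free": 100.0,
        }
    )
    df = pd.DataFrame(rows)
    df.attrs["objective_added_pct"] = int(
        _round_half_up(sum(added_counts[:6]) / n_added * 100)
    )
    df.attrs["objective_free_pct"] = int(
        _round_half_up(sum(free_counts[:6]) / n_free * 100)
    )
    return df


def step_distribution(estimates: dict[str, SugarEstimate]) -> pd.DataFrame:
    """Counts and percentages per step and sugar type, plus objective fractions."""
    if not estimates:
        raise ValidationError("no estimates to summarise")
    added = [0] * 10
    free = [0] * 10
    for est in estimates.values():
        added[est.step_added - 1] += 1
        free[est.step_free - 1] += 1
    return distribution_from_counts(added, free)


def sugar_containing_share(n_added: int, n_free: int, n_total: int) -> tuple[int, int]:
    """Integer-percent shares of items containing added resp. free sugars."""
    if n_total <= 0:
        raise ValidationError("empty database")
    return (
        int(_round_half_up(n_added / n_total * 100)),
        int(_round_half_up(n_free / n_total * 100)),
    )


ESTIMATE_COLUMNS = [
    "item_id",
    "step_added",
    "step_free",
    "added_sugars_g_per100",
    "free_sugars_g_per100",
    "objective_added",
    "objective_free",
    "notes",
]


def estimates_to_frame(estimates: dict[str, SugarEstimate]) -> pd.DataFrame:
    rows = [
        {
            "item_id": e.item_id,
            "step_added": e.step_added,
            "step_free": e.step_free,
            "added_sugars_g_per100": e.added_sugars,
            "free_sugars_g_per100": e.free_sugars,
            "objective_added": e.objective_added,
            "objective_free": e.objective_free,
            "notes": e.notes,
        }
        for e in sorted(estimates.values(), key=lambda e: e.item_id)
    ]
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def write_estimates(estimates: dict[str, SugarEstimate], path) -> None:
    df = estimates_to_frame(estimates).copy()
    for col in ("added_sugars_g_per100", "free_sugars_g_per100"):
        df[col] = df[col].map(lambda x: f"{x:.6f}")
    df.to_csv(path, index=False, lineterminator="\n")


def load_estimates(path) -> dict[str, SugarEstimate]:
    df = pd.read_csv(path, dtype={"item_id": str}, keep_default_na=False)
    out: dict[str, SugarEstimate] = {}
    for _, row in df.iterrows():
        out[row["item_id"]] = SugarEstimate(
            item_id=row["item_id"],
            step_added=int(row["step_added"]),
            step_free=int(row["step_free"]),
            added_sugars=float(row["added_sugars_g_per100"]),
            free_sugars=float(row["free_sugars_g_per100"]),
            notes=str(row.get("notes", "")),
        )
    return out
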