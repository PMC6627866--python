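"""Domain types and file I/O for the food composition database and survey tables.

A food composition database holds *single* items (nutrient values assigned
directly, per 100 g edible portion) and *composite* items (nutrient values
derived from a recipe over other items).  This module defines the validated
in-memory representation and comma-delimited readers/writers for:

* ``foods.csv`` — one row per food item,
* ``recipes.csv`` / ``recipe_meta.csv`` — recipe components and batch weights,
* ``participants.csv`` / ``records.csv`` — the dietary-survey side.

All nutrient quantities are grams per 100 g edible portion except energy,
which is kJ per 100 g.  Recipe weights are grams per batch.
"""

from __future__ import annotations

import csv
import enum
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Kind",
    "Category",
    "Sex",
    "NutrientProfile",
    "FoodFlags",
    "FoodItem",
    "RecipeComponent",
    "Recipe",
    "FoodDB",
    "ValidationError",
    "load_food_db",
    "write_food_db",
    "load_participants",
    "write_participants",
    "load_records",
    "write_records",
]

_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when a database file or in-memory object violates an invariant."""


class Kind(str, enum.Enum):
    SINGLE = "single"
    COMPOSITE = "composite"


class Category(str, enum.Enum):
    """Food groups driving the sugars decision procedure."""

    BEVERAGE_SOFT = "beverage_soft"
    JUICE_FRUIT = "juice_fruit"
    JUICE_VEGETABLE = "juice_vegetable"
    HONEY = "honey"
    SYRUP = "syrup"
    FRUIT_RAW = "fruit_raw"
    VEGETABLE_RAW = "vegetable_raw"
    DAIRY_PLAIN = "dairy_plain"
    DAIRY_SWEETENED = "dairy_sweetened"
    BREAD_PLAIN = "bread_plain"
    BAKED_SWEET = "baked_sweet"
    CEREAL_BREAKFAST = "cereal_breakfast"
    CONFECTIONERY = "confectionery"
    PICKLED_SWEETENED = "pickled_sweetened"
    PSEUDOCEREAL = "pseudocereal"
    MEAT_FISH_PLAIN = "meat_fish_plain"
    FAT_OIL = "fat_oil"
    OTHER_SINGLE = "other_single"
    COMPOSITE = "composite"


class Sex(str, enum.Enum):
    GIRL = "girl"
    BOY = "boy"


SCHOOL_YEARS = (5, 8, 11)


@dataclass(frozen=True)
class NutrientProfile:
    """Per-100 g sugar and energy composition of one food item.

    ``fructose`` is the analytically determined free-fructose content; it is
    ``None`` when no analytical value exists, which makes the item ineligible
    for the fructose-subtraction step of the procedure (absence is meaningful
    and distinct from zero).
    """

    monosaccharides: float
    disaccharides: float
    total_sugars: float
    energy: float
    fructose: float | None = None

    def validate(self, where: str = "profile") -> None:
        m, d, t = self.monosaccharides, self.disaccharides, self.total_sugars
        if not (m >= -_TOL and d >= -_TOL):
            raise ValidationError(f"{where}: negative saccharide value")
        if abs(m + d - t) > _TOL:
            raise ValidationError(
                f"{where}: total_sugars {t} != monosaccharides {m} + disaccharides {d}"
            )
        if t > 100 + _TOL:
            raise ValidationError(f"{where}: total_sugars {t} > 100 g/100 g")
        if self.fructose is not None:
            if self.fructose < -_TOL or self.fructose > m + _TOL:
                raise ValidationError(
                    f"{where}: fructose {self.fructose} outside [0, monosaccharides={m}]"
                )
        if self.energy < 0:
            raise ValidationError(f"{where}: negative energy {self.energy}")


@dataclass(frozen=True)
class FoodFlags:
    sugars_all_added: bool = False
    sugars_all_free: bool = False
    contains_fruit_or_veg: bool = False
    label_derived: bool = False


@dataclass(frozen=True)
class FoodItem:
    item_id: str
    name: str
    kind: Kind
    category: Category
    profile: NutrientProfile | None = None
    flags: FoodFlags = field(default_factory=FoodFlags)
    unsweetened_counterpart_id: str | None = None
    provenance: str = ""

    def validate(self) -> None:
        if self.kind is Kind.SINGLE:
            if self.profile is None:
                raise ValidationError(f"item {self.item_id}: single item lacks a profile")
            self.profile.validate(where=f"item {self.item_id}")
        if self.category is Category.HONEY and self.flags.sugars_all_added:
            # Honey sugars are free but not added under the NNR definition used here.
            raise ValidationError(
                f"item {self.item_id}: honey cannot carry sugars_all_added"
            )
        if self.category is Category.JUICE_VEGETABLE and self.flags.sugars_all_free:
            raise ValidationError(
                f"item {self.item_id}: vegetable-juice sugars are excluded from free sugars"
            )


@dataclass(frozen=True)
class RecipeComponent:
    composite_id: str
    ingredient_id: str
    raw_weight: float  # grams per batch

    def validate(self) -> None:
        if self.raw_weight <= 0:
            raise ValidationError(
                f"recipe {self.composite_id}: component {self.ingredient_id} "
                f"has non-positive raw_weight {self.raw_weight}"
            )
        if self.ingredient_id == self.composite_id:
            raise ValidationError(
                f"recipe {self.composite_id}: item used as its own ingredient"
            )


@dataclass(frozen=True)
class Recipe:
    """Ingredient list for one composite item.

    ``batch_post_weight`` is the finished (post-cooking) batch weight in grams;
    it defaults to the raw batch weight.  A post-weight above the pre-weight is
    only legal when ``water_added`` is set.
    """

    composite_id: str
    components: tuple[RecipeComponent, ...]
    batch_post_weight: float | None = None
    water_added: bool = False

    @property
    def batch_pre_weight(self) -> float:
        return sum(c.raw_weight for c in self.components)

    @property
    def post_weight(self) -> float:
        return self.batch_post_weight if self.batch_post_weight is not None else self.batch_pre_weight

    def validate(self) -> None:
        if not self.components:
            raise ValidationError(f"recipe {self.composite_id}: empty component list")
        for c in self.components:
            c.validate()
        if self.post_weight <= 0:
            raise ValidationError(
                f"recipe {self.composite_id}: non-positive batch_post_weight"
            )
        if self.post_weight > self.batch_pre_weight + _TOL and not self.water_added:
            raise ValidationError(
                f"recipe {self.composite_id}: post-weight {self.post_weight} exceeds "
                f"pre-weight {self.batch_pre_weight} without water_added flag"
            )


@dataclass
class FoodDB:
    """Validated mapping of item ids to food items and recipes."""

    items: dict[str, FoodItem]
    recipes: dict[str, Recipe]

    def validate(self) -> None:
        for item in self.items.values():
            item.validate()
            if item.kind is Kind.COMPOSITE and item.item_id not in self.recipes:
                raise ValidationError(
                    f"item {item.item_id}: composite item without a recipe"
                )
            cp = item.unsweetened_counterpart_id
            if cp is not None and cp not in self.items:
                raise ValidationError(
                    f"item {item.item_id}: unsweetened counterpart {cp!r} not in database"
                )
        for rid, recipe in self.recipes.items():
            if rid not in self.items:
                raise ValidationError(f"recipe for unknown item {rid!r}")
            if self.items[rid].kind is not Kind.COMPOSITE:
                raise ValidationError(f"recipe attached to single item {rid!r}")
            recipe.validate()
            for c in recipe.components:
                if c.ingredient_id not in self.items:
                    raise ValidationError(
                        f"recipe {rid}: ingredient {c.ingredient_id!r} not in database"
                    )

    @property
    def single_ids(self) -> list[str]:
        return sorted(i for i, it in self.items.items() if it.kind is Kind.SINGLE)

    @property
    def composite_ids(self) -> list[str]:
        return sorted(i for i, it in self.items.items() if it.kind is Kind.COMPOSITE)

    def __len__(self) -> int:
        return len(self.items)


# ---------------------------------------------------------------------------
# File I/O.  Column order is fixed and numerics are written as 6-decimal
# fixed point so that write → load → write is byte-stable.
# ---------------------------------------------------------------------------

FOOD_COLUMNS = [
    "item_id",
    "name",
    "kind",
    "category",
    "monosaccharides_g",
    "disaccharides_g",
    "total_sugars_g",
    "fructose_g",
    "energy_kJ",
    "sugars_all_added",
    "sugars_all_free",
    "contains_fruit_or_veg",
    "unsweetened_counterpart_id",
    "provenance",
]
RECIPE_COLUMNS = ["composite_id", "ingredient_id", "raw_weight_g"]
RECIPE_META_COLUMNS = ["composite_id", "batch_post_weight_g"]
PARTICIPANT_COLUMNS = ["participant_id", "sex", "school_year"]
RECORD_COLUMNS = ["participant_id", "day_index", "day_class", "food_id", "amount_g"]


def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:.6f}"


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def _parse_bool(s: str) -> bool:
    s = str(s).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", ""}:
        return False
    raise ValidationError(f"unparseable boolean {s!r}")


def _parse_float(s, where: str) -> float | None:
    if s is None or (isinstance(s, float) and math.isnan(s)) or str(s).strip() == "":
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ValidationError(f"{where}: unparseable number {s!r}") from exc


def write_food_db(db: FoodDB, food_path, recipe_path, recipe_meta_path=None) -> None:
    """Write a database to ``foods.csv`` / ``recipes.csv`` (+ optional meta file).

    Output is deterministic: items sorted by id, fixed column order, 6-decimal
    fixed-point numerics, LF line endings.
    """
    with open(food_path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(FOOD_COLUMNS)
        for iid in sorted(db.items):
            it = db.items[iid]
            p = it.profile
            writer.writerow(
                [
                    it.item_id,
                    it.name,
                    it.kind.value,
                    it.category.value,
                    _fmt(p.monosaccharides) if p else "",
                    _fmt(p.disaccharides) if p else "",
                    _fmt(p.total_sugars) if p else "",
                    _fmt(p.fructose) if p and p.fructose is not None else "",
                    _fmt(p.energy) if p else "",
                    _fmt_bool(it.flags.sugars_all_added),
                    _fmt_bool(it.flags.sugars_all_free),
                    _fmt_bool(it.flags.contains_fruit_or_veg),
                    it.unsweetened_counterpart_id or "",
                    it.provenance,
                ]
            )

    rlines = [",".join(RECIPE_COLUMNS)]
    mlines = [",".join(RECIPE_META_COLUMNS)]
    for rid in sorted(db.recipes):
        r = db.recipes[rid]
        for c in sorted(r.components, key=lambda c: c.ingredient_id):
            rlines.append(f"{rid},{c.ingredient_id},{_fmt(c.raw_weight)}")
        if r.batch_post_weight is not None:
            mlines.append(f"{rid},{_fmt(r.batch_post_weight)}")
    with open(recipe_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(rlines) + "\n")
    if recipe_meta_path is not None:
        with open(recipe_meta_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(mlines) + "\n")


def load_food_db(food_path, recipe_path, recipe_meta_path=None) -> FoodDB:
    """Load and validate a food database from delimited files.

    Referential integrity of recipe links and counterpart ids is enforced; a
    missing ingredient id raises :class:`ValidationError` naming the id.
    """
    foods = pd.read_csv(food_path, dtype=str, keep_default_na=False)
    missing = [c for c in FOOD_COLUMNS if c not in foods.columns]
    if missing:
        raise ValidationError(f"{food_path}: missing columns {missing}")

    items: dict[str, FoodItem] = {}
    for _, row in foods.iterrows():
        iid = row["item_id"].strip()
        if not iid:
            raise ValidationError(f"{food_path}: empty item_id")
        if iid in items:
            raise ValidationError(f"{food_path}: duplicate item_id {iid!r}")
        try:
            kind = Kind(row["kind"])
            category = Category(row["category"])
        except ValueError as exc:
            raise ValidationError(f"item {iid}: {exc}") from exc
        profile = None
        if kind is Kind.SINGLE:
            profile = NutrientProfile(
                monosaccharides=_parse_float(row["monosaccharides_g"], f"item {iid}") or 0.0,
                disaccharides=_parse_float(row["disaccharides_g"], f"item {iid}") or 0.0,
                total_sugars=_parse_float(row["total_sugars_g"], f"item {iid}") or 0.0,
                energy=_parse_float(row["energy_kJ"], f"item {iid}") or 0.0,
                fructose=_parse_float(row["fructose_g"], f"item {iid}"),
            )
        cp = row["unsweetened_counterpart_id"].strip() or None
        items[iid] = FoodItem(
            item_id=iid,
            name=row["name"],
            kind=kind,
            category=category,
            profile=profile,
            flags=FoodFlags(
                sugars_all_added=_parse_bool(row["sugars_all_added"]),
                sugars_all_free=_parse_bool(row["sugars_all_free"]),
                contains_fruit_or_veg=_parse_bool(row["contains_fruit_or_veg"]),
                # label-derived values are a provenance fact, not a column
                label_derived="label" in row["provenance"].lower(),
            ),
            unsweetened_counterpart_id=cp,
            provenance=row["provenance"],
        )

    recipes_df = pd.read_csv(recipe_path, dtype=str, keep_default_na=False)
    rmissing = [c for c in RECIPE_COLUMNS if c not in recipes_df.columns]
    if rmissing:
        raise ValidationError(f"{recipe_path}: missing columns {rmissing}")
    post_weights: dict[str, float] = {}
    if recipe_meta_path is not None:
        meta = pd.read_csv(recipe_meta_path, dtype=str, keep_default_na=False)
        for _, row in meta.iterrows():
            post_weights[row["composite_id"]] = float(row["batch_post_weight_g"])

    comps: dict[str, list[RecipeComponent]] = {}
    for _, row in recipes_df.iterrows():
        cid = row["composite_id"].strip()
        comps.setdefault(cid, []).append(
            RecipeComponent(
                composite_id=cid,
                ingredient_id=row["ingredient_id"].strip(),
                raw_weight=float(row["raw_weight_g"]),
            )
        )
    recipes: dict[str, Recipe] = {}
    for cid, clist in comps.items():
        pre = sum(c.raw_weight for c in clist)
        post = post_weights.get(cid)
        water_added = post is not None and post > pre + _TOL
        if water_added:
            warnings.warn(
                f"recipe {cid}: post-weight {post} exceeds raw weight {pre}; "
                "treating as water addition",
                stacklevel=2,
            )
        recipes[cid] = Recipe(
            composite_id=cid,
            components=tuple(sorted(clist, key=lambda c: c.ingredient_id)),
            batch_post_weight=post,
            water_added=water_added,
        )

    db = FoodDB(items=items, recipes=recipes)
    db.validate()
    return db


def write_participants(participants: pd.DataFrame, path) -> None:
    df = participants[PARTICIPANT_COLUMNS].sort_values("participant_id")
    df.to_csv(path, index=False, lineterminator="\n")


def load_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "sex": str, "school_year": int})
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate participant_id {dup!r}")
    bad_sex = set(df["sex"]) - {s.value for s in Sex}
    if bad_sex:
        raise ValidationError(f"{path}: unknown sex values {sorted(bad_sex)}")
    bad_year = set(df["school_year"]) - set(SCHOOL_YEARS)
    if bad_year:
        raise ValidationError(f"{path}: unknown school years {sorted(bad_year)}")
    return df[PARTICIPANT_COLUMNS]


def write_records(records: pd.DataFrame, path) -> None:
    df = records[RECORD_COLUMNS].sort_values(["participant_id", "day_index", "food_id"])
    df = df.copy()
    df["amount_g"] = df["amount_g"].map(lambda x: f"{x:.6f}")
    df.to_csv(path, index=False, lineterminator="\n")


def load_records(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "participant_id": str,
            "day_index": int,
            "day_class": str,
            "food_id": str,
            "amount_g": float,
        },
    )
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if (df["amount_g"] < 0).any():
        bad = df.loc[df["amount_g"] < 0].iloc[0]
        raise ValidationError(
            f"{path}: negative amount for participant {bad['participant_id']} food {bad['food_id']}"
        )
    bad_class = set(df["day_class"]) - {"weekday", "weekend"}
    if bad_class:
        raise ValidationError(f"{path}: unknown day_class values {sorted(bad_class)}")
    bad_day = set(df["day_index"]) - {1, 2}
    if bad_day:
        raise ValidationError(f"{path}: day_index must be 1 or 2, got {sorted(bad_day)}")
    return df[RECORD_COLUMNS]
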