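"""Recursive recipe resolution over the food-database DAG.

Composite items form a directed acyclic graph: every composite is built from
single items and/or previously defined composites, so every item ultimately
originates from single items.  Nutrient values per 100 g of finished food are
obtained by yield-adjusted weighted aggregation:

    nutrient per 100 g = sum_i(raw_weight_i * nutrient_i / 100) / batch_post_weight * 100

Cooking losses are modelled solely through the post-cooking batch weight
(water loss); sugars are assumed fully retained.
"""

from __future__ import annotations

import networkx as nx

from .food_model import FoodDB, Kind, NutrientProfile, ValidationError

__all__ = [
    "CycleError",
    "recipe_graph",
    "topological_order",
    "resolve_profile",
    "resolve_all_profiles",
    "flatten_to_singles",
]


class CycleError(ValidationError):
    """Raised when recipes are mutually recursive."""


def recipe_graph(db: FoodDB) -> nx.DiGraph:
    """Directed graph with an edge ingredient → composite for every usage."""
    g = nx.DiGraph()
    g.add_nodes_from(db.items)
    for rid, recipe in db.recipes.items():
        for c in recipe.components:
            g.add_edge(c.ingredient_id, rid)
    return g


def topological_order(db: FoodDB) -> list[str]:
    """Item ids ordered so every ingredient precedes every composite using it.

    Deterministic: ties are broken by lexicographic item id.  Raises
    :class:`CycleError` naming the offending ids if recipes are cyclic.
    """
    g = recipe_graph(db)
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        ids = [edge[0] for edge in cycle]
        raise CycleError(f"recipe cycle detected: {' -> '.join(ids + [ids[0]])}") from None


def _aggregate(db: FoodDB, composite_id: str, profiles: dict[str, NutrientProfile]) -> NutrientProfile:
    recipe = db.recipes[composite_id]
    post = recipe.post_weight
    if post <= 0:
        raise ValidationError(f"recipe {composite_id}: non-positive batch_post_weight")
    mono = di = total = energy = 0.0
    fructose: float | None = 0.0
    for c in recipe.components:
        p = profiles[c.ingredient_id]
        w = c.raw_weight / 100.0
        mono += w * p.monosaccharides
        di += w * p.disaccharides
        total += w * p.total_sugars
        energy += w * p.energy
        if fructose is not None:
            fructose = None if p.fructose is None else fructose + w * p.fructose
    scale = 100.0 / post
    out = NutrientProfile(
        monosaccharides=mono * scale,
        disaccharides=di * scale,
        total_sugars=total * scale,
        energy=energy * scale,
        fructose=None if fructose is None else fructose * scale,
    )
    assert out.total_sugars >= 0 and out.energy >= 0
    return out


def resolve_all_profiles(db: FoodDB) -> dict[str, NutrientProfile]:
    """Resolve every item's per-100 g profile bottom-up (memoised).

    Single items map to their own profile; composites are aggregated in
    topological order so shared sub-recipes are computed once.
    """
    order = topological_order(db)
    profiles: dict[str, NutrientProfile] = {}
    for iid in order:
        item = db.items[iid]
        if item.kind is Kind.SINGLE:
            assert item.profile is not None
            profiles[iid] = item.profile
        else:
            profiles[iid] = _aggregate(db, iid, profiles)
    return profiles


def resolve_profile(db: FoodDB, composite_id: str, cache: dict[str, NutrientProfile] | None = None) -> NutrientProfile:
    """Per-100 g profile of one finished (post-yield) composite food."""
    item = db.items.get(composite_id)
    if item is None:
        raise ValidationError(f"unknown item {composite_id!r}")
    if item.kind is Kind.SINGLE:
        assert item.profile is not None
        return item.profile
    if cache is not None and composite_id in cache:
        return cache[composite_id]
    profiles = resolve_all_profiles(db) if cache is None else cache
    if composite_id not in profiles:
        profiles.update(resolve_all_profiles(db))
    if cache is not None:
        cache.update(profiles)
    return profiles[composite_id]


def flatten_to_singles(db: FoodDB, item_id: str) -> dict[str, float]:
    """Expand nested recipes to single-item leaves.

    Returns the effective grams of each single item (in its finished form)
    contained in 100 g of the finished food.  For a single item this is
    ``{item_id: 100.0}``.  Summing leaf profiles weighted by these grams
    reproduces the recursively resolved profile.
    """
    if item_id not in db.items:
        raise ValidationError(f"unknown item {item_id!r}")
    order = topological_order(db)  # raises CycleError on cycles
    flat: dict[str, dict[str, float]] = {}
    for iid in order:
        item = db.items[iid]
        if item.kind is Kind.SINGLE:
            flat[iid] = {iid: 100.0}
        else:
            recipe = db.recipes[iid]
            scale = 100.0 / recipe.post_weight
            acc: dict[str, float] = {}
            for c in recipe.components:
                for leaf, grams in flat[c.ingredient_id].items():
                    acc[leaf] = acc.get(leaf, 0.0) + c.raw_weight * scale * grams / 100.0
            flat[iid] = acc
        if iid == item_id:
            return flat[iid]
    return flat[item_id]
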