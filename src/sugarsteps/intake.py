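"""Per-day intake computation and stratified survey summaries.

Converts dietary records (grams of each food consumed per participant-day)
plus per-100 g sugar estimates into daily intakes of added, free and total
sugars and energy, derives energy-percent (E%) values and produces the
stratified median (p25; p75) table with guideline-threshold adherence and
between-sex Mann–Whitney tests.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .food_model import FoodDB, ValidationError
from .recipe_engine import resolve_all_profiles
from .sugar_steps import SugarEstimate

__all__ = [
    "ENERGY_KJ_PER_G_SUGAR",
    "daily_intake",
    "energy_percent",
    "mann_whitney",
    "summarize",
]

#: kJ per gram of sugars (EU/NNR carbohydrate convention).
ENERGY_KJ_PER_G_SUGAR = 17.0

INTAKE_COLUMNS = ["added_g", "free_g", "total_g", "energy_kJ"]


def daily_intake(records: pd.DataFrame, estimates: dict[str, SugarEstimate],
                 db: FoodDB) -> pd.DataFrame:
    """Per participant-day intakes: sum over foods of grams × per-100 g value.

    Returns one row per (participant_id, day_index) with day_class and the
    four intake columns.  Unknown food ids raise, naming the record.
    """
    profiles = resolve_all_profiles(db)
    unknown = set(records["food_id"]) - set(estimates)
    if unknown:
        bad = records[records["food_id"].isin(unknown)].iloc[0]
        raise ValidationError(
            f"record participant {bad['participant_id']} day {bad['day_index']}: "
            f"unknown food_id {bad['food_id']!r}"
        )
    per100 = pd.DataFrame(
        {
            "food_id": list(estimates),
            "added_per100": [estimates[i].added_sugars for i in estimates],
            "free_per100": [estimates[i].free_sugars for i in estimates],
            "total_per100": [profiles[i].total_sugars for i in estimates],
            "energy_per100": [profiles[i].energy for i in estimates],
        }
    )
    merged = records.merge(per100, on="food_id", how="left")
    w = merged["amount_g"] / 100.0
    merged["added_g"] = w * merged["added_per100"]
    merged["free_g"] = w * merged["free_per100"]
    merged["total_g"] = w * merged["total_per100"]
    merged["energy_kJ"] = w * merged["energy_per100"]
    out = (
        merged.groupby(["participant_id", "day_index", "day_class"], as_index=False)[
            INTAKE_COLUMNS
        ]
        .sum()
        .sort_values(["participant_id", "day_index"])
        .reset_index(drop=True)
    )
    return out


def energy_percent(sugars_g, energy_kj, factor: float = ENERGY_KJ_PER_G_SUGAR):
    """Percent of total energy contributed by ``sugars_g`` grams of sugars.

    Vectorised; zero or missing energy yields NaN (flagged missing) with a
    warning rather than an error.
    """
    sugars = np.asarray(sugars_g, dtype=float)
    energy = np.asarray(energy_kj, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(energy > 0, sugars * factor / energy * 100.0, np.nan)
    if np.isnan(out).any():
        warnings.warn("zero energy intake: E%% undefined for some rows", stacklevel=2)
    if out.ndim == 0:
        return float(out)
    return out


def mann_whitney(x, y) -> float:
    """Two-sided Mann–Whitney U p-value for a between-sex comparison.

    Exact when both groups have at most 20 observations and no ties are
    present; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return float("nan")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (max(x.size, y.size) <= 20 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _quantiles(values: np.ndarray) -> tuple[float, float, float]:
    # linear interpolation between order statistics (numpy default)
    return (
        float(np.percentile(values, 50)),
        float(np.percentile(values, 25)),
        float(np.percentile(values, 75)),
    )


def _adherence_pct(values: np.ndarray, threshold: float) -> int:
    # share strictly below the threshold, rounded to integer percent
    return int(math.floor(np.mean(values < threshold) * 100 + 0.5))


def _stratum_row(label, sex_label, sub: pd.DataFrame, energy_factor: float) -> dict:
    row: dict = {"school_year": label, "sex": sex_label, "n": len(sub)}
    for col, short in (("added_g", "added_g"), ("free_g", "free_g"), ("total_g", "total_g")):
        med, p25, p75 = _quantiles(sub[col].to_numpy())
        row[f"{short}_median"] = med
        row[f"{short}_p25"] = p25
        row[f"{short}_p75"] = p75
        row[f"{short}_display"] = f"{med:.0f} ({p25:.0f}; {p75:.0f})"
    for col, short in (("added_g", "added_E"), ("free_g", "free_E"), ("total_g", "total_E")):
        e_pct = energy_percent(sub[col], sub["energy_kJ"], energy_factor)
        med, p25, p75 = _quantiles(np.asarray(e_pct))
        row[f"{short}_median"] = med
        row[f"{short}_p25"] = p25
        row[f"{short}_p75"] = p75
        row[f"{short}_display"] = f"{med:.0f} ({p25:.0f}; {p75:.0f})"
    added_e = np.asarray(energy_percent(sub["added_g"], sub["energy_kJ"], energy_factor))
    free_e = np.asarray(energy_percent(sub["free_g"], sub["energy_kJ"], energy_factor))
    row["adherence_added_lt10_pct"] = _adherence_pct(added_e, 10.0)
    row["adherence_free_lt10_pct"] = _adherence_pct(free_e, 10.0)
    row["adherence_free_lt5_pct"] = _adherence_pct(free_e, 5.0)
    return row


def summarize(usual_intakes: pd.DataFrame, participants: pd.DataFrame,
              energy_factor: float = ENERGY_KJ_PER_G_SUGAR) -> pd.DataFrame:
    """Stratified habitual-intake summary by school year × sex.

    One usual (habitual) intake row per participant is expected.  Emits one
    row per school year for All/Girl/Boy plus an overall row: medians and
    quartiles of g/day and E%, adherence to the 10% and 5% E% guideline
    thresholds (share strictly below, integer percent), and the two-sided
    Mann–Whitney p-value comparing girls and boys within each stratum
    (attached to the "all"-sex rows).
    """
    if usual_intakes["participant_id"].duplicated().any():
        raise ValidationError("expected one usual-intake row per participant")
    df = usual_intakes.merge(participants, on="participant_id", how="left", validate="1:1")
    if df["sex"].isna().any():
        bad = df.loc[df["sex"].isna(), "participant_id"].iloc[0]
        raise ValidationError(f"participant {bad!r} missing from roster")

    rows: list[dict] = []
    years = sorted(df["school_year"].unique())
    for year in years:
        ydf = df[df["school_year"] == year]
        if ydf.empty:
            warnings.warn(f"empty stratum: school year {year}; row omitted", stacklevel=2)
            continue
        row = _stratum_row(year, "all", ydf, energy_factor)
        girls = ydf[ydf["sex"] == "girl"]
        boys = ydf[ydf["sex"] == "boy"]
        row["mw_p_added_E"] = mann_whitney(
            energy_percent(girls["added_g"], girls["energy_kJ"], energy_factor),
            energy_percent(boys["added_g"], boys["energy_kJ"], energy_factor),
        )
        row["mw_p_free_E"] = mann_whitney(
            energy_percent(girls["free_g"], girls["energy_kJ"], energy_factor),
            energy_percent(boys["free_g"], boys["energy_kJ"], energy_factor),
        )
        rows.append(row)
        for sex, sub in (("girl", girls), ("boy", boys)):
            if sub.empty:
                warnings.warn(
                    f"empty stratum: year {year} {sex}; row omitted", stacklevel=2
                )
                continue
            rows.append(_stratum_row(year, sex, sub, energy_factor))
    overall = _stratum_row("all", "all", df, energy_factor)
    girls = df[df["sex"] == "girl"]
    boys = df[df["sex"] == "boy"]
    overall["mw_p_added_E"] = mann_whitney(
        energy_percent(girls["added_g"], girls["energy_kJ"], energy_factor),
        energy_percent(boys["added_g"], boys["energy_kJ"], energy_factor),
    )
    overall["mw_p_free_E"] = mann_whitney(
        energy_percent(girls["free_g"], girls["energy_kJ"], energy_factor),
        energy_percent(boys["free_g"], boys["energy_kJ"], energy_factor),
    )
    rows.append(overall)
    out = pd.DataFrame(rows)
    out.attrs["quantile_convention"] = "linear interpolation between order statistics"
    out.attrs["energy_factor_kJ_per_g"] = energy_factor
    return out
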