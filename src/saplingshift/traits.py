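"""Trait assembly: hierarchical imputation and seed-size classification.

Stems receive continuous trait values by a species -> genus -> family
fallback: the species-level value if one exists, otherwise the unweighted
mean of species-level values within the genus, otherwise within the family,
otherwise missing.  Means are over species (not stems), so abundant species
do not leak extra weight into genus/family means.

Seed-size dispersal limitation is a species-level flag: seed length
strictly greater than 18 mm, falling back to seed width strictly greater
than 12 mm when length is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SeedSizeClass",
    "impute_trait",
    "classify_seed_limitation",
    "count_limited_species",
]

PROVENANCE_LEVELS = ("species", "genus", "family", "missing")

SL_THRESHOLD_MM = 18.0
SW_THRESHOLD_MM = 12.0


@dataclass(frozen=True)
class SeedSizeClass:
    species_id: str
    limited: bool
    rule_used: str  # "SL>18mm" or "SW>12mm"


def impute_trait(
    stems: pd.DataFrame,
    traits: pd.DataFrame,
    trait: str,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Attach one trait to every stem with species->genus->family fallback.

    Parameters
    ----------
    stems
        One row per stem with columns ``species, genus, family`` (family may
        be null, in which case provenance is capped at genus).
    traits
        Species-level table with columns ``species, genus, family, <trait>``;
        null entries mean "no species-level value".
    trait
        Name of the trait column in ``traits``.

    Returns
    -------
    (assignments, coverage)
        ``assignments``: DataFrame aligned with ``stems`` (same index) with
        columns ``value`` and ``provenance``; ``coverage``: fraction of stems
        resolved at each provenance level (sums to 1).
    """
    if trait not in traits.columns:
        raise ValueError(f"trait column {trait!r} not in trait table")
    for col in ("species", "genus", "family"):
        if col not in stems.columns:
            raise ValueError(f"stem table missing column {col!r}")

    sp = traits.drop_duplicates("species").set_index("species")
    species_val = sp[trait]
    # genus/family means over species-level values only
    genus_mean = sp.groupby("genus", dropna=True)[trait].mean()
    family_mean = sp.dropna(subset=["family"]).groupby("family")[trait].mean()

    value = stems["species"].map(species_val)
    provenance = pd.Series(
        np.where(value.notna(), "species", "missing"), index=stems.index
    )

    need = value.isna()
    g_val = stems.loc[need, "genus"].map(genus_mean)
    value.loc[need] = g_val
    provenance.loc[need & value.notna()] = "genus"

    need = value.isna()
    f_val = stems.loc[need, "family"].map(family_mean)
    value.loc[need] = f_val
    provenance.loc[need & value.notna()] = "family"

    assignments = pd.DataFrame({"value": value, "provenance": provenance})
    n = len(stems)
    coverage = {
        level: (float((provenance == level).sum()) / n if n else 0.0)
        for level in PROVENANCE_LEVELS
    }
    return assignments, coverage


def classify_seed_limitation(
    species_id: str,
    sl_mm: float | None,
    sw_mm: float | None = None,
    *,
    sl_threshold: float = SL_THRESHOLD_MM,
    sw_threshold: float = SW_THRESHOLD_MM,
) -> SeedSizeClass:
    """Flag a species as potentially dispersal-limited by seed size.

    Seed length is the primary metric (strictly > 18 mm); seed width
    (strictly > 12 mm) is used only when length is unavailable.  Boundary
    values are NOT limited.
    """
    sl_ok = sl_mm is not None and not pd.isna(sl_mm)
    sw_ok = sw_mm is not None and not pd.isna(sw_mm)
    if sl_ok:
        return SeedSizeClass(species_id, bool(sl_mm > sl_threshold), "SL>18mm")
    if sw_ok:
        return SeedSizeClass(species_id, bool(sw_mm > sw_threshold), "SW>12mm")
    raise ValueError(f"species {species_id!r}: both SL and SW absent")


def count_limited_species(
    species_table: pd.DataFrame,
    *,
    sl_col: str = "sl_mm",
    sw_col: str = "sw_mm",
    mode_col: str = "dispersal_mode",
) -> dict[str, float | int | None]:
    """Count endozoochorous species flagged as seed-size limited.

    Counts distinct species (not stems).  Species with neither SL nor SW are
    excluded from both numerator and denominator of the fraction.
    """
    sp = species_table.drop_duplicates("species")
    endo = sp[sp[mode_col] == "endozoochory"]
    n_endo = int(len(endo))
    if n_endo == 0:
        return {"n_limited": 0, "n_endozoochorous": 0, "fraction": None}
    n_limited = 0
    n_classifiable = 0
    for row in endo.itertuples(index=False):
        sl = getattr(row, sl_col, None)
        sw = getattr(row, sw_col, None)
        try:
            cls = classify_seed_limitation(row.species, sl, sw)
        except ValueError:
            continue
        n_classifiable += 1
        n_limited += int(cls.limited)
    fraction = n_limited / n_classifiable if n_classifiable else None
    return {
        "n_limited": n_limited,
        "n_endozoochorous": n_endo,
        "fraction": fraction,
    }
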