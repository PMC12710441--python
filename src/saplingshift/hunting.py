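"""Plot-level hunting-pressure (HP) proxy.

The index summarizes the accessibility of a forest plot to hunters as the
sum of settlement population / distance ratios over the nearest village and
the two regional towns:

    HP = S_vil / d_vil + S_car / d_car + S_ita / d_ita

where ``S`` is a settlement's human population and ``d`` the distance (km)
from the plot centroid to that settlement (Euclidean for villages, fluvial
for towns; the distinction is the data supplier's responsibility and is
carried as metadata only).  HP is strictly increasing in every population
and strictly decreasing in every distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Settlement",
    "nearest_village",
    "hunting_pressure",
    "compute_hp_table",
]

VILLAGE = "village"
TOWN = "town"


@dataclass(frozen=True)
class Settlement:
    """A human settlement with its distance to one plot centroid."""

    name: str
    kind: str  # "village" or "town"
    population: float  # persons, >= 1
    distance_km: float  # > 0; Euclidean (villages) or fluvial (towns)

    def __post_init__(self) -> None:
        if self.kind not in (VILLAGE, TOWN):
            raise ValueError(f"settlement kind must be village|town, got {self.kind!r}")
        if self.population < 1:
            raise ValueError(f"settlement population must be >= 1, got {self.population}")
        if not self.distance_km > 0:
            raise ValueError(
                f"settlement distance must be > 0 km, got {self.distance_km} "
                f"(plot centroid coinciding with a settlement is outside the model)"
            )

    @property
    def pressure(self) -> float:
        """Population / distance contribution, persons per km."""
        return self.population / self.distance_km


def nearest_village(settlements: Iterable[Settlement]) -> Settlement:
    """Return the village minimizing distance; ties broken by name order."""
    villages = [s for s in settlements if s.kind == VILLAGE]
    if not villages:
        raise ValueError("no village among settlements")
    return min(villages, key=lambda s: (s.distance_km, s.name))


def hunting_pressure(
    village: Settlement,
    town_carauari: Settlement,
    town_itamarati: Settlement,
) -> float:
    """HP index for one plot: nearest village plus both towns.

    All three contributions are population/distance ratios (persons/km).
    """
    return village.pressure + town_carauari.pressure + town_itamarati.pressure


def hp_from_settlements(
    settlements: Sequence[Settlement],
    *,
    all_villages_within_km: float | None = None,
) -> float:
    """HP from one plot's settlement list (villages + exactly two towns).

    By default only the nearest village contributes.  For sensitivity
    analysis, ``all_villages_within_km`` switches to summing every village
    within that radius.
    """
    towns = sorted((s for s in settlements if s.kind == TOWN), key=lambda s: s.name)
    if len(towns) != 2:
        raise ValueError(f"expected exactly two towns per plot, got {len(towns)}")
    if all_villages_within_km is None:
        vil = nearest_village(settlements).pressure
    else:
        vils = [
            s
            for s in settlements
            if s.kind == VILLAGE and s.distance_km <= all_villages_within_km
        ]
        vil = sum(s.pressure for s in vils)
    return vil + towns[0].pressure + towns[1].pressure


def compute_hp_table(
    settlements: pd.DataFrame,
    *,
    all_villages_within_km: float | None = None,
) -> pd.DataFrame:
    """Per-plot HP from a settlement table.

    Parameters
    ----------
    settlements
        Columns ``plot_id, name, kind, population, distance_km``; one row per
        settlement per plot (distances are plot-specific).

    Returns
    -------
    DataFrame with columns ``plot_id, hp`` (one row per plot).
    """
    required = {"plot_id", "name", "kind", "population", "distance_km"}
    missing = required - set(settlements.columns)
    if missing:
        raise ValueError(f"settlement table missing columns: {sorted(missing)}")
    rows = []
    for plot_id, grp in settlements.groupby("plot_id", sort=True):
        objs = [
            Settlement(r.name_, r.kind, float(r.population), float(r.distance_km))
            for r in grp.rename(columns={"name": "name_"}).itertuples(index=False)
        ]
        rows.append(
            {
                "plot_id": plot_id,
                "hp": hp_from_settlements(
                    objs, all_villages_within_km=all_villages_within_km
                ),
            }
        )
    return pd.DataFrame(rows)
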