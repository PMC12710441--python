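"""Species-by-plot recruitment records.

Adult trees are censused on the full plot (default 0.25 ha) and saplings on
a nested subplot (default 0.05 ha), so abundances are converted to
per-hectare densities before the two life stages are compared.  Two
recruitment responses are built for every species with at least one
conspecific adult in a plot:

* ``sapling_present`` — 1 if at least one conspecific sapling occurs in the
  subplot, else 0 (the presence/absence analysis universe conditions on a
  conspecific adult being present);
* ``st_ratio`` — log10(sapling density / adult density), defined only where
  both stages were recorded at least once.  Positive values mean saplings
  outnumber conspecific adults on a per-hectare basis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["stem_density", "st_ratio", "build_recruitment_table"]

ADULT = "adult"
SAPLING = "sapling"


def stem_density(count: float, area_ha: float) -> float:
    """Stems per hectare."""
    if not area_ha > 0:
        raise ValueError(f"area must be > 0 ha, got {area_ha}")
    return count / area_ha


def st_ratio(d_sapling: float, d_tree: float) -> float:
    """log10 sapling-to-tree density ratio; both densities must be > 0."""
    if not (d_sapling > 0 and d_tree > 0):
        raise ValueError("st_ratio requires both densities > 0")
    return float(np.log10(d_sapling / d_tree))


def build_recruitment_table(stems: pd.DataFrame, plots: pd.DataFrame) -> pd.DataFrame:
    """One record per species x plot with >= 1 conspecific adult.

    Parameters
    ----------
    stems
        One row per stem; columns ``plot_id, species, stage`` with stage in
        {"adult", "sapling"}.  Stems with a null species label are dropped.
    plots
        Columns ``plot_id, tree_area_ha, sapling_area_ha``.

    Returns
    -------
    DataFrame with columns ``species, plot_id, n_adults, n_saplings, d_tree,
    d_sapling, sapling_present, st_ratio`` (st_ratio is NaN unless both
    stages have >= 1 stem).
    """
    for col in ("plot_id", "species", "stage"):
        if col not in stems.columns:
            raise ValueError(f"stem table missing column {col!r}")
    stems = stems.dropna(subset=["species"])
    bad = set(stems["stage"].unique()) - {ADULT, SAPLING}
    if bad:
        raise ValueError(f"unknown life stages: {sorted(bad)}")

    counts = (
        stems.groupby(["plot_id", "species", "stage"], sort=True)
        .size()
        .unstack("stage", fill_value=0)
        .reindex(columns=[ADULT, SAPLING], fill_value=0)
        .reset_index()
        .rename(columns={ADULT: "n_adults", SAPLING: "n_saplings"})
    )
    counts = counts[counts["n_adults"] >= 1].copy()

    areas = plots.set_index("plot_id")[["tree_area_ha", "sapling_area_ha"]]
    counts = counts.join(areas, on="plot_id")
    if counts["tree_area_ha"].isna().any():
        missing = counts.loc[counts["tree_area_ha"].isna(), "plot_id"].unique()
        raise ValueError(f"plots absent from plot table: {sorted(missing)}")

    counts["d_tree"] = counts["n_adults"] / counts["tree_area_ha"]
    counts["d_sapling"] = counts["n_saplings"] / counts["sapling_area_ha"]
    counts["sapling_present"] = (counts["n_saplings"] >= 1).astype(int)
    both = (counts["n_adults"] >= 1) & (counts["n_saplings"] >= 1)
    counts["st_ratio"] = np.where(
        both, np.log10(counts["d_sapling"].where(both) / counts["d_tree"]), np.nan
    )
    return counts[
        [
            "species",
            "plot_id",
            "n_adults",
            "n_saplings",
            "d_tree",
            "d_sapling",
            "sapling_present",
            "st_ratio",
        ]
    ].reset_index(drop=True)
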