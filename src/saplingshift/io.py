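"""Reading and writing the pipeline's tables.

Everything round-trips through delimited UTF-8 text (CSV with a header
row).  Real inventories may also arrive as a spreadsheet workbook; because
workbook sheet and column names vary between data suppliers, XLSX ingestion
goes through a small user-editable column-mapping file (YAML) that names,
for each of the three input tables, the sheet and the column renames needed
to reach the package's canonical columns:

    stems:  {sheet: ..., columns: {<source>: <canonical>, ...}}
    traits: {sheet: ..., columns: {...}}
    plots:  {sheet: ..., columns: {...}}

Canonical columns: stems -> plot_id, stage, species, genus, family, dbh_cm;
traits -> species, genus, family, dispersal_mode, sl_mm, sw_mm, sm_g,
wd_gcm3, lma_gcm2; plots -> plot_id, site_id, hp, cec, vdnd, tree_area_ha,
sapling_area_ha.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd
import yaml

__all__ = [
    "read_table",
    "write_table",
    "read_newick",
    "write_newick",
    "load_xlsx_inputs",
]

STEM_COLUMNS = ["plot_id", "stage", "species", "genus", "family", "dbh_cm"]
TRAIT_COLUMNS = [
    "species",
    "genus",
    "family",
    "dispersal_mode",
    "sl_mm",
    "sw_mm",
    "sm_g",
    "wd_gcm3",
    "lma_gcm2",
]
PLOT_COLUMNS = ["plot_id", "site_id", "hp", "cec", "vdnd", "tree_area_ha", "sapling_area_ha"]


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tree.write(path=str(path), schema="newick")
    return path


def _require(df: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing required columns: {missing}")
    return df


def load_xlsx_inputs(
    workbook: str | Path, mapping: str | Path | dict
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load (stems, traits, plots) from a workbook via a mapping file."""
    if not isinstance(mapping, dict):
        with open(mapping, "r", encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh)
    out = {}
    for key, required in (
        ("stems", STEM_COLUMNS),
        ("traits", TRAIT_COLUMNS),
        ("plots", PLOT_COLUMNS),
    ):
        sheet_map = mapping[key]
        df = pd.read_excel(workbook, sheet_name=sheet_map["sheet"])
        df = df.rename(columns=sheet_map.get("columns", {}))
        out[key] = _require(df, required, key)
    return out["stems"], out["traits"], out["plots"]
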