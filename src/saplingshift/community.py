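"""Basal area and basal-area-weighted community mean traits (CWM).

CWM_j = sum_i BA_ji * T_i / sum_i BA_ji over the stems i of plot j (and one
life stage), where BA = pi * (DBH/2)^2.  Only stems whose trait value is
known at the species level or imputed at the genus level enter a CWM;
family-level imputations are kept for coverage reporting but excluded here.
For saplings "DBH" is the diameter at the point of measurement and the same
formula applies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["basal_area", "cwm", "cwm_table", "CWMRecord"]

log = logging.getLogger(__name__)

CWM_ELIGIBLE_PROVENANCE = ("species", "genus")


@dataclass(frozen=True)
class CWMRecord:
    plot_id: str
    life_stage: str
    trait: str
    cwm: float
    total_ba: float  # cm^2
    n_stems_used: int


def basal_area(dbh_cm: float) -> float:
    """Stem cross-sectional area pi*(DBH/2)^2 in cm^2."""
    if not dbh_cm > 0:
        raise ValueError(f"DBH must be > 0 cm, got {dbh_cm}")
    return math.pi * (dbh_cm / 2.0) ** 2


def cwm(
    stems: pd.DataFrame,
    plot_id: str,
    life_stage: str,
    trait: str,
    *,
    weight: str = "basal_area",
) -> CWMRecord | None:
    """Basal-area-weighted mean of one trait for one plot and life stage.

    ``stems`` must carry columns ``plot_id, stage, dbh_cm, {trait},
    {trait}_provenance``.  Stems with family-level or missing provenance are
    excluded.  Returns None (with a logged warning) when no stem is
    eligible.  ``weight="count"`` gives the unweighted (stem-count) variant
    for sensitivity analysis.
    """
    sel = stems[(stems["plot_id"] == plot_id) & (stems["stage"] == life_stage)]
    prov = sel[f"{trait}_provenance"]
    sel = sel[prov.isin(CWM_ELIGIBLE_PROVENANCE) & sel[trait].notna()]
    if sel.empty:
        log.warning(
            "no eligible stems for CWM (plot=%s stage=%s trait=%s)",
            plot_id,
            life_stage,
            trait,
        )
        return None
    ba = np.pi * (sel["dbh_cm"].to_numpy() / 2.0) ** 2
    w = ba if weight == "basal_area" else np.ones_like(ba)
    t = sel[trait].to_numpy(dtype=float)
    return CWMRecord(
        plot_id=plot_id,
        life_stage=life_stage,
        trait=trait,
        cwm=float(np.average(t, weights=w)),
        total_ba=float(ba.sum()),
        n_stems_used=int(len(sel)),
    )


def cwm_table(
    stems: pd.DataFrame,
    traits: list[str],
    *,
    weight: str = "basal_area",
) -> pd.DataFrame:
    """CWM for every plot x life stage x trait combination present.

    Returns a DataFrame with columns ``plot_id, life_stage, trait, cwm,
    total_ba, n_stems_used``; combinations with no eligible stems are
    omitted.
    """
    records = []
    for plot_id in sorted(stems["plot_id"].unique()):
        for stage in sorted(stems.loc[stems["plot_id"] == plot_id, "stage"].unique()):
            for trait in traits:
                rec = cwm(stems, plot_id, stage, trait, weight=weight)
                if rec is not None:
                    records.append(rec.__dict__)
    return pd.DataFrame(records)
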