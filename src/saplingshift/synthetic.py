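"""Synthetic species pools, landscapes and stem inventories.

The generator emulates the study conditions of a hunting-gradient forest
inventory: 15 sites each holding two 0.25-ha tree plots with nested 0.05-ha
sapling subplots, a hunting-pressure (HP) index spanning roughly 2.4-13.8,
and a species pool dominated by endozoochory (~79% of species, vs ~12%
abiotic and ~9% scatter-hoarded).  Per-mode trait distributions follow the
qualitative orderings reported for such assemblages: wood density highest
in scatter-hoarded species; leaf mass per area ordered scatter-hoarded >
endozoochorous > abiotic; seed length similar in scatter-hoarded and
abiotic species and smaller in endozoochorous ones, with positive
trait correlations within endozoochorous species and a negative wood
density-seed length correlation within abiotic species.

Ground truth (HP slopes per mode, an HP x seed-length interaction for
endozoochorous species, covariate effects, random-intercept SDs) is stored
with every simulated inventory so that model-recovery tests have a known
answer.  Adult abundances are independent of HP (negative binomial on a
lognormal species-abundance distribution); sapling counts are Poisson with
a log-mean that embeds the ground-truth effect structure plus the plot /
subplot area ratio, so that with all effects zero the sapling and adult
per-hectare densities match the configured density ratio exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from . import hunting

__all__ = [
    "MODES",
    "GroundTruth",
    "Landscape",
    "Inventory",
    "generate_species_pool",
    "generate_landscape",
    "generate_inventory",
    "pure_birth_tree",
]

MODES = ("abiotic", "scatter_hoarded", "endozoochory")
DEFAULT_MODE_PROPS = (0.121, 0.088, 0.791)

TREE_PLOT_HA = 0.25
SAPLING_SUBPLOT_HA = 0.05

TOWN_POPULATIONS = {"Carauari": 28076, "Itamarati": 7888}

# Per-mode lognormal trait parameters (meanlog, sdlog).  Chosen to
# reproduce the qualitative orderings above; endozoochorous seed length is
# calibrated so ~29% of endozoochorous species exceed the 18-mm limitation
# threshold and the mode mean sits slightly below it.
TRAIT_PARAMS = {
    "abiotic": {"sl": (3.00, 0.55), "wd": (np.log(0.60), 0.16), "lma": (np.log(0.0078), 0.22)},
    "scatter_hoarded": {"sl": (3.05, 0.50), "wd": (np.log(0.74), 0.15), "lma": (np.log(0.0115), 0.22)},
    "endozoochory": {"sl": (2.56, 0.60), "wd": (np.log(0.60), 0.16), "lma": (np.log(0.0095), 0.22)},
}
WD_BOUNDS = (0.105, 1.195)

DEFAULT_MISSING = {"wd_gcm3": 0.25, "lma_gcm2": 0.30, "sl_mm": 0.15, "sw_mm": 0.35, "sm_g": 0.40}

TRAIT_COLS = ("sl_mm", "sw_mm", "sm_g", "wd_gcm3", "lma_gcm2")


@dataclass(frozen=True)
class GroundTruth:
    """Effect structure injected into a simulated inventory.

    Slopes act on standardized predictors (z-scores across plots, and
    z(seed length) across endozoochorous species) on the log scale of the
    sapling Poisson mean.
    """

    beta_hp_by_mode: dict[str, float] = field(
        default_factory=lambda: {m: 0.0 for m in MODES}
    )
    beta_hp_x_sl: float = 0.0
    beta_cec: float = 0.0
    beta_vdnd: float = 0.0
    sigma_species: float = 0.3
    sigma_family: float = 0.15
    log_density_ratio: float = float(np.log(6.4))  # sapling:adult per-ha density
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [*self.beta_hp_by_mode.values(), self.beta_hp_x_sl, self.beta_cec, self.beta_vdnd]
        if not all(np.isfinite(vals)):
            raise ValueError("ground-truth effects must be finite")
        if self.sigma_species < 0 or self.sigma_family < 0:
            raise ValueError("random-effect SDs must be >= 0")


@dataclass
class Landscape:
    sites: list[str]
    plots: pd.DataFrame  # plot_id, site_id, hp, cec, vdnd, tree_area_ha, sapling_area_ha
    settlements: pd.DataFrame  # plot_id, name, kind, population, distance_km


@dataclass
class Inventory:
    stems: pd.DataFrame  # stem_id, plot_id, site_id, stage, species, genus, family, dbh_cm
    truth: GroundTruth
    expected_sapling_mean: pd.DataFrame  # species x plot Poisson means (diagnostic)

    def truth_dict(self) -> dict:
        return asdict(self.truth)


def _correlated_lognormals(rng, n, params, corr):
    """Draw (sl, wd, lma) with a Gaussian copula on the log scale."""
    L = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 3)) @ L.T
    sl = np.exp(params["sl"][0] + params["sl"][1] * z[:, 0])
    wd = np.exp(params["wd"][0] + params["wd"][1] * z[:, 1])
    lma = np.exp(params["lma"][0] + params["lma"][1] * z[:, 2])
    return sl, np.clip(wd, *WD_BOUNDS), lma


def generate_species_pool(
    n_species: int = 300,
    mode_props: tuple[float, float, float] = DEFAULT_MODE_PROPS,
    seed: int = 0,
    *,
    endo_rho: float = 0.3,
    abiotic_wd_sl_rho: float = -0.45,
    missing: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Generate a species pool with modes, taxonomy and correlated traits.

    Returns a DataFrame with one row per species: observed trait columns
    (with missingness for the imputation machinery to exercise), hidden
    ``*_true`` columns used by the inventory generator, and per-trait
    provenance ("species" where observed, "missing" otherwise).
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    props = np.asarray(mode_props, dtype=float)
    if props.shape != (3,) or (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"mode proportions must be 3 non-negative values summing to 1, got {mode_props}"
        )
    rng = np.random.default_rng(seed)
    modes = rng.choice(MODES, size=n_species, p=props)

    # taxonomy sized so genus- and family-level fallbacks both occur
    n_genera = max(2, round(n_species / 3.2))
    n_families = max(2, round(n_genera / 4))
    genus_family = rng.integers(0, n_families, size=n_genera)
    genus_w = np.exp(rng.normal(0.0, 1.0, size=n_genera))
    genus_of = rng.choice(n_genera, size=n_species, p=genus_w / genus_w.sum())

    corr_by_mode = {
        "abiotic": np.array(
            [[1.0, abiotic_wd_sl_rho, 0.0], [abiotic_wd_sl_rho, 1.0, 0.0], [0.0, 0.0, 1.0]]
        ),
        "scatter_hoarded": np.eye(3),
        "endozoochory": np.array(
            [[1.0, endo_rho, endo_rho], [endo_rho, 1.0, endo_rho], [endo_rho, endo_rho, 1.0]]
        ),
    }
    sl = np.empty(n_species)
    wd = np.empty(n_species)
    lma = np.empty(n_species)
    for mode in MODES:
        sel = modes == mode
        if sel.sum() == 0:
            continue
        s, w, l = _correlated_lognormals(rng, int(sel.sum()), TRAIT_PARAMS[mode], corr_by_mode[mode])
        sl[sel], wd[sel], lma[sel] = s, w, l
    sw = sl * np.exp(rng.normal(np.log(0.7), 0.15, size=n_species))
    sm = 5e-4 * sl**2.5 * np.exp(rng.normal(0.0, 0.5, size=n_species))

    pool = pd.DataFrame(
        {
            "species": [f"sp{i:04d}" for i in range(n_species)],
            "genus": [f"gen{g:03d}" for g in genus_of],
            "family": [f"fam{genus_family[g]:02d}" for g in genus_of],
            "dispersal_mode": modes,
            "sl_mm": sl,
            "sw_mm": sw,
            "sm_g": sm,
            "wd_gcm3": wd,
            "lma_gcm2": lma,
        }
    )
    for col in TRAIT_COLS:
        pool[f"true_{col}"] = pool[col]
    miss = DEFAULT_MISSING if missing is None else missing
    for col, frac in miss.items():
        drop = rng.random(n_species) < frac
        pool.loc[drop, col] = np.nan
    for col in TRAIT_COLS:
        pool[f"{col}_provenance"] = np.where(pool[col].notna(), "species", "missing")
    return pool


def generate_landscape(
    n_sites: int = 15,
    hp_range: tuple[float, float] = (2.4, 13.8),
    seed: int = 0,
    *,
    plots_per_site: int = 2,
) -> Landscape:
    """Generate sites, plots, covariates and the settlement geometry.

    Target HP values are log-spaced across plots so the realized index
    spans ``hp_range`` inclusively; settlement populations are drawn and
    their distances solved so that the HP computed from the settlement
    table reproduces the targets exactly.  CEC is right-skewed positive
    (lognormal) and VDND non-negative (gamma), both matching the reported
    plot-covariate scales.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    lo, hi = float(hp_range[0]), float(hp_range[1])
    if not (lo > 0 and hi >= lo):
        raise ValueError(f"invalid hp_range {hp_range}")
    rng = np.random.default_rng(seed)
    n_plots = n_sites * plots_per_site
    # right-skewed spacing: most plots sit at the lightly hunted end, a few
    # peri-urban plots carry the heavy tail (mean ~ 4.6 for the default range)
    u = np.linspace(0.0, 1.0, n_plots)
    targets = lo * (hi / lo) ** (u**2.6)
    # adjacent targets share a site; site order shuffled for realism
    order = rng.permutation(n_sites)

    sites = [f"S{i + 1:02d}" for i in range(n_sites)]
    plot_rows = []
    settlement_rows = []
    k = 0
    for si, site_i in enumerate(order):
        for p in range(plots_per_site):
            hp_target = targets[si * plots_per_site + p]
            plot_id = f"P{k + 1:02d}"
            site_id = sites[site_i]
            # split the index between the nearest village and the two towns
            f_vil, f_car, f_ita = 0.5, 0.3, 0.2
            pop_vil = int(rng.integers(50, 251))
            d_vil = pop_vil / (f_vil * hp_target)
            d_car = TOWN_POPULATIONS["Carauari"] / (f_car * hp_target)
            d_ita = TOWN_POPULATIONS["Itamarati"] / (f_ita * hp_target)
            settlement_rows += [
                {"plot_id": plot_id, "name": f"village_{plot_id}", "kind": "village", "population": pop_vil, "distance_km": d_vil},
                {"plot_id": plot_id, "name": "Carauari", "kind": "town", "population": TOWN_POPULATIONS["Carauari"], "distance_km": d_car},
                {"plot_id": plot_id, "name": "Itamarati", "kind": "town", "population": TOWN_POPULATIONS["Itamarati"], "distance_km": d_ita},
            ]
            plot_rows.append({"plot_id": plot_id, "site_id": site_id})
            k += 1
    plots = pd.DataFrame(plot_rows)
    settlements = pd.DataFrame(settlement_rows)
    hp = hunting.compute_hp_table(settlements).set_index("plot_id")["hp"]
    plots["hp"] = plots["plot_id"].map(hp)
    plots["cec"] = rng.lognormal(mean=np.log(0.6), sigma=0.85, size=n_plots)
    plots["vdnd"] = rng.gamma(shape=1.8, scale=9.0, size=n_plots)
    plots["tree_area_ha"] = TREE_PLOT_HA
    plots["sapling_area_ha"] = SAPLING_SUBPLOT_HA
    return Landscape(sites=sites, plots=plots, settlements=settlements)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_inventory(
    pool: pd.DataFrame,
    landscape: Landscape,
    truth: GroundTruth,
    *,
    mean_adults_per_plot: float = 160.0,
) -> Inventory:
    """Simulate the stem inventory given a pool, landscape and ground truth.

    Adult counts per species x plot are negative binomial (dispersion 1) on
    a lognormal species-abundance distribution, independent of HP.  Sapling
    counts are Poisson with log-mean

        log(mu_adult * subplot/plot area ratio) + log density ratio
        + beta_mode(HP slope) * z(HP) [per dispersal mode]
        + beta_hp_x_sl * z(HP) * z(SL)   [endozoochorous species only]
        + beta_cec * z(CEC) + beta_vdnd * z(VDND)
        + species and family random intercepts.

    Adult DBH >= 10 cm; sapling diameters uniform on [1, 5] cm.
    """
    rng = np.random.default_rng(truth.seed)
    plots = landscape.plots
    n_sp, n_plots = len(pool), len(plots)

    z_hp = _zscore(plots["hp"].to_numpy())
    z_cec = _zscore(plots["cec"].to_numpy())
    z_vdnd = _zscore(plots["vdnd"].to_numpy())

    endo = (pool["dispersal_mode"] == "endozoochory").to_numpy()
    sl_true = pool["true_sl_mm"].to_numpy(dtype=float)
    z_sl = np.zeros(n_sp)
    if endo.any():
        z_sl[endo] = _zscore(np.log(sl_true[endo]))

    # lognormal SAD; scale so E[plot total adults] hits the target
    log_abund = rng.normal(0.0, 1.0, size=n_sp)
    lam_adult = np.exp(log_abund)
    lam_adult *= mean_adults_per_plot / lam_adult.sum()

    u_species = rng.normal(0.0, truth.sigma_species, size=n_sp)
    families = pool["family"].to_numpy()
    fam_levels, fam_idx = np.unique(families, return_inverse=True)
    u_family = rng.normal(0.0, truth.sigma_family, size=len(fam_levels))[fam_idx]

    beta_mode = np.array([truth.beta_hp_by_mode.get(m, 0.0) for m in pool["dispersal_mode"]])

    # species x plot expected counts
    A = np.tile(lam_adult[:, None], (1, n_plots))
    eta = (
        np.log(A * (SAPLING_SUBPLOT_HA / TREE_PLOT_HA))
        + truth.log_density_ratio
        + beta_mode[:, None] * z_hp[None, :]
        + (endo * truth.beta_hp_x_sl * z_sl)[:, None] * z_hp[None, :]
        + truth.beta_cec * z_cec[None, :]
        + truth.beta_vdnd * z_vdnd[None, :]
        + (u_species + u_family)[:, None]
    )
    mu_sap = np.exp(eta)

    # negative binomial with size 1: gamma-Poisson mixture
    gam = rng.gamma(shape=1.0, scale=A)
    n_adults = rng.poisson(gam)
    n_saplings = rng.poisson(mu_sap)

    sp_i, pl_j = np.nonzero(n_adults + n_saplings)
    rows = []
    species = pool["species"].to_numpy()
    genus = pool["genus"].to_numpy()
    plot_ids = plots["plot_id"].to_numpy()
    site_ids = plots["site_id"].to_numpy()
    for i, j in zip(sp_i, pl_j):
        na, ns = int(n_adults[i, j]), int(n_saplings[i, j])
        if na:
            dbh = 10.0 * np.exp(rng.exponential(0.35, size=na))
            for d in dbh:
                rows.append((plot_ids[j], site_ids[j], "adult", species[i], genus[i], families[i], float(d)))
        if ns:
            dbh = rng.uniform(1.0, 5.0, size=ns)
            for d in dbh:
                rows.append((plot_ids[j], site_ids[j], "sapling", species[i], genus[i], families[i], float(d)))
    stems = pd.DataFrame(
        rows,
        columns=["plot_id", "site_id", "stage", "species", "genus", "family", "dbh_cm"],
    )
    stems.insert(0, "stem_id", [f"stem{n:06d}" for n in range(len(stems))])

    expected = pd.DataFrame(mu_sap, index=species, columns=plot_ids)
    return Inventory(stems=stems, truth=truth, expected_sapling_mean=expected)


def pure_birth_tree(species: list[str], seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree over the given species ids, branch lengths in
    arbitrary time units."""
    import random as _random

    from dendropy.model import birthdeath

    taxa = dendropy.TaxonNamespace(species)
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=len(species),
        taxon_namespace=taxa,
        rng=_random.Random(seed),
    )
    # the simulation stops exactly at the n-th birth, which leaves
    # zero-length terminal branches; extend every tip by a further draw
    # from the waiting-time distribution so tips are distinct
    ext = np.random.default_rng(seed).exponential(1.0 / len(species), size=len(species))
    leaves = list(tree.leaf_node_iter())
    for leaf, e in zip(leaves, ext):
        leaf.edge.length = (leaf.edge.length or 0.0) + float(e)
    # bind every leaf to one of the requested species labels
    for leaf, name in zip(leaves, species):
        leaf.taxon = taxa.get_taxon(name) or taxa.new_taxon(name)
    return tree
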