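import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from saplingshift import recruitment, synthetic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def zscore(x: pd.Series) -> pd.Series:
    return (x - x.mean()) / x.std(ddof=0)


def build_records(pool, landscape, inventory, *, plot_level_z=False):
    """Recruitment table joined with species modes and plot covariates."""
    rec = recruitment.build_recruitment_table(inventory.stems, landscape.plots)
    sp = pool.drop_duplicates("species").set_index("species")
    rec = rec.join(sp[["dispersal_mode", "family", "sl_mm", "true_sl_mm"]], on="species")
    pl = landscape.plots.set_index("plot_id")
    if plot_level_z:
        for c in ("hp", "cec", "vdnd"):
            rec[c] = rec["plot_id"].map(zscore(pl[c]))
    else:
        rec = rec.join(pl[["hp", "cec", "vdnd"]], on="plot_id")
    return rec


def simulate_study(
    seed,
    *,
    n_species=120,
    n_sites=15,
    truth_kwargs=None,
    plot_level_z=False,
):
    """One synthetic study: (pool, landscape, inventory, recruitment records)."""
    pool = synthetic.generate_species_pool(n_species, seed=seed)
    land = synthetic.generate_landscape(n_sites, seed=seed + 7_000_000)
    truth = synthetic.GroundTruth(seed=seed + 14_000_000, **(truth_kwargs or {}))
    inv = synthetic.generate_inventory(pool, land, truth)
    rec = build_records(pool, land, inv, plot_level_z=plot_level_z)
    return pool, land, inv, rec


@pytest.fixture(scope="session")
def null_study():
    """A medium synthetic study with no injected hunting effects."""
    return simulate_study(421)


@pytest.fixture(scope="session")
def effect_study():
    """A synthetic study with opposing HP slopes by dispersal mode and a
    negative HP x seed-length interaction among endozoochorous species."""
    return simulate_study(
        91,
        n_species=300,
        truth_kwargs={
            "beta_hp_by_mode": {
                "abiotic": 0.15,
                "scatter_hoarded": 0.15,
                "endozoochory": -0.3,
            },
            "beta_hp_x_sl": -0.3,
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
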