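import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saplingshift import synthetic
from saplingshift.synthetic import (
    GroundTruth,
    generate_inventory,
    generate_landscape,
    generate_species_pool,
)


class TestSpeciesPool:
    def test_mode_frequencies_within_binomial_bounds(self):
        n = 1000
        pool = generate_species_pool(n, (0.121, 0.088, 0.791), seed=17)
        freq = pool["dispersal_mode"].value_counts()
        for mode, p in zip(synthetic.MODES, (0.121, 0.088, 0.791)):
            lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
            assert lo <= freq.get(mode, 0) <= hi

    def test_degenerate_proportions(self):
        pool = generate_species_pool(3, (1.0, 0.0, 0.0), seed=0)
        assert (pool["dispersal_mode"] == "abiotic").all()

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="proportions"):
            generate_species_pool(10, (0.5, 0.5, 0.5))

    def test_endo_copula_correlation_recovered(self):
        pool = generate_species_pool(5000, (0.0, 0.0, 1.0), seed=23, endo_rho=0.3)
        r = np.corrcoef(np.log(pool["true_sl_mm"]), np.log(pool["true_wd_gcm3"]))[0, 1]
        assert r == pytest.approx(0.3, abs=0.05)

    def test_trait_orderings_match_study_pattern(self):
        pool = generate_species_pool(3000, seed=29)
        med = pool.groupby("dispersal_mode")[
            ["true_wd_gcm3", "true_lma_gcm2", "true_sl_mm"]
        ].median()
        # WD: scatter-hoarded > endozoochory ~ abiotic
        assert med.loc["scatter_hoarded", "true_wd_gcm3"] > med.loc["endozoochory", "true_wd_gcm3"]
        assert med.loc["endozoochory", "true_wd_gcm3"] == pytest.approx(
            med.loc["abiotic", "true_wd_gcm3"], rel=0.1
        )
        # LMA: scatter > endo > abiotic
        assert (
            med.loc["scatter_hoarded", "true_lma_gcm2"]
            > med.loc["endozoochory", "true_lma_gcm2"]
            > med.loc["abiotic", "true_lma_gcm2"]
        )
        # SL: scatter ~ abiotic > endo
        assert med.loc["scatter_hoarded", "true_sl_mm"] > med.loc["endozoochory", "true_sl_mm"]
        assert med.loc["abiotic", "true_sl_mm"] > med.loc["endozoochory", "true_sl_mm"]

    def test_abiotic_wd_sl_negative_correlation(self):
        pool = generate_species_pool(4000, (1.0, 0.0, 0.0), seed=31)
        r = np.corrcoef(np.log(pool["true_sl_mm"]), np.log(pool["true_wd_gcm3"]))[0, 1]
        assert r < -0.3

    def test_wd_bounds(self):
        pool = generate_species_pool(3000, seed=3)
        assert pool["true_wd_gcm3"].between(0.1, 1.2).all()

    def test_taxonomy_supports_fallbacks(self):
        pool = generate_species_pool(300, seed=5)
        assert (pool.groupby("genus").size() > 1).any()
        assert pool.groupby("family")["genus"].nunique().max() > 1


class TestLandscape:
    def test_default_scale_and_hp_span(self):
        land = generate_landscape(15, (2.4, 13.8), seed=1)
        assert len(land.plots) == 30
        assert land.plots["site_id"].value_counts().eq(2).all()
        assert land.plots["hp"].min() <= 2.6
        assert land.plots["hp"].max() >= 13.0
        assert (land.plots["tree_area_ha"] == 0.25).all()
        assert (land.plots["sapling_area_ha"] == 0.05).all()
        assert (land.plots["vdnd"] >= 0).all()
        assert (land.plots["cec"] > 0).all()

    def test_degenerate_range(self):
        land = generate_landscape(2, (5.0, 5.0), seed=0)
        assert land.plots["hp"].to_numpy() == pytest.approx([5.0] * 4)

    def test_deterministic_under_seed(self):
        a = generate_landscape(6, seed=9)
        b = generate_landscape(6, seed=9)
        pd.testing.assert_frame_equal(a.plots, b.plots)
        pd.testing.assert_frame_equal(a.settlements, b.settlements)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            generate_landscape(1)


@pytest.fixture(scope="module")
def study():
    pool = generate_species_pool(150, seed=41)
    land = generate_landscape(10, seed=42)
    truth = GroundTruth(seed=43)
    return pool, land, generate_inventory(pool, land, truth)


class TestInventory:
    def test_stage_diameter_legality(self, study):
        _, _, inv = study
        adults = inv.stems[inv.stems["stage"] == "adult"]
        saps = inv.stems[inv.stems["stage"] == "sapling"]
        assert (adults["dbh_cm"] >= 10.0).all()
        assert saps["dbh_cm"].between(1.0, 5.0).all()

    def test_byte_identical_under_seed(self):
        pool = generate_species_pool(60, seed=7)
        land = generate_landscape(4, seed=8)
        a = generate_inventory(pool, land, GroundTruth(seed=9))
        b = generate_inventory(pool, land, GroundTruth(seed=9))
        assert a.stems.to_csv(index=False) == b.stems.to_csv(index=False)

    def test_sapling_total_tracks_expected_mean(self, study):
        # Poisson totals concentrate: realized total within 5% of the summed
        # expected means stored alongside the inventory
        _, _, inv = study
        expected = inv.expected_sapling_mean.to_numpy().sum()
        realized = (inv.stems["stage"] == "sapling").sum()
        assert realized == pytest.approx(expected, rel=0.05)

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(sigma_species=-1.0)
        with pytest.raises(ValueError):
            GroundTruth(beta_cec=np.inf)

    def test_equal_density_null_centers_st_near_zero(self, rng):
        # equal per-ha densities: adult counts Poisson(mu) on 0.25 ha and
        # sapling counts Poisson(mu/5) on 0.05 ha; the area normalization
        # must center mean S:T at ~0 once counts are large
        from saplingshift.recruitment import build_recruitment_table

        mu = 60.0
        rows = []
        for p in range(40):
            for s in range(10):
                for stage, lam in (("adult", mu), ("sapling", mu / 5)):
                    n = rng.poisson(lam)
                    rows += [
                        {"plot_id": f"P{p}", "species": f"s{s}", "stage": stage}
                    ] * n
        plots = pd.DataFrame(
            {
                "plot_id": [f"P{p}" for p in range(40)],
                "tree_area_ha": 0.25,
                "sapling_area_ha": 0.05,
            }
        )
        rec = build_recruitment_table(pd.DataFrame(rows), plots)
        st = rec["st_ratio"].dropna()
        assert len(st) > 350
        assert abs(st.mean()) < 0.03
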