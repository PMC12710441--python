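"""End-to-end orchestration of the analysis.

``run_pipeline`` sequences the whole study on either synthetic or supplied
inputs: hunting-pressure context, trait assembly with hierarchical
imputation, the recruitment table, the three mixed/linear model fits,
basal-area-weighted community means and their linear models, trait
correlations and pairwise mode tests, and the Pagel's-lambda residual
diagnostic.  Every table is written as delimited text in the run directory
together with a structured log and the configuration (echoed verbatim and
hashed), so each reported number is recomputable from the intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, io, models, phylo, recruitment, traits
from . import synthetic as synth

__all__ = ["RunConfig", "run_pipeline", "summarize_inventory"]

log = logging.getLogger("saplingshift.pipeline")

CWM_TRAITS = ["wd_gcm3", "lma_gcm2", "sl_mm"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    synthetic: bool = True
    # synthetic scale (defaults follow the study design)
    n_sites: int = 15
    n_species: int = 300
    hp_range: tuple[float, float] = (2.4, 13.8)
    mode_props: tuple[float, float, float] = synth.DEFAULT_MODE_PROPS
    truth: dict = field(default_factory=dict)  # GroundTruth overrides
    # real-data inputs (synthetic=False)
    stems_path: str | None = None
    traits_path: str | None = None
    plots_path: str | None = None
    tree_path: str | None = None
    xlsx_path: str | None = None
    xlsx_mapping: str | None = None
    # analysis options
    standardize: bool = True
    sl_threshold_mm: float = 18.0
    sw_threshold_mm: float = 12.0
    collinearity_threshold: float = 0.7
    glmm_link: str = "logit"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("hp_range", "mode_props"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def summarize_inventory(stems: pd.DataFrame, trait_table: pd.DataFrame) -> dict:
    """Inventory summary: counts by stage and taxon, mode shares."""
    if stems.empty:
        return {
            "n_trees": 0,
            "n_saplings": 0,
            "n_species": 0,
            "n_genera": 0,
            "n_families": 0,
            "total_tree_area_ha": 0.0,
            "mode_share_species": {},
            "mode_share_trees": {},
            "mode_share_saplings": {},
        }
    mode_of = trait_table.drop_duplicates("species").set_index("species")["dispersal_mode"]
    st = stems.copy()
    st["dispersal_mode"] = st["species"].map(mode_of)
    adults = st[st["stage"] == "adult"]
    saps = st[st["stage"] == "sapling"]

    def shares(frame: pd.DataFrame) -> dict[str, float]:
        if frame.empty:
            return {}
        return (frame["dispersal_mode"].value_counts(normalize=True)).round(6).to_dict()

    sp_modes = st.dropna(subset=["species"]).drop_duplicates("species")
    return {
        "n_trees": int(len(adults)),
        "n_saplings": int(len(saps)),
        "n_species": int(st["species"].nunique()),
        "n_genera": int(st["genus"].nunique()),
        "n_families": int(st["family"].dropna().nunique()),
        "mode_share_species": shares(sp_modes),
        "mode_share_trees": shares(adults),
        "mode_share_saplings": shares(saps),
    }


def _acquire_inputs(config: RunConfig):
    """Return (stems, trait_table, plots, tree_or_None)."""
    if config.synthetic:
        pool = synth.generate_species_pool(
            config.n_species, config.mode_props, seed=config.seed
        )
        landscape = synth.generate_landscape(
            config.n_sites, config.hp_range, seed=config.seed + 1
        )
        truth = synth.GroundTruth(seed=config.seed + 2, **config.truth)
        inv = synth.generate_inventory(pool, landscape, truth)
        tree = synth.pure_birth_tree(list(pool["species"]), seed=config.seed + 3)
        return inv.stems, pool, landscape.plots, tree, landscape, truth
    if config.xlsx_path:
        stems, trait_table, plots = io.load_xlsx_inputs(
            config.xlsx_path, config.xlsx_mapping
        )
    else:
        if not (config.stems_path and config.traits_path and config.plots_path):
            raise ValueError("non-synthetic runs need stems/traits/plots paths or an xlsx")
        stems = io.read_table(config.stems_path)
        trait_table = io.read_table(config.traits_path)
        plots = io.read_table(config.plots_path)
    for df, cols, what in (
        (stems, io.STEM_COLUMNS, "stems"),
        (trait_table, io.TRAIT_COLUMNS, "traits"),
        (plots, io.PLOT_COLUMNS, "plots"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{what} table missing required columns: {missing}")
    tree = io.read_newick(config.tree_path) if config.tree_path else None
    return stems, trait_table, plots, tree, None, None


def _species_residuals(fit: models.FitResult) -> pd.Series:
    """Average marginal residuals per species (tip-indexed for lambda)."""
    return fit.residuals.groupby(fit.groups.to_numpy()).mean()


def run_pipeline(config: RunConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("saplingshift")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    try:
        from . import __version__

        log.info("package version %s", __version__)
        log.info("config hash %s seed %d", config.config_hash(), config.seed)
        (outdir / "config_echo.yaml").write_text(config.to_yaml(), encoding="utf-8")

        stems, trait_table, plots, tree, landscape, truth = _acquire_inputs(config)
        log.info("inputs: %d stems, %d species in trait table, %d plots",
                 len(stems), trait_table["species"].nunique(), len(plots))
        io.write_table(stems, outdir / "stems.csv")
        io.write_table(trait_table, outdir / "trait_table.csv")
        io.write_table(plots, outdir / "plots.csv")
        if landscape is not None:
            io.write_table(landscape.settlements, outdir / "settlements.csv")
        if truth is not None:
            (outdir / "ground_truth.yaml").write_text(
                yaml.safe_dump(asdict(truth)), encoding="utf-8"
            )
        if tree is not None:
            io.write_newick(tree, outdir / "tree.nwk")

        # --- inventory summary + trait coverage ledger
        summary = summarize_inventory(stems, trait_table)
        summary["total_tree_area_ha"] = float(plots["tree_area_ha"].sum())
        summary["total_sapling_area_ha"] = float(plots["sapling_area_ha"].sum())
        summary["mean_hp"] = float(plots["hp"].mean())
        summary["hp_min"] = float(plots["hp"].min())
        summary["hp_max"] = float(plots["hp"].max())
        summary["mean_cec"] = float(plots["cec"].mean())
        summary["mean_vdnd"] = float(plots["vdnd"].mean())

        coverage = {}
        assembled = stems.copy()
        for trait in CWM_TRAITS:
            assign, cov = traits.impute_trait(stems, trait_table, trait)
            assembled[trait] = assign["value"]
            assembled[f"{trait}_provenance"] = assign["provenance"]
            coverage[trait] = cov
            log.info("trait %s coverage: %s", trait, cov)
        summary["trait_coverage"] = coverage
        limited = traits.count_limited_species(trait_table)
        summary["seed_limited_endozoochorous"] = limited
        io.write_table(assembled, outdir / "stems_with_traits.csv")

        # --- collinearity screen on plot covariates
        corr, flags = models.collinearity_screen(
            plots[["hp", "cec", "vdnd"]], threshold=config.collinearity_threshold
        )
        corr.to_csv(outdir / "covariate_correlations.csv")
        results["collinearity_flags"] = flags
        log.info("collinearity flags (|r|>%.2f): %s", config.collinearity_threshold, flags)

        # --- recruitment table
        rec = recruitment.build_recruitment_table(stems, plots)
        sp_info = trait_table.drop_duplicates("species").set_index("species")
        rec = rec.join(sp_info[["dispersal_mode", "family", "sl_mm"]], on="species")
        rec = rec.join(plots.set_index("plot_id")[["hp", "cec", "vdnd"]], on="plot_id")
        rec = rec.rename(columns={"sl_mm": "sl"})
        rec = rec.dropna(subset=["dispersal_mode"])
        io.write_table(rec, outdir / "recruitment.csv")
        log.info("recruitment table: %d species-plot records (%d with S:T)",
                 len(rec), int(rec["st_ratio"].notna().sum()))

        lambda_rows = []

        def _phylo_check(name: str, fit: models.FitResult) -> None:
            if tree is None:
                log.info("no tree supplied; skipping lambda for %s", name)
                return
            res = phylo.estimate_lambda(_species_residuals(fit), tree)
            lambda_rows.append(
                {
                    "model": name,
                    "lambda": res.lambda_hat,
                    "loglik": res.loglik_at_hat,
                    "loglik_lambda0": res.loglik_at_zero,
                    "p": res.lrt_p,
                    "n_species": res.n_species,
                }
            )
            log.info("phylo signal %s: lambda=%.4f p=%.4f", name, res.lambda_hat, res.lrt_p)

        def _save_fit(name: str, fit: models.FitResult) -> None:
            tbl = fit.coef_table()
            tbl.insert(0, "term", tbl.index)
            io.write_table(tbl.reset_index(drop=True), outdir / f"model_{name}_coefficients.csv")
            r2m, r2c = models.nakagawa_r2(fit)
            stats_row = {
                "model": name,
                "converged": fit.converged,
                "loglik": fit.loglik,
                "r2_marginal": r2m,
                "r2_conditional": r2c,
                **{f"var_{k}": v for k, v in fit.varcomps.items()},
            }
            results.setdefault("model_stats", []).append(stats_row)
            log.info("model %s: converged=%s R2m=%.4f R2c=%.4f", name, fit.converged, r2m, r2c)

        # --- model 1: sapling presence GLMM
        fit_glmm = None
        if rec["sapling_present"].nunique() < 2:
            log.info("presence response is constant; skipping recruitment GLMM")
        elif rec["dispersal_mode"].nunique() < 2:
            log.info("fewer than two dispersal modes; skipping recruitment GLMM")
        else:
            fit_glmm = models.fit_recruitment_glmm(
                rec, link=config.glmm_link, standardize=config.standardize
            )
            _save_fit("recruitment_glmm", fit_glmm)
            io.write_table(models.mode_hp_slopes(fit_glmm), outdir / "mode_hp_slopes_glmm.csv")
            _phylo_check("recruitment_glmm", fit_glmm)
            grid = np.linspace(plots["hp"].min(), plots["hp"].max(), 25)
            margins = pd.concat(
                [
                    models.marginal_effects(fit_glmm, grid, mode=m)
                    for m in sorted(rec["dispersal_mode"].unique())
                ]
            )
            io.write_table(margins, outdir / "marginal_effects_recruitment.csv")

        # --- model 2: S:T LMM (all modes)
        fit_st = None
        if rec["st_ratio"].notna().sum() < 10:
            log.info("too few S:T records; skipping S:T LMM")
        else:
            fit_st = models.fit_st_lmm(rec, standardize=config.standardize)
            _save_fit("st_lmm", fit_st)
            io.write_table(models.mode_hp_slopes(fit_st), outdir / "mode_hp_slopes_st.csv")
            _phylo_check("st_lmm", fit_st)

        # --- model 3: endozoochorous S:T ~ HP x SL
        endo = rec[(rec["dispersal_mode"] == "endozoochory")]
        fit_endo = None
        if endo["st_ratio"].notna().sum() < 10 or endo["sl"].notna().sum() < 10:
            log.info("too few endozoochorous S:T records with SL; skipping seed-size LMM")
        else:
            fit_endo = models.fit_endozoochory_lmm(
                endo.dropna(subset=["sl"]), standardize=config.standardize
            )
            _save_fit("endozoochory_lmm", fit_endo)
            io.write_table(
                models.hp_slopes_at_sl(fit_endo, [1.0, 18.0, 50.0]),
                outdir / "hp_slopes_by_seed_length.csv",
            )
            _phylo_check("endozoochory_lmm", fit_endo)

        if lambda_rows:
            io.write_table(pd.DataFrame(lambda_rows), outdir / "phylo_signal.csv")

        # --- community-weighted means and their linear models
        cwm_tbl = community.cwm_table(assembled, CWM_TRAITS)
        if not cwm_tbl.empty:
            cwm_tbl = cwm_tbl.join(plots.set_index("plot_id")[["hp", "cec", "vdnd"]], on="plot_id")
            io.write_table(cwm_tbl, outdir / "cwm.csv")
        for trait in CWM_TRAITS:
            sub = cwm_tbl[cwm_tbl["trait"] == trait] if not cwm_tbl.empty else pd.DataFrame()
            if sub.empty or set(sub["life_stage"]) != {"adult", "sapling"}:
                log.info("CWM model for %s skipped (missing a life stage)", trait)
                continue
            fit_cwm = models.fit_cwm_lm(cwm_tbl, trait, standardize=config.standardize)
            _save_fit(f"cwm_{trait}", fit_cwm)

        # --- trait correlations and pairwise mode tests
        corr_all = models.trait_correlations(trait_table, CWM_TRAITS, by_mode=False)
        corr_mode = models.trait_correlations(trait_table, CWM_TRAITS, by_mode=True)
        io.write_table(pd.concat([corr_all, corr_mode]), outdir / "trait_correlations.csv")
        tests = pd.concat(
            [
                models.pairwise_mode_tests(trait_table, t).assign(trait=t)
                for t in CWM_TRAITS
            ]
        )
        io.write_table(tests, outdir / "pairwise_mode_tests.csv")

        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump({"summary": summary, **results}, fh, indent=2, default=float)
        log.info("run complete: %s", outdir)
    except Exception:
        log.exception("pipeline failed; removing partial outputs")
        for p in sorted(outdir.glob("*")):
            if p.name != "run.log":
                p.unlink()
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
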