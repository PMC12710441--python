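# saplingshift

Defaunation by hunting removes the large frugivores that disperse most
tropical tree species, and the damage shows up a generation later: beneath
an intact adult canopy, the sapling layer slowly drifts toward species that
do not need those animals.  `saplingshift` is a Python package for
quantifying that drift from paired tree/sapling inventories along a
hunting-pressure gradient, for ecologists analysing real plot networks and
for methodologists who want a fully synthetic testbed with known ground
truth.

## What it computes

**Hunting pressure.**  A plot-level accessibility index over the nearest
village and the two regional towns,

    HP = S_vil / d_vil + S_car / d_car + S_ita / d_ita,

with `S` a settlement's population and `d` its distance (km) to the plot
centroid.

**Recruitment.**  For every species with ≥ 1 conspecific adult in a plot:
sapling presence/absence, and the log sapling-to-tree density ratio

    S:T = log10( D_sapling / D_tree ),

densities per hectare (adults censused on 0.25-ha plots, saplings on nested
0.05-ha subplots).  Positive S:T means saplings out-number conspecific
adults per hectare.

**Traits.**  Wood density (g/cm³), leaf mass per area (g/cm²), seed length
/width/mass attached to stems with a species → genus → family imputation
ledger; dispersal mode (abiotic, scatter-hoarded, endozoochory); seed-size
dispersal-limitation flags (SL > 18 mm, or SW > 12 mm when SL is missing).

**Community-weighted means.**  Per plot and life stage,

    CWM_j = Σ_i BA_ji · T_i / Σ_i BA_ji,   BA_i = π (DBH_i / 2)²,

using only species- or genus-level trait values.

**Model suite.**
* binomial GLMM (Laplace ML, species random intercept):
  `presence ~ HP × mode + CEC + VDND + n_adults`;
* Gaussian REML LMM with the same structure for S:T;
* Gaussian LMM for endozoochorous species only,
  `S:T ~ HP × seed length + CEC + VDND`, species nested in family;
* OLS per trait: `CWM ~ HP × life stage + VDND + CEC`;
* Nakagawa marginal/conditional R², marginal-effect curves, Pearson trait
  correlations, pairwise Welch t-tests with significance stars, a
  collinearity screen (|r| > 0.7), and Pagel's λ (profiled ML on [0, 1],
  boundary-corrected LRT) on species-averaged model residuals.

**Synthetic inventories.**  A generator that reproduces the study design —
15 sites × 2 plots, HP spanning ≈ 2.4–13.8, ~79 % endozoochorous species
pools with mode-specific trait distributions — and injects known HP ×
dispersal-mode and HP × seed-length effects for calibration and recovery
testing.

## Worked example

```python
from saplingshift import (GroundTruth, generate_species_pool, generate_landscape,
                          generate_inventory, build_recruitment_table,
                          fit_recruitment_glmm, nakagawa_r2)
from saplingshift.models import mode_hp_slopes

pool = generate_species_pool(n_species=300, seed=1)
land = generate_landscape(n_sites=15, seed=2)
truth = GroundTruth(
    beta_hp_by_mode={"abiotic": 0.15, "scatter_hoarded": 0.15, "endozoochory": -0.3},
    seed=3,
)
inv = generate_inventory(pool, land, truth)

records = build_recruitment_table(inv.stems, land.plots)
sp = pool.set_index("species")
records = records.join(sp[["dispersal_mode", "family"]], on="species")
records = records.join(land.plots.set_index("plot_id")[["hp", "cec", "vdnd"]], on="plot_id")

fit = fit_recruitment_glmm(records)
print(mode_hp_slopes(fit).round(3).to_string(index=False))
```

prints

```
 dispersal_mode  slope    se      z     p
        abiotic  0.015 0.136  0.111 0.912
   endozoochory -0.457 0.056 -8.170 0.000
scatter_hoarded  0.374 0.155  2.408 0.016
```

The generator injected a −0.3 hunting-pressure slope (per SD of HP, on the
log sapling-intensity scale) for endozoochorous species and +0.15 for the
other modes; the fitted mode-specific slopes recover the signs — sapling
recruitment of animal-ingested-seed species falls as hunting pressure
rises, while abiotically dispersed and rodent-cached species hold or gain.
`nakagawa_r2(fit)` gives (0.044, 0.372): fixed effects explain ~4 % of
latent variance, species identity most of the rest.

A shell workflow does the same end to end:

```bash
saplingshift analyze --outdir run --seed 7     # full pipeline, all tables
saplingshift report --rundir run               # marginal-effect / boxplot / CWM figures
saplingshift hp --settlements run/settlements.csv --out hp.csv
```

Real inventories enter as delimited text (`stems.csv`, `trait_table.csv`,
`plots.csv`) or as an XLSX workbook with a YAML column-mapping file; see
`saplingshift.io`.

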