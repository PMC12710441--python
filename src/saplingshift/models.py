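"""The analysis model suite.

* collinearity screen (pairwise Pearson r, |r| > 0.7 flags);
* binomial GLMM for sapling presence ~ HP x dispersal mode + CEC + VDND +
  n_adults with a species random intercept (in-house Laplace fitter);
* Gaussian LMM for the sapling-to-tree log-ratio with the same structure
  (statsmodels MixedLM, REML);
* Gaussian LMM for endozoochorous species only, S:T ~ HP x seed length +
  CEC + VDND with species nested in family;
* per-trait OLS for community-weighted means ~ HP x life stage + VDND + CEC;
* Nakagawa marginal/conditional R^2; marginal-effect curves with
  delta-method intervals; trait correlations; pairwise Welch t-tests with
  significance stars.

Continuous predictors are centered and scaled to unit SD by default so
coefficients are comparable across models and simulations; raw-scale
fitting is available via ``standardize=False``.  The dispersal-mode factor
uses treatment contrasts with "abiotic" (alphabetically first) as the
reference; mode-specific HP slopes are reported as derived contrasts so the
coding is immaterial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .glmm import fit_binomial_glmm

__all__ = [
    "FitResult",
    "collinearity_screen",
    "fit_recruitment_glmm",
    "fit_st_lmm",
    "fit_endozoochory_lmm",
    "fit_cwm_lm",
    "nakagawa_r2",
    "marginal_effects",
    "mode_hp_slopes",
    "hp_slopes_at_sl",
    "trait_correlations",
    "pairwise_mode_tests",
    "significance_stars",
]

MODES = ("abiotic", "endozoochory", "scatter_hoarded")
MODE_REFERENCE = "abiotic"

COLLINEARITY_THRESHOLD = 0.7


# ---------------------------------------------------------------------------
# design handling


@dataclass
class Design:
    """Fixed-effect design with enough metadata to rebuild prediction rows."""

    kind: str  # "recruitment" | "endo" | "cwm"
    columns: list[str]
    scalers: dict[str, tuple[float, float]]  # raw-scale (mean, sd) per continuous var
    covariate_means: dict[str, float]  # raw-scale means used for margins
    hp_range: tuple[float, float]
    mode_levels: tuple[str, ...] = ()
    stage_levels: tuple[str, ...] = ()

    def _z(self, name: str, value: float) -> float:
        mean, sd = self.scalers.get(name, (0.0, 1.0))
        return (value - mean) / sd

    def row(self, **kw: object) -> np.ndarray:
        """One prediction row; unspecified covariates sit at training means."""
        vals: dict[str, float] = {"Intercept": 1.0}
        cont = {k: kw.get(k, self.covariate_means.get(k)) for k in self.scalers}
        for k, v in cont.items():
            vals[k] = self._z(k, float(v))
        if self.kind == "recruitment":
            mode = str(kw.get("mode", MODE_REFERENCE))
            for lev in self.mode_levels:
                d = 1.0 if mode == lev else 0.0
                vals[f"mode[{lev}]"] = d
                vals[f"hp:mode[{lev}]"] = d * vals["hp"]
        elif self.kind == "endo":
            vals["hp:sl"] = vals["hp"] * vals["sl"]
        elif self.kind == "cwm":
            stage = str(kw.get("stage", "adult"))
            d = 1.0 if stage == "sapling" else 0.0
            vals["stage[sapling]"] = d
            vals["hp:stage[sapling]"] = d * vals["hp"]
        return np.array([vals[c] for c in self.columns])


def _scaled(df: pd.DataFrame, cols: list[str], standardize: bool):
    scalers = {}
    out = {}
    for c in cols:
        x = df[c].to_numpy(dtype=float)
        if standardize:
            sd = float(np.std(x, ddof=0))
            scalers[c] = (float(np.mean(x)), sd if sd > 0 else 1.0)
        else:
            scalers[c] = (0.0, 1.0)
        m, s = scalers[c]
        out[c] = (x - m) / s
    return out, scalers


def _drop_constant(X: np.ndarray, cols: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop non-intercept columns with zero variance (degenerate designs)."""
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    return X[:, keep], [cols[j] for j in keep]


def _recruitment_design(df: pd.DataFrame, standardize: bool) -> tuple[np.ndarray, Design]:
    cont = ["hp", "cec", "vdnd", "n_adults"]
    z, scalers = _scaled(df, cont, standardize)
    levels = tuple(sorted(set(df["dispersal_mode"]) - {MODE_REFERENCE}))
    cols = ["Intercept", "hp"]
    mats = [np.ones(len(df)), z["hp"]]
    for lev in levels:
        mats.append((df["dispersal_mode"] == lev).to_numpy(dtype=float))
        cols.append(f"mode[{lev}]")
    for lev in levels:
        mats.append((df["dispersal_mode"] == lev).to_numpy(dtype=float) * z["hp"])
        cols.append(f"hp:mode[{lev}]")
    for c in ("cec", "vdnd", "n_adults"):
        mats.append(z[c])
        cols.append(c)
    X, cols = _drop_constant(np.column_stack(mats), cols)
    design = Design(
        kind="recruitment",
        columns=cols,
        scalers=scalers,
        covariate_means={c: float(df[c].mean()) for c in cont},
        hp_range=(float(df["hp"].min()), float(df["hp"].max())),
        mode_levels=levels,
    )
    return X, design


def _endo_design(df: pd.DataFrame, standardize: bool) -> tuple[np.ndarray, Design]:
    cont = ["hp", "cec", "vdnd"]
    z, scalers = _scaled(df, cont, standardize)
    # seed length is always standardized before entering the model
    zsl, sl_scaler = _scaled(df, ["sl"], True)
    scalers["sl"] = sl_scaler["sl"]
    cols = ["Intercept", "hp", "sl", "hp:sl", "cec", "vdnd"]
    X = np.column_stack(
        [
            np.ones(len(df)),
            z["hp"],
            zsl["sl"],
            z["hp"] * zsl["sl"],
            z["cec"],
            z["vdnd"],
        ]
    )
    X, cols = _drop_constant(X, cols)
    design = Design(
        kind="endo",
        columns=cols,
        scalers=scalers,
        covariate_means={c: float(df[c].mean()) for c in cont + ["sl"]},
        hp_range=(float(df["hp"].min()), float(df["hp"].max())),
    )
    return X, design


def _cwm_design(df: pd.DataFrame, standardize: bool) -> tuple[np.ndarray, Design]:
    cont = ["hp", "vdnd", "cec"]
    z, scalers = _scaled(df, cont, standardize)
    sap = (df["life_stage"] == "sapling").to_numpy(dtype=float)
    cols = ["Intercept", "hp", "stage[sapling]", "hp:stage[sapling]", "vdnd", "cec"]
    X = np.column_stack([np.ones(len(df)), z["hp"], sap, sap * z["hp"], z["vdnd"], z["cec"]])
    X, cols = _drop_constant(X, cols)
    design = Design(
        kind="cwm",
        columns=cols,
        scalers=scalers,
        covariate_means={c: float(df[c].mean()) for c in cont},
        hp_range=(float(df["hp"].min()), float(df["hp"].max())),
        stage_levels=("adult", "sapling"),
    )
    return X, design


# ---------------------------------------------------------------------------
# fit results


@dataclass
class FitResult:
    """Uniform container for every model in the suite."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    varcomps: dict[str, float]
    resid_var: float | None
    loglik: float | None
    residuals: pd.Series  # marginal (fixed-effects-only) response residuals
    linpred_marginal: np.ndarray
    converged: bool
    family: str  # "binomial" | "gaussian"
    link: str
    design: Design
    groups: pd.Series | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )

    def contrast(self, c: np.ndarray) -> tuple[float, float]:
        """Estimate and SE of a linear combination c' beta."""
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov_params.to_numpy() @ c))
        return est, se

    def wald_test(self, names: list[str]) -> tuple[float, int, float]:
        """Joint Wald chi-square test that the named coefficients are zero."""
        idx = [list(self.params.index).index(n) for n in names]
        b = self.params.to_numpy()[idx]
        V = self.cov_params.to_numpy()[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# operations


def collinearity_screen(
    covariates: pd.DataFrame, *, threshold: float = COLLINEARITY_THRESHOLD
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson r between plot covariates; flag |r| > threshold.

    Constant covariates yield undefined correlations, reported as NaN and
    never flagged.
    """
    num = covariates.select_dtypes(include=[np.number])
    if num.shape[1] < 2:
        raise ValueError("need at least two numeric covariates")
    if len(num) < 3:
        raise ValueError("need at least three plots")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns -> NaN, not noise
        corr = num.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    for c in num.columns:  # constant column: undefined even with itself
        if num[c].nunique() <= 1:
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
    flags = [
        (a, b, float(corr.loc[a, b]))
        for a, b in combinations(num.columns, 2)
        if np.isfinite(corr.loc[a, b]) and abs(corr.loc[a, b]) > threshold
    ]
    return corr, flags


def _check_recruitment_frame(df: pd.DataFrame) -> None:
    needed = {"sapling_present", "hp", "cec", "vdnd", "n_adults", "dispersal_mode", "species"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"recruitment frame missing columns: {sorted(missing)}")


def fit_recruitment_glmm(
    records: pd.DataFrame,
    *,
    link: str = "logit",
    standardize: bool = True,
) -> FitResult:
    """Binomial GLMM: sapling presence ~ HP x mode + CEC + VDND + n_adults,
    with a species random intercept (Laplace ML)."""
    _check_recruitment_frame(records)
    df = records.reset_index(drop=True)
    X, design = _recruitment_design(df, standardize)
    y = df["sapling_present"].to_numpy(dtype=float)
    fit = fit_binomial_glmm(X, y, df["species"].to_numpy(), link=link)
    if not fit.converged and not standardize:
        # non-convergence policy: retry once on rescaled predictors
        X, design = _recruitment_design(df, True)
        fit = fit_binomial_glmm(X, y, df["species"].to_numpy(), link=link)
    params = pd.Series(fit.params, index=design.columns)
    bse = pd.Series(fit.bse, index=design.columns)
    pvals = pd.Series(2 * stats.norm.sf(np.abs(fit.params / fit.bse)), index=design.columns)
    return FitResult(
        params=params,
        bse=bse,
        pvalues=pvals,
        cov_params=pd.DataFrame(fit.cov_params, index=design.columns, columns=design.columns),
        varcomps={"species": fit.sigma2},
        resid_var=None,
        loglik=fit.loglik,
        residuals=pd.Series(y - fit.fitted_marginal, index=df.index),
        linpred_marginal=fit.linpred_marginal,
        converged=fit.converged,
        family="binomial",
        link=link,
        design=design,
        groups=df["species"],
        diagnostics={"n_obs": fit.n_obs, "n_groups": fit.n_groups},
    )


def _wrap_mixedlm(res, df, design, X, y, varcomps, groups) -> FitResult:
    fe = np.asarray(res.fe_params)
    k = len(design.columns)
    cov = np.asarray(res.cov_params())[:k, :k]
    params = pd.Series(fe, index=design.columns)
    bse = pd.Series(np.sqrt(np.diag(cov)), index=design.columns)
    pvals = pd.Series(2 * stats.norm.sf(np.abs(fe) / bse.to_numpy()), index=design.columns)
    lin = X @ fe
    return FitResult(
        params=params,
        bse=bse,
        pvalues=pvals,
        cov_params=pd.DataFrame(cov, index=design.columns, columns=design.columns),
        varcomps=varcomps,
        resid_var=float(res.scale),
        loglik=float(res.llf),
        residuals=pd.Series(y - lin, index=df.index),
        linpred_marginal=lin,
        converged=bool(getattr(res, "converged", True)),
        family="gaussian",
        link="identity",
        design=design,
        groups=groups,
    )


def fit_st_lmm(records: pd.DataFrame, *, standardize: bool = True) -> FitResult:
    """Gaussian REML LMM: S:T log-ratio with the same fixed/random structure
    as the recruitment GLMM (species random intercept)."""
    _check_recruitment_frame(records)
    df = records.dropna(subset=["st_ratio"]).reset_index(drop=True)
    X, design = _recruitment_design(df, standardize)
    y = df["st_ratio"].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=df["species"].to_numpy())
        res = model.fit(reml=True)
    varcomps = {"species": float(np.asarray(res.cov_re)[0, 0])}
    return _wrap_mixedlm(res, df, design, X, y, varcomps, df["species"])


def fit_endozoochory_lmm(records: pd.DataFrame, *, standardize: bool = True) -> FitResult:
    """Gaussian REML LMM on endozoochorous species only:
    S:T ~ HP x seed length + CEC + VDND, species nested within family.

    Seed length (``sl``, mm) is standardized before entering the model.
    With a single family the nesting degenerates to a species-only random
    intercept (warned).
    """
    needed = {"st_ratio", "hp", "cec", "vdnd", "sl", "species", "family"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"endozoochory frame missing columns: {sorted(missing)}")
    df = records.dropna(subset=["st_ratio", "sl"]).reset_index(drop=True)
    X, design = _endo_design(df, standardize)
    y = df["st_ratio"].to_numpy(dtype=float)
    safe_names = [c.replace(":", "_") for c in design.columns]
    data = pd.DataFrame(X, columns=safe_names)
    data["y"] = y
    data["species"] = df["species"].to_numpy()
    data["family"] = df["family"].to_numpy()
    single_family = data["family"].nunique() < 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if single_family:
            warnings.warn("single family: nesting degenerates to species-only")
            model = sm.MixedLM(y, X, groups=data["species"].to_numpy())
            res = model.fit(reml=True)
            varcomps = {"species": float(np.asarray(res.cov_re)[0, 0])}
        else:
            model = sm.MixedLM.from_formula(
                "y ~ 0 + " + " + ".join(safe_names),
                data,
                groups="family",
                re_formula="1",
                vc_formula={"species": "0 + C(species)"},
            )
            res = model.fit(reml=True)
            varcomps = {
                "family": float(np.asarray(res.cov_re)[0, 0]),
                "species": float(res.vcomp[0]),
            }
    if single_family:
        return _wrap_mixedlm(res, df, design, X, y, varcomps, df["species"])
    # formula route: map patsy names back onto the design columns
    fe = res.fe_params.reindex(safe_names).to_numpy()
    covm = res.cov_params().loc[safe_names, safe_names].to_numpy()
    params = pd.Series(fe, index=design.columns)
    bse = pd.Series(np.sqrt(np.diag(covm)), index=design.columns)
    pvals = pd.Series(2 * stats.norm.sf(np.abs(fe) / bse.to_numpy()), index=design.columns)
    lin = X @ fe
    return FitResult(
        params=params,
        bse=bse,
        pvalues=pvals,
        cov_params=pd.DataFrame(covm, index=design.columns, columns=design.columns),
        varcomps=varcomps,
        resid_var=float(res.scale),
        loglik=float(res.llf),
        residuals=pd.Series(y - lin, index=df.index),
        linpred_marginal=lin,
        converged=bool(getattr(res, "converged", True)),
        family="gaussian",
        link="identity",
        design=design,
        groups=df["species"],
    )


def fit_cwm_lm(cwm: pd.DataFrame, trait: str, *, standardize: bool = True) -> FitResult:
    """OLS: CWM(trait) ~ HP x life stage + VDND + CEC."""
    df = cwm[cwm["trait"] == trait].dropna(subset=["cwm"]).reset_index(drop=True)
    stages = set(df["life_stage"])
    if not {"adult", "sapling"} <= stages:
        raise ValueError(f"both life stages required, got {sorted(stages)}")
    X, design = _cwm_design(df, standardize)
    y = df["cwm"].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    params = pd.Series(res.params, index=design.columns)
    bse = pd.Series(res.bse, index=design.columns)
    pvals = pd.Series(res.pvalues, index=design.columns)
    lin = X @ np.asarray(res.params)
    return FitResult(
        params=params,
        bse=bse,
        pvalues=pvals,
        cov_params=pd.DataFrame(np.asarray(res.cov_params()), index=design.columns, columns=design.columns),
        varcomps={},
        resid_var=float(res.mse_resid),
        loglik=float(res.llf),
        residuals=pd.Series(y - lin, index=df.index),
        linpred_marginal=lin,
        converged=True,
        family="gaussian",
        link="identity",
        design=design,
    )


def nakagawa_r2(fit: FitResult) -> tuple[float, float]:
    """Marginal and conditional R^2 for a mixed model.

    R2m = var_fixed / (var_fixed + sum var_random + var_resid);
    R2c adds the random-effect variances to the numerator.  For the
    binomial-logit family the residual variance is pi^2 / 3 (logistic
    distribution); for cloglog pi^2 / 6 (Gumbel).
    """
    var_f = float(np.var(fit.linpred_marginal, ddof=0))
    var_r = float(sum(fit.varcomps.values()))
    if fit.family == "binomial":
        var_e = np.pi**2 / 3 if fit.link == "logit" else np.pi**2 / 6
    else:
        var_e = fit.resid_var if fit.resid_var is not None else 0.0
    total = var_f + var_r + var_e
    if total <= 0:
        raise ValueError("zero total variance; R^2 undefined")
    return var_f / total, (var_f + var_r) / total


def _inv_link(eta: np.ndarray, family: str, link: str) -> np.ndarray:
    if family == "gaussian":
        return eta
    if link == "logit":
        return stats.logistic.cdf(eta)
    return -np.expm1(-np.exp(np.clip(eta, -700, 700)))


def marginal_effects(
    fit: FitResult,
    hp_values: np.ndarray,
    *,
    mode: str | None = None,
    stage: str | None = None,
    sl_mm: float | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted response over an HP grid, other covariates at sample means
    and random effects at zero; delta-method confidence band.

    HP values outside the fitted range are flagged ``extrapolated`` rather
    than refused.
    """
    zcrit = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for hp in np.asarray(hp_values, dtype=float):
        kw: dict[str, object] = {"hp": hp}
        if mode is not None:
            kw["mode"] = mode
        if stage is not None:
            kw["stage"] = stage
        if sl_mm is not None:
            kw["sl"] = sl_mm
        c = fit.design.row(**kw)
        eta, se = fit.contrast(c)
        lo, hi = eta - zcrit * se, eta + zcrit * se
        pred, plo, phi = _inv_link(np.array([eta, lo, hi]), fit.family, fit.link)
        rows.append(
            {
                "hp": hp,
                "linpred": eta,
                "se": se,
                "predicted": float(pred),
                "ci_low": float(plo),
                "ci_high": float(phi),
                "extrapolated": bool(
                    hp < fit.design.hp_range[0] or hp > fit.design.hp_range[1]
                ),
            }
        )
    out = pd.DataFrame(rows)
    if mode is not None:
        out.insert(1, "mode", mode)
    if stage is not None:
        out.insert(1, "stage", stage)
    if sl_mm is not None:
        out.insert(1, "sl_mm", sl_mm)
    return out


def mode_hp_slopes(fit: FitResult) -> pd.DataFrame:
    """HP slope (per SD of HP if standardized) for each dispersal mode,
    derived as contrasts of the treatment-coded fit."""
    cols = list(fit.params.index)
    levels = (MODE_REFERENCE,) + tuple(fit.design.mode_levels)
    rows = []
    for mode in levels:
        c = np.zeros(len(cols))
        c[cols.index("hp")] = 1.0
        name = f"hp:mode[{mode}]"
        if name in cols:
            c[cols.index(name)] = 1.0
        est, se = fit.contrast(c)
        z = est / se
        rows.append(
            {
                "dispersal_mode": mode,
                "slope": est,
                "se": se,
                "z": z,
                "p": 2 * stats.norm.sf(abs(z)),
            }
        )
    return pd.DataFrame(rows)


def hp_slopes_at_sl(fit: FitResult, sl_mm: list[float]) -> pd.DataFrame:
    """HP slope of the endozoochory model evaluated at given seed lengths."""
    cols = list(fit.params.index)
    mean, sd = fit.design.scalers["sl"]
    rows = []
    for sl in sl_mm:
        zsl = (sl - mean) / sd
        c = np.zeros(len(cols))
        c[cols.index("hp")] = 1.0
        c[cols.index("hp:sl")] = zsl
        est, se = fit.contrast(c)
        z = est / se
        rows.append(
            {"sl_mm": sl, "slope": est, "se": se, "z": z, "p": 2 * stats.norm.sf(abs(z))}
        )
    return pd.DataFrame(rows)


def trait_correlations(
    species_table: pd.DataFrame,
    traits: list[str],
    *,
    by_mode: bool = False,
    mode_col: str = "dispersal_mode",
) -> pd.DataFrame:
    """Pearson correlations between species-level traits.

    Complete-pairs deletion per trait pair; pairs with fewer than 3
    complete observations are reported as NaN (with n recorded).  With
    ``by_mode=True`` correlations are computed within each dispersal mode.
    """
    sp = species_table.drop_duplicates("species")
    groups = [("all", sp)] if not by_mode else list(sp.groupby(mode_col))
    rows = []
    for gname, g in groups:
        for a, b in combinations(traits, 2):
            pair = g[[a, b]].dropna()
            if len(pair) < 3:
                rows.append({"group": gname, "trait_a": a, "trait_b": b, "r": np.nan, "p": np.nan, "n": len(pair)})
                continue
            r, p = stats.pearsonr(pair[a], pair[b])
            rows.append({"group": gname, "trait_a": a, "trait_b": b, "r": float(r), "p": float(p), "n": len(pair)})
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star code (boundary 0.05 -> '*')."""
    if p is None or not np.isfinite(p):
        return "n.s."
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


def pairwise_mode_tests(
    species_table: pd.DataFrame,
    trait: str,
    *,
    mode_col: str = "dispersal_mode",
    holm: bool = False,
) -> pd.DataFrame:
    """Welch two-sample t-tests of a trait between dispersal-mode pairs.

    Modes with fewer than 2 non-missing values are skipped.  Raw p-values
    by default (as in conventional boxplot annotations); Holm correction
    behind the ``holm`` flag.
    """
    sp = species_table.drop_duplicates("species")
    samples = {
        m: g[trait].dropna().to_numpy()
        for m, g in sp.groupby(mode_col)
        if g[trait].dropna().size >= 2
    }
    rows = []
    for a, b in combinations(sorted(samples), 2):
        xa, xb = samples[a], samples[b]
        if np.ptp(np.concatenate([xa, xb])) == 0:
            p = np.nan  # identical constants: t undefined, treated as n.s.
            t = np.nan
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"mode_a": a, "mode_b": b, "t": float(t), "p": float(p) if np.isfinite(p) else np.nan, "n_a": len(xa), "n_b": len(xb)})
    out = pd.DataFrame(
        rows, columns=["mode_a", "mode_b", "t", "p", "n_a", "n_b"]
    )
    if holm and len(out):
        from statsmodels.stats.multitest import multipletests

        mask = out["p"].notna()
        adj = out["p"].copy()
        if mask.any():
            adj.loc[mask] = multipletests(out.loc[mask, "p"], method="holm")[1]
        out["p_holm"] = adj
        out["stars"] = [significance_stars(p) for p in out["p_holm"]]
    else:
        out["stars"] = [significance_stars(p) for p in out["p"]]
    return out
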