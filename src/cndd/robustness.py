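"""Robustness machinery: randomizations, influence filtering, residual
spatial-autocorrelation screening and life-history confounder models."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .meta import MetaFit, fit_meta_regression
from .mortality import fit_mortality_model, model_residual_quantiles

__all__ = [
    "RandomizationSpec",
    "randomize_dataset",
    "null_pipeline_check",
    "influence_filter",
    "cooks_distances",
    "morans_i",
    "spatial_autocorrelation_screen",
    "compute_life_history",
    "confounder_meta_models",
]


@dataclass(frozen=True)
class RandomizationSpec:
    mode: str                      # status_within_species | conD_within_species
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self):
        if self.mode not in ("status_within_species", "conD_within_species"):
            raise ValueError(f"unknown randomization mode {self.mode!r}")


def randomize_dataset(observations: pd.DataFrame, spec: RandomizationSpec,
                      replicate: int = 0) -> pd.DataFrame:
    """Permute tree status (or conspecific density) within each species-site
    group, leaving every other column untouched.  Preserves the group-wise
    multiset of the shuffled column exactly; deterministic given the seed."""
    column = "Y" if spec.mode == "status_within_species" else "conD"
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, replicate)))
    out = observations.copy()
    values = out[column].to_numpy().copy()
    for _, idx in out.groupby(["site", "species"]).indices.items():
        values[idx] = values[rng.permutation(idx)]
    out[column] = values
    return out


def null_pipeline_check(observations: pd.DataFrame, site_latitudes: dict,
                        abundances: dict, spec: RandomizationSpec,
                        growth_forms: dict | None = None,
                        delta_conD: float | None = None,
                        n_draws: int = 200, k: int = 10) -> pd.DataFrame:
    """Re-run mortality fits, AMEs and the meta-regressions on randomized
    data; one row per replicate with the meta-analytic mean and latitude /
    abundance terms (Wald CIs)."""
    from .pipeline import analyze_observations

    rows = []
    for rep in range(spec.n_replicates):
        rand = randomize_dataset(observations, spec, replicate=rep)
        bundle = analyze_observations(rand, site_latitudes, abundances,
                                      growth_forms=growth_forms,
                                      delta_conD=delta_conD,
                                      n_draws=n_draws, k=k,
                                      seed=spec.seed + 7919 * rep,
                                      variants=("equilibrium",))
        mean_fit: MetaFit = bundle["meta_fits"]["mean"]
        mlo, mhi = mean_fit.ci()
        row = {"replicate": rep, "mean": mean_fit.beta[0],
               "mean_lo": mlo[0], "mean_hi": mhi[0], "mean_p": mean_fit.p[0]}
        fit = bundle["meta_fits"].get("latitude")
        if fit is not None and "tLatitude" in fit.terms:
            i = fit.terms.index("tLatitude")
            lo, hi = fit.ci()
            row.update(lat_slope=fit.beta[i], lat_lo=lo[i], lat_hi=hi[i],
                       lat_p=fit.p[i])
        ab_fit = bundle["meta_fits"].get("abundance")
        if ab_fit is not None and "tAbundance" in ab_fit.terms:
            i = ab_fit.terms.index("tAbundance")
            alo, ahi = ab_fit.ci()
            row.update(ab_slope=ab_fit.beta[i], ab_lo=alo[i], ab_hi=ahi[i],
                       ab_p=ab_fit.p[i])
        rows.append(row)
    return pd.DataFrame(rows)


def cooks_distances(records: pd.DataFrame, fit: MetaFit, terms) -> np.ndarray:
    """Leave-one-out Cook's distance on the fixed effects, with variance
    components held at their full-data estimates:
    D_i = (b_(-i) - b)' (X'V^-1 X) (b_(-i) - b)."""
    from .meta import _design, _build_V

    y = records["y"].to_numpy(dtype=float)
    v = records["v"].to_numpy(dtype=float)
    X = _design(records, list(terms))
    use_site = "site" in fit.random and records["site"].nunique() > 1
    site_codes = pd.factorize(records["site"])[0] if use_site else None
    V = _build_V(v, site_codes, fit.sigma_r**2, fit.sigma_s**2)
    Vi = np.linalg.inv(V)
    F = X.T @ Vi @ X
    b_full = np.linalg.solve(F, X.T @ Vi @ y)
    n = len(records)
    D = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Vi_sub = np.linalg.inv(V[np.ix_(keep, keep)])
        Xs = X[keep]
        b_i = np.linalg.solve(Xs.T @ Vi_sub @ Xs, Xs.T @ Vi_sub @ y[keep])
        d = b_i - b_full
        D[i] = d @ F @ d
    return D


def influence_filter(records: pd.DataFrame, fit: MetaFit, terms,
                     threshold: float = 0.005):
    """Drop records with Cook's distance above the threshold and refit.

    Returns ``(reduced_records, refit, report)`` where report lists every
    record's distance and removal flag."""
    D = cooks_distances(records, fit, terms)
    removed = D > threshold
    report = records[["site", "species"]].copy()
    report["cooks_d"] = D
    report["removed"] = removed
    reduced = records[~removed].reset_index(drop=True)
    reduced.attrs.update(records.attrs)
    if len(reduced) < len(terms) + 2:
        warnings.warn("influence filter removed too many records; refit skipped")
        return reduced, None, report
    try:
        refit = fit_meta_regression(reduced, terms, random=fit.random)
    except RuntimeError as exc:
        warnings.warn(f"refit after influence filtering failed: {exc}")
        refit = None
    return reduced, refit, report


def morans_i(values: np.ndarray, xy: np.ndarray, max_dist: float = 30.0,
             n_permutations: int = 999, seed=None):
    """Moran's I with inverse-distance weights for pairs within
    ``max_dist``; two-sided permutation p-value."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(max_dist, output_type="ndarray")
    if len(pairs) == 0 or np.ptp(values) == 0:
        return np.nan, np.nan
    d = np.hypot(*(xy[pairs[:, 0]] - xy[pairs[:, 1]]).T)
    w = 1.0 / np.maximum(d, 1e-6)
    w_sum = 2.0 * w.sum()                   # symmetric pairs counted once

    def stat(z):
        z = z - z.mean()
        s2 = np.sum(z**2)
        cross = 2.0 * np.sum(w * z[pairs[:, 0]] * z[pairs[:, 1]])
        return (n / w_sum) * cross / s2

    i_obs = stat(values)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for b in range(n_permutations):
        perms[b] = stat(values[rng.permutation(n)])
    center = perms.mean()
    p = (1.0 + np.sum(np.abs(perms - center) >= abs(i_obs - center))) / (n_permutations + 1)
    return float(i_obs), float(p)


def spatial_autocorrelation_screen(fits: dict, observations: pd.DataFrame,
                                   seed: int = 0, min_obs: int = 10,
                                   n_permutations: int = 999,
                                   alpha: float = 0.05) -> pd.DataFrame:
    """Moran's I on randomized quantile residuals for every fitted model,
    with Holm-adjusted p-values across models.

    ``fits`` maps (site, species) to a convergent MortalityModelFit.
    Models with fewer than ``min_obs`` observations, or degenerate
    residuals, are skipped.
    """
    rows = []
    seq = np.random.SeedSequence(seed)
    for (key, fit), child in zip(sorted(fits.items()), seq.spawn(len(fits))):
        site, species = key
        sub = observations[(observations["site"] == site)
                           & (observations["species"] == species)]
        if len(sub) < min_obs or not fit.converged:
            continue
        rng_seed = child.spawn(2)
        resid = model_residual_quantiles(fit, sub, seed=rng_seed[0])
        if np.ptp(resid) == 0:
            warnings.warn(f"constant residuals for {key}; spatial test skipped")
            continue
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        i_obs, p = morans_i(resid, xy, n_permutations=n_permutations,
                            seed=rng_seed[1])
        if np.isfinite(p):
            rows.append({"site": site, "species": species,
                         "moran_i": i_obs, "p_raw": p})
    table = pd.DataFrame(rows)
    if len(table):
        flag, p_adj, _, _ = multipletests(table["p_raw"], alpha=alpha, method="holm")
        table["p_holm"] = p_adj
        table["flagged"] = flag
        table.attrs["flagged_share"] = float(flag.mean())
    else:
        table.attrs["flagged_share"] = np.nan
    return table


def _standardize(series: pd.Series) -> pd.Series:
    sd = series.std(ddof=1)
    return (series - series.mean()) / (sd if sd and sd > 0 else 1.0)


def compute_life_history(trees: pd.DataFrame, observations: pd.DataFrame,
                         site: str) -> pd.DataFrame:
    """Species-level life-history covariates for one site.

    growth:   log(median annual DBH increment + 1)
    survival: logit of annual survival from an intercept-only hazard fit
    stature:  log 90th-percentile DBH
    all standardized within the site; two trade-off axes from principal-
    component rotations of (growth, survival) and (stature, recruitment
    proxy = log1p sapling influx per census).
    """
    rows = {}
    merged = trees.sort_values("census_index")
    for species, sub in merged.groupby("species"):
        piv = sub.pivot_table(index="tree_id", columns="census_index",
                              values=["dbh", "date", "status"], aggfunc="first")
        incs = []
        censuses = sorted(sub["census_index"].unique())
        influx = []
        for c0, c1 in zip(censuses[:-1], censuses[1:]):
            try:
                alive_both = ((piv[("status", c0)] == "alive")
                              & (piv[("status", c1)] == "alive"))
                dt = piv[("date", c1)] - piv[("date", c0)]
                inc = (piv[("dbh", c1)] - piv[("dbh", c0)])[alive_both] / dt[alive_both]
                incs.append(inc.dropna())
                newcomers = piv[("status", c1)].notna() & piv[("status", c0)].isna()
                influx.append(int(newcomers.sum()))
            except KeyError:
                continue
        inc_all = pd.concat(incs) if incs else pd.Series(dtype=float)
        growth = np.log1p(inc_all.median()) if len(inc_all) else np.nan
        obs = observations[(observations["site"] == site)
                           & (observations["species"] == species)]
        survival = np.nan
        if len(obs) and obs["Y"].nunique() >= 1:
            fit = fit_mortality_model(obs, predictors=())
            annual_p = float(np.clip(-np.expm1(-np.exp(fit.beta[0])), 1e-9, 1 - 1e-9))
            survival = float(special.logit(1.0 - annual_p))
        stature = float(np.log(sub["dbh"].quantile(0.9)))
        rows[species] = {"growth": growth, "survival": survival, "stature": stature,
                         "recruitment": float(np.log1p(np.mean(influx))) if influx else np.nan}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "species"
    for col in list(table.columns):
        table[f"{col}_raw"] = table[col]
        table[col] = _standardize(table[col])
    # trade-off axes: first principal component of each standardized pair
    for axis, pair in (("axis_growth_survival", ("growth", "survival")),
                       ("axis_stature_recruitment", ("stature", "recruitment"))):
        sub = table[list(pair)].dropna()
        if len(sub) >= 2 and sub.std().min() > 0:
            M = sub.to_numpy()
            _, _, Vt = np.linalg.svd(M - M.mean(axis=0), full_matrices=False)
            table.loc[sub.index, axis] = (M - M.mean(axis=0)) @ Vt[0]
        else:
            table[axis] = table[pair[0]]
    table["site"] = site
    return table.reset_index()


def confounder_meta_models(records: pd.DataFrame, covariates: pd.DataFrame,
                           base_terms=("tLatitude", "tAbundance", "tLatitude:tAbundance"),
                           extra_pairs=(("growth", "survival"),
                                        ("axis_growth_survival", "axis_stature_recruitment")),
                           random=("site", "species")) -> dict:
    """Abundance-mediated meta-regression augmented with life-history
    main effects and their interaction; reports whether the abundance
    effect keeps its sign and significance."""
    merged = records.merge(covariates, on=["site", "species"], how="left")
    results = {}
    base_fit = fit_meta_regression(records, list(base_terms), random=random)
    i_ab = base_fit.terms.index("tAbundance")
    for pair in extra_pairs:
        a, b = pair
        sub = merged.dropna(subset=[a, b]).reset_index(drop=True)
        sub.attrs.update(records.attrs)
        if len(sub) < len(base_fit.terms) + 4:
            warnings.warn(f"too few records for confounder pair {pair}; skipped")
            continue
        terms = list(base_terms)
        for c in pair:
            if sub[c].std(ddof=0) == 0:
                warnings.warn(f"zero-variance covariate {c!r} dropped")
            else:
                terms.append(c)
        inter = f"{a}:{b}"
        if a in terms and b in terms:
            sub[inter] = sub[a] * sub[b]
            terms.append(inter)
        from .meta import _design
        X = _design(sub, terms)
        if np.linalg.cond(X.T @ X) > 1e8:
            warnings.warn(f"collinearity among confounder terms {terms}")
        fit = fit_meta_regression(sub, terms, random=random)
        j = fit.terms.index("tAbundance")
        results[pair] = {
            "fit": fit,
            "abundance_beta": float(fit.beta[j]),
            "abundance_p": float(fit.p[j]),
            "sign_retained": bool(np.sign(fit.beta[j]) == np.sign(base_fit.beta[i_ab])),
            "significance_retained": bool((fit.p[j] < 0.05) == (base_fit.p[i_ab] < 0.05)),
        }
    results["base_fit"] = base_fit
    return results
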