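"""Config-driven orchestration of the full analysis.

Stages: simulate (or ingest) -> neighborhood densities (optional kernel
grid search) -> species-site mortality fits (individual + pooled rare
groups) -> average marginal effects (three variants) -> meta-regressions
-> robustness.  Every stochastic stage takes its seed from the config and
outputs are plain CSV / JSON in a run directory with a content-hash
manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import forest_data, marginal_effects, meta, mortality, neighborhood, synthetic

__all__ = [
    "PipelineConfig",
    "validate_config",
    "neighbor_tables_from_censuses",
    "attach_densities",
    "fit_species_models",
    "compute_ame_table",
    "analyze_observations",
    "run",
    "make_report",
]

_DEFAULTS = {
    "k": 10,
    "n_draws": 500,
    "mu_grid": list(range(1, 26, 2)),
    "radius": 30.0,
    "buffer_m": 30.0,
    "center_latitude": 11.75,
    "center_abundance": 1.0,
    "alpha": 0.05,
    "cooks_threshold": 0.005,
    "estimator": "BA",
    "kernel": "exponential",
    "mu_con": 3.0,
    "mu_tot": 17.0,
    "grid_search": False,
    "seed": 0,
    "variants": ["equilibrium", "invasion", "interquantile"],
    "stages": {"robustness": True},
    "scenario": {},
    "output_dir": "cndd_run",
}


@dataclass
class PipelineConfig:
    settings: dict = field(default_factory=lambda: dict(_DEFAULTS))

    def __getattr__(self, name):
        try:
            return self.settings[name]
        except KeyError as exc:
            raise AttributeError(name) from exc

    def density_config(self) -> neighborhood.DensityConfig:
        return neighborhood.DensityConfig(
            self.settings["estimator"],
            neighborhood.KernelSpec(self.settings["kernel"], self.settings["mu_con"]),
            neighborhood.KernelSpec(self.settings["kernel"], self.settings["mu_tot"]),
            self.settings["radius"])

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.settings, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(source) -> tuple[PipelineConfig | None, list[str]]:
    """Normalize a YAML/JSON config (path, text or dict): inject defaults,
    collect unknown-key and type errors."""
    if isinstance(source, dict):
        raw = source
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text) or {}
    errors = []
    merged = dict(_DEFAULTS)
    for key, value in raw.items():
        if key not in _DEFAULTS:
            errors.append(f"unknown config key {key!r}")
            continue
        if value is None:
            continue
        default = _DEFAULTS[key]
        if isinstance(default, bool) and not isinstance(value, bool):
            errors.append(f"{key}: expected boolean, got {type(value).__name__}")
            continue
        if isinstance(default, (int, float)) and not isinstance(default, bool) \
                and not isinstance(value, (int, float)):
            errors.append(f"{key}: expected number, got {type(value).__name__}")
            continue
        merged[key] = value
    for key in ("radius", "buffer_m", "mu_con", "mu_tot"):
        if not (isinstance(merged[key], (int, float)) and merged[key] > 0):
            errors.append(f"{key} must be positive")
    if errors:
        return None, errors
    return PipelineConfig(merged), []


def neighbor_tables_from_censuses(censuses: list, site: str) -> dict:
    """``{(site, j): live trees at the census preceding interval j}``."""
    tables = {}
    for j, census in enumerate(censuses[:-1], start=1):
        alive = census[census["status"] == "alive"].reset_index(drop=True)
        tables[(site, j)] = alive
    return tables


def attach_densities(observations: pd.DataFrame, neighbor_tables: dict,
                     config: neighborhood.DensityConfig,
                     drop_edge: bool = True) -> pd.DataFrame:
    """Join kernel-weighted conD/totD onto the observation table; edge-
    excluded focal trees are dropped from modelling."""
    obs = observations.reset_index(drop=True)
    parts = []
    for (site, j), sub in obs.groupby(["site", "j"]):
        dens = neighborhood.compute_densities(sub, neighbor_tables[(site, j)], config)
        parts.append(sub.assign(conD=dens["conD"], totD=dens["totD"]))
    out = pd.concat(parts, ignore_index=False).sort_index()
    if drop_edge:
        out = out[~out["edge_excluded"]].reset_index(drop=True)
    return out


def fit_species_models(observations: pd.DataFrame, growth_forms: dict,
                       delta_conD: float, k: int = 10):
    """Eligibility-routed fits: individual models per qualifying species,
    plus one pooled fit per rare growth-form group and site.

    Returns ``(fits, memberships)``: fits keyed by (site, species-or-group),
    memberships mapping each pooled (site, species) to its group key.
    """
    fits = {}
    memberships = {}
    pooled_rows = {}
    for (site, species), sub in observations.groupby(["site", "species"]):
        form = growth_forms.get(species, "tree")
        elig = mortality.assess_eligibility(sub, delta_conD, growth_form=form)
        if elig.decision == "individual":
            fit = mortality.fit_mortality_model(sub, k=k)
            if fit.converged:
                fits[(site, species)] = fit
                continue
            # non-convergent individual fits fall back to the pooled group
        group = elig.decision if elig.decision != "individual" else (
            "pooled_rare_shrub" if form == "shrub" else "pooled_rare_tree")
        memberships[(site, species)] = (site, group)
        pooled_rows.setdefault((site, group), []).append(sub)
    for (site, group), frames in pooled_rows.items():
        pooled = pd.concat(frames, ignore_index=True)
        if pooled["Y"].nunique() < 2:
            warnings.warn(f"rare group {group} at {site} degenerate; skipped")
            continue
        fits[(site, group)] = mortality.fit_mortality_model(pooled.assign(group=group), k=k)
    return fits, memberships


def compute_ame_table(fits: dict, memberships: dict, observations: pd.DataFrame,
                      delta_conD: float, variants=("equilibrium",),
                      n_draws: int = 500, seed: int = 0) -> pd.DataFrame:
    """AME estimates per species-site (or pooled group) and variant.

    Pooled groups contribute one estimate per site and group, averaged
    over the pooled member observations with the group coefficients.
    """
    rows = []
    seq = np.random.SeedSequence(seed)
    keys = sorted(fits.keys())
    children = dict(zip(keys, seq.spawn(len(keys))))
    pooled_members = {}
    for member, group_key in memberships.items():
        pooled_members.setdefault(group_key, []).append(member)
    for key in keys:
        fit = fits[key]
        site, name = key
        if not fit.converged:
            continue
        if key in pooled_members or name.startswith("pooled_"):
            members = pooled_members.get(key, [])
            if not members:
                continue
            sub = observations[
                observations.set_index(["site", "species"]).index.isin(members)]
        else:
            sub = observations[(observations["site"] == site)
                               & (observations["species"] == name)]
        if len(sub) == 0:
            continue
        variant_seeds = children[key].spawn(len(variants))
        for vi, variant in enumerate(variants):
            try:
                est = marginal_effects.ame_uncertainty(
                    fit, sub, delta_conD, variant=variant, n_draws=n_draws,
                    seed=variant_seeds[vi], site=site, species=name)
            except ValueError:
                continue
            rows.append({
                "site": est.site, "species": est.species, "variant": est.variant,
                "aAME": est.aAME, "rAME": est.rAME,
                "var_log_rAME_plus1": est.var_log_rAME_plus1,
                "var_aAME": est.var_aAME, "p": est.p_value,
                "n_obs": est.n_obs, "n_draws": est.n_draws,
                "significant": est.significant,
                "unstable": bool(est.flags.get("unstable", False)),
            })
    return pd.DataFrame(rows)


def analyze_observations(observations: pd.DataFrame, site_latitudes: dict,
                         abundances: dict, growth_forms: dict | None = None,
                         delta_conD: float | None = None, k: int = 10,
                         n_draws: int = 500, seed: int = 0,
                         variants=("equilibrium",),
                         center_latitude: float = 11.75,
                         center_abundance: float = 1.0) -> dict:
    """Mortality fits -> AMEs -> meta-regressions for a density-augmented
    observation table.  Returns a results bundle (dict of tables/fits)."""
    growth_forms = growth_forms or {}
    if delta_conD is None:
        delta_conD = neighborhood.perturbation_delta(neighborhood.DensityConfig())
    fits, memberships = fit_species_models(observations, growth_forms, delta_conD, k=k)
    ame = compute_ame_table(fits, memberships, observations, delta_conD,
                            variants=variants, n_draws=n_draws, seed=seed)
    bundle = {"fits": fits, "memberships": memberships, "ame_table": ame,
              "delta_conD": delta_conD, "meta_fits": {}, "records": None}
    if len(ame) == 0:
        return bundle
    # abundance for pooled groups: mean of member-species abundances
    full_abund = dict(abundances)
    group_members = {}
    for (site, sp), (gsite, group) in memberships.items():
        group_members.setdefault((gsite, group), []).append((site, sp))
    for gkey, members in group_members.items():
        vals = [abundances[m] for m in members if m in abundances]
        if vals:
            full_abund[gkey] = forest_data.group_abundance(vals)
    eq = ame[ame["variant"] == "equilibrium"]
    records = meta.build_records(eq, site_latitudes, full_abund,
                                 center_latitude=center_latitude,
                                 center_abundance=center_abundance)
    bundle["records"] = records
    if len(records) >= 3:
        bundle["meta_fits"]["mean"] = meta.fit_meta_regression(records, ())
        bundle["meta_fits"]["latitude"] = meta.fit_meta_regression(
            records, ("tLatitude",))
        if records["log_abundance"].nunique() > 1:
            bundle["meta_fits"]["abundance"] = meta.fit_meta_regression(
                records, ("tLatitude", "tAbundance", "tLatitude:tAbundance"))
    if "interquantile" in variants:
        iq = ame[ame["variant"] == "interquantile"]
        iq_records = meta.build_records(iq, site_latitudes, full_abund)
        if len(iq_records) >= 3:
            bundle["interquantile_summary"] = meta.global_interquantile_summary(iq_records)
    return bundle


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run(config: PipelineConfig, outdir=None) -> dict:
    """Execute the synthetic-scenario pipeline end to end, writing CSV/JSON
    outputs and a manifest into the run directory."""
    outdir = Path(outdir or config.settings["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "stages": {}}
    t0 = time.time()

    scen_kwargs = dict(config.settings.get("scenario") or {})
    comm = synthetic.CommunityConfig(**scen_kwargs.pop("community", {}))
    scenario = synthetic.ScenarioSpec(
        latitudes=scen_kwargs.pop("latitudes", [5.0, 45.0]),
        community=comm, seed=config.settings["seed"], **scen_kwargs)
    sites = synthetic.make_latitudinal_ensemble(scenario)
    synthetic.write_ground_truth(sites, outdir / "ground_truth.json")

    all_obs = []
    neighbor_tables = {}
    site_latitudes = {}
    abundances = {}
    growth_forms = {}
    for site in sites:
        plot = site.plot
        site_latitudes[plot.site_name] = plot.absolute_latitude
        trees = pd.concat(site.censuses, ignore_index=True)
        obs = forest_data.build_observations(trees, plot,
                                             buffer_m=config.settings["buffer_m"])
        all_obs.append(obs)
        neighbor_tables.update(
            neighbor_tables_from_censuses(site.censuses, plot.site_name))
        growth_forms.update(forest_data.classify_growth_form(trees))
        for sp in trees["species"].unique():
            abundances[(plot.site_name, sp)] = forest_data.compute_abundance(
                site.censuses[0], plot, sp)
    observations = pd.concat(all_obs, ignore_index=True)
    forest_data.write_observations(observations, outdir / "observations.csv")
    manifest["stages"]["simulate"] = {"wall_s": time.time() - t0,
                                      "n_observations": len(observations)}

    t0 = time.time()
    dcfg = config.density_config()
    if config.settings["grid_search"]:
        dcfg, grid_table = neighborhood.grid_search_mu(
            observations[~observations["edge_excluded"]], neighbor_tables,
            mu_grid=config.settings["mu_grid"], radius=config.settings["radius"],
            k=config.settings["k"])
        grid_table.to_csv(outdir / "grid_search.csv", index=False)
    obs_d = attach_densities(observations, neighbor_tables, dcfg)
    obs_d.to_csv(outdir / "densities.csv", index=False)
    manifest["stages"]["densities"] = {"wall_s": time.time() - t0,
                                       "config_hash": dcfg.config_hash()}

    t0 = time.time()
    delta = neighborhood.perturbation_delta(dcfg)
    bundle = analyze_observations(
        obs_d, site_latitudes, abundances, growth_forms=growth_forms,
        delta_conD=delta, k=config.settings["k"],
        n_draws=config.settings["n_draws"], seed=config.settings["seed"],
        variants=tuple(config.settings["variants"]),
        center_latitude=config.settings["center_latitude"],
        center_abundance=config.settings["center_abundance"])
    bundle["ame_table"].to_csv(outdir / "ame.csv", index=False)
    manifest["stages"]["models"] = {"wall_s": time.time() - t0,
                                    "n_fits": len(bundle["fits"])}

    coef_rows = []
    for name, fit in bundle["meta_fits"].items():
        summ = fit.summary()
        summ.insert(0, "model", name)
        summ["sigma_r"] = fit.sigma_r
        summ["sigma_s"] = fit.sigma_s
        coef_rows.append(summ)
    if coef_rows:
        pd.concat(coef_rows, ignore_index=True).to_csv(
            outdir / "meta_coefficients.csv", index=False)
    records = bundle.get("records")
    if records is not None and len(records):
        summaries, trend = meta.site_summaries(records)
        summaries.to_csv(outdir / "site_summaries.csv", index=False)
        bundle["site_summaries"] = summaries
        bundle["cv_trend"] = trend

    if config.settings["stages"].get("robustness", True) and records is not None \
            and len(records) and "abundance" in bundle["meta_fits"]:
        from . import robustness
        t0 = time.time()
        terms = ("tLatitude", "tAbundance", "tLatitude:tAbundance")
        _, refit, report = robustness.influence_filter(
            records, bundle["meta_fits"]["abundance"], terms,
            threshold=config.settings["cooks_threshold"])
        report.to_csv(outdir / "influence.csv", index=False)
        bundle["influence_refit"] = refit
        screen = robustness.spatial_autocorrelation_screen(
            bundle["fits"], obs_d, seed=config.settings["seed"],
            n_permutations=199)
        screen.to_csv(outdir / "spatial_screen.csv", index=False)
        bundle["spatial_screen"] = screen
        manifest["stages"]["robustness"] = {"wall_s": time.time() - t0}

    for name in ("observations.csv", "ame.csv", "meta_coefficients.csv"):
        path = outdir / name
        if path.exists():
            manifest["stages"].setdefault("hashes", {})[name] = _hash_file(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    bundle["manifest"] = manifest
    bundle["outdir"] = outdir
    return bundle


def make_report(bundle: dict) -> str:
    """Markdown summary: coefficient table, per-site CV table, robustness
    synopsis.  Deterministic given the bundle."""
    lines = ["# CNDD analysis report", ""]
    meta_fits = bundle.get("meta_fits", {})
    if meta_fits:
        lines.append("## Meta-regression coefficients")
        for name, fit in sorted(meta_fits.items()):
            lines.append(f"### model: {name} (sigma_r={fit.sigma_r:.4g}, "
                         f"sigma_s={fit.sigma_s:.4g})")
            lines.append(fit.summary().to_string(index=False))
            lines.append("")
    else:
        lines.append("## Meta-regression coefficients\n_skipped_\n")
    if bundle.get("site_summaries") is not None and "site_summaries" in bundle:
        lines.append("## Site summaries (CV of CNDD)")
        lines.append(bundle["site_summaries"].to_string(index=False))
        trend = bundle.get("cv_trend", {})
        lines.append(f"CV-latitude OLS slope: {trend.get('slope', float('nan')):.4g} "
                     f"(p={trend.get('p', float('nan')):.3g})")
        lines.append("")
    else:
        lines.append("## Site summaries\n_skipped_\n")
    if "spatial_screen" in bundle:
        share = bundle["spatial_screen"].attrs.get("flagged_share", float("nan"))
        lines.append(f"## Robustness\nspatial-autocorrelation flagged share "
                     f"(Holm-adjusted): {share:.3f}")
    else:
        lines.append("## Robustness\n_skipped_")
    if "interquantile_summary" in bundle:
        s = bundle["interquantile_summary"]
        lines.append(f"\nGlobal interquantile mean CNDD: {s['mean_percent']:.2f}% "
                     f"({s['ci_low_percent']:.2f} to {s['ci_high_percent']:.2f}%)")
    return "\n".join(lines)
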