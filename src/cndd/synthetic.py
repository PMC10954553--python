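"""Synthetic multi-site forest censuses with known ground-truth CNDD.

Communities are sampled with log-series species abundances, Thomas-process
spatial clustering and truncated-lognormal stem sizes.  Mortality between
censuses follows a cloglog model whose linear predictor is *linear* in
kernel-weighted conspecific basal area (the true CNDD coefficient), total
basal area and DBH — so true average marginal effects have a closed form
and downstream smooth fits are tested against a linear truth.

Seeds are split hierarchically (ensemble -> site -> census) via
``numpy.random.SeedSequence`` so adding sites never perturbs earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forest_data import PlotMetadata
from .neighborhood import DensityConfig, KernelSpec, compute_densities, basal_area

__all__ = [
    "CommunityConfig",
    "MortalityGenerator",
    "ScenarioSpec",
    "sample_community",
    "simulate_census_interval",
    "make_latitudinal_ensemble",
    "true_rAME",
    "SiteTruth",
    "write_ground_truth",
]


@dataclass
class CommunityConfig:
    n_species: int = 30
    fisher_alpha: float = 8.0
    width: float = 300.0              # metres
    height: float = 300.0
    cluster_rate: float = 1.0         # Thomas parents per ha per species
    cluster_sd: float = 15.0          # offspring dispersion, metres
    dbh_median: float = 2.5           # lognormal median, cm
    dbh_sigma: float = 1.0            # lognormal sigma (log scale)
    dbh_max: float = 100.0

    def __post_init__(self):
        if min(self.n_species, self.fisher_alpha, self.width, self.height,
               self.cluster_rate, self.cluster_sd, self.dbh_median,
               self.dbh_sigma) <= 0:
            raise ValueError("all community rates must be positive")

    @property
    def area_ha(self) -> float:
        return self.width * self.height / 10_000.0

    @property
    def expected_stems(self) -> float:
        # Fisher's relation: S = alpha * ln(1 + N/alpha)
        return self.fisher_alpha * np.expm1(self.n_species / self.fisher_alpha)


@dataclass
class MortalityGenerator:
    """True cloglog mortality model on the hazard scale.

    eta = beta0[sp] + beta_con[sp] * conD + beta_tot * totD + beta_dbh * DBH,
    p(death over dt) = 1 - exp(-exp(eta) * dt).  Densities are kernel-
    weighted basal areas (cm2) under ``density_config``.
    """

    beta0: dict                      # species -> log baseline hazard (1/yr)
    beta_con: dict                   # species -> per weighted-cm2 coefficient
    beta_tot: float = 0.0
    beta_dbh: float = 0.0
    density_config: DensityConfig = field(default_factory=DensityConfig)
    growth_rate: float = 0.15        # deterministic DBH increment, cm/yr

    def linear_predictor(self, census: pd.DataFrame, dens: pd.DataFrame) -> np.ndarray:
        b0 = census["species"].map(self.beta0).to_numpy(dtype=float)
        bc = census["species"].map(self.beta_con).to_numpy(dtype=float)
        return (b0 + bc * dens["conD"].to_numpy()
                + self.beta_tot * dens["totD"].to_numpy()
                + self.beta_dbh * census["dbh"].to_numpy(dtype=float))


@dataclass
class ScenarioSpec:
    """Latitudinal ensemble: site latitudes, a linear trend in the mean
    true effect (on the log(rAME+1) scale), interspecific spread, and a
    target correlation between log abundance and the species effect."""

    latitudes: list
    community: CommunityConfig = field(default_factory=CommunityConfig)
    rame_intercept: float = 0.004     # mean log(rAME+1) at latitude 0
    rame_slope: float = 0.0           # change per degree absolute latitude
    species_sd: float = 0.0           # interspecific s.d. of log(rAME+1)
    abundance_correlation: float = 0.0
    baseline_mortality: tuple = (0.03, 0.12)   # annual, drawn uniform per species
    beta_tot: float = -1e-5
    beta_dbh: float = -0.02
    delta_t: float = 5.0
    n_censuses: int = 2
    seed: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.latitudes)


def _thomas_points(n: int, config: CommunityConfig, rng: np.random.Generator):
    """Thomas cluster process: Poisson parents, Gaussian offspring, points
    kept inside the plot by resampling (no toroidal wrap)."""
    if config.cluster_sd >= 3.0 * max(config.width, config.height):
        # dispersion far beyond the plot: the process degenerates to CSR
        return (rng.uniform(0, config.width, n),
                rng.uniform(0, config.height, n))
    n_parents = max(1, rng.poisson(config.cluster_rate * config.area_ha))
    px = rng.uniform(0, config.width, n_parents)
    py = rng.uniform(0, config.height, n_parents)
    xs = np.empty(n)
    ys = np.empty(n)
    filled = 0
    while filled < n:
        need = n - filled
        parent = rng.integers(0, n_parents, need)
        x = px[parent] + rng.normal(0, config.cluster_sd, need)
        y = py[parent] + rng.normal(0, config.cluster_sd, need)
        ok = (x >= 0) & (x <= config.width) & (y >= 0) & (y <= config.height)
        k = int(ok.sum())
        xs[filled:filled + k] = x[ok]
        ys[filled:filled + k] = y[ok]
        filled += k
    return xs, ys


def _truncated_lognormal(n: int, config: CommunityConfig, rng: np.random.Generator):
    mu = np.log(config.dbh_median)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, config.dbh_sigma, 2 * (n - filled) + 8)
        draw = draw[(draw >= 1.0) & (draw <= config.dbh_max)]
        k = min(len(draw), n - filled)
        out[filled:filled + k] = draw[:k]
        filled += k
    return out


def sample_community(config: CommunityConfig, seed) -> pd.DataFrame:
    """Initial census: log-series abundances, clustered locations,
    truncated-lognormal DBHs.  Deterministic given the seed."""
    if config.expected_stems <= 0:
        raise ValueError("expected total stems must be positive")
    rng = np.random.default_rng(seed)
    n_total = config.expected_stems
    p = n_total / (n_total + config.fisher_alpha)
    from scipy.stats import logser
    counts = logser.rvs(p, size=config.n_species, random_state=rng)
    frames = []
    next_id = 1
    for s in range(config.n_species):
        n = int(counts[s])
        x, y = _thomas_points(n, config, rng)
        dbh = _truncated_lognormal(n, config, rng)
        frames.append(pd.DataFrame({
            "tree_id": np.arange(next_id, next_id + n),
            "species": f"sp{s + 1:03d}", "x": x, "y": y, "dbh": dbh,
        }))
        next_id += n
    census = pd.concat(frames, ignore_index=True)
    census["stem_id"] = census["tree_id"]
    census["status"] = "alive"
    census["census_index"] = 1
    census["date"] = 2000.0
    from .forest_data import STEM_COLUMNS
    return census[STEM_COLUMNS]


def simulate_census_interval(census: pd.DataFrame, generator: MortalityGenerator,
                             delta_t: float, seed) -> pd.DataFrame:
    """Advance one census interval under the generating mortality model.

    Every live tree dies with p = 1 - exp(-exp(eta + log dt)); survivors
    grow deterministically.  Dead trees are carried into the next census
    with status 'dead'.
    """
    rng = np.random.default_rng(seed)
    alive = census[census["status"] == "alive"].reset_index(drop=True)
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    if delta_t == 0:
        p = np.zeros(len(alive))
    else:
        dens = compute_densities(alive, alive, generator.density_config)
        eta = generator.linear_predictor(alive, dens) + np.log(delta_t)
        with np.errstate(over="ignore"):
            p = -np.expm1(-np.exp(np.clip(eta, -700, 700)))
    dies = rng.uniform(size=len(alive)) < p
    nxt = alive.copy()
    nxt["status"] = np.where(dies, "dead", "alive")
    nxt.loc[~dies, "dbh"] = nxt.loc[~dies, "dbh"] + generator.growth_rate * delta_t
    nxt["census_index"] = alive["census_index"] + 1
    nxt["date"] = alive["date"] + delta_t
    return nxt


def true_rAME(generator: MortalityGenerator, census: pd.DataFrame,
              species: str, delta_conD: float | None = None,
              buffer_m: float = 30.0, plot: PlotMetadata | None = None,
              densities: pd.DataFrame | None = None) -> float:
    """Analytic equilibrium rAME under the generating model (dt = 1 year).

    Averages p(conD + delta)/p(conD) - 1 over the species' live sapling
    observations (1 <= DBH < 10 cm, edge-excluded when plot given), the
    same estimand as the fitted pipeline's equilibrium variant.
    """
    from .neighborhood import perturbation_delta
    if delta_conD is None:
        delta_conD = perturbation_delta(generator.density_config)
    alive = census[census["status"] == "alive"].reset_index(drop=True)
    focal = alive[(alive["species"] == species)
                  & (alive["dbh"] >= 1.0) & (alive["dbh"] < 10.0)]
    if plot is not None:
        focal = focal[(focal["x"] >= buffer_m) & (focal["x"] <= plot.width - buffer_m)
                      & (focal["y"] >= buffer_m) & (focal["y"] <= plot.height - buffer_m)]
    if len(focal) == 0:
        raise ValueError(f"species {species!r} has no focal saplings")
    dens = (compute_densities(focal, alive, generator.density_config)
            if densities is None else densities.loc[focal.index])
    eta0 = generator.linear_predictor(focal, dens.loc[focal.index])
    bc = focal["species"].map(generator.beta_con).to_numpy(dtype=float)
    eta1 = eta0 + bc * delta_conD
    p0 = -np.expm1(-np.exp(eta0))
    p1 = -np.expm1(-np.exp(eta1))
    return float(np.mean(p1 / p0 - 1.0))


@dataclass
class SiteTruth:
    plot: PlotMetadata
    censuses: list                      # list of stem DataFrames
    generator: MortalityGenerator
    truth: dict                         # per-species beta_con, target rAME, abundance


def make_latitudinal_ensemble(scenario: ScenarioSpec) -> list[SiteTruth]:
    """Simulate every site of the scenario with stored ground truth.

    Per species, the target log(rAME+1) is the site's latitude trend mean
    plus an interspecific deviation correlated (at the requested level)
    with the species' realized log abundance; the conspecific coefficient
    follows from the small-probability identity log(rAME+1) = beta_con *
    delta_conD.  Baseline intercepts are calibrated so the annual death
    rate at mean covariates matches the drawn species baseline.
    """
    from .neighborhood import perturbation_delta
    root = np.random.SeedSequence(scenario.seed)
    site_seeds = root.spawn(scenario.n_sites)
    delta = perturbation_delta(DensityConfig())
    sites = []
    for s, lat in enumerate(scenario.latitudes):
        seq = site_seeds[s]
        seed_comm, seed_pars, *seed_cens = seq.spawn(2 + scenario.n_censuses - 1)
        rng = np.random.default_rng(seed_pars)
        census0 = sample_community(scenario.community, seed_comm)
        species = sorted(census0["species"].unique())
        counts = census0.groupby("species").size()
        log_ab = np.log(counts.loc[species].to_numpy() / scenario.community.area_ha)

        mean_y = scenario.rame_intercept + scenario.rame_slope * abs(lat)
        z = (log_ab - log_ab.mean()) / (log_ab.std() if log_ab.std() > 0 else 1.0)
        r = scenario.abundance_correlation
        eps = rng.standard_normal(len(species))
        dev = r * z + np.sqrt(max(0.0, 1.0 - r**2)) * eps
        y_target = mean_y + scenario.species_sd * dev
        beta_con = {sp: y_target[i] / delta for i, sp in enumerate(species)}

        lo, hi = scenario.baseline_mortality
        m0 = rng.uniform(lo, hi, len(species))
        gen = MortalityGenerator(
            beta0={sp: 0.0 for sp in species}, beta_con=beta_con,
            beta_tot=scenario.beta_tot, beta_dbh=scenario.beta_dbh,
            density_config=DensityConfig())
        # calibrate intercepts: annual hazard at species-mean covariates
        alive = census0.reset_index(drop=True)
        dens = compute_densities(alive, alive, gen.density_config)
        stats_df = pd.DataFrame({"species": alive["species"],
                                 "conD": dens["conD"], "totD": dens["totD"],
                                 "dbh": alive["dbh"]}).groupby("species").mean()
        beta0 = {}
        for i, sp in enumerate(species):
            row = stats_df.loc[sp]
            beta0[sp] = (np.log(-np.log1p(-m0[i]))
                         - beta_con[sp] * row["conD"]
                         - scenario.beta_tot * row["totD"]
                         - scenario.beta_dbh * row["dbh"])
        gen.beta0 = beta0

        censuses = [census0]
        for c in range(scenario.n_censuses - 1):
            censuses.append(simulate_census_interval(
                censuses[-1], gen, scenario.delta_t, seed_cens[c]))

        plot = PlotMetadata(
            site_name=f"site{s + 1:02d}", width=scenario.community.width,
            height=scenario.community.height, absolute_latitude=abs(lat),
            census_dates=[2000.0 + c * scenario.delta_t
                          for c in range(scenario.n_censuses)])
        truth = {
            "latitude": abs(lat), "mean_log_rame1": mean_y,
            "delta_conD": delta,
            "species": {sp: {"beta_con": beta_con[sp], "beta0": beta0[sp],
                             "target_rAME": float(np.expm1(y_target[i])),
                             "abundance": float(counts[sp] / scenario.community.area_ha)}
                        for i, sp in enumerate(species)},
        }
        sites.append(SiteTruth(plot, censuses, gen, truth))
    return sites


def write_ground_truth(sites: list[SiteTruth], path) -> None:
    payload = {site.plot.site_name: site.truth for site in sites}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=float)
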