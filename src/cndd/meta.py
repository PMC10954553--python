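"""Multilevel measurement-error meta-regression of species-site effects.

Each record carries an effect ``y`` (log(rAME + 1), or aAME untransformed)
with a known sampling variance ``v``.  The model adds a site random
intercept (variance sigma_r^2), a species-in-site random intercept
(sigma_s^2, one level per record) and the known per-record error:

    y_lm = x_lm' b + r_l + s_lm + e_lm,   e_lm ~ N(0, v_lm)

Variance components are profiled by REML (quasi-Newton on log variances,
multi-start); fixed effects are GLS at the optimum with Wald-z inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MetaFit",
    "build_records",
    "fit_meta_regression",
    "predict_cndd_percent",
    "inference_at",
    "site_summaries",
    "site_abundance_models",
    "global_interquantile_summary",
    "reml_neg2_loglik",
]

CENTER_LATITUDE = 11.75      # degrees absolute latitude
CENTER_ABUNDANCE = 1.0       # trees per hectare


def build_records(ame_table: pd.DataFrame, site_latitudes: dict,
                  abundances: dict,
                  center_latitude: float = CENTER_LATITUDE,
                  center_abundance: float = CENTER_ABUNDANCE,
                  transform: str = "log1p") -> pd.DataFrame:
    """Meta-analytic records from an AME table.

    ``y`` is log(rAME + 1) with variance ``var_log_rAME_plus1`` (or raw
    aAME with ``var_aAME`` when ``transform='none'``); latitude and log
    abundance are centered so intercepts refer to a rare tropical species.
    Records flagged unstable, or with non-finite y/v, are dropped and
    counted in ``attrs['n_dropped']``.
    """
    rows = []
    dropped = 0
    for est in ame_table.itertuples():
        if getattr(est, "unstable", False):
            dropped += 1
            continue
        abundance = abundances.get((est.site, est.species))
        if abundance is None:
            raise KeyError(f"missing abundance for {(est.site, est.species)}")
        if transform == "log1p":
            y = np.log1p(est.rAME)
            v = est.var_log_rAME_plus1
        else:
            y = est.aAME
            v = est.var_aAME
        if not (np.isfinite(y) and np.isfinite(v) and v >= 0):
            dropped += 1
            continue
        rows.append({
            "site": est.site, "species": est.species, "y": y, "v": v,
            "absolute_latitude": abs(site_latitudes[est.site]),
            "log_abundance": np.log(abundance),
            "tLatitude": abs(site_latitudes[est.site]) - center_latitude,
            "tAbundance": np.log(abundance) - np.log(center_abundance),
        })
    records = pd.DataFrame(rows)
    if len(records):
        records["tLatitude:tAbundance"] = records["tLatitude"] * records["tAbundance"]
    records.attrs["n_dropped"] = dropped
    records.attrs["center_latitude"] = center_latitude
    records.attrs["center_abundance"] = center_abundance
    return records


@dataclass
class MetaFit:
    terms: list
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    sigma_r: float               # site random-intercept s.d.
    sigma_s: float               # species-in-site random-intercept s.d.
    reml: float                  # -2 restricted log-likelihood (up to a constant)
    n: int
    converged: bool
    center_latitude: float = CENTER_LATITUDE
    center_abundance: float = CENTER_ABUNDANCE
    random: tuple = ("site", "species")

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def ci(self, level: float = 0.95):
        q = stats.norm.ppf(0.5 + level / 2.0)
        return self.beta - q * self.se, self.beta + q * self.se

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci()
        return pd.DataFrame({"term": self.terms, "beta": self.beta, "se": self.se,
                             "ci_low": lo, "ci_high": hi, "z": self.z, "p": self.p})


def _design(records: pd.DataFrame, terms) -> np.ndarray:
    X = [np.ones(len(records))]
    for t in terms:
        X.append(records[t].to_numpy(dtype=float))
    return np.column_stack(X)


def _build_V(v, site_codes, s2_r, s2_s):
    V = np.diag(v + s2_s)
    if site_codes is not None and s2_r > 0:
        same = site_codes[:, None] == site_codes[None, :]
        V = V + s2_r * same
    return V


def reml_neg2_loglik(y, X, v, site_codes, s2_r, s2_s) -> float:
    """-2 * restricted log-likelihood (constant terms dropped)."""
    V = _build_V(v, site_codes, s2_r, s2_s)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    XtViX = X.T @ Vi_X
    sign, logdet_F = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    b = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ b
    quad = r @ np.linalg.solve(V, r)
    out = float(logdet_V + logdet_F + quad)
    return out if np.isfinite(out) else np.inf


def fit_meta_regression(records: pd.DataFrame, terms=(),
                        random=("site", "species"),
                        n_starts: int = 3) -> MetaFit:
    """REML fit of the multilevel measurement-error model.

    ``terms`` are fixed-effect column names of ``records`` (intercept is
    implicit); ``random`` selects which variance components to estimate.
    """
    terms = list(terms)
    y = records["y"].to_numpy(dtype=float)
    v = records["v"].to_numpy(dtype=float)
    X = _design(records, terms)
    use_site = "site" in random and records["site"].nunique() > 1
    site_codes = pd.factorize(records["site"])[0] if use_site else None
    use_species = "species" in random
    scale = max(float(np.var(y)), float(np.mean(v)), 1e-12)

    idx = []
    if use_site:
        idx.append("r")
    if use_species:
        idx.append("s")

    def unpack(theta):
        d = dict(zip(idx, np.exp(np.clip(theta, -60.0, 20.0))))
        return d.get("r", 0.0), d.get("s", 0.0)

    def objective(theta):
        s2_r, s2_s = unpack(theta)
        return reml_neg2_loglik(y, X, v, site_codes, s2_r, s2_s)

    if not idx:
        best_theta, best_val, ok = np.zeros(0), objective(np.zeros(0)), True
    else:
        starts = [np.log(scale) + off for off in (0.0, -4.0, 3.0)][:n_starts]
        best_val, best_theta, ok = np.inf, None, False
        for s0 in starts:
            res = optimize.minimize(objective, np.full(len(idx), s0),
                                    method="L-BFGS-B",
                                    bounds=[(-60.0, 20.0)] * len(idx),
                                    options={"ftol": 1e-12, "gtol": 1e-10})
            if res.fun < best_val:
                best_val, best_theta, ok = float(res.fun), res.x, bool(res.success)
        if best_theta is None:
            raise RuntimeError("meta-regression REML optimization failed")

    s2_r, s2_s = unpack(best_theta)
    V = _build_V(v, site_codes, s2_r, s2_s)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    cov = np.linalg.inv(XtViX)
    beta = cov @ (Vi_X.T @ y)
    se = np.sqrt(np.diag(cov))
    if not ok and not np.isfinite(best_val):
        raise RuntimeError("meta-regression did not converge")
    return MetaFit(["Intercept"] + terms, beta, se, cov,
                   float(np.sqrt(s2_r)), float(np.sqrt(s2_s)), best_val,
                   len(records), ok,
                   records.attrs.get("center_latitude", CENTER_LATITUDE),
                   records.attrs.get("center_abundance", CENTER_ABUNDANCE),
                   tuple(random))


def predict_cndd_percent(fit: MetaFit, latitude: float,
                         abundance: float = CENTER_ABUNDANCE) -> float:
    """Back-transformed CNDD prediction: 100 * (exp(linear predictor) - 1).

    The linear predictor is evaluated at covariates centered the way the
    model was fitted (latitude minus the centering latitude, log abundance
    minus log centering abundance, interaction as their product).
    """
    if not (0.0 <= abs(latitude) <= 66.5):
        import warnings
        warnings.warn("latitude outside the supported 0-66.5 degree range; extrapolating")
    t_lat = abs(latitude) - fit.center_latitude
    t_ab = np.log(abundance) - np.log(fit.center_abundance)
    values = {"Intercept": 1.0, "tLatitude": t_lat, "tAbundance": t_ab,
              "tLatitude:tAbundance": t_lat * t_ab}
    lp = 0.0
    for term, b in zip(fit.terms, fit.beta):
        if term not in values:
            raise KeyError(f"no covariate value for term {term!r}")
        lp += b * values[term]
    return float(100.0 * np.expm1(lp))


def inference_at(records: pd.DataFrame, terms, latitude: float,
                 abundance: float = CENTER_ABUNDANCE,
                 random=("site", "species")) -> MetaFit:
    """Refit with covariates recentered at a new (latitude, abundance) so
    main-effect tests apply at that point of the surface."""
    rec = records.copy()
    rec["tLatitude"] = rec["absolute_latitude"] - abs(latitude)
    if "log_abundance" in rec:
        rec["tAbundance"] = rec["log_abundance"] - np.log(abundance)
        rec["tLatitude:tAbundance"] = rec["tLatitude"] * rec["tAbundance"]
    rec.attrs["center_latitude"] = abs(latitude)
    rec.attrs["center_abundance"] = abundance
    return fit_meta_regression(rec, terms, random=random)


def site_summaries(records: pd.DataFrame, min_estimates: int = 2,
                   cv_threshold: float = 0.4) -> tuple[pd.DataFrame, dict]:
    """Per-site mean / latent s.d. / CV of the transformed effect, plus the
    OLS trend of CV on absolute latitude.

    Mean and s.d. are the intercept and species random-effect s.d. of an
    intercept-only per-site meta-regression; CV is computed only where the
    mean is positive.  Sites with fewer than ``min_estimates`` records are
    skipped.
    """
    rows = []
    for site, sub in records.groupby("site"):
        if len(sub) < min_estimates:
            continue
        fit = fit_meta_regression(sub, terms=(), random=("species",))
        mean_y = float(fit.beta[0])
        sd_y = fit.sigma_s
        cv = sd_y / mean_y if mean_y > 0 else np.nan
        rows.append({"site": site, "n": len(sub), "mean_y": mean_y, "sd_y": sd_y,
                     "CV": cv, "included_in_cv_analysis": mean_y > 0,
                     "cv_above_threshold": bool(mean_y > 0 and cv > cv_threshold),
                     "absolute_latitude": float(sub["absolute_latitude"].iloc[0])})
    table = pd.DataFrame(rows)
    trend = {"slope": np.nan, "p": np.nan, "intercept": np.nan}
    sub = table[table["included_in_cv_analysis"]] if len(table) else table
    if len(sub) >= 3:
        res = stats.linregress(sub["absolute_latitude"], sub["CV"])
        trend = {"slope": float(res.slope), "p": float(res.pvalue),
                 "intercept": float(res.intercept)}
    return table, trend


def site_abundance_models(records: pd.DataFrame) -> pd.DataFrame:
    """Per-site meta-regression of effect on log abundance (species random
    intercept): slope, Wald CI and p per site."""
    rows = []
    for site, sub in records.groupby("site"):
        if len(sub) < 2 or sub["log_abundance"].nunique() < 2:
            continue
        fit = fit_meta_regression(sub, terms=("tAbundance",), random=("species",))
        lo, hi = fit.ci()
        rows.append({"site": site, "slope": float(fit.beta[1]),
                     "ci_low": float(lo[1]), "ci_high": float(hi[1]),
                     "p": float(fit.p[1]), "n": len(sub)})
    return pd.DataFrame(rows)


def global_interquantile_summary(records: pd.DataFrame) -> dict:
    """Intercept-only multilevel fit of interquantile-variant estimates,
    back-transformed to a global mean % change with a 95% Wald CI.  Not
    comparable across species (the density change differs per species)."""
    fit = fit_meta_regression(records, terms=(), random=("site", "species"))
    lo, hi = fit.ci()
    return {"mean_percent": float(100.0 * np.expm1(fit.beta[0])),
            "ci_low_percent": float(100.0 * np.expm1(lo[0])),
            "ci_high_percent": float(100.0 * np.expm1(hi[0])),
            "fit": fit}
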