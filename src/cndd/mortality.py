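"""Species-site discrete-time survival models.

Mortality over a census interval is modelled as a binomial outcome with a
complementary log-log link and an offset of log interval length, so the
linear predictor acts on the log cumulative hazard and unequal census
intervals are handled exactly for a constant hazard:

    log(-log(1 - Pr(death))) = b0 + f(conD) + f(totD) + f(DBH) + u_j + log(dt)

Smooths are penalized B-splines (second-order difference penalty, whose
null space contains linear functions); the census random intercept u_j is
an extra ridge-penalized block.  Smoothing parameters (and the implied
random-intercept variance) are chosen by Laplace-approximate restricted
marginal likelihood (REML), and the returned covariance is the Bayesian
posterior covariance of all coefficients at the selected penalties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.interpolate import BSpline
from sklearn.metrics import roc_auc_score

__all__ = [
    "SmoothTerm",
    "LinearTerm",
    "SpeciesEligibility",
    "MortalityModelFit",
    "assess_eligibility",
    "fit_mortality_model",
    "fit_rare_group_models",
    "predict_mortality",
    "draw_coefficients",
    "model_residual_quantiles",
    "cloglog_inv",
]

_ETA_LO, _ETA_HI = -30.0, 7.0
_P_FLOOR = 1e-12


def cloglog_inv(eta):
    """p = 1 - exp(-exp(eta)), clipped away from {0, 1}."""
    eta = np.clip(eta, _ETA_LO, _ETA_HI)
    p = -np.expm1(-np.exp(eta))
    return np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)


# ---------------------------------------------------------------------------
# model terms


@dataclass
class SmoothTerm:
    """Centered penalized B-spline smooth of one predictor."""

    name: str
    knots: np.ndarray
    degree: int
    constraint: np.ndarray        # k x (k-1) null-space transform of the centering constraint
    penalty: np.ndarray           # constrained penalty matrix
    penalty_rank: int
    penalty_logdet: float         # log pseudo-determinant of `penalty`

    @property
    def n_coef(self) -> int:
        return self.constraint.shape[1]

    def design(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        k = len(self.knots) - self.degree - 1
        B = BSpline(self.knots, np.eye(k), self.degree, extrapolate=True)(x)
        return B @ self.constraint


@dataclass
class LinearTerm:
    """Unpenalized linear fallback when too few unique values for a smooth."""

    name: str
    center: float
    scale: float

    @property
    def n_coef(self) -> int:
        return 1

    def design(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return ((x - self.center) / self.scale)[:, None]


def _make_smooth(name: str, x: np.ndarray, k: int, degree: int = 3) -> SmoothTerm:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError(f"predictor {name} is constant")
    step = (hi - lo) / (k - degree)
    knots = lo + step * np.arange(-degree, k + 1, dtype=float)
    B = BSpline(knots, np.eye(k), degree, extrapolate=True)(x)
    c = B.mean(axis=0)
    Z = linalg.null_space(c[None, :])          # k x (k-1)
    D = np.diff(np.eye(k), 2, axis=0)
    S = Z.T @ (D.T @ D) @ Z
    ev = linalg.eigvalsh(S)
    tol = max(ev) * 1e-10
    pos = ev[ev > tol]
    return SmoothTerm(name, knots, degree, Z, S, len(pos), float(np.sum(np.log(pos))))


# ---------------------------------------------------------------------------
# eligibility


@dataclass
class SpeciesEligibility:
    n_alive: int
    n_dead: int
    n_unique_conD: int
    range_covers_evaluation: bool
    decision: str                  # individual | pooled_rare_tree | pooled_rare_shrub


def assess_eligibility(observations: pd.DataFrame, perturbation_delta: float,
                       growth_form: str = "tree") -> SpeciesEligibility:
    """Individual model iff >=20 alive, >=20 dead, >=4 unique conD values
    and an observed conD range at least as wide as the evaluation
    perturbation; otherwise routed to the rare-species pooled group of the
    matching growth form."""
    y = observations["Y"].to_numpy()
    n_dead = int(y.sum())
    n_alive = int(len(y) - n_dead)
    conD = observations["conD"].to_numpy(dtype=float)
    n_unique = len(np.unique(conD))
    covers = bool(len(conD) and (conD.max() - conD.min()) >= perturbation_delta)
    ok = n_alive >= 20 and n_dead >= 20 and n_unique >= 4 and covers
    if ok:
        decision = "individual"
    else:
        decision = "pooled_rare_shrub" if growth_form == "shrub" else "pooled_rare_tree"
    return SpeciesEligibility(n_alive, n_dead, n_unique, covers, decision)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class MortalityModelFit:
    terms: list
    beta: np.ndarray
    cov: np.ndarray                # Bayesian posterior covariance at selected penalties
    lambdas: np.ndarray
    census_levels: list | None     # unique census interval labels, or None
    sigma_u: float
    loglik: float
    reml: float
    converged: bool
    auc: float
    edf: float
    n_obs: int
    predictors: tuple = ("conD", "totD", "dbh")
    flags: dict = field(default_factory=dict)

    @property
    def n_coef(self) -> int:
        return len(self.beta)

    def design_matrix(self, data: pd.DataFrame, census: bool = False) -> np.ndarray:
        """Fixed-effect design rows for new data.

        Census random-intercept columns are zeroed (population-mean
        prediction) unless ``census`` is requested and levels match.
        """
        n = len(data)
        cols = [np.ones((n, 1))]
        for term in self.terms:
            cols.append(term.design(data[term.name].to_numpy(dtype=float)))
        if self.census_levels is not None:
            Zc = np.zeros((n, len(self.census_levels)))
            if census and "j" in data:
                lev = {l: i for i, l in enumerate(self.census_levels)}
                for r, j in enumerate(data["j"].to_numpy()):
                    if j in lev:
                        Zc[r, lev[j]] = 1.0
            cols.append(Zc)
        return np.hstack(cols)


def _pirls(X, y, offset, Slam, beta=None, max_iter=100, tol=1e-10):
    n, p = X.shape
    if beta is None:
        mu = np.clip((y + 0.5) / 2.0, 0.05, 0.95)
        eta = np.log(-np.log(1 - mu))
    else:
        eta = np.clip(X @ beta + offset, _ETA_LO, _ETA_HI)

    def pen_ll(b, eta_lin):
        prob = cloglog_inv(eta_lin)
        ll = np.sum(y * np.log(prob) + (1 - y) * np.log1p(-prob))
        return ll - 0.5 * (b @ Slam @ b)

    beta_cur = beta if beta is not None else np.zeros(p)
    pll_cur = -np.inf if beta is None else pen_ll(beta_cur, eta)
    converged = False
    for _ in range(max_iter):
        eta_c = np.clip(eta, _ETA_LO, _ETA_HI)
        theta = np.exp(eta_c)
        prob = cloglog_inv(eta_c)
        dmu = theta * np.exp(-theta)
        var = prob * (1 - prob)
        w = np.maximum(dmu**2 / var, 1e-10)
        # score-form right-hand side: W z = W (eta - offset) + (y-p) mu' / V,
        # which never divides by mu' (numerically safe at extreme eta)
        score_vec = (y - prob) * dmu / var
        XtW = X.T * w
        H = XtW @ X + Slam
        try:
            c, low = linalg.cho_factor(H, lower=True)
            rhs = XtW @ (eta_c - offset) + X.T @ score_vec
            beta_new = linalg.cho_solve((c, low), rhs)
        except linalg.LinAlgError:
            return beta_cur, None, False, pll_cur
        # step halving on the penalized log-likelihood
        step = 1.0
        b_try, pll_try, eta_try = beta_new, -np.inf, eta
        for _ in range(30):
            b_try = (beta_cur + step * (beta_new - beta_cur)
                     if np.isfinite(pll_cur) else beta_new)
            eta_try = np.clip(X @ b_try + offset, _ETA_LO, _ETA_HI)
            pll_try = pen_ll(b_try, eta_try)
            if np.isfinite(pll_try) and (pll_try >= pll_cur - 1e-10
                                         or not np.isfinite(pll_cur)):
                break
            step /= 2.0
        delta = np.max(np.abs(b_try - beta_cur)) / (1.0 + np.max(np.abs(b_try)))
        improved = pll_try - pll_cur if np.isfinite(pll_cur) else np.inf
        beta_cur, eta, pll_cur = b_try, eta_try, pll_try
        if (step == 1.0 and delta < 1e-9) or \
                (np.isfinite(improved) and 0 <= improved < tol * (1.0 + abs(pll_cur))):
            converged = True
            break
    return beta_cur, eta, converged, pll_cur


def _assemble(data: pd.DataFrame, predictors, k: int):
    """Build terms, design matrix, penalty blocks and census structure."""
    n = len(data)
    terms = []
    for name in predictors:
        x = data[name].to_numpy(dtype=float)
        nvals = len(np.unique(x))
        if nvals < 2:
            continue                      # constant predictor: drop
        k_eff = k if nvals >= 10 else nvals - 2
        if k_eff >= 4:
            terms.append(_make_smooth(name, x, k_eff))
        else:
            terms.append(LinearTerm(name, float(x.mean()), float(x.std() or 1.0)))
    census_levels = None
    if "j" in data.columns:
        levels = sorted(pd.unique(data["j"]))
        if len(levels) > 1:
            census_levels = levels

    cols = [np.ones((n, 1))]
    blocks = []                           # (slice, S, rank, logdet, kind)
    pos = 1
    for term in terms:
        q = term.n_coef
        cols.append(term.design(data[term.name].to_numpy(dtype=float)))
        if isinstance(term, SmoothTerm):
            blocks.append((slice(pos, pos + q), term.penalty,
                           term.penalty_rank, term.penalty_logdet, "smooth"))
        pos += q
    if census_levels is not None:
        q = len(census_levels)
        Zc = np.zeros((n, q))
        lev = {l: i for i, l in enumerate(census_levels)}
        for r, j in enumerate(data["j"].to_numpy()):
            Zc[r, lev[j]] = 1.0
        cols.append(Zc)
        blocks.append((slice(pos, pos + q), np.eye(q), q, 0.0, "ranef"))
        pos += q
    X = np.hstack(cols)
    return terms, X, blocks, census_levels


def fit_mortality_model(data: pd.DataFrame, k: int = 10,
                        predictors=("conD", "totD", "dbh"),
                        fixed_log_lambda=None,
                        correct_covariance: bool = True) -> MortalityModelFit:
    """Fit the penalized cloglog survival model by PIRLS + REML.

    Parameters
    ----------
    data
        Observations with columns ``Y`` (1 = dead), ``dt`` (years) and the
        predictor columns; optional ``j`` census interval labels.
    k
        Smooth basis dimension (reduced to nvals - 2 when a predictor has
        fewer than 10 unique values; below 4 a linear term is used).
    fixed_log_lambda
        Optional array of log smoothing parameters to skip REML selection
        (one per penalized block, census ridge last).

    Non-convergence is flagged on the returned fit, never raised.
    """
    data = data.reset_index(drop=True)
    y = data["Y"].to_numpy(dtype=float)
    dt = data["dt"].to_numpy(dtype=float)
    offset = np.log(dt)
    avail = [p for p in predictors if p in data.columns]
    terms, X, blocks, census_levels = _assemble(data, avail, k)
    n, p = X.shape
    n_pen = len(blocks)
    mp = p - sum(b[2] for b in blocks)     # dimension of the unpenalized space
    if fixed_log_lambda is not None and len(fixed_log_lambda) != n_pen:
        fixed_log_lambda = None            # block structure differs: reselect

    def slam_of(rho):
        S = np.zeros((p, p))
        for (sl, Sj, _, _, _), r in zip(blocks, rho):
            S[sl, sl] += np.exp(r) * Sj
        return S

    warm = {"beta": None}

    def laml(rho):
        rho = np.clip(rho, -18.0, 20.0)
        Slam = slam_of(rho)
        beta, eta, conv, pll = _pirls(X, y, offset, Slam, beta=warm["beta"])
        if eta is None or not np.isfinite(pll):
            return 1e10
        warm["beta"] = beta.copy()
        theta = np.exp(np.clip(eta, _ETA_LO, _ETA_HI))
        prob = cloglog_inv(eta)
        dmu = np.maximum(theta * np.exp(-theta), 1e-15)
        w = np.maximum(dmu**2 / (prob * (1 - prob)), 1e-12)
        H = (X.T * w) @ X + Slam
        sign, logdet_H = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        logdet_S = sum(r * rho_j + ld for (_, _, r, ld, _), rho_j in zip(blocks, rho))
        return -pll + 0.5 * logdet_H - 0.5 * logdet_S - 0.5 * mp * np.log(2 * np.pi)

    opt_ok = True
    if n_pen == 0:
        rho_hat = np.zeros(0)
        reml = laml(rho_hat)
    elif fixed_log_lambda is not None:
        rho_hat = np.asarray(fixed_log_lambda, dtype=float)
        reml = laml(rho_hat)
    else:
        res = optimize.minimize(laml, np.zeros(n_pen), method="Nelder-Mead",
                                options={"xatol": 0.02, "fatol": 1e-4,
                                         "maxiter": 120 * max(n_pen, 1)})
        rho_hat = np.clip(res.x, -18.0, 20.0)
        reml = float(res.fun)
        opt_ok = bool(np.isfinite(res.fun))

    def beta_at(rho):
        Slam_r = slam_of(np.clip(rho, -18.0, 20.0))
        b, e, _, pll = _pirls(X, y, offset, Slam_r, beta=warm["beta"])
        return b if e is not None else None

    Slam = slam_of(rho_hat)
    beta, eta, pirls_ok, _ = _pirls(X, y, offset, Slam, beta=warm["beta"],
                                    max_iter=200, tol=1e-12)
    flags = {}
    if eta is None:
        return MortalityModelFit(terms, beta, np.full((p, p), np.nan),
                                 np.exp(rho_hat), census_levels, np.nan,
                                 -np.inf, np.inf, False, np.nan, np.nan, n,
                                 tuple(avail), {"pirls_failed": True})
    prob = cloglog_inv(eta)
    theta = np.exp(np.clip(eta, _ETA_LO, _ETA_HI))
    dmu = np.maximum(theta * np.exp(-theta), 1e-15)
    w = np.maximum(dmu**2 / (prob * (1 - prob)), 1e-12)
    H = (X.T * w) @ X + Slam
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cov = linalg.inv(H)
        if caught:
            flags["ill_conditioned"] = True
        cov = 0.5 * (cov + cov.T)
        cov_ok = np.all(np.isfinite(cov))
    except linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        cov_ok = False
    # smoothing-parameter uncertainty correction ("unconditional" covariance):
    # Vc = Vp + J Sigma_rho J', with J = d beta_hat / d rho (central
    # differences) and Sigma_rho the inverse LAML Hessian in log-lambda,
    # restricted to its positive-curvature subspace.
    if cov_ok and n_pen > 0 and fixed_log_lambda is None and opt_ok \
            and correct_covariance:
        try:
            h = 0.5
            J = np.zeros((p, n_pen))
            fd_ok = True
            f0 = reml
            hess = np.zeros((n_pen, n_pen))
            b_plus, b_minus = [], []
            f_plus = np.zeros(n_pen)
            f_minus = np.zeros(n_pen)
            for i in range(n_pen):
                e = np.zeros(n_pen)
                e[i] = h
                bp = beta_at(rho_hat + e)
                bm = beta_at(rho_hat - e)
                f_plus[i] = laml(rho_hat + e)
                f_minus[i] = laml(rho_hat - e)
                if bp is None or bm is None:
                    fd_ok = False
                    break
                J[:, i] = (bp - bm) / (2.0 * h)
                hess[i, i] = (f_plus[i] - 2.0 * f0 + f_minus[i]) / h**2
            if fd_ok:
                for i in range(n_pen):
                    for j in range(i + 1, n_pen):
                        ei = np.zeros(n_pen); ei[i] = h
                        ej = np.zeros(n_pen); ej[j] = h
                        fpp = laml(rho_hat + ei + ej)
                        fmm = laml(rho_hat - ei - ej)
                        hess[i, j] = hess[j, i] = (
                            fpp + fmm + 2.0 * f0
                            - f_plus[i] - f_minus[i] - f_plus[j] - f_minus[j]
                        ) / (2.0 * h**2)
                ev, U = linalg.eigh(0.5 * (hess + hess.T))
                inv_ev = np.where(ev > 1e-6, 1.0 / np.maximum(ev, 1e-6), 0.0)
                sigma_rho = (U * inv_ev) @ U.T
                cov = cov + J @ sigma_rho @ J.T
                cov = 0.5 * (cov + cov.T)
                flags["cov_corrected"] = True
            else:
                flags["cov_conditional"] = True
        except (linalg.LinAlgError, ValueError):
            flags["cov_conditional"] = True
    elif n_pen > 0:
        flags["cov_conditional"] = True

    loglik = float(np.sum(y * np.log(prob) + (1 - y) * np.log1p(-prob)))
    score = X.T @ ((y - prob) * dmu / (prob * (1 - prob))) - Slam @ beta
    # convergence is judged by the Newton decrement g' H^-1 g / 2 (the
    # attainable penalized log-likelihood gain), which unlike a raw
    # max|score| threshold is invariant to the penalty scale
    try:
        decrement = 0.5 * float(score @ linalg.solve(H, score, assume_a="pos"))
        score_ok = bool(np.isfinite(decrement) and decrement < 1e-6 * max(1.0, n / 1000.0))
    except linalg.LinAlgError:
        decrement, score_ok = np.inf, False
    if not score_ok:
        flags["score"] = float(np.max(np.abs(score)))
        flags["newton_decrement"] = float(decrement)
    edf = float(np.trace(cov @ ((X.T * w) @ X))) if cov_ok else np.nan
    sigma_u = np.nan
    if census_levels is not None:
        # ridge weight on the census block is the precision of u_j
        ranef_rho = rho_hat[[i for i, b in enumerate(blocks) if b[4] == "ranef"][0]]
        sigma_u = float(np.exp(-0.5 * ranef_rho))
    if len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, prob))
    else:
        auc = np.nan
    converged = bool(pirls_ok and opt_ok and cov_ok and score_ok)
    fit = MortalityModelFit(terms, beta, cov, np.exp(rho_hat), census_levels,
                            sigma_u, loglik, reml, converged, auc, edf, n,
                            tuple(avail), flags)
    return fit


def fit_rare_group_models(pooled: pd.DataFrame, k: int = 10) -> dict:
    """One joint fit per rare-species group (``group`` column holds
    ``pooled_rare_tree`` / ``pooled_rare_shrub``).  Empty groups are
    skipped with a warning."""
    fits = {}
    for group, sub in pooled.groupby("group"):
        if len(sub) == 0 or sub["Y"].nunique() < 2:
            warnings.warn(f"rare group {group} degenerate; skipped")
            continue
        fits[group] = fit_mortality_model(sub, k=k)
    return fits


def predict_mortality(fit: MortalityModelFit, covariates: pd.DataFrame,
                      delta_t=1.0, beta=None) -> np.ndarray:
    """Mortality probability over ``delta_t`` years at population-mean
    census effect (u_j = 0)."""
    X = fit.design_matrix(covariates)
    b = fit.beta if beta is None else beta
    eta = X @ b + np.log(np.asarray(delta_t, dtype=float))
    return cloglog_inv(eta)


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    ev, V = linalg.eigh(cov)
    ev_clip = np.clip(ev, 0.0, None)
    return (V * ev_clip) @ V.T


def draw_coefficients(fit: MortalityModelFit, n_draws: int = 500,
                      seed: int | None = None) -> np.ndarray:
    """``n_draws`` coefficient vectors ~ MVN(beta, cov); deterministic given
    seed.  Non-PSD covariances are repaired by eigenvalue clipping."""
    rng = np.random.default_rng(seed)
    cov = fit.cov
    try:
        L = linalg.cholesky(cov + 1e-300 * np.eye(fit.n_coef), lower=True)
    except linalg.LinAlgError:
        warnings.warn("covariance not PSD; repaired by eigenvalue clipping")
        cov = _nearest_psd(cov)
        L = linalg.cholesky(cov + 1e-12 * np.trace(cov) / fit.n_coef * np.eye(fit.n_coef),
                            lower=True)
    z = rng.standard_normal((n_draws, fit.n_coef))
    return fit.beta + z @ L.T


def model_residual_quantiles(fit: MortalityModelFit, observations: pd.DataFrame,
                             seed: int | None = None) -> np.ndarray:
    """Randomized quantile residuals: uniform on [0, 1] under the fitted
    model.  For a Bernoulli outcome with death probability p the residual
    is U(0, 1-p) for survivors and U(1-p, 1) for deaths."""
    rng = np.random.default_rng(seed)
    p = predict_mortality(fit, observations, observations["dt"].to_numpy(dtype=float))
    u = rng.uniform(size=len(observations))
    y = observations["Y"].to_numpy(dtype=float)
    return np.where(y == 1.0, (1 - p) + u * p, u * (1 - p))
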