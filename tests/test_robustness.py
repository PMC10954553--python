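import numpy as np
import pandas as pd
import pytest
from scipy import special
from statsmodels.stats.multitest import multipletests

from cndd.meta import fit_meta_regression
from cndd.robustness import (RandomizationSpec, compute_life_history,
                             confounder_meta_models, cooks_distances,
                             influence_filter, morans_i, randomize_dataset,
                             spatial_autocorrelation_screen)


@pytest.fixture
def observations(rng):
    n = 400
    return pd.DataFrame({
        "site": "s1",
        "species": rng.choice(["A", "B", "C", "solo"], n,
                              p=[0.4, 0.35, 0.2475, 0.0025]),
        "Y": rng.integers(0, 2, n),
        "dt": 5.0,
        "conD": rng.gamma(2, 20, n),
        "totD": rng.gamma(3, 100, n),
        "dbh": rng.uniform(1, 10, n),
        "x": rng.uniform(0, 100, n),
        "y": rng.uniform(0, 100, n)})


class TestRandomize:
    def test_status_shuffle_preserves_species_death_counts(self, observations):
        spec = RandomizationSpec("status_within_species", seed=1)
        out = randomize_dataset(observations, spec)
        before = observations.groupby("species")["Y"].sum()
        after = out.groupby("species")["Y"].sum()
        pd.testing.assert_series_equal(before, after)

    def test_conD_shuffle_leaves_other_columns(self, observations):
        spec = RandomizationSpec("conD_within_species", seed=2)
        out = randomize_dataset(observations, spec)
        for col in ("Y", "totD", "dbh", "dt"):
            np.testing.assert_array_equal(observations[col], out[col])
        # multiset within species preserved
        for sp, sub in observations.groupby("species"):
            np.testing.assert_allclose(np.sort(sub["conD"]),
                                       np.sort(out.loc[sub.index, "conD"]))

    def test_single_observation_species_unchanged(self, observations):
        solo = observations[observations["species"] == "solo"]
        assert len(solo) >= 1
        spec = RandomizationSpec("conD_within_species", seed=3)
        out = randomize_dataset(observations, spec)
        np.testing.assert_array_equal(solo["conD"], out.loc[solo.index, "conD"])

    def test_determinism(self, observations):
        spec = RandomizationSpec("status_within_species", seed=9)
        a = randomize_dataset(observations, spec)
        b = randomize_dataset(observations, spec)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            RandomizationSpec("bogus")


def toy_meta_records(seed=0, n_sites=4, n_species=6):
    rng = np.random.default_rng(seed)
    rows = []
    for l in range(n_sites):
        for m in range(n_species):
            rows.append({"site": f"s{l}", "species": f"sp{m}",
                         "y": rng.normal(0.005, 0.003),
                         "v": rng.uniform(1e-6, 4e-6),
                         "absolute_latitude": 5.0 + 12.0 * l,
                         "log_abundance": rng.normal(2, 1)})
    rec = pd.DataFrame(rows)
    rec["tLatitude"] = rec["absolute_latitude"] - 11.75
    rec["tAbundance"] = rec["log_abundance"]
    rec["tLatitude:tAbundance"] = rec["tLatitude"] * rec["tAbundance"]
    return rec


class TestInfluence:
    def test_on_surface_large_v_near_zero_distance(self):
        rec = toy_meta_records(seed=1)
        terms = ("tLatitude",)
        fit = fit_meta_regression(rec, terms)
        # append a record exactly on the fitted surface with huge variance
        new = rec.iloc[[0]].copy()
        new["y"] = fit.beta[0] + fit.beta[1] * new["tLatitude"]
        new["v"] = 10.0
        new["species"] = "extra"
        rec2 = pd.concat([rec, new], ignore_index=True)
        fit2 = fit_meta_regression(rec2, terms)
        D = cooks_distances(rec2, fit2, terms)
        assert D[-1] < 1e-4

    def test_matches_bruteforce_loo_oracle(self):
        from cndd.meta import _design, _build_V
        rec = toy_meta_records(seed=2, n_sites=2, n_species=5)
        terms = ("tLatitude",)
        fit = fit_meta_regression(rec, terms)
        D = cooks_distances(rec, fit, terms)
        # oracle: explicit GLS refit per left-out record, V fixed
        y = rec["y"].to_numpy()
        X = _design(rec, list(terms))
        codes = pd.factorize(rec["site"])[0]
        V = _build_V(rec["v"].to_numpy(), codes, fit.sigma_r**2, fit.sigma_s**2)
        Vi = np.linalg.inv(V)
        F = X.T @ Vi @ X
        b = np.linalg.solve(F, X.T @ Vi @ y)
        for i in range(len(rec)):
            keep = np.arange(len(rec)) != i
            Vs = np.linalg.inv(V[np.ix_(keep, keep)])
            bi = np.linalg.solve(X[keep].T @ Vs @ X[keep], X[keep].T @ Vs @ y[keep])
            d = bi - b
            assert D[i] == pytest.approx(d @ F @ d, abs=1e-6)

    def test_threshold_infinity_removes_nothing(self):
        rec = toy_meta_records(seed=3)
        terms = ("tLatitude",)
        fit = fit_meta_regression(rec, terms)
        reduced, refit, report = influence_filter(rec, fit, terms, threshold=np.inf)
        assert len(reduced) == len(rec)
        assert not report["removed"].any()

    def test_lower_threshold_removes_superset(self):
        rec = toy_meta_records(seed=4)
        terms = ("tLatitude",)
        fit = fit_meta_regression(rec, terms)
        _, _, rep_hi = influence_filter(rec, fit, terms, threshold=0.05)
        _, _, rep_lo = influence_filter(rec, fit, terms, threshold=0.005)
        hi_removed = set(rep_hi.index[rep_hi["removed"]])
        lo_removed = set(rep_lo.index[rep_lo["removed"]])
        assert hi_removed <= lo_removed


class TestHolm:
    def test_printed_example(self):
        flag, p_adj, _, _ = multipletests([0.01, 0.04], alpha=0.05, method="holm")
        np.testing.assert_allclose(p_adj, [0.02, 0.04])
        assert flag.all()

    def test_monotone_and_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 20)
        _, p_adj, _, _ = multipletests(p, method="holm")
        assert (p_adj >= p - 1e-15).all()


class TestMoransI:
    def test_iid_residuals_not_flagged(self, rng):
        xy = rng.uniform(0, 100, (150, 2))
        vals = rng.uniform(size=150)
        i_obs, p = morans_i(vals, xy, n_permutations=199, seed=1)
        assert p > 0.01

    def test_strong_gradient_detected(self, rng):
        xy = rng.uniform(0, 100, (150, 2))
        vals = xy[:, 0] / 100.0 + rng.normal(0, 0.02, 150)
        i_obs, p = morans_i(vals, xy, n_permutations=199, seed=2)
        assert i_obs > 0
        assert p < 0.02

    def test_constant_values_degenerate(self, rng):
        xy = rng.uniform(0, 100, (50, 2))
        i_obs, p = morans_i(np.ones(50), xy)
        assert np.isnan(p)

    def test_screen_runs_and_holm_adjusts(self, observations):
        from cndd.mortality import fit_mortality_model
        fits = {}
        for sp, sub in observations.groupby("species"):
            if len(sub) > 50:
                fits[("s1", sp)] = fit_mortality_model(sub)
        table = spatial_autocorrelation_screen(fits, observations, seed=0,
                                               n_permutations=99)
        assert {"moran_i", "p_raw", "p_holm", "flagged"} <= set(table.columns)
        assert (table["p_holm"] >= table["p_raw"] - 1e-12).all()


class TestLifeHistory:
    def make_trees(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for sp, (inc, surv) in {"A": (0.2, 0.98), "B": (0.5, 0.90),
                                "C": (0.1, 0.95)}.items():
            for t in range(40):
                dbh0 = rng.uniform(1, 12)
                alive = rng.uniform() < surv**5
                rows.append([f"{sp}{t}", sp, dbh0, "alive", 1, 2000.0])
                rows.append([f"{sp}{t}", sp, dbh0 + 5 * inc,
                             "alive" if alive else "dead", 2, 2005.0])
        return pd.DataFrame(rows, columns=["tree_id", "species", "dbh",
                                           "status", "census_index", "date"])

    def make_obs(self, trees):
        first = trees[trees["census_index"] == 1].set_index("tree_id")
        second = trees[trees["census_index"] == 2].set_index("tree_id")
        return pd.DataFrame({
            "site": "s1", "species": first["species"],
            "Y": (second["status"] == "dead").astype(int),
            "dt": 5.0, "conD": 1.0, "totD": 1.0, "dbh": first["dbh"]})

    def test_growth_raw_is_log1p_median_increment(self):
        trees = self.make_trees()
        cov = compute_life_history(trees, self.make_obs(trees), "s1")
        a = cov.set_index("species")
        assert a.loc["B", "growth_raw"] == pytest.approx(np.log1p(0.5), abs=1e-9)
        assert a.loc["A", "growth_raw"] == pytest.approx(np.log1p(0.2), abs=1e-9)

    def test_survival_raw_is_logit_annual_survival(self):
        trees = self.make_trees(seed=1)
        cov = compute_life_history(trees, self.make_obs(trees), "s1").set_index("species")
        # spot-check scale: logit(0.98) = 3.8918
        assert special.logit(0.98) == pytest.approx(3.8918, abs=1e-4)
        assert cov["survival_raw"].between(0, 8).all()

    def test_standardized_columns(self):
        trees = self.make_trees(seed=2)
        cov = compute_life_history(trees, self.make_obs(trees), "s1")
        for col in ("growth", "survival", "stature"):
            assert cov[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert cov[col].std(ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestConfounderModels:
    def test_orthogonal_covariates_keep_abundance_effect(self):
        rec = toy_meta_records(seed=6, n_sites=4, n_species=8)
        rng = np.random.default_rng(0)
        cov = rec[["site", "species"]].drop_duplicates().copy()
        cov["growth"] = rng.standard_normal(len(cov))
        cov["survival"] = rng.standard_normal(len(cov))
        cov["axis_growth_survival"] = rng.standard_normal(len(cov))
        cov["axis_stature_recruitment"] = rng.standard_normal(len(cov))
        out = confounder_meta_models(rec, cov)
        base = out["base_fit"]
        i = base.terms.index("tAbundance")
        res = out[("growth", "survival")]
        assert abs(res["abundance_beta"] - base.beta[i]) < 1.5 * base.se[i]

    def test_zero_variance_covariate_warns(self):
        rec = toy_meta_records(seed=7)
        cov = rec[["site", "species"]].drop_duplicates().copy()
        cov["growth"] = 0.0
        cov["survival"] = np.random.default_rng(1).standard_normal(len(cov))
        cov["axis_growth_survival"] = cov["survival"]
        cov["axis_stature_recruitment"] = cov["survival"]
        with pytest.warns(UserWarning):
            confounder_meta_models(rec, cov, extra_pairs=(("growth", "survival"),))
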