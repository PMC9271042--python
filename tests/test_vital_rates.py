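"""Penalized vital-rate models: oracle equivalence, recovery, prediction."""

import numpy as np
import pandas as pd
import pytest

import batlife as bl
from batlife.vital_rates import (LinearTerm, ModelSpec, SmoothTerm, fit_model,
                                 predict_rates, select_model,
                                 sensitivity_excluding_year)


def _expit(x):
    return 1 / (1 + np.exp(-x))


def _logistic_data(n, beta, seed, extra_noise_col=False):
    r = np.random.default_rng(seed)
    x1 = r.normal(0, 1, n)
    x2 = r.normal(0, 1, n)
    eta = beta[0] + beta[1] * x1 + beta[2] * x2
    y = (r.random(n) < _expit(eta)).astype(int)
    df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    if extra_noise_col:
        df["noise"] = r.normal(0, 1, n)
    return df


def _newton_logistic(X, y, tol=1e-12, max_iter=200):
    """Brute-force Newton-Raphson logistic MLE (independent oracle)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = _expit(X @ beta)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * (mu * (1 - mu))[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestOracleEquivalence:
    def test_unpenalized_linear_matches_newton_raphson(self):
        df = _logistic_data(3000, (-0.5, 0.8, -0.4), seed=1)
        spec = ModelSpec(response="y", linear=("x1", "x2"),
                         select=False, alpha=0.0)
        m = fit_model(df, spec)
        X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
        oracle = _newton_logistic(X, df["y"].to_numpy())
        assert np.max(np.abs(m.coef - oracle)) < 1e-6

    def test_predictions_match_unpenalized_mle_within_3se(self):
        df = _logistic_data(5000, (-0.3, 0.7, 0.0), seed=2)
        spec = ModelSpec(response="y", smooth=(SmoothTerm("x1", k=6),),
                         select=True)
        m = fit_model(df, spec)
        X = np.column_stack([np.ones(len(df)), df["x1"]])
        oracle = _newton_logistic(X, df["y"].to_numpy())
        grid = np.linspace(-1.5, 1.5, 7)
        pred = m.predict(pd.DataFrame({"x1": grid}))["fit"].to_numpy()
        # oracle predictions and their delta-method SEs
        Xg = np.column_stack([np.ones(7), grid])
        mu = _expit(X @ oracle)
        cov = np.linalg.inv(X.T @ (X * (mu * (1 - mu))[:, None]))
        eta_g = Xg @ oracle
        se_eta = np.sqrt(np.einsum("ij,jk,ik->i", Xg, cov, Xg))
        se_p = _expit(eta_g) * (1 - _expit(eta_g)) * se_eta
        assert np.all(np.abs(pred - _expit(eta_g)) < 3 * se_p + 0.01)


class TestFitBehaviour:
    def test_null_model_deviance_explained_zero(self):
        df = _logistic_data(500, (0.2, 0.0, 0.0), seed=3)
        m = fit_model(df, ModelSpec(response="y"))
        assert m.deviance_explained == 0.0

    def test_independent_response_near_flat_smooth(self):
        df = _logistic_data(4000, (-0.2, 0.0, 0.0), seed=4)
        m = fit_model(df, ModelSpec(response="y", smooth=(SmoothTerm("x1", k=8),)))
        assert m.edf_by_term["s(x1)"] < 2.5
        assert m.deviance_explained < 0.01

    def test_monotone_truth_gives_monotone_partial_effect(self):
        df = _logistic_data(10_000, (0.0, 1.0, 0.0), seed=5)
        m = fit_model(df, ModelSpec(response="y", smooth=(SmoothTerm("x1", k=8),)))
        lo, hi = np.quantile(df["x1"], [0.05, 0.95])
        grid = np.linspace(lo, hi, 40)
        fit = m.predict(pd.DataFrame({"x1": grid}))["fit"].to_numpy()
        assert np.all(np.diff(fit) > -1e-6)

    def test_single_class_response_raises(self):
        df = pd.DataFrame({"y": np.zeros(50), "x1": np.arange(50)})
        with pytest.raises(ValueError, match="single class"):
            fit_model(df, ModelSpec(response="y", linear=("x1",)))

    def test_k_reduced_when_exceeding_unique_values(self):
        r = np.random.default_rng(0)
        df = pd.DataFrame({"y": r.integers(0, 2, 300),
                           "x1": r.integers(0, 4, 300).astype(float)})
        with pytest.warns(UserWarning, match="reduced"):
            fit_model(df, ModelSpec(response="y", smooth=(SmoothTerm("x1", k=8),),
                                    select=False, alpha=1.0))

    def test_poisson_family_fits_counts(self):
        r = np.random.default_rng(6)
        x = r.normal(0, 1, 2000)
        y = r.poisson(np.exp(0.3 + 0.5 * x))
        df = pd.DataFrame({"y": y, "x1": x})
        m = fit_model(df, ModelSpec(response="y", linear=("x1",),
                                    family="poisson", select=False, alpha=0.0))
        assert m.term_stats["x1"]["coef"] == pytest.approx(0.5, abs=0.1)


class TestSelectModel:
    def test_single_candidate_returned_as_best(self):
        df = _logistic_data(500, (0.0, 0.5, 0.0), seed=7)
        spec = ModelSpec(response="y", linear=("x1",), select=False, alpha=0.0)
        ranked = select_model(df, [spec])
        assert ranked[0][0] is spec

    def test_true_model_usually_preferred_over_underfit(self):
        wins = 0
        for seed in range(15):
            df = _logistic_data(2000, (0.0, 0.8, 0.5), seed=100 + seed)
            true_spec = ModelSpec(response="y", linear=("x1", "x2"),
                                  select=False, alpha=0.0)
            under = ModelSpec(response="y", linear=("x1",),
                              select=False, alpha=0.0)
            ranked = select_model(df, [under, true_spec])
            wins += ranked[0][0] is true_spec
        assert wins >= 12  # >= 80 %

    def test_noise_covariate_mean_aic_gain_below_two(self):
        gains = []
        for seed in range(10):
            df = _logistic_data(2000, (0.0, 0.8, 0.0), seed=200 + seed,
                                extra_noise_col=True)
            base = fit_model(df, ModelSpec(response="y", linear=("x1",),
                                           select=False, alpha=0.0))
            noisy = fit_model(df, ModelSpec(response="y", linear=("x1", "noise"),
                                            select=False, alpha=0.0))
            gains.append(base.aic - noisy.aic)
        assert np.mean(gains) < 2.0


class TestMortalityWithCosts:
    def test_restricted_cohort_and_cost_signs(self, tables):
        m = bl.fit_mortality_with_reproduction_costs(tables["pp"], select=False,
                                                     alpha=1.0)
        assert m.term_stats["afr_covariate"]["coef"] < 0
        assert m.term_stats["fecundity_covariate"]["coef"] > 0

    def test_empty_restricted_cohort_raises(self, tables):
        pp = tables["pp"].assign(complete_life=False)
        with pytest.raises(ValueError, match="empty"):
            bl.fit_mortality_with_reproduction_costs(pp)


class TestSensitivity:
    def test_filter_removes_exactly_that_year(self, tables):
        pp = tables["pp"]
        year = int(pp["year"].median())
        spec = ModelSpec(response="died", linear=("age", "size_centered"),
                         select=False, alpha=0.0)
        res = sensitivity_excluding_year(pp, year, spec)
        assert res.n_removed == int((pp["year"] == year).sum())
        assert res.reduced.n_obs == len(pp) - res.n_removed

    def test_excluding_uneventful_year_changes_little(self):
        r = np.random.default_rng(9)
        n = 4000
        df = pd.DataFrame({
            "age": r.integers(1, 10, n).astype(float),
            "year": r.integers(2000, 2010, n),
        })
        df["died"] = (r.random(n) < _expit(-2 + 0.15 * df["age"])).astype(int)
        df.loc[df["year"] == 2005, "died"] = 0  # a year without deaths
        spec = ModelSpec(response="died", linear=("age",), select=False, alpha=0.0)
        res = sensitivity_excluding_year(df, 2005, spec)
        assert abs(res.linear_coef_delta["age"]) < 0.05

    def test_missing_year_raises(self, tables):
        spec = ModelSpec(response="died", linear=("age",), select=False, alpha=0.0)
        with pytest.raises(ValueError):
            sensitivity_excluding_year(tables["pp"], 1800, spec)


class TestMgcvCrossCheck:
    def test_penalized_fit_agrees_with_mgcv_reml(self, tmp_path):
        """Independent oracle: mgcv's REML fit (gamma=1.4) of the same
        binomial smooth model yields near-identical response predictions."""
        import subprocess

        df = _logistic_data(4000, (-0.5, 0.9, 0.0), seed=12)
        m = fit_model(df, ModelSpec(response="y", smooth=(SmoothTerm("x1", k=8),)))
        grid = np.linspace(*np.quantile(df["x1"], [0.05, 0.95]), 21)
        mine = m.predict(pd.DataFrame({"x1": grid}))["fit"].to_numpy()

        data_csv = tmp_path / "d.csv"
        grid_csv = tmp_path / "g.csv"
        out_csv = tmp_path / "p.csv"
        df.to_csv(data_csv, index=False)
        pd.DataFrame({"x1": grid}).to_csv(grid_csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(mgcv))\n"
            f"d <- read.csv('{data_csv}')\n"
            f"g <- read.csv('{grid_csv}')\n"
            "m <- gam(y ~ s(x1, k=8), family=binomial, method='REML',"
            " gamma=1.4, data=d)\n"
            "p <- predict(m, g, type='response')\n"
            f"write.csv(data.frame(p=p), '{out_csv}', row.names=FALSE)\n")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        theirs = pd.read_csv(out_csv)["p"].to_numpy()
        assert np.corrcoef(mine, theirs)[0, 1] > 0.99
        assert np.max(np.abs(mine - theirs)) < 0.05


class TestPrediction:
    def test_probabilities_within_unit_interval(self, tables):
        pp = tables["pp"]
        spec = ModelSpec(response="died",
                         smooth=(SmoothTerm("size_centered", k=6),
                                 SmoothTerm("age", k=6)),
                         select=False, alpha=1.0)
        m = fit_model(pp, spec)
        surf = predict_rates(m, np.linspace(-2, 2, 9), np.arange(1, 12))
        for col in ("rate", "lo", "hi"):
            assert surf[col].between(0, 1).all()

    def test_surface_invariant_to_centering_constant(self):
        df = _logistic_data(4000, (-0.5, 0.6, 0.0), seed=10)
        m1 = fit_model(df, ModelSpec(response="y", smooth=(SmoothTerm("x1", k=6),),
                                     select=False, alpha=1.0))
        shifted = df.assign(x1=df["x1"] + 5.0)
        m2 = fit_model(shifted, ModelSpec(response="y",
                                          smooth=(SmoothTerm("x1", k=6),),
                                          select=False, alpha=1.0))
        g = np.linspace(-1, 1, 11)
        p1 = m1.predict(pd.DataFrame({"x1": g}))["fit"].to_numpy()
        p2 = m2.predict(pd.DataFrame({"x1": g + 5.0}))["fit"].to_numpy()
        assert np.allclose(p1, p2, atol=1e-8)

    def test_prediction_matches_binned_empirical_rate(self):
        df = _logistic_data(20_000, (-0.5, 0.8, 0.0), seed=11)
        m = fit_model(df, ModelSpec(response="y", smooth=(SmoothTerm("x1", k=8),)))
        for center in (-1.0, 0.0, 1.0):
            sel = df[np.abs(df["x1"] - center) < 0.15]
            emp = sel["y"].mean()
            fit = m.predict(pd.DataFrame({"x1": [center]}))["fit"].iloc[0]
            se = np.sqrt(emp * (1 - emp) / len(sel))
            assert abs(fit - emp) < 4 * se + 0.01

    def test_extrapolation_flagged(self, tables):
        pp = tables["pp"]
        spec = ModelSpec(response="died", smooth=(SmoothTerm("age", k=5),),
                         select=False, alpha=1.0)
        m = fit_model(pp, spec)
        out = m.predict(pd.DataFrame({"age": [999.0]}), flag_extrapolation=False)
        assert bool(out["extrapolated"].iloc[0])

    def test_model_summary_is_json_serializable(self, tables):
        import json

        spec = ModelSpec(response="died", smooth=(SmoothTerm("age", k=5),),
                         random=("colony_id",), select=False, alpha=1.0)
        m = fit_model(tables["pp"], spec)
        json.dumps(m.summary())
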