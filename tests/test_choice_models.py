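"""GLMM engine oracles (ordinary logistic, lme4), choice-model contracts,
learning curves, and AIC comparison."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import flocklearn as fl
from flocklearn.choice_models import (compare_models, daily_counts,
                                      fit_choice_model, fit_learning_curve,
                                      model_spec, orthogonal_poly)
from flocklearn.exceptions import ComparisonError, SpecificationError
from flocklearn.glmm import fit_binomial_glmm


def _logistic_data(seed, n=600, nb=30, sigma=0.0,
                   beta=(-0.4, 0.8, -0.3)):
    rng = np.random.default_rng(seed)
    g = rng.integers(nb, size=n)
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    eta = X @ np.asarray(beta) + rng.normal(0, sigma, nb)[g]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y, g


def test_zero_heterogeneity_recovers_ordinary_logistic():
    """With no group variance the mixed fit collapses to plain logistic
    regression (statsmodels Logit as the independent oracle)."""
    import statsmodels.api as sm
    X, y, g = _logistic_data(0, sigma=0.0)
    f = fit_binomial_glmm(X, y, g, method="agh")
    lr = sm.Logit(y, X).fit(disp=0)
    assert f.boundary_sigma or f.sigma < 0.15
    # refit with sigma pinned at the boundary matches Logit to 1e-4
    f0 = fit_binomial_glmm(X, y, g, method="gh",
                           start=np.append(lr.params, 0.0))
    if f0.boundary_sigma:
        np.testing.assert_allclose(f0.beta, lr.params, atol=1e-4)
        np.testing.assert_allclose(f0.loglik, lr.llf, atol=1e-4)


def test_glmm_matches_lme4_glmer(tmp_path):
    """Coefficients, intercept SD, and log-likelihood agree with lme4's
    adaptive-quadrature glmer on a heterogeneous fixture."""
    X, y, g = _logistic_data(1, n=800, nb=40, sigma=0.8)
    f = fit_binomial_glmm(X, y, g, method="agh")
    csv = tmp_path / "d.csv"
    pd.DataFrame({"y": y, "x1": X[:, 1], "x2": X[:, 2], "g": g}).to_csv(
        csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv('{csv}')
        m <- glmer(y ~ x1 + x2 + (1|g), data=d, family=binomial, nAGQ=25)
        co <- summary(m)$coefficients
        cat(co[,1], co[,2], sqrt(unlist(VarCorr(m))[1]),
            as.numeric(logLik(m)), sep='\\n')
    """))
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, check=True)
    vals = [float(v) for v in out.stdout.split()]
    beta_r, se_r, sigma_r, ll_r = vals[:3], vals[3:6], vals[6], vals[7]
    np.testing.assert_allclose(f.beta, beta_r, atol=2e-3)
    np.testing.assert_allclose(f.se, se_r, atol=5e-3)
    assert f.sigma == pytest.approx(sigma_r, abs=5e-3)
    assert f.loglik == pytest.approx(ll_r, abs=1e-3)


def test_quadrature_methods_agree():
    X, y, g = _logistic_data(2, sigma=0.6)
    fa = fit_binomial_glmm(X, y, g, method="agh")
    fg = fit_binomial_glmm(X, y, g, method="gh")
    np.testing.assert_allclose(fa.beta, fg.beta, atol=1e-4)
    assert fa.loglik == pytest.approx(fg.loglik, abs=1e-4)
    np.testing.assert_allclose(fa.se, fg.se, atol=1e-3)


def test_all_zero_social_column_dropped_equals_asocial_model(choice_table):
    t = choice_table.copy()
    t["O_plus"] = 0.0
    t["O_minus"] = 0.0
    full = fit_choice_model(t, model_spec("base"))
    asoc = fit_choice_model(t, model_spec("asocial_only"))
    assert set(full.fit.dropped) == {"O_plus", "O_minus"}
    assert full.loglik == pytest.approx(asoc.loglik, abs=1e-6)


def test_species_reparameterisation_invariance(choice_table):
    """6a-style split and 6b-style difference coding span the same design:
    identical likelihood, and the difference coefficient equals the
    conspecific-minus-heterospecific contrast."""
    fa = fit_choice_model(choice_table, model_spec("species_split"))
    fb = fit_choice_model(choice_table, model_spec("species_diff"))
    assert fa.loglik == pytest.approx(fb.loglik, abs=1e-5)
    ca, cb = fa.coef_original, fb.coef_original
    assert cb["O_minus_C"] == pytest.approx(
        ca["O_minus_C"] - ca["O_minus_H"], abs=1e-3)
    assert cb["O_plus_C"] == pytest.approx(
        ca["O_plus_C"] - ca["O_plus_H"], abs=1e-3)


def test_standardize_backtransform_matches_unstandardized_refit(choice_table):
    """Back-transformed standardized coefficients are a stationary point of
    the unstandardized likelihood: an unstandardized refit started there
    reproduces them."""
    fs = fit_choice_model(choice_table, model_spec("base", standardize=True))
    co_s = fs.coef_original
    start = np.array([co_s["(Intercept)"]]
                     + [co_s[t] for t in fs.spec.terms] + [fs.sigma_b])
    fu = fit_choice_model(choice_table, model_spec("base", standardize=False),
                          start=start)
    co_u = fu.coef_original
    assert fu.loglik == pytest.approx(fs.loglik, abs=1e-6)
    for term in ["(Intercept)"] + fs.spec.terms:
        assert co_s[term] == pytest.approx(co_u[term], rel=1e-4, abs=1e-5)


def test_compare_models_contract(choice_table):
    base = fit_choice_model(choice_table, model_spec("base"))
    asoc = fit_choice_model(choice_table, model_spec("asocial_only"))
    tab = compare_models([base, asoc])
    assert tab["dAIC"].iloc[0] == 0.0
    assert list(tab["AIC"]) == sorted(tab["AIC"])
    single = compare_models([base])
    assert single["dAIC"].iloc[0] == 0.0
    other = fit_choice_model(choice_table.iloc[:-5], model_spec("base"))
    with pytest.raises(ComparisonError):
        compare_models([base, other])


def test_noise_term_costs_two_aic_in_expectation():
    """Adding a pure-noise covariate raises AIC by ~+2 on average."""
    rng = np.random.default_rng(3)
    deltas = []
    for rep in range(25):
        X, y, g = _logistic_data(100 + rep, n=400, nb=20, sigma=0.0)
        noise = rng.normal(size=len(y))
        f1 = fit_binomial_glmm(X, y, g, method="gh", compute_se=False)
        f2 = fit_binomial_glmm(np.column_stack([X, noise]), y, g,
                               method="gh", compute_se=False)
        deltas.append(f2.aic - f1.aic)
    assert 0.5 < np.mean(deltas) < 3.5


def test_missing_column_rejected(choice_table):
    with pytest.raises(SpecificationError):
        fit_choice_model(choice_table.drop(columns=["O_minus"]),
                         model_spec("base"))
    with pytest.raises(SpecificationError):
        model_spec("nonsense")


def test_orthogonal_poly_properties():
    x = np.arange(1, 9, dtype=float)
    q = orthogonal_poly(x, 2)
    gram = q.T @ q
    np.testing.assert_allclose(gram, np.eye(2), atol=1e-10)
    assert np.corrcoef(q[:, 0], x)[0, 1] > 0.999


def _curve_stream(seed, slope_adult, slope_juv, n_days=8, nb=30):
    """Bird-day binomial stream with age-specific quadratic learning."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(nb):
        age = "juvenile" if b % 2 else "adult"
        sp = "A" if b % 3 else "B"
        c2 = slope_juv if age == "juvenile" else slope_adult
        for day in range(1, n_days + 1):
            m = rng.poisson(20) + 1
            eta = 0.5 - 0.15 * day + c2 * day ** 2
            k = rng.binomial(m, 1 / (1 + np.exp(-eta)))
            for i in range(m):
                rows.append((f"b{b}", sp, age, "S1",
                             86400.0 * day + 10.0 * i + (i < k) * 0.5,
                             int(i >= k)))
    return pd.DataFrame(rows, columns=["bird_id", "species", "age",
                                       "station", "time", "palatable"])


def test_learning_curve_age_difference_sign():
    """Juveniles with a slower quadratic decline: the selected model carries
    the day^2 x age interaction with the generator's sign."""
    visits = _curve_stream(4, slope_adult=-0.04, slope_juv=-0.005)
    fit = fit_learning_curve(visits, raw_poly=True)
    assert "day2:ag" in fit.fit.names
    j = fit.fit.names.index("day2:ag")
    # juvenile day^2 effect minus adult: -0.005 - (-0.04) > 0
    assert fit.fit.beta[j] > 0


def test_learning_curve_null_recovery():
    """Constant choice probability: the day^2 x age interaction, when kept,
    has a CI covering 0 (usually a smaller model is selected outright)."""
    visits = _curve_stream(5, slope_adult=0.0, slope_juv=0.0)
    fit = fit_learning_curve(visits)
    if "day2:ag" in fit.fit.names:
        j = fit.fit.names.index("day2:ag")
        lo, hi = fit.fit.beta[j] - 1.96 * fit.fit.se[j], \
            fit.fit.beta[j] + 1.96 * fit.fit.se[j]
        assert lo <= 0 <= hi
    else:
        assert fit.selection_table is not None


def test_daily_counts_aggregation(avoidance):
    visits, _ = avoidance
    counts = daily_counts(visits)
    assert counts["n_total"].sum() == len(visits)
    assert (counts["n_unpal"] <= counts["n_total"]).all()
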