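"""Survey-weighted logistic regression, stepwise AIC, Hosmer-Lemeshow."""

import numpy as np
import pandas as pd
import pytest

from ccikit import (ModelSpec, Term, backward_stepwise_aic, fit_svy_logistic,
                    hosmer_lemeshow, or_table)
from ccikit.errors import ConfigurationError, DataError

from conftest import make_srs_design


def simulate_frame(n, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "x": rng.normal(size=n),
        "g": rng.choice(["lo", "mid", "hi"], n),
        "noise": rng.normal(size=n),
    })
    eta = -0.4 + 0.9 * df.x + 0.6 * (df.g == "hi")
    df["y"] = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    return df


def test_intercept_only_symmetry():
    df = pd.DataFrame({"y": [1.0, 0.0, 1.0, 0.0]})
    d = make_srs_design(4)
    fit = fit_svy_logistic(df, d, ModelSpec("y", ()))
    assert fit.params["Intercept"] == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(fit.fitted, 0.5)


def test_matches_classical_mle_at_equal_weights():
    """Equal-weight element sampling: pseudo-MLE equals the classical MLE.

    The oracle is statsmodels' Newton optimiser on the same likelihood.
    """
    sm = pytest.importorskip("statsmodels.api")
    df = simulate_frame(600, seed=4)
    d = make_srs_design(600)
    spec = ModelSpec("y", (Term("x", "numeric"),
                           Term("g", "categorical", "lo")))
    fit = fit_svy_logistic(df, d, spec)
    X = np.column_stack([np.ones(600), df.x, (df.g == "hi"),
                         (df.g == "mid")]).astype(float)
    oracle = sm.Logit(df.y, X).fit(disp=0)
    mine = fit.params[["Intercept", "x", "g[hi]", "g[mid]"]].to_numpy()
    assert np.max(np.abs(mine - oracle.params)) < 1e-6


def test_weight_scale_invariance():
    df = simulate_frame(400, seed=5)
    rng = np.random.default_rng(1)
    w = rng.uniform(0.5, 4.0, 400)
    strata = np.repeat([0, 1], 200)
    psu = np.repeat(np.arange(40), 10)
    from ccikit import SurveyDesign
    spec = ModelSpec("y", (Term("x", "numeric"),))
    a = fit_svy_logistic(df, SurveyDesign(strata, psu, w), spec)
    b = fit_svy_logistic(df, SurveyDesign(strata, psu, w * 9.0), spec)
    assert np.allclose(a.params, b.params, atol=1e-10)
    assert np.allclose(a.cov, b.cov, rtol=1e-8)
    assert a.aic == pytest.approx(b.aic, rel=1e-10)


def test_parameter_recovery_within_design_se():
    df = simulate_frame(3000, seed=7)
    d = make_srs_design(3000)
    spec = ModelSpec("y", (Term("x", "numeric"),
                           Term("g", "categorical", "lo")))
    fit = fit_svy_logistic(df, d, spec)
    se = fit.se
    assert abs(fit.params["x"] - 0.9) < 3 * se["x"]
    assert abs(fit.params["g[hi]"] - 0.6) < 3 * se["g[hi]"]


def test_complete_case_logged():
    df = simulate_frame(100, seed=2)
    df.loc[:4, "x"] = np.nan
    d = make_srs_design(100)
    fit = fit_svy_logistic(df, d, ModelSpec("y", (Term("x", "numeric"),)))
    assert fit.n_dropped == 5
    assert fit.n == 95


def test_rank_deficiency_errors():
    df = simulate_frame(100, seed=3)
    df["x2"] = df["x"]
    d = make_srs_design(100)
    from ccikit.errors import FitError
    with pytest.raises(FitError):
        fit_svy_logistic(df, d, ModelSpec(
            "y", (Term("x", "numeric"), Term("x2", "numeric"))))


class TestStepwise:
    def test_noise_dropped_and_aic_non_increasing(self):
        df = simulate_frame(1500, seed=11)
        d = make_srs_design(1500)
        full = ModelSpec("y", (Term("x", "numeric"),
                               Term("g", "categorical", "lo"),
                               Term("noise", "numeric")))
        spec, fit, trail = backward_stepwise_aic(df, d, full)
        names = [t.name for t in spec.terms]
        assert "noise" not in names
        assert "x" in names
        aics = [s.aic for s in trail]
        assert all(b <= a + 1e-9 for a, b in zip(aics, aics[1:]))
        assert fit.aic <= aics[0]

    def test_all_null_may_reach_intercept_only(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame({"a": rng.normal(size=800),
                           "b": rng.normal(size=800),
                           "y": rng.binomial(1, 0.4, 800).astype(float)})
        d = make_srs_design(800)
        spec, fit, trail = backward_stepwise_aic(
            df, d, ModelSpec("y", (Term("a", "numeric"),
                                   Term("b", "numeric"))))
        aics = [s.aic for s in trail]
        assert all(b <= a + 1e-9 for a, b in zip(aics, aics[1:]))
        assert len(spec.terms) <= 2

    def test_exact_tie_drops_earliest_term(self):
        # data symmetric under swapping x1 <-> x2, so dropping either gives
        # the identical AIC; the documented tie-break keeps spec order
        base = pd.DataFrame({
            "x1": [0, 0, 1, 1] * 8,
            "x2": [0, 1, 0, 1] * 8,
            "y": [0.0, 1.0, 1.0, 0.0] * 8,
        })
        d = make_srs_design(len(base))
        full = ModelSpec("y", (Term("x1", "numeric"), Term("x2", "numeric")))
        spec, fit, trail = backward_stepwise_aic(base, d, full)
        dropped = [s.dropped for s in trail[1:]]
        assert dropped[0] == "x1"

    def test_locked_terms_survive(self):
        df = simulate_frame(800, seed=12)
        d = make_srs_design(800)
        full = ModelSpec("y", (Term("noise", "numeric"),
                               Term("x", "numeric")))
        spec, _, _ = backward_stepwise_aic(df, d, full,
                                           locked_terms=("noise",))
        assert "noise" in [t.name for t in spec.terms]

    def test_determinism(self):
        df = simulate_frame(900, seed=13)
        d = make_srs_design(900)
        full = ModelSpec("y", (Term("x", "numeric"),
                               Term("g", "categorical", "lo"),
                               Term("noise", "numeric")))
        t1 = backward_stepwise_aic(df, d, full)[2]
        t2 = backward_stepwise_aic(df, d, full)[2]
        assert [(s.dropped, s.aic) for s in t1] == \
            [(s.dropped, s.aic) for s in t2]


class TestHosmerLemeshow:
    def test_saturated_grouped_model_statistic_near_zero(self):
        # one binary predictor: fitted probabilities equal group rates
        df = pd.DataFrame({
            "x": np.repeat([0.0, 1.0], 100),
            "y": np.r_[np.repeat([0.0, 1.0], [60, 40]),
                       np.repeat([0.0, 1.0], [30, 70])],
        })
        d = make_srs_design(200)
        fit = fit_svy_logistic(df, d, ModelSpec("y", (Term("x", "numeric"),)))
        with pytest.warns(UserWarning):     # 2 distinct fitted values < g
            hl = hosmer_lemeshow(fit, g=10)
        assert hl.statistic == pytest.approx(0.0, abs=1e-8)

    def test_group_sizes_balanced(self):
        df = simulate_frame(100, seed=30)
        d = make_srs_design(100)
        fit = fit_svy_logistic(df, d, ModelSpec("y", (Term("x", "numeric"),)))
        hl = hosmer_lemeshow(fit, g=10)
        assert hl.df == 8
        sizes = hl.table.weighted_n.to_numpy()
        assert sizes.max() - sizes.min() <= 1.0 + 1e-9
        assert sizes.sum() == pytest.approx(100.0)

    def test_g_validation(self):
        df = simulate_frame(50, seed=31)
        d = make_srs_design(50)
        fit = fit_svy_logistic(df, d, ModelSpec("y", (Term("x", "numeric"),)))
        with pytest.raises(ConfigurationError):
            hosmer_lemeshow(fit, g=2)


class TestOrTable:
    def test_reference_rows_and_null_term(self):
        df = simulate_frame(1200, seed=40)
        d = make_srs_design(1200)
        fit = fit_svy_logistic(df, d, ModelSpec(
            "y", (Term("g", "categorical", "lo"), Term("noise", "numeric"))))
        tab = or_table(fit, decimals=2)
        ref = tab[(tab.term == "g") & (tab.level == "lo")].iloc[0]
        assert ref.OR == "—" and ref["95% CI"] == "—"
        noise = tab[tab.term == "noise"].iloc[0]
        lo, hi = map(float, noise["95% CI"].split(", "))
        assert lo < 1.0 < hi           # true null: CI spans 1

    def test_ci_contains_point_estimate(self):
        df = simulate_frame(500, seed=41)
        d = make_srs_design(500)
        fit = fit_svy_logistic(df, d, ModelSpec("y", (Term("x", "numeric"),)))
        ors = fit.odds_ratios()
        assert ((ors.ci_low <= ors.OR) & (ors.OR <= ors.ci_high)).all()
        assert (ors.OR > 0).all()


def test_response_among_predictors_rejected():
    with pytest.raises(ConfigurationError):
        ModelSpec("y", (Term("y", "numeric"),))


def test_missing_column_rejected():
    df = pd.DataFrame({"y": [0.0, 1.0]})
    d = make_srs_design(2)
    with pytest.raises(DataError):
        fit_svy_logistic(df, d, ModelSpec("y", (Term("zz", "numeric"),)))
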