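"""Simulation-based validation studies for the design-based machinery.

Each study generates data under known conditions and measures a frequency
property of an estimator or test: type-I error of the Rao-Scott corrected
chi-square under a clustered null, rejection rate of the Hosmer-Lemeshow
test under a correctly specified model, confidence-interval coverage of the
design-based proportion under two-stage sampling, and recovery of the
generator's true logistic coefficients within design-based standard errors.

These run in seconds-to-a-minute at their default replicate counts and are
used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import SurveyDesign, design_proportion, rao_scott_test
from .logit import ModelSpec, Term, fit_svy_logistic, hosmer_lemeshow
from .simulate import COMPONENT_FEATURES, SimulationConfig, draw_sample, \
    generate_population


def rao_scott_type1_study(n_replicates: int = 1000, n_clusters: int = 30,
                          cluster_size: int = 15, re_sd: float = 0.8,
                          alpha: float = 0.05, seed: int = 12345) -> float:
    """Rejection rate of the Rao-Scott test for two independent binary
    variables that are each correlated within clusters (null holds)."""
    rng = np.random.default_rng(seed)
    rej = tested = 0
    for _ in range(n_replicates):
        a = rng.normal(0, re_sd, n_clusters)
        b = rng.normal(0, re_sd, n_clusters)
        psu = np.repeat(np.arange(n_clusters), cluster_size)
        x = rng.binomial(1, 1 / (1 + np.exp(-a[psu])))
        y = rng.binomial(1, 1 / (1 + np.exp(-b[psu])))
        if x.min() == x.max() or y.min() == y.max():
            continue
        d = SurveyDesign(np.zeros(len(psu)), psu, np.ones(len(psu)))
        tested += 1
        rej += rao_scott_test(d, x, y).p < alpha
    return rej / tested


def hosmer_lemeshow_calibration_study(n_replicates: int = 500, n: int = 400,
                                      alpha: float = 0.05,
                                      seed: int = 777) -> float:
    """Rejection rate of the Hosmer-Lemeshow test when the fitted logistic
    model is the true data-generating model."""
    rng = np.random.default_rng(seed)
    rej = 0
    spec = ModelSpec("y", (Term("x1", "numeric"), Term("x2", "numeric")))
    for _ in range(n_replicates):
        df = pd.DataFrame({"x1": rng.normal(size=n),
                           "x2": rng.binomial(1, 0.4, n).astype(float)})
        eta = -0.2 + 0.7 * df.x1 + 0.5 * df.x2
        df["y"] = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        d = SurveyDesign(np.zeros(n), np.arange(n), np.ones(n))
        fit = fit_svy_logistic(df, d, spec)
        rej += hosmer_lemeshow(fit, g=10).p < alpha
    return rej / n_replicates


def ci_coverage_study(n_replicates: int = 500, component: str = "SBA",
                      seed: int = 2024) -> float:
    """95% CI coverage of the design-based proportion over replicate
    two-stage samples from one fixed synthetic population."""
    cfg = SimulationConfig(clusters_per_stratum=8, households_per_cluster=30,
                           seed=seed)
    pop, _ = generate_population(cfg)
    true_p = pop[component].mean()
    cover = 0
    for r in range(n_replicates):
        s, _ = draw_sample(pop, 4, 15, seed=50_000 + seed + r)
        d = SurveyDesign(s.stratum_id, s.cluster_id, s.weight)
        dp = design_proportion(d, s[component].to_numpy())
        cover += dp.ci_low <= true_p <= dp.ci_high
    return cover / n_replicates


def recovery_study(n_seeds: int = 20, component: str = "SBA",
                   seed: int = 0) -> pd.DataFrame:
    """Survey-logistic recovery of the generator's true coefficients.

    Fits the true component model on ~5,000-record two-stage samples and
    returns one row per (seed, coefficient) with the absolute deviation
    from truth in design-SE units.
    """
    rows = []
    spec = ModelSpec(component,
                     tuple(Term(f, "numeric") for f in COMPONENT_FEATURES[1:]))
    for s_i in range(n_seeds):
        cfg = SimulationConfig(clusters_per_stratum=10,
                               households_per_cluster=60, seed=seed + s_i)
        pop, truth = generate_population(cfg)
        samp, _ = draw_sample(pop, 8, 40, seed=seed + s_i + 500)
        samp = samp.rename(columns={"planned_pregnancy": "planned"})
        samp["wealth_c"] = samp.wealth_quintile - 3.0
        samp["edu_any"] = (samp.mother_edu != "none").astype(float)
        d = SurveyDesign(samp.stratum_id, samp.cluster_id, samp.weight)
        fit = fit_svy_logistic(samp, d, spec)
        beta_true = dict(zip(COMPONENT_FEATURES,
                             truth.component_coefficients[component]))
        for name in fit.params.index:
            t = beta_true["intercept" if name == "Intercept" else name]
            rows.append({"seed": seed + s_i, "coefficient": name,
                         "true": t, "estimate": fit.params[name],
                         "se": fit.se[name],
                         "z_dev": abs(fit.params[name] - t) / fit.se[name],
                         "n": fit.n})
    return pd.DataFrame(rows)
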