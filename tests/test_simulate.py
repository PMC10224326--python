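"""Synthetic survey generator: determinism, calibration, design weights."""

import numpy as np
import pandas as pd
import pytest

from ccikit import (COMPONENTS, GUINEA_REGIONS, SimulationConfig,
                    draw_sample, generate_population, guinea_adjacency,
                    score_records)
from ccikit.simulate import COMPONENT_FEATURES
from ccikit.errors import ConfigurationError, SamplingError


def flat_config(intercept, **kw):
    coeffs = {c: (intercept,) + (0.0,) * (len(COMPONENT_FEATURES) - 1)
              for c in COMPONENTS}
    return SimulationConfig(component_coefficients=coeffs, **kw)


class TestGeneratePopulation:
    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(clusters_per_stratum=3,
                               households_per_cluster=20, seed=5)
        a, ta = generate_population(cfg)
        b, tb = generate_population(cfg)
        pd.testing.assert_frame_equal(a, b)
        assert ta.to_dict() == tb.to_dict()

    def test_zero_coefficients_give_half_coverage(self):
        # logistic(0) = 0.5; population of ~50,000 pins each component
        # coverage within 3 Monte-Carlo SE
        cfg = flat_config(0.0)
        pop, _ = generate_population(cfg)
        assert len(pop) > 45_000
        for comp in COMPONENTS:
            x = pop[comp].dropna()
            se = np.sqrt(0.25 / len(x))
            assert abs(x.mean() - 0.5) < 3 * se, comp

    def test_saturating_intercept_gives_all_optimal(self):
        cfg = flat_config(20.0, clusters_per_stratum=2,
                          households_per_cluster=15)
        pop, truth = generate_population(cfg)
        scored = score_records(pop)
        assert (scored.cci_score == 1.0).all()
        assert (scored.cci_label == "optimal").all()
        assert truth.marginal_optimal_proportion == 1.0

    def test_applicability_consistency(self, small_population):
        _, pop, _ = small_population
        assert (pop.ORT.notna() == (pop.diarrhoea == 1)).all()
        assert (pop.CPNM.notna() == (pop.cough == 1)).all()
        for comp in ("FPS", "SBA", "ANCS", "DTC3", "MSL", "BCG"):
            assert pop[comp].notna().all()

    def test_truth_region_vector_matches_population(self, small_population):
        _, pop, truth = small_population
        scored = score_records(pop)
        for region in GUINEA_REGIONS:
            direct = (scored.loc[scored.region == region, "cci_label"]
                      == "optimal").mean()
            assert truth.region_optimal_proportion[region] == \
                pytest.approx(direct)

    @pytest.mark.parametrize("field, value", [
        ("clusters_per_stratum", 0),
        ("households_per_cluster", -1),
        ("urban_fraction", 1.5),
    ])
    def test_invalid_config_names_field(self, field, value):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(ConfigurationError, match=field):
            cfg.validate()

    def test_invalid_component_coefficients(self):
        cfg = SimulationConfig(component_coefficients={"FPS": (0.0,) * 7})
        with pytest.raises(ConfigurationError, match="component"):
            cfg.validate()
        cfg2 = SimulationConfig()
        cfg2.component_coefficients["SBA"] = (1.0,)
        with pytest.raises(ConfigurationError, match="SBA"):
            cfg2.validate()

    def test_invalid_applicability(self):
        cfg = SimulationConfig(applicability_rates={"diarrhoea": 2.0,
                                                    "cough": 0.2})
        with pytest.raises(ConfigurationError, match="diarrhoea"):
            cfg.validate()


class TestDrawSample:
    def test_census_weights_are_one(self, small_population):
        cfg, pop, _ = small_population
        s, _ = draw_sample(pop, cfg.clusters_per_stratum, 10 ** 9, seed=0)
        assert len(s) == len(pop)
        assert np.allclose(s.weight, 1.0)

    def test_oversized_request_errors(self, small_population):
        cfg, pop, _ = small_population
        with pytest.raises(SamplingError):
            draw_sample(pop, cfg.clusters_per_stratum + 1, 10, seed=0)

    def test_single_cluster_per_stratum_warns(self, small_population):
        _, pop, _ = small_population
        with pytest.warns(UserWarning, match="single PSU"):
            _, warns = draw_sample(pop, 1, 10, seed=0)
        assert warns

    def test_weights_positive_and_selfweighting_within_stratum(
            self, small_population):
        _, pop, _ = small_population
        s, _ = draw_sample(pop, 4, 20, seed=3)
        assert (s.weight > 0).all()
        # two-stage PPS + fixed take: equal weights within each stratum
        spread = s.groupby("stratum_id").weight.agg(lambda v: v.max() - v.min())
        assert (spread < 1e-9).all()

    def test_horvitz_thompson_calibration(self, small_population):
        """Over 200 replicate samples the weighted component-coverage
        estimates centre on the finite-population values (brute-force
        population means are the oracle)."""
        _, pop, _ = small_population
        truth = {c: pop[c].dropna().mean() for c in COMPONENTS}
        reps = {c: [] for c in COMPONENTS}
        for r in range(200):
            s, _ = draw_sample(pop, 3, 15, seed=10_000 + r)
            for c in COMPONENTS:
                ok = s[c].notna()
                w = s.weight[ok]
                reps[c].append(float((s[c][ok] * w).sum() / w.sum()))
        for c in COMPONENTS:
            est = np.asarray(reps[c])
            se_mean = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - truth[c]) < 3 * se_mean, c

    def test_sample_determinism(self, small_population):
        _, pop, _ = small_population
        a, _ = draw_sample(pop, 4, 12, seed=77)
        b, _ = draw_sample(pop, 4, 12, seed=77)
        pd.testing.assert_frame_equal(a, b)


class TestAdjacency:
    def test_symmetric_connected_and_complete(self):
        adj = guinea_adjacency()
        assert sorted(adj) == sorted(GUINEA_REGIONS)
        for u, nbrs in adj.items():
            assert len(nbrs) >= 1
            assert len(set(nbrs)) == len(nbrs)
            for v in nbrs:
                assert u in adj[v]
        # connectivity by BFS
        seen, stack = set(), [next(iter(adj))]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(adj[u])
        assert seen == set(adj)

    def test_conakry_borders_kindia(self):
        adj = guinea_adjacency()
        assert "Kindia" in adj["Conakry"]
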