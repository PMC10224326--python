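"""Moran's I, LISA quadrants, permutation inference, regional surface."""

import itertools

import numpy as np
import pytest

from ccikit import (SurveyDesign, build_weights, global_moran, local_moran,
                    regional_cci_surface, score_records, guinea_adjacency)
from ccikit.spatial import _moran_stat
from ccikit.errors import DataError, DomainError

ROOK_2X2 = {"a": ["b", "c"], "b": ["a", "d"],
            "c": ["a", "d"], "d": ["b", "c"]}


class TestWeights:
    def test_rook_lattice_binary(self):
        sw = build_weights(ROOK_2X2, style="binary")
        assert (sw.binary.sum(axis=1) == 2).all()
        assert sw.s0 == 8

    def test_row_standardised_rows_sum_to_one(self):
        sw = build_weights(ROOK_2X2)
        assert np.allclose(sw.row_standardised.sum(axis=1), 1.0)

    def test_island_rejected_unless_allowed(self):
        adj = {"a": ["b"], "b": ["a"], "c": []}
        with pytest.raises(DataError, match="c"):
            build_weights(adj)
        sw = build_weights(adj, allow_islands=True)
        assert sw.n == 3

    def test_asymmetry_rejected(self):
        with pytest.raises(DataError, match="asymmetric"):
            build_weights({"a": ["b"], "b": []}, allow_islands=True)

    def test_self_loop_rejected(self):
        with pytest.raises(DataError):
            build_weights({"a": ["a", "b"], "b": ["a"]})


class TestGlobalMoran:
    def test_checkerboard_is_minus_one(self):
        sw = build_weights(ROOK_2X2, style="binary")
        res = global_moran([1, 0, 0, 1], sw, n_permutations=99, seed=0)
        assert res.I == pytest.approx(-1.0, abs=1e-12)
        assert res.expected == pytest.approx(-1 / 3)

    def test_permutation_mean_equals_expectation(self):
        # brute-force mean of I over every relabelling equals -1/(n-1)
        sw = build_weights(ROOK_2X2, style="binary")
        x = np.array([0.3, 1.2, -0.5, 2.0])
        z = x - x.mean()
        vals = [_moran_stat(z[list(p)], sw.W, sw.s0)
                for p in itertools.permutations(range(4))]
        assert np.mean(vals) == pytest.approx(-1 / 3, abs=1e-12)

    def test_smooth_gradient_on_path_graph(self):
        n = 10
        adj = {str(i): [str(j) for j in (i - 1, i + 1) if 0 <= j < n]
               for i in range(n)}
        sw = build_weights(adj)
        res = global_moran(np.arange(1, n + 1.0), sw, n_permutations=999,
                          seed=5)
        assert res.I > 0
        assert res.p_perm_two_sided < 0.05

    def test_affine_invariance(self):
        sw = build_weights(ROOK_2X2)
        x = np.array([0.1, 0.9, 0.4, 0.7])
        a = global_moran(x, sw, n_permutations=49, seed=1)
        b = global_moran(5.0 * x + 3.0, sw, n_permutations=49, seed=1)
        assert a.I == pytest.approx(b.I, abs=1e-12)
        assert a.p_perm_two_sided == b.p_perm_two_sided

    def test_seed_reproducibility(self):
        sw = build_weights(ROOK_2X2)
        x = [0.2, 0.8, 0.5, 0.1]
        a = global_moran(x, sw, n_permutations=199, seed=7)
        b = global_moran(x, sw, n_permutations=199, seed=7)
        assert a.p_perm_two_sided == b.p_perm_two_sided
        assert a.p_perm_one_sided == b.p_perm_one_sided

    def test_exact_enumeration_close_to_monte_carlo(self):
        adj = {"a": ["b"], "b": ["a", "c"], "c": ["b", "d"], "d": ["c", "e"],
               "e": ["d"]}
        sw = build_weights(adj)
        x = [1.0, 2.0, 3.0, 5.0, 8.0]
        exact = global_moran(x, sw, exact=True)
        mc = global_moran(x, sw, n_permutations=19999, seed=11)
        assert abs(exact.p_perm_two_sided - mc.p_perm_two_sided) < 0.02

    def test_constant_values_rejected(self):
        sw = build_weights(ROOK_2X2)
        with pytest.raises(DomainError, match="zero variance"):
            global_moran([1.0, 1.0, 1.0, 1.0], sw)


class TestLocalMoran:
    def test_mean_local_equals_global_row_standardised(self):
        adj = guinea_adjacency()
        sw = build_weights(adj)
        rng = np.random.default_rng(3)
        x = rng.uniform(0.2, 0.8, 8)
        g = global_moran(x, sw, n_permutations=99, seed=0)
        loc = local_moran(x, sw, n_permutations=99, seed=0)
        assert loc.table.local_I.mean() == pytest.approx(g.I, abs=1e-10)

    def test_quadrant_assignment(self):
        # path a-b-c-d-e: centre unit far above mean, neighbours above mean
        adj = {"a": ["b"], "b": ["a", "c"], "c": ["b", "d"], "d": ["c", "e"],
               "e": ["d"]}
        sw = build_weights(adj)
        x = np.array([0.0, 10.0, 20.0, 10.0, 0.0])   # mean 8
        loc = local_moran(x, sw, n_permutations=49, seed=0)
        tab = loc.table.set_index("unit")
        assert tab.loc["c", "quadrant"] == "high-high"    # 20, lag 10 > 8
        assert tab.loc["a", "quadrant"] == "low-high"     # 0, neighbour 10
        assert set(tab.quadrant) <= {"high-high", "low-low",
                                     "high-low", "low-high"}

    def test_seed_reproducibility(self):
        sw = build_weights(ROOK_2X2)
        x = [0.9, 0.1, 0.2, 0.8]
        a = local_moran(x, sw, n_permutations=199, seed=13)
        b = local_moran(x, sw, n_permutations=199, seed=13)
        assert (a.table.p_perm == b.table.p_perm).all()

    def test_affine_invariance_of_local_i(self):
        sw = build_weights(ROOK_2X2)
        x = np.array([0.9, 0.1, 0.2, 0.8])
        a = local_moran(x, sw, n_permutations=9, seed=0).table.local_I
        b = local_moran(3 * x + 1, sw, n_permutations=9, seed=0).table.local_I
        assert np.allclose(a, b, atol=1e-12)


class TestRegionalSurface:
    def test_guinea_fixture_runs_end_to_end(self, clustered_sample):
        df, design = clustered_sample
        scored = score_records(df)
        sw = build_weights(guinea_adjacency())
        table, moran, lisa = regional_cci_surface(
            scored, design, sw, n_permutations=99, seed=0)
        assert len(table) == 8
        assert set(table.region) == set(sw.names)
        assert np.isfinite(moran.I)
        assert len(lisa.table) == 8

    def test_constant_proportions_surface_error(self):
        import pandas as pd
        from conftest import full_record
        rows = []
        for i, region in enumerate(guinea_adjacency()):
            for j in range(4):
                rows.append({**full_record(), "region": region,
                             "stratum_id": i, "cluster_id": 10 * i + j,
                             "weight": 1.0})
        df = score_records(pd.DataFrame(rows))
        design = SurveyDesign(df.stratum_id, df.cluster_id, df.weight)
        sw = build_weights(guinea_adjacency())
        with pytest.raises(DomainError):
            regional_cci_surface(df, design, sw)

    def test_missing_region_errors(self, clustered_sample):
        df, design = clustered_sample
        scored = score_records(df)
        adj = guinea_adjacency()
        adj["Atlantis"] = ["Conakry"]
        adj["Conakry"].append("Atlantis")
        sw = build_weights(adj)
        with pytest.raises(DataError, match="Atlantis"):
            regional_cci_surface(scored, design, sw)
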