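"""Cluster permutation tests, ROI tests, and the split-plot mixed ANOVA."""

import numpy as np
import pandas as pd
import pytest

from segtag.cluster import (build_adjacency, cluster_permutation, mixed_anova,
                            roi_tests)


def grid_graph(nx, ny, max_dist=1.5):
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny))
    pos = np.column_stack([xx.ravel(), yy.ravel(),
                           np.zeros(nx * ny)]).astype(float)
    return build_adjacency(pos, max_dist)


class TestAdjacency:
    def test_chain_of_three(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        g = build_adjacency(pos, 1.0)
        assert [len(n) for n in g.neighbors] == [1, 2, 1]

    def test_grid_center_has_six_face_neighbors(self):
        ax = np.arange(3.0)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        g = build_adjacency(pos, 1.0)
        center = 13  # (1,1,1)
        assert len(g.neighbors[center]) == 6

    def test_zero_distance_gives_no_neighbors(self):
        g = build_adjacency(np.array([[0.0, 0, 0], [1.0, 0, 0]]), 0.0)
        assert all(n.size == 0 for n in g.neighbors)


class TestClusterPermutation:
    def test_planted_effect_found_with_matching_extent(self):
        rng = np.random.default_rng(0)
        g = grid_graph(10, 8)
        planted = {y * 10 + x for x in range(3) for y in range(3)}
        A = rng.standard_normal((10, 80))
        B = rng.standard_normal((10, 80))
        A[:, list(planted)] += 2.0
        res = cluster_permutation(A, B, "paired", g, n_perm=300, seed=1)
        sig = [set(c[0].tolist()) for c, p in zip(res.clusters, res.p_values)
               if p <= 0.05]
        assert sig
        best = max(len(s & planted) / len(s | planted) for s in sig)
        assert best > 0.5

    def test_unpaired_design_recovers_effect(self):
        rng = np.random.default_rng(2)
        g = grid_graph(10, 8)
        planted = list(range(33, 37)) + list(range(43, 47))
        A = rng.standard_normal((12, 80))
        B = rng.standard_normal((14, 80))
        A[:, planted] += 2.0
        res = cluster_permutation(A, B, "unpaired", g, n_perm=300, seed=2)
        assert any(p <= 0.05 for p in res.p_values)

    def test_isolated_suprathreshold_node_is_excluded(self):
        rng = np.random.default_rng(3)
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0], [6.0, 0, 0], [7.0, 0, 0]])
        g = build_adjacency(pos, 1.2)
        A = rng.standard_normal((10, 4)) * 0.1
        B = rng.standard_normal((10, 4)) * 0.1
        A[:, 0] += 5.0  # strong but isolated: node 0 has no neighbors
        res = cluster_permutation(A, B, "paired", g, n_perm=100, seed=3,
                                  min_neighbors=2)
        assert all(0 not in c[0] for c in res.clusters)

    def test_result_invariant_to_global_scaling(self):
        rng = np.random.default_rng(4)
        g = grid_graph(6, 5)
        A = rng.standard_normal((8, 30))
        B = rng.standard_normal((8, 30))
        A[:, :6] += 2.0
        r1 = cluster_permutation(A, B, "paired", g, n_perm=150, seed=5)
        r2 = cluster_permutation(1e3 * A, 1e3 * B, "paired", g, n_perm=150, seed=5)
        assert len(r1.clusters) == len(r2.clusters)
        assert np.allclose(r1.p_values, r2.p_values)
        for (n1, s1, _), (n2, s2, _) in zip(r1.clusters, r2.clusters):
            assert np.array_equal(n1, n2)
            assert s1 == pytest.approx(s2)

    def test_invariant_to_subject_reordering(self):
        rng = np.random.default_rng(5)
        g = grid_graph(6, 5)
        A = rng.standard_normal((8, 30))
        B = rng.standard_normal((8, 30))
        A[:, :6] += 1.5
        r1 = cluster_permutation(A, B, "paired", g, n_perm=150, seed=6)
        perm = rng.permutation(8)
        # permuting subjects jointly leaves the observed t map unchanged
        r2 = cluster_permutation(A[perm], B[perm], "paired", g, n_perm=150,
                                 seed=6)
        assert np.allclose(r1.t_values, r2.t_values)

    def test_degenerate_equal_data_has_no_clusters(self):
        g = grid_graph(4, 4)
        A = np.ones((6, 16))
        res = cluster_permutation(A, A.copy(), "paired", g, n_perm=100, seed=0)
        assert res.clusters == []

    def test_few_permutations_warn(self):
        g = grid_graph(4, 4)
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning):
            cluster_permutation(rng.standard_normal((6, 16)),
                                rng.standard_normal((6, 16)), "paired", g,
                                n_perm=50, seed=0)

    def test_family_wise_error_is_controlled(self):
        # null simulations: fraction of datasets with any significant
        # cluster stays near the nominal level
        g = grid_graph(12, 10)
        rng = np.random.default_rng(7)
        fw = 0
        n_runs = 100
        for run in range(n_runs):
            A = rng.standard_normal((10, 120))
            B = rng.standard_normal((10, 120))
            res = cluster_permutation(A, B, "paired", g, n_perm=200, seed=run)
            fw += any(p <= 0.05 for p in res.p_values)
        assert 0 <= fw / n_runs <= 0.10


class TestROITests:
    ROIS = {"left": np.array([0, 1]), "right": np.array([2, 3])}

    def test_bonferroni_alpha_for_twelve_tests(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((8, 4))
        B = rng.standard_normal((8, 4))
        out = roi_tests(A, B, self.ROIS, "paired", alpha=0.05, n_tests=12)
        for r in out.values():
            assert r["corrected_alpha"] == pytest.approx(0.05 / 12, abs=1e-6)
            assert r["corrected_alpha"] == pytest.approx(0.0042, abs=2e-4)

    def test_identical_paired_samples_give_p_one(self):
        A = np.tile(np.arange(6.0)[:, None], (1, 4))
        out = roi_tests(A, A.copy(), self.ROIS, "paired")
        assert all(r["p"] == 1.0 for r in out.values())

    def test_signed_rank_exact_p_for_consistent_direction(self):
        # n=6, all differences positive and untied: two-sided p = 2/64
        A = np.tile((10 + np.arange(6.0) * 0.1)[:, None], (1, 4))
        B = np.tile(np.arange(6.0)[:, None] * 0.01, (1, 4))
        out = roi_tests(A, B, self.ROIS, "paired", n_tests=1)
        for r in out.values():
            assert r["p"] == pytest.approx(2 / 64)

    def test_unpaired_uses_rank_sum(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((9, 4)) + 3.0
        B = rng.standard_normal((9, 4))
        out = roi_tests(A, B, self.ROIS, "unpaired", n_tests=2)
        assert all(r["significant"] for r in out.values())


class TestMixedAnova:
    @staticmethod
    def fixture_frame():
        """Deterministic 2 (between) x 6 subjects x 2 x 2 within dataset."""
        rng = np.random.default_rng(7)
        rows = []
        for g, gname in enumerate(["exp1", "exp2"]):
            for s in range(6):
                sid = f"{gname}_s{s}"
                base = rng.normal(0, 0.5)
                for c, cname in enumerate(["german", "other"]):
                    for h, hname in enumerate(["left", "right"]):
                        val = (base + 0.8 * c + 0.3 * h + 0.2 * g
                               + 0.25 * c * g + rng.normal(0, 0.3))
                        rows.append((gname, sid, cname, hname, round(val, 6)))
        return pd.DataFrame(rows, columns=["experiment", "participant",
                                           "condition", "hemisphere", "value"])

    def test_matches_reference_split_plot_decomposition(self):
        # frozen oracle: R aov(value ~ experiment*condition*hemisphere +
        # Error(participant/(condition*hemisphere))) on this exact frame
        res = mixed_anova(self.fixture_frame())
        expected_f = {
            "experiment": 2.588004,
            "condition": 138.588901,
            "experiment*condition": 6.301724,
            "hemisphere": 59.736303,
            "experiment*hemisphere": 0.008213,
            "condition*hemisphere": 0.127670,
            "experiment*condition*hemisphere": 0.224750,
        }
        for effect, f in expected_f.items():
            assert res[effect]["F"] == pytest.approx(f, abs=1e-4), effect
            assert res[effect]["df"] == (1, 10)
        assert res["condition"]["p"] < 1e-6
        assert 0 < res["condition"]["partial_eta_sq"] <= 1

    def test_planted_condition_effect_only(self):
        rng = np.random.default_rng(1)
        rows = []
        for gname in ("e1", "e2"):
            for s in range(10):
                base = rng.normal(0, 0.2)
                for c, cname in enumerate(["a", "b"]):
                    for hname in ("l", "r"):
                        rows.append((gname, f"{gname}{s}", cname, hname,
                                     base + 1.0 * c + rng.normal(0, 0.2)))
        df = pd.DataFrame(rows, columns=["experiment", "participant",
                                         "condition", "hemisphere", "value"])
        res = mixed_anova(df)
        assert res["condition"]["F"] > 50
        assert res["experiment*condition"]["F"] < 5
        assert res["condition*hemisphere"]["F"] < 5

    def test_all_equal_data_reports_zero_f(self):
        df = self.fixture_frame()
        df["value"] = 1.0
        res = mixed_anova(df)
        assert all(r["F"] == 0.0 and r["p"] == 1.0 for r in res.values())

    def test_incomplete_cells_rejected(self):
        df = self.fixture_frame().iloc[:-1]
        with pytest.raises(ValueError):
            mixed_anova(df)

    def test_detects_planted_coherence_reduction_with_power(self):
        # a 25% reduction of 4 Hz coupling in one condition, simulated at
        # the ROI level for 19 subjects, is detectable in >= 80% of runs
        rng = np.random.default_rng(2)
        detected = 0
        n_rep = 40
        for _ in range(n_rep):
            rows = []
            for gname in ("e1", "e2"):
                for s in range(10 if gname == "e1" else 9):
                    base = rng.normal(0.8, 0.15)
                    for cname, scale in (("with_words", 1.0), ("no_words", 0.75)):
                        for hname in ("l", "r"):
                            z = np.arctanh(np.clip(
                                base * scale + rng.normal(0, 0.08), 0.05, 0.99))
                            rows.append((gname, f"{gname}{s}", cname, hname, z))
            df = pd.DataFrame(rows, columns=["experiment", "participant",
                                             "condition", "hemisphere", "value"])
            detected += mixed_anova(df)["condition"]["p"] < 0.05
        assert detected / n_rep >= 0.8
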