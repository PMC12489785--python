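from collections import deque
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ieegconn import (
    BinaryNetwork,
    backward_eliminate,
    betweenness_centrality,
    build_node_table,
    degree,
    fit_intercept_only,
    fit_multilevel,
    spearman_with_fdr,
)
from ieegconn.synthetic import SimConfig, generate_cohort_table


def bc_oracle(adj):
    """Exhaustive BFS path-counting betweenness over unordered pairs."""
    n = len(adj)
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        # BFS distances from s
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if adj[u][v] and v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        if t not in dist:
            continue
        # enumerate all shortest s-t paths by DFS along decreasing distance
        paths = []
        stack = [[t]]
        while stack:
            path = stack.pop()
            u = path[-1]
            if u == s:
                paths.append(path)
                continue
            for v in range(n):
                if adj[u][v] and dist.get(v, -1) == dist[u] - 1:
                    stack.append(path + [v])
        sigma = len(paths)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / sigma
    return bc


def star(n):
    adj = np.zeros((n, n), dtype=bool)
    adj[0, 1:] = adj[1:, 0] = True
    return BinaryNetwork(tuple(f"n{i}" for i in range(n)), adj)


class TestDegree:
    def test_star_degrees(self):
        d = degree(star(5))
        assert d[0] == 4 and all(d[1:] == 1)

    def test_empty_network_all_zero(self):
        net = BinaryNetwork(("a", "b", "c"), np.zeros((3, 3), bool))
        assert degree(net).sum() == 0

    def test_handshake_identity(self, rng):
        for _ in range(10):
            n = rng.integers(3, 12)
            adj = np.triu(rng.random((n, n)) < 0.4, 1)
            net = BinaryNetwork(tuple(f"n{i}" for i in range(n)), adj | adj.T)
            assert degree(net).sum() == 2 * net.n_edges


class TestBetweenness:
    def test_path_graph_centre(self):
        net = BinaryNetwork.from_edges("abc", [("a", "b"), ("b", "c")])
        assert np.allclose(betweenness_centrality(net), [0, 1, 0])

    def test_star_centre_counts_all_leaf_pairs(self):
        assert betweenness_centrality(star(5))[0] == pytest.approx(6.0)

    def test_complete_graph_all_zero(self):
        n = 6
        net = BinaryNetwork(tuple(f"n{i}" for i in range(n)),
                            ~np.eye(n, dtype=bool))
        assert np.allclose(betweenness_centrality(net), 0.0)

    def test_matches_exhaustive_oracle_on_small_graphs(self, rng):
        """Shortest-path counting agrees with brute-force enumeration on
        random graphs of up to 8 nodes, including disconnected ones."""
        for _ in range(30):
            n = int(rng.integers(2, 9))
            p = rng.uniform(0.1, 0.9)
            adj = np.triu(rng.random((n, n)) < p, 1)
            adj = adj | adj.T
            net = BinaryNetwork(tuple(f"n{i}" for i in range(n)), adj)
            assert np.allclose(betweenness_centrality(net),
                               bc_oracle(adj.astype(int)))

    def test_relabelling_equivariance(self, rng):
        n = 7
        adj = np.triu(rng.random((n, n)) < 0.4, 1)
        adj = adj | adj.T
        labels = tuple(f"n{i}" for i in range(n))
        base = betweenness_centrality(BinaryNetwork(labels, adj))
        perm = rng.permutation(n)
        net2 = BinaryNetwork(tuple(labels[i] for i in perm),
                             adj[np.ix_(perm, perm)])
        assert np.allclose(betweenness_centrality(net2), base[perm])


class TestSpearmanWithFdr:
    def test_monotone_relation_gives_rho_one(self):
        x = np.arange(10.0)
        res = spearman_with_fdr({"p1": (x, np.exp(x)), "p2": (x, -x)})
        assert res.set_index("patient").loc["p1", "rho"] == pytest.approx(1.0)
        assert res.set_index("patient").loc["p2", "rho"] == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        x = np.arange(6.0)
        res = spearman_with_fdr({"p1": (x, np.ones(6)), "p2": (x, x)})
        row = res.set_index("patient").loc["p1"]
        assert row["constant"] and np.isnan(row["rho"])

    def test_fdr_less_conservative_than_bonferroni(self, rng):
        per_patient = {}
        for k in range(8):
            x = rng.normal(size=30)
            y = 0.8 * x + rng.normal(scale=0.5, size=30)
            per_patient[f"p{k}"] = (x, y)
        res = spearman_with_fdr(per_patient)
        assert (res["p_fdr"] >= res["p"] - 1e-12).all()
        assert (res["p_fdr"] <= res["p"] * len(res) + 1e-12).all()

    def test_null_rejection_rate_near_q(self):
        """Independent metrics are flagged significant at roughly the FDR
        level across repeated cohorts."""
        rng = np.random.default_rng(99)
        rejections = 0
        trials = 300
        for _ in range(trials):
            res = spearman_with_fdr(
                {"p": (rng.normal(size=60), rng.normal(size=60))}
            )
            rejections += int(res["significant"].iloc[0])
        rate = rejections / trials
        assert abs(rate - 0.05) < 0.03


class TestMultilevelModel:
    def test_generative_icc_from_planted_variances(self):
        """Intercept-only ICC tracks the planted 0.37 / (0.37 + 0.63) split."""
        cfg = SimConfig(n_patients=40, nodes_per_patient=60,
                        beta_ecd=0.0, beta_np=0.0)
        table = generate_cohort_table(cfg, seed=5)
        fit = fit_intercept_only(table, standardize=False)
        assert fit.icc == pytest.approx(0.37, abs=0.06)

    def test_zero_between_patient_variance_gives_icc_near_zero(self):
        cfg = SimConfig(n_patients=20, nodes_per_patient=50, beta_ecd=0.0,
                        beta_np=0.0, intercept_sd=0.0)
        table = generate_cohort_table(cfg, seed=2)
        fit = fit_intercept_only(table, standardize=False)
        assert fit.icc < 0.05

    def test_pure_between_patient_variance_gives_icc_near_one(self):
        rng = np.random.default_rng(0)
        rows = []
        for p in range(8):
            mean = rng.normal(scale=3.0)
            vals = mean + rng.normal(scale=1e-3, size=30)
            rows.append(pd.DataFrame({"patient": f"P{p}", "sc_degree": vals}))
        fit = fit_intercept_only(pd.concat(rows), standardize=False)
        assert fit.icc > 0.99

    def test_single_patient_rejected(self):
        table = pd.DataFrame({"patient": "P1", "sc_degree": np.arange(10.0)})
        with pytest.raises(ValueError, match="2 patients"):
            fit_intercept_only(table)

    def test_near_noiseless_fixed_effect_recovered(self):
        rng = np.random.default_rng(4)
        rows = []
        for p in range(5):
            x = rng.normal(size=40)
            y = 0.5 * x + p + rng.normal(scale=1e-6, size=40)
            rows.append(pd.DataFrame({"patient": f"P{p}", "sc_degree": y,
                                      "ec_degree": x}))
        fit = fit_multilevel(pd.concat(rows), predictors=("ec_degree",),
                             standardize=False)
        assert fit.terms.loc["ec_degree", "beta"] == pytest.approx(0.5,
                                                                   abs=1e-4)

    def test_conditional_r2_bounds_marginal(self):
        cfg = SimConfig(n_patients=10, nodes_per_patient=40)
        table = generate_cohort_table(cfg, seed=8)
        fit = fit_multilevel(table, predictors=("ec_degree", "proximity"))
        assert fit.r2_conditional >= fit.r2_marginal
        assert 0 <= fit.icc <= 1

    def test_null_predictor_usually_not_significant(self):
        hits = 0
        for seed in range(30):
            cfg = SimConfig(n_patients=8, nodes_per_patient=40)
            table = generate_cohort_table(cfg, seed=seed)
            fit = fit_multilevel(table, predictors=("vea",))
            hits += int(fit.terms.loc["vea", "p"] < 0.05)
        assert hits <= 5  # ~5% type-I rate, generous bound


class TestBackwardElimination:
    def test_retains_true_predictors_drops_null_ones(self):
        cfg = SimConfig()  # 13 patients x 66 nodes, beta = +-0.13
        table = generate_cohort_table(cfg, seed=21)
        fit = backward_eliminate(table)
        assert set(fit.retained) == {"ec_degree", "proximity"}
        dropped = {step["dropped"] for step in fit.elimination_path}
        assert dropped == {"vea", "soz"}

    def test_single_significant_predictor_unchanged(self):
        cfg = SimConfig(n_patients=10, nodes_per_patient=60)
        table = generate_cohort_table(cfg, seed=3)
        fit = backward_eliminate(table, predictors=("ec_degree",))
        assert fit.retained == ("ec_degree",)
        assert fit.elimination_path == []

    def test_all_null_predictors_can_collapse_to_intercept_only(self):
        cfg = SimConfig(n_patients=10, nodes_per_patient=40,
                        beta_ecd=0.0, beta_np=0.0)
        table = generate_cohort_table(cfg, seed=14)
        fit = backward_eliminate(table, predictors=("vea", "soz"))
        if fit.all_eliminated:
            assert fit.retained == ()
        else:  # a false retention is possible but rare
            assert set(fit.retained) <= {"vea", "soz"}


class TestBuildNodeTable:
    def test_one_row_per_node_with_metrics(self, rng):
        labels = tuple("abcd")
        adj = np.zeros((4, 4), bool)
        adj[0, 1] = adj[1, 0] = True
        sc = BinaryNetwork(labels, adj)
        ec = BinaryNetwork.from_edges(labels, [("a", "c")])
        table = build_node_table({
            "P1": {"sc": sc, "ec": ec, "proximity": np.arange(4.0),
                   "vea": np.full(4, 64.0), "soz": np.zeros(4)},
        })
        assert len(table) == 4
        assert list(table["sc_degree"]) == [1, 1, 0, 0]
        assert list(table["ec_degree"]) == [1, 0, 1, 0]
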