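"""CGBN engine against independent oracles: closed-form and quadrature
marginal likelihoods, exhaustive DAG enumeration for the greedy search,
full-joint enumeration for Markov-neighborhood prediction, and pairwise
concordance counting for the AUC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from bnomics import network as net
from bnomics.network import (
    BayesNetwork, NodeSpec, ScoreConfig, auc, bootstrap_learn,
    consensus_sweep, family_score_continuous, family_score_discrete,
    fit_parameters, greedy_learn, markov_neighborhood, predict_phenotype,
    total_score,
)


def nig_evidence_2d_quadrature(y, cfg: ScoreConfig) -> float:
    """Intercept-only oracle: nested adaptive quadrature over the mean and
    the variance (independent of the closed form under test)."""
    y = np.asarray(y, dtype=float)

    def lik_given_sigma2(s2):
        val, _ = integrate.quad(
            lambda mu: np.prod(stats.norm.pdf(y - mu, scale=np.sqrt(s2)))
            * stats.norm.pdf(mu, scale=np.sqrt(s2 / cfg.tau)),
            -np.inf, np.inf, limit=200)
        return val

    val, _ = integrate.quad(
        lambda s2: lik_given_sigma2(s2)
        * stats.invgamma.pdf(s2, cfg.a0, scale=cfg.b0),
        0, np.inf, limit=300)
    return float(np.log(val))


def nig_evidence_mvn_quadrature(y, X, cfg: ScoreConfig) -> float:
    """General oracle: coefficients marginalized through scipy's
    multivariate-normal density (y | s2 ~ N(0, s2 (I + X X'/tau))), then
    1-D adaptive quadrature over the variance."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    cov0 = np.eye(len(y)) + X @ X.T / cfg.tau

    def integrand(s2):
        return (stats.multivariate_normal.pdf(y, cov=s2 * cov0)
                * stats.invgamma.pdf(s2, cfg.a0, scale=cfg.b0))

    val, _ = integrate.quad(integrand, 0, np.inf, limit=500)
    return float(np.log(val))


class TestFamilyScoreDiscrete:
    def test_binary_child_uniform_prior_gives_one_sixth(self):
        # alpha_total=2 (alpha=1,1), data {0,1}: evidence = 1/6
        cfg = ScoreConfig(dirichlet_alpha_total=2.0)
        score = family_score_discrete(np.array([0, 1]), [], 2, [], cfg)
        assert score == pytest.approx(np.log(1.0 / 6.0))

    def test_matches_direct_dirichlet_multinomial_formula(self):
        from scipy.special import gammaln

        rng = np.random.default_rng(0)
        cfg = ScoreConfig(dirichlet_alpha_total=1.0)
        child = rng.integers(0, 3, size=40)
        parent = rng.integers(0, 2, size=40)
        score = family_score_discrete(child, [parent], 3, [2], cfg)
        expected = 0.0
        for pa in (0, 1):
            counts = np.bincount(child[parent == pa], minlength=3)
            a = 1.0 / 3.0
            expected += gammaln(1.0) - gammaln(1.0 + counts.sum())
            expected += (gammaln(a + counts) - gammaln(a)).sum()
        assert score == pytest.approx(expected)

    def test_observation_order_invariance(self):
        rng = np.random.default_rng(1)
        child = rng.integers(0, 2, size=30)
        parent = rng.integers(0, 3, size=30)
        cfg = ScoreConfig()
        s1 = family_score_discrete(child, [parent], 2, [3], cfg)
        perm = rng.permutation(30)
        s2 = family_score_discrete(child[perm], [parent[perm]], 2, [3], cfg)
        assert s1 == pytest.approx(s2)

    def test_empty_data_scores_zero(self):
        assert family_score_discrete(np.array([], dtype=int), [], 2, [],
                                     ScoreConfig()) == 0.0


class TestFamilyScoreContinuous:
    def test_single_observation_matches_student_t_predictive(self):
        cfg = ScoreConfig()
        score = family_score_continuous(np.array([0.0]), [], [], [], cfg)
        # predictive at the prior mean: t with 2*a0 df,
        # scale^2 = (b0/a0) * (1 + 1/tau)
        scale = np.sqrt(cfg.b0 / cfg.a0 * (1 + 1 / cfg.tau))
        expected = stats.t.logpdf(0.0, df=2 * cfg.a0, scale=scale)
        assert score == pytest.approx(float(expected), rel=1e-10)

    def test_intercept_only_matches_2d_quadrature(self):
        cfg = ScoreConfig()
        y = np.array([0.3, -0.6, 1.1])
        score = family_score_continuous(y, [], [], [], cfg)
        oracle = nig_evidence_2d_quadrature(y, cfg)
        assert score == pytest.approx(oracle, rel=1e-6)

    def test_one_continuous_parent_matches_quadrature(self):
        cfg = ScoreConfig(tau=2.0, a0=1.5, b0=0.8)
        y = np.array([0.5, -0.2, 0.9, -1.1, 0.3])
        x = np.array([1.0, -0.5, 0.7, -1.2, 0.1])
        score = family_score_continuous(y, [], [x], [], cfg)
        X = np.column_stack([np.ones(5), x])
        oracle = nig_evidence_mvn_quadrature(y, X, cfg)
        assert score == pytest.approx(oracle, rel=1e-6)

    def test_discrete_parent_sums_over_configurations(self):
        cfg = ScoreConfig()
        rng = np.random.default_rng(2)
        y = rng.normal(size=12)
        d = np.array([0, 1] * 6)
        score = family_score_continuous(y, [d], [], [2], cfg)
        parts = sum(
            family_score_continuous(y[d == v], [], [], [], cfg)
            for v in (0, 1))
        assert score == pytest.approx(parts)

    def test_observation_order_invariance(self):
        cfg = ScoreConfig()
        rng = np.random.default_rng(3)
        y = rng.normal(size=20)
        x = rng.normal(size=20)
        perm = rng.permutation(20)
        assert family_score_continuous(y, [], [x], [], cfg) == pytest.approx(
            family_score_continuous(y[perm], [], [x[perm]], [], cfg))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            family_score_continuous(np.ones(3), [], [np.ones(4)], [],
                                    ScoreConfig())


def all_dags_3nodes(names):
    """Every DAG on 3 labeled nodes, as edge lists."""
    pairs = [(a, b) for a in names for b in names if a != b]
    for r in range(len(pairs) + 1):
        for combo in itertools.combinations(pairs, r):
            g = BayesNetwork([NodeSpec(n, "continuous") for n in names])
            ok = True
            for p, c in combo:
                if g.creates_cycle(p, c):
                    ok = False
                    break
                g.add_edge(p, c)
            if ok:
                yield list(combo)


class TestGreedyLearn:
    def test_first_move_is_globally_best_single_edge(self):
        # exhaustive enumeration over all single-edge networks, 20 random
        # 3-node continuous datasets
        names = ["a", "b", "c"]
        specs = [NodeSpec(n, "continuous") for n in names]
        cfg = ScoreConfig()
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame(rng.normal(size=(30, 3)), columns=names)
            data["b"] += 0.8 * data["a"]
            empty_score = total_score(BayesNetwork(specs), data, cfg)
            best_edge, best_score = None, empty_score
            for p, c in itertools.permutations(names, 2):
                s = total_score(BayesNetwork(specs, [(p, c)]), data, cfg)
                if s > best_score:
                    best_edge, best_score = (p, c), s
            learned = greedy_learn(data, specs, cfg)
            if best_edge is None:
                assert learned.edges == []
            else:
                # re-trace the first move: highest-delta edge
                first = max(
                    itertools.permutations(names, 2),
                    key=lambda e: total_score(
                        BayesNetwork(specs, [e]), data, cfg))
                assert first == best_edge
                assert best_edge in learned.edges or tuple(
                    reversed(best_edge)) in learned.edges

    def test_independent_data_learns_empty_network(self):
        rng = np.random.default_rng(7)
        names = [f"x{i}" for i in range(5)]
        data = pd.DataFrame(rng.normal(size=(200, 5)), columns=names)
        learned = greedy_learn(data, [NodeSpec(n, "continuous")
                                      for n in names])
        assert learned.edges == []

    def test_strong_dependence_recovered_in_some_orientation(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=150)
        data = pd.DataFrame({"x": x, "y": x + 0.1 * rng.normal(size=150)})
        specs = [NodeSpec("x", "continuous"), NodeSpec("y", "continuous")]
        learned = greedy_learn(data, specs)
        assert ("x", "y") in learned.edges or ("y", "x") in learned.edges

    def test_cg_restriction_no_continuous_parent_of_discrete(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=300)
        d = (z > 0).astype(int)
        data = pd.DataFrame({"z": z, "d": d})
        specs = [NodeSpec("z", "continuous"), NodeSpec("d", "discrete", (0, 1))]
        learned = greedy_learn(data, specs)
        assert ("z", "d") not in learned.edges
        assert ("d", "z") in learned.edges  # the dependence is real

    def test_max_parents_respected(self):
        rng = np.random.default_rng(10)
        parents = rng.normal(size=(100, 5))
        y = parents.sum(axis=1) + 0.1 * rng.normal(size=100)
        data = pd.DataFrame(parents, columns=[f"p{i}" for i in range(5)])
        data["y"] = y
        cfg = ScoreConfig(max_parents=2)
        learned = greedy_learn(data, list(
            NodeSpec(c, "continuous") for c in data.columns), cfg)
        assert all(len(ps) <= 2 for ps in learned.parents.values())


class TestDecomposability:
    def test_total_score_is_sum_of_families_and_local_change(self):
        rng = np.random.default_rng(11)
        names = ["a", "b", "c", "d"]
        data = pd.DataFrame(rng.normal(size=(40, 4)), columns=names)
        specs = [NodeSpec(n, "continuous") for n in names]
        cfg = ScoreConfig()
        net0 = BayesNetwork(specs, [("a", "b")])
        net1 = BayesNetwork(specs, [("a", "b"), ("c", "b")])
        delta_total = total_score(net1, data, cfg) - total_score(net0, data, cfg)
        fam0 = family_score_continuous(
            data["b"].to_numpy(), [], [data["a"].to_numpy()], [], cfg)
        fam1 = family_score_continuous(
            data["b"].to_numpy(), [],
            [data["a"].to_numpy(), data["c"].to_numpy()], [], cfg)
        assert delta_total == pytest.approx(fam1 - fam0)

    def test_score_equivalence_gap_is_small_for_standardized_pair(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=100)
        y = 0.6 * x + 0.8 * rng.normal(size=100)
        for v in (x, y):
            v -= v.mean()
            v /= v.std()
        data = pd.DataFrame({"x": x, "y": y})
        specs = [NodeSpec("x", "continuous"), NodeSpec("y", "continuous")]
        cfg = ScoreConfig()
        s_xy = total_score(BayesNetwork(specs, [("x", "y")]), data, cfg)
        s_yx = total_score(BayesNetwork(specs, [("y", "x")]), data, cfg)
        # the two orientations differ only through the prior
        assert abs(s_xy - s_yx) < 2.0


class TestBootstrap:
    def test_single_bootstrap_tally_is_indicator(self, planted_cohort):
        from conftest import network_table

        data, specs = network_table(planted_cohort[0])
        tally = bootstrap_learn(data, specs, B=1, seed=0)
        assert tally.B == 1
        assert set(tally.frequencies.values()) == {1.0}

    def test_degenerate_identical_rows_give_zero_one_frequencies(self):
        row = {"x": 1.0, "y": 2.0, "d": 1}
        data = pd.DataFrame([row] * 30)
        specs = [NodeSpec("x", "continuous"), NodeSpec("y", "continuous"),
                 NodeSpec("d", "discrete", (0, 1))]
        tally = bootstrap_learn(data, specs, B=10, seed=1)
        assert all(f in (0.0, 1.0) for f in tally.frequencies.values())

    def test_planted_edges_attain_top_frequencies(self):
        # 6-node planted chain, n=200: the true couplings dominate the tally
        rng = np.random.default_rng(13)
        n = 200
        a = rng.normal(size=n)
        b = a + 0.5 * rng.normal(size=n)
        c = b + 0.5 * rng.normal(size=n)
        data = pd.DataFrame({
            "a": a, "b": b, "c": c,
            "u": rng.normal(size=n), "v": rng.normal(size=n),
            "w": rng.normal(size=n)})
        specs = [NodeSpec(k, "continuous") for k in data.columns]
        tally = bootstrap_learn(data, specs, B=50, seed=2)
        freqs = tally.frequencies
        planted = {frozenset(("a", "b")), frozenset(("b", "c"))}
        undirected: dict[frozenset, float] = {}
        for (p, ch), f in freqs.items():
            key = frozenset((p, ch))
            undirected[key] = undirected.get(key, 0.0) + f
        top2 = sorted(undirected, key=undirected.get, reverse=True)[:2]
        assert set(top2) == planted


class TestMarkovNeighborhood:
    def _fig5_like(self):
        """Phenotype with two metabolite children, each with SNP
        co-parents: the published consensus topology."""
        specs = [NodeSpec("pheno", "discrete", (0, 1)),
                 NodeSpec("S1P", "continuous"),
                 NodeSpec("monoHETE", "continuous")] + [
            NodeSpec(s, "discrete", (0, 1, 2))
            for s in ("rs9522789", "rs7147228", "rs7201423", "rs759582")]
        edges = [("pheno", "S1P"), ("pheno", "monoHETE"),
                 ("rs9522789", "S1P"), ("rs7147228", "S1P"),
                 ("rs7201423", "monoHETE"), ("rs759582", "monoHETE")]
        return BayesNetwork(specs, edges)

    def test_isolated_node_has_empty_neighborhood(self):
        bn = BayesNetwork([NodeSpec("pheno", "discrete", (0, 1)),
                           NodeSpec("m", "continuous")])
        assert markov_neighborhood(bn, "pheno") == []

    def test_child_and_coparent(self):
        bn = BayesNetwork(
            [NodeSpec("pheno", "discrete", (0, 1)),
             NodeSpec("M1", "continuous"),
             NodeSpec("S1", "discrete", (0, 1, 2))],
            [("pheno", "M1"), ("S1", "M1")])
        assert markov_neighborhood(bn, "pheno") == ["M1", "S1"]

    def test_consensus_topology_gives_two_metabolites_four_snps(self):
        bn = self._fig5_like()
        mn = markov_neighborhood(bn, "pheno")
        assert len(mn) == 6
        assert sum(m in ("S1P", "monoHETE") for m in mn) == 2
        assert sum(m.startswith("rs") for m in mn) == 4

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            markov_neighborhood(self._fig5_like(), "nope")


class TestPredictPhenotype:
    def _random_discrete_net(self, rng, n_nodes):
        names = [f"n{i}" for i in range(n_nodes)]
        specs = [NodeSpec(n, "discrete", (0, 1)) for n in names]
        bn = BayesNetwork(specs)
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.uniform() < 0.4:
                    bn.add_edge(names[i], names[j])
        data = pd.DataFrame(
            rng.integers(0, 2, size=(60, n_nodes)), columns=names)
        fit_parameters(bn, data)
        return bn, data, names

    def _joint_posterior(self, bn, evidence, node):
        """Brute-force: enumerate the full joint from the fitted CPTs."""
        names = bn.order
        post = np.zeros(2)
        for s in (0, 1):
            total = 0.0
            assign = dict(evidence)
            assign[node] = s
            prob = 1.0
            for n in names:
                fam = bn.parameters[n]
                key = tuple(int(assign[p]) for p in fam["parents"])
                probs = fam["cpt"].get(key, fam["prior"])
                prob *= probs[int(assign[n])]
            total += prob
            post[s] = total
        return post / post.sum()

    def test_equals_full_joint_enumeration(self):
        rng = np.random.default_rng(14)
        for trial in range(15):
            n_nodes = int(rng.integers(3, 6))
            bn, data, names = self._random_discrete_net(rng, n_nodes)
            node = names[int(rng.integers(n_nodes))]
            row = data.iloc[int(rng.integers(len(data)))]
            expected = self._joint_posterior(bn, row.to_dict(), node)
            got = predict_phenotype(bn, row, node)
            assert np.allclose(got, expected, atol=1e-12), (trial, node)

    def test_empty_neighborhood_returns_marginal_prevalence(self):
        rng = np.random.default_rng(15)
        bn = BayesNetwork([NodeSpec("pheno", "discrete", (0, 1)),
                           NodeSpec("m", "continuous")])
        data = pd.DataFrame({"pheno": rng.integers(0, 2, 50),
                             "m": rng.normal(size=50)})
        fit_parameters(bn, data)
        post = predict_phenotype(bn, data.iloc[0], "pheno")
        prev = bn.parameters["pheno"]["cpt"][()]
        assert np.allclose(post, prev)

    def test_tail_evidence_moves_posterior_monotonically(self):
        rng = np.random.default_rng(16)
        y = rng.integers(0, 2, 400)
        m = np.where(y == 1, 1.5, -1.5) + rng.normal(size=400)
        bn = BayesNetwork([NodeSpec("pheno", "discrete", (0, 1)),
                           NodeSpec("m", "continuous")],
                          [("pheno", "m")])
        data = pd.DataFrame({"pheno": y, "m": m})
        fit_parameters(bn, data)
        posts = [predict_phenotype(
            bn, pd.Series({"m": v, "pheno": 0}), "pheno")[1]
            for v in (-3.0, -1.0, 0.0, 1.0, 3.0)]
        assert all(np.diff(posts) > 0)
        # independent density-ratio check at one point
        mu1 = bn.parameters["m"]["by_config"][(1,)]["coef"][0]
        mu0 = bn.parameters["m"]["by_config"][(0,)]["coef"][0]
        v1 = bn.parameters["m"]["by_config"][(1,)]["var"]
        v0 = bn.parameters["m"]["by_config"][(0,)]["var"]
        prior = bn.parameters["pheno"]["cpt"][()]
        num = prior[1] * stats.norm.pdf(3.0, mu1, np.sqrt(v1))
        den = num + prior[0] * stats.norm.pdf(3.0, mu0, np.sqrt(v0))
        assert posts[-1] == pytest.approx(num / den, rel=1e-9)

    def test_prediction_calibration_matches_prevalence(self):
        rng = np.random.default_rng(17)
        n = 1000
        y = (rng.uniform(size=n) < 0.35).astype(int)
        m = 0.8 * y + rng.normal(size=n)
        bn = BayesNetwork([NodeSpec("pheno", "discrete", (0, 1)),
                           NodeSpec("m", "continuous")],
                          [("pheno", "m")])
        data = pd.DataFrame({"pheno": y, "m": m})
        fit_parameters(bn, data)
        mean_post = np.mean([predict_phenotype(bn, data.iloc[i], "pheno")[1]
                             for i in range(n)])
        assert abs(mean_post - y.mean()) < 0.05


class TestParameterRecovery:
    def test_cpt_and_regression_within_ten_percent(self):
        rng = np.random.default_rng(18)
        n = 5000
        d = (rng.uniform(size=n) < 0.3).astype(int)
        x = rng.normal(size=n)
        y = np.where(d == 1, 1.0 + 0.5 * x, -0.5 + 1.5 * x) \
            + np.sqrt(0.8) * rng.normal(size=n)
        bn = BayesNetwork(
            [NodeSpec("d", "discrete", (0, 1)), NodeSpec("x", "continuous"),
             NodeSpec("y", "continuous")],
            [("d", "y"), ("x", "y")])
        data = pd.DataFrame({"d": d, "x": x, "y": y})
        fit_parameters(bn, data)
        assert bn.parameters["d"]["cpt"][()][1] == pytest.approx(0.3, rel=0.1)
        c1 = bn.parameters["y"]["by_config"][(1,)]
        c0 = bn.parameters["y"]["by_config"][(0,)]
        assert c1["coef"][0] == pytest.approx(1.0, rel=0.1)
        assert c1["coef"][1] == pytest.approx(0.5, rel=0.1)
        assert c0["coef"][0] == pytest.approx(-0.5, rel=0.1)
        assert c0["coef"][1] == pytest.approx(1.5, rel=0.1)
        assert c1["var"] == pytest.approx(0.8, rel=0.1)


class TestConsensusSweep:
    def test_threshold_one_keeps_only_unanimous_edges(self, planted_cohort):
        from conftest import network_table

        from bnomics.network import consensus_network

        data, specs = network_table(planted_cohort[0])
        tally = bootstrap_learn(data, specs, B=5, seed=3)
        bn = consensus_network(tally, specs, 1.0)
        for e in bn.edges:
            assert tally.frequencies[e] == 1.0

    def test_identical_bootstraps_give_single_network_trace(self):
        row0 = {"x": 0.0, "y": 1.0, "pheno": 0}
        row1 = {"x": 1.0, "y": 0.0, "pheno": 1}
        data = pd.DataFrame([row0] * 15 + [row1] * 15)
        specs = [NodeSpec("x", "continuous"), NodeSpec("y", "continuous"),
                 NodeSpec("pheno", "discrete", (0, 1))]
        tally = bootstrap_learn(data, specs, B=8, seed=4)
        if not tally.counts:
            pytest.skip("no edges learned on degenerate data")
        sweep = consensus_sweep(tally, data, specs, k_folds=3, seed=4,
                                phenotype="pheno")
        assert sweep.chosen_auc == max(t["cv_auc"] for t in sweep.trace)

    def test_missing_phenotype_rejected(self):
        data = pd.DataFrame({"x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="phenotype"):
            consensus_sweep(net.EdgeTally({}, 1), data,
                            [NodeSpec("x", "continuous")], phenotype="pheno")

    def test_chosen_network_acyclic_and_auc_is_max(self, planted_cohort):
        from conftest import network_table

        data, specs = network_table(planted_cohort[0])
        tally = bootstrap_learn(data, specs, B=10, seed=5)
        sweep = consensus_sweep(tally, data, specs, k_folds=5, seed=5)
        assert sweep.chosen_network.is_acyclic()
        assert sweep.chosen_auc == pytest.approx(
            max(t["cv_auc"] for t in sweep.trace))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            n = int(rng.integers(4, 12))
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)),
                              replace=False)] = 1
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            scores = rng.integers(0, 5, size=n).astype(float)
            expected = 0.0
            for i in np.flatnonzero(labels == 1):
                for j in np.flatnonzero(labels == 0):
                    expected += (1.0 if scores[i] > scores[j]
                                 else 0.5 if scores[i] == scores[j] else 0.0)
            expected /= labels.sum() * (n - labels.sum())
            assert auc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([1.0, 2.0], [1, 1])


class TestNetworkStructure:
    def test_cycle_detection(self):
        bn = BayesNetwork([NodeSpec(n, "continuous") for n in "abc"],
                          [("a", "b"), ("b", "c")])
        assert bn.creates_cycle("c", "a")
        with pytest.raises(ValueError, match="cycle"):
            bn.add_edge("c", "a")

    def test_cg_violation_rejected(self):
        bn = BayesNetwork([NodeSpec("x", "continuous"),
                           NodeSpec("d", "discrete", (0, 1))])
        with pytest.raises(ValueError, match="CG restriction"):
            bn.add_edge("x", "d")

    def test_json_round_trip_fields(self, tmp_path):
        bn = BayesNetwork([NodeSpec("x", "continuous"),
                           NodeSpec("d", "discrete", (0, 1))],
                          [("d", "x")])
        bn.to_json(tmp_path / "net.json")
        import json

        loaded = json.loads((tmp_path / "net.json").read_text())
        assert loaded["edges"][0]["parent"] == "d"
        assert {n["name"] for n in loaded["nodes"]} == {"x", "d"}


def test_extended_moves_can_only_improve_score():
    rng = np.random.default_rng(20)
    n = 120
    a = rng.normal(size=n)
    b = a + 0.6 * rng.normal(size=n)
    c = b + 0.6 * rng.normal(size=n)
    data = pd.DataFrame({"a": a, "b": b, "c": c})
    specs = [NodeSpec(k, "continuous") for k in data.columns]
    cfg = ScoreConfig()
    base = greedy_learn(data, specs, cfg)
    refined = greedy_learn(data, specs, cfg, extended_moves=True)
    assert total_score(refined, data, cfg) >= total_score(base, data, cfg) - 1e-9
    assert refined.is_acyclic()
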