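"""Stability scoring, variable ranking, inference, clustering, bootstrap."""

import numpy as np
import pytest

from ridgenet import benchmark_sim as bs
from ridgenet import kinetic_network as kn
from ridgenet.cli import make_fixture
from ridgenet.ridge_io import Experiment, Ridge, TimeGrid


def env_dict_from_fixture(kind="chain_kinetics", seed=2):
    coll = make_fixture(kind, seed)
    envs = {}
    for exp in coll.experiments.values():
        envs.setdefault(exp.condition.get("environment", exp.experiment_id), []).append(exp)
    return envs


def single_reaction_envs(n_env=3, seed=2, k=0.7):
    """dB/dt = k*A exactly; C is an unrelated decaying curve."""
    grid = np.linspace(0, 5, 26)
    tg = TimeGrid(grid)
    rng = np.random.default_rng(seed)
    reactions = [bs.Reaction((0,), (1,), k)]
    environments = {}
    for e in range(n_env):
        init = rng.uniform(0.2, 1.0, 3)
        X = bs.simulate(reactions, init, grid)
        X[2] = init[2] * np.exp(-rng.uniform(0.1, 1.0) * grid)
        exp = Experiment(f"e{e}", tg, condition={"environment": f"e{e}"})
        for i, name in enumerate("ABC"):
            exp.add(Ridge(name, f"e{e}", np.full(26, 1.0 + i), X[i]))
        environments[f"e{e}"] = [exp]
    return kn.prepare_environments(environments, dense_factor=2)


class TestPrescreen:
    def test_perfect_predictor_ranked_first(self):
        envs = single_reaction_envs()
        ranked = kn.prescreen("B", envs, k=2)
        assert ranked[0] == "A"

    def test_matches_bruteforce_correlation_loop(self):
        envs = kn.prepare_environments(env_dict_from_fixture(), dense_factor=2)
        fids = envs[0].feature_ids
        target = "B"
        ti = fids.index(target)
        d = np.concatenate([e.derivs[:, ti, :].ravel() for e in envs])
        cors = {}
        for si, s in enumerate(fids):
            if s == target:
                continue
            x = np.concatenate([e.values[:, si, :].ravel() for e in envs])
            cors[s] = abs(np.corrcoef(d, x)[0, 1])
        oracle = sorted(cors, key=lambda s: (-cors[s], s))
        assert kn.prescreen(target, envs, k=10) == oracle


class TestScoreModel:
    def test_true_generator_scores_near_zero(self):
        """dB/dt = 0.7*A: the {A} model integrates to the held-out curve."""
        envs = single_reaction_envs()
        true_score = kn.score_model(kn.CandidateModel("B", (("A",),)), envs)
        false_score = kn.score_model(kn.CandidateModel("B", (("C",),)), envs)
        assert true_score < 1e-3
        assert false_score > 100 * true_score

    def test_intercept_only_on_constant_target(self):
        grid = np.linspace(0, 5, 26)
        tg = TimeGrid(grid)
        environments = {}
        for e in range(2):
            exp = Experiment(f"e{e}", tg, condition={})
            exp.add(Ridge("K", f"e{e}", np.full(26, 1.0), np.full(26, 2.0 + e)))
            exp.add(Ridge("X", f"e{e}", np.full(26, 2.0), np.linspace(1, 0.2 + e, 26)))
            environments[f"e{e}"] = [exp]
        envs = kn.prepare_environments(environments, dense_factor=2)
        score = kn.score_model(kn.CandidateModel("K", ()), envs)
        assert score == pytest.approx(0.0, abs=1e-4)

    def test_invariant_to_environment_relabeling(self):
        envs = single_reaction_envs()
        m = kn.CandidateModel("B", (("A",),))
        s1 = kn.score_model(m, envs)
        s2 = kn.score_model(m, list(reversed(envs)), )
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_requires_two_environments(self):
        envs = single_reaction_envs()[:1]
        with pytest.raises(ValueError):
            kn.score_model(kn.CandidateModel("B", (("A",),)), envs)


class TestEnumerateModels:
    def test_counts_with_interactions(self):
        models = kn.enumerate_models("T", ["a", "b", "c"])
        # 3 singles + 3 pairs-of-singles + 3 interaction products
        assert len(models) == 9
        assert all(len(m.terms) <= 2 for m in models)

    def test_no_self_edges_possible_terms(self):
        models = kn.enumerate_models("T", ["a", "b"])
        assert all("T" not in m.covariates for m in models)


class TestRankVariables:
    def test_ranksum_oracle_on_toy_score_table(self):
        """Enumerated toy: covariate 'a' in systematically better models."""
        from scipy.stats import mannwhitneyu

        scored = []
        rng = np.random.default_rng(0)
        for i in range(10):
            scored.append(kn.CandidateModel("T", (("a",), (f"x{i}",)), float(0.1 + 0.01 * i)))
        for i in range(10):
            scored.append(kn.CandidateModel("T", ((f"x{i}",),), float(5 + i)))
        out = {e.covariate: e for e in kn.rank_variables("T", scored)}
        with_a = [m.score for m in scored if "a" in m.covariates]
        without_a = [m.score for m in scored if "a" not in m.covariates]
        expected = mannwhitneyu(with_a, without_a, alternative="less").pvalue
        assert out["a"].p_value == pytest.approx(expected)
        assert out["a"].p_value < 0.01
        assert out["a"].importance == pytest.approx(min(with_a))

    def test_exchangeable_null_no_edge(self):
        scored = []
        for i, s in enumerate(np.linspace(1, 2, 12)):
            cov = "a" if i % 2 == 0 else "b"
            scored.append(kn.CandidateModel("T", ((cov,), (f"x{i}",)), float(s)))
        out = {e.covariate: e for e in kn.rank_variables("T", scored)}
        assert out["a"].p_value > 0.05

    def test_insufficient_models_p_one(self):
        scored = [kn.CandidateModel("T", (("a",),), 0.5)]
        out = kn.rank_variables("T", scored)
        assert all(e.p_value == 1.0 for e in out)


class TestInferNetwork:
    def test_chain_recovered_noiseless(self):
        """A->B->C chain among decoy features over 5 environments: the
        A-B and B-C edges are found and the transitive A-C edge is not.

        Decoy features (independent exponential decays) give the
        significance test enough candidate models to resolve; with only
        three features the model space is too small for any covariate to
        reach significance at the 5% level.
        """
        grid = np.linspace(0, 5, 26)
        tg = TimeGrid(grid)
        rng = np.random.default_rng(7)
        reactions = [bs.Reaction((0,), (1,), 0.7), bs.Reaction((1,), (2,), 0.4)]
        names = ["A", "B", "C", "D0", "D1", "D2"]
        environments = {}
        for e in range(5):
            X = bs.simulate(reactions, rng.uniform(0.2, 1.0, 3), grid)
            decoys = [
                init * np.exp(-rate * grid)
                for init, rate in zip(rng.uniform(0.2, 1.0, 3), rng.uniform(0.1, 1.2, 3))
            ]
            curves = list(X) + decoys
            exp = Experiment(f"e{e}", tg, condition={"environment": f"e{e}"})
            for i, name in enumerate(names):
                exp.add(Ridge(name, f"e{e}", np.full(26, 1.0 + i), curves[i]))
            environments[f"e{e}"] = [exp]
        envs = kn.prepare_environments(environments, dense_factor=2)
        net = kn.infer_network(envs, alpha=0.05, prescreen_k=5)
        edges = {tuple(sorted(e)) for e in net.edge_set()}
        assert ("A", "B") in edges
        assert ("B", "C") in edges
        assert ("A", "C") not in edges

    def test_single_environment_rejected(self):
        envs = single_reaction_envs()[:1]
        with pytest.raises(ValueError, match="multiple conditions"):
            kn.infer_network(envs)

    def test_feature_order_invariance(self):
        envs = single_reaction_envs()
        net1 = kn.infer_network(envs, prescreen_k=3)
        # rebuild with reversed feature order
        envs_r = [
            kn.EnvironmentData(
                e.environment_id,
                list(reversed(e.feature_ids)),
                e.grid,
                e.values[:, ::-1, :],
                e.derivs[:, ::-1, :],
            )
            for e in envs
        ]
        net2 = kn.infer_network(envs_r, prescreen_k=3)
        assert net1.edge_set() == net2.edge_set()


class TestCommunityCluster:
    def _net(self, edges, nodes):
        net = kn.FunctionalNetwork(node_ids=list(nodes))
        for a, b in edges:
            net.add_edge(a, b, 0.1, 0.01)
        return net

    def test_two_cliques_two_communities(self):
        nodes = [f"n{i}" for i in range(10)]
        edges = [(f"n{i}", f"n{j}") for i in range(5) for j in range(i + 1, 5)]
        edges += [(f"n{i}", f"n{j}") for i in range(5, 10) for j in range(i + 1, 10)]
        edges.append(("n0", "n5"))
        net = self._net(edges, nodes)
        labels = kn.community_cluster(net)
        assert len({labels[f"n{i}"] for i in range(5)}) == 1
        assert len({labels[f"n{i}"] for i in range(5, 10)}) == 1
        assert labels["n0"] != labels["n9"]

    def test_complete_graph_one_community(self):
        nodes = [f"n{i}" for i in range(6)]
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        labels = kn.community_cluster(self._net(edges, nodes))
        assert len(set(labels.values())) == 1

    def test_empty_network_singletons(self):
        net = self._net([], ["a", "b", "c"])
        labels = kn.community_cluster(net)
        assert sorted(labels) == ["a", "b", "c"]
        assert len(set(labels.values())) == 3

    def test_planted_partition_matches_modularity_oracle(self):
        """Greedy labels equal networkx's agglomerative modularity result
        and carry near-optimal modularity on a planted-partition graph."""
        import networkx as nx

        rng = np.random.default_rng(5)
        n_half = 15
        nodes = [f"v{i:02d}" for i in range(2 * n_half)]
        edges = []
        for i in range(2 * n_half):
            for j in range(i + 1, 2 * n_half):
                same = (i < n_half) == (j < n_half)
                p = 0.6 if same else 0.05
                if rng.random() < p:
                    edges.append((nodes[i], nodes[j]))
        net = self._net(edges, nodes)
        labels = kn.community_cluster(net)
        parts: dict[int, set] = {}
        for nid, c in labels.items():
            parts.setdefault(c, set()).add(nid)
        g = net.to_graph()
        got_q = nx.algorithms.community.modularity(g, list(parts.values()))
        planted_q = nx.algorithms.community.modularity(
            g, [set(nodes[:n_half]), set(nodes[n_half:])]
        )
        assert got_q >= planted_q - 1e-9


@pytest.fixture(scope="module")
def replicate_envs():
    grid = np.linspace(0, 5, 26)
    tg = TimeGrid(grid)
    rng = np.random.default_rng(13)
    reactions = [bs.Reaction((0,), (1,), 0.7)]
    environments = {}
    for e in range(2):
        init = rng.uniform(0.3, 1.0, 3)
        X = bs.simulate(reactions, init, grid)
        X[2] = init[2] * np.exp(-rng.uniform(0.2, 0.8) * grid)
        reps = []
        for r in range(2):
            exp = Experiment(f"e{e}r{r}", tg, condition={"environment": f"e{e}"})
            for i, name in enumerate("ABC"):
                y = bs.add_noise(X[i][None, :], rng)[0]
                exp.add(Ridge(name, exp.experiment_id, np.full(26, 1.0 + i), y))
            reps.append(exp)
        environments[f"e{e}"] = reps
    return kn.prepare_environments(environments, dense_factor=2)


class TestBootstrap:
    def test_identical_replicates_give_binary_support(self):
        envs = single_reaction_envs()
        # duplicate the single replicate: resampling cannot vary
        envs2 = [
            kn.EnvironmentData(
                e.environment_id,
                e.feature_ids,
                e.grid,
                np.repeat(e.values, 2, axis=0),
                np.repeat(e.derivs, 2, axis=0),
            )
            for e in envs
        ]
        net = kn.bootstrap_support(envs2, B=5, seed=1, prescreen_k=2)
        for attrs in net.edges.values():
            assert attrs["support"] in (0.0, 1.0)
        cc = net.cocluster_frequency
        assert np.allclose(cc, cc.T)
        assert np.allclose(np.diag(cc), 1.0)
        assert set(np.unique(cc)) <= {0.0, 1.0}

    def test_seeded_determinism(self, replicate_envs):
        n1 = kn.bootstrap_support(replicate_envs, B=4, seed=9, prescreen_k=2)
        n2 = kn.bootstrap_support(replicate_envs, B=4, seed=9, prescreen_k=2)
        assert np.array_equal(n1.cocluster_frequency, n2.cocluster_frequency)
        assert {k: v["support"] for k, v in n1.edges.items()} == {
            k: v["support"] for k, v in n2.edges.items()
        }

    def test_invalid_b_rejected(self, replicate_envs):
        with pytest.raises(ValueError):
            kn.bootstrap_support(replicate_envs, B=0, seed=1)

    def test_coupled_pair_coclusters_above_background(self, replicate_envs):
        """The reacting pair A-B shares a cluster more often than the
        unrelated feature C does with either."""
        net = kn.bootstrap_support(replicate_envs, B=10, seed=3, prescreen_k=2)
        fids = net.node_ids
        cc = net.cocluster_frequency
        iA, iB, iC = fids.index("A"), fids.index("B"), fids.index("C")
        assert cc[iA, iB] >= max(cc[iA, iC], cc[iB, iC])
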