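import numpy as np
import pandas as pd
import pytest

from addbn import (ABNSpec, DAG, Dataset, Family, NodeModel,
                   SearchConstraints, VariableSpec, build_score_cache,
                   exact_search, hill_climb, multivariable_search,
                   network_score, simulate)
from conftest import random_constraints, random_mixed_dataset
from oracles import best_network_by_enumeration, robinson_dag_count


class TestExactSearchOracle:
    def test_dag_count_matches_robinson(self):
        _, _, count = best_network_by_enumeration(
            _DummyCache(), ("a", "b", "c", "d"))
        assert count == robinson_dag_count(4) == 543

    @pytest.mark.parametrize("seed", range(5))
    def test_unconstrained_optimum_equals_brute_force(self, seed):
        ds = random_mixed_dataset(seed)
        cache = build_score_cache(ds)
        result = exact_search(cache)
        best, _, count = best_network_by_enumeration(cache, ds.names)
        assert count == 543
        assert result.score == pytest.approx(best, abs=1e-9)
        assert result.score == pytest.approx(network_score(result.dag, cache))

    @pytest.mark.parametrize("seed", range(5))
    def test_constrained_optimum_equals_brute_force(self, seed):
        ds = random_mixed_dataset(seed + 100)
        cons = random_constraints(seed, ds.names)
        cache = build_score_cache(ds, cons)
        result = exact_search(cache)
        best, _, _ = best_network_by_enumeration(cache, ds.names,
                                                 constraints=cons)
        assert result.score == pytest.approx(best, abs=1e-9)
        assert cons.satisfied_by(result.dag)

    def test_single_variable_returns_empty_dag(self):
        rng = np.random.default_rng(0)
        ds = Dataset(pd.DataFrame({"g1": rng.normal(size=30)}),
                     [VariableSpec("g1", Family.GAUSSIAN)])
        cache = build_score_cache(ds)
        result = exact_search(cache)
        assert result.dag.arcs == frozenset()
        assert result.score == pytest.approx(cache.score("g1", []))

    def test_chain_skeleton_recovered(self):
        dag = DAG(["a", "b", "c"], [("a", "b"), ("b", "c")])
        models = {
            "a": NodeModel("a", (), Family.GAUSSIAN, (0.0,), 1.0),
            "b": NodeModel("b", ("a",), Family.GAUSSIAN, (0.0, 1.0), 1.0),
            "c": NodeModel("c", ("b",), Family.GAUSSIAN, (0.0, 1.0), 1.0),
        }
        ds = simulate(ABNSpec(dag, models), 500, 42)
        cache = build_score_cache(ds)
        result = exact_search(cache)
        assert result.dag.skeleton() == {frozenset({"a", "b"}),
                                         frozenset({"b", "c"})}

    def test_variable_limit_refusal(self, six_node_data):
        cache = build_score_cache(six_node_data,
                                  SearchConstraints(max_parents=1))
        with pytest.raises(Exception, match="hill_climb"):
            exact_search(cache, limit=4)

    def test_deterministic_given_cache(self, six_node_data):
        cache = build_score_cache(six_node_data,
                                  SearchConstraints(max_parents=2))
        r1, r2 = exact_search(cache), exact_search(cache)
        assert r1.dag == r2.dag and r1.score == r2.score


class _DummyCache:
    """Score lookup that accepts everything — used only to count DAGs."""

    def score(self, child, parents):
        return 0.0


class TestMultivariableSearch:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_subset_enumeration(self, seed):
        ds = random_mixed_dataset(seed, V=4)
        response = "v1"
        result = multivariable_search(ds, response)
        cache = build_score_cache(ds)
        import itertools
        others = [x for x in ds.names if x != response]
        best = max(
            cache.score(response, s)
            for k in range(len(others) + 1)
            for s in itertools.combinations(others, k))
        best += sum(cache.score(x, []) for x in others)
        assert result.score == pytest.approx(best, abs=1e-9)
        # all arcs terminate at the response, everything else is parentless
        assert all(c == response for _, c in result.dag.arcs)

    @pytest.mark.parametrize("seed", range(4))
    def test_restriction_bound(self, seed):
        ds = random_mixed_dataset(seed + 50, V=4)
        unrestricted = exact_search(build_score_cache(ds))
        restricted = multivariable_search(ds, "v2")
        assert restricted.score <= unrestricted.score + 1e-9

    def test_pure_noise_selects_empty_parent_set(self):
        hits = 0
        for rep in range(25):
            rng = np.random.default_rng(900 + rep)
            frame = pd.DataFrame({f"g{i}": rng.normal(size=400) for i in range(4)})
            ds = Dataset(frame, [VariableSpec(f"g{i}", Family.GAUSSIAN)
                                 for i in range(4)])
            result = multivariable_search(ds, "g0")
            hits += int(result.dag.parents("g0") == frozenset())
        # the diffuse prior's complexity penalty should almost always pick ∅
        assert hits >= 24


class TestHillClimb:
    @pytest.mark.parametrize("seed", range(3))
    def test_bounded_by_and_usually_matching_exact(self, seed):
        ds = random_mixed_dataset(seed + 10, V=5, n=150)
        cache = build_score_cache(ds)
        exact = exact_search(cache)
        hc = hill_climb(cache, restarts=20, seed=seed)
        assert hc.score <= exact.score + 1e-9
        assert hc.score == pytest.approx(exact.score, abs=1e-6)

    def test_deterministic_given_seed(self, six_node_data):
        cache = build_score_cache(six_node_data,
                                  SearchConstraints(max_parents=2))
        r1 = hill_climb(cache, restarts=5, seed=3)
        r2 = hill_climb(cache, restarts=5, seed=3)
        assert r1.dag == r2.dag and r1.score == r2.score

    def test_respects_retained_arcs(self, six_node_data):
        cons = SearchConstraints(retained_arcs={("g1", "g4")}, max_parents=2)
        cache = build_score_cache(six_node_data, cons)
        result = hill_climb(cache, restarts=5, seed=0)
        assert ("g1", "g4") in result.dag.arcs


class TestStructureRecovery:
    def test_shd_decreases_with_sample_size(self):
        """Median skeleton distance to truth shrinks as n grows (scaled down)."""
        from addbn import random_dag
        from addbn.simulate import _random_models
        medians = []
        for n in (100, 400, 2000):
            shds = []
            for rep in range(10):
                rng = np.random.default_rng(5_000 + rep)
                names = ["b1", "b2", "b3", "g1", "g2", "g3", "g4", "g5"]
                fam = {x: (Family.BERNOULLI if x.startswith("b")
                           else Family.GAUSSIAN) for x in names}
                dag = random_dag(names, 8, rng, max_parents=3)
                models = _random_models(dag, fam, rng, (0.5, 1.0))
                ds = simulate(ABNSpec(dag, models), n, rng)
                cache = build_score_cache(ds, SearchConstraints(max_parents=3))
                learned = exact_search(cache).dag
                shds.append(len(dag.skeleton() ^ learned.skeleton()))
            medians.append(float(np.median(shds)))
        assert medians[0] >= medians[1] >= medians[2]
        assert medians[2] < medians[0]
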