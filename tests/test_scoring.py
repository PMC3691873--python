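import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from addbn import (DAG, Dataset, Family, PriorSpec, ScoreCache, ScoringError,
                   SearchConstraints, VariableSpec, build_score_cache,
                   compare_evidence, network_score, score_node)
from oracles import conjugate_gaussian_evidence, quadrature_bernoulli_evidence


def _gaussian_dataset(seed, n=200, slope=0.0):
    rng = np.random.default_rng(seed)
    g1 = rng.normal(size=n)
    g2 = slope * g1 + rng.normal(size=n)
    frame = pd.DataFrame({"g1": g1, "g2": g2})
    return Dataset(frame, [VariableSpec("g1", Family.GAUSSIAN),
                           VariableSpec("g2", Family.GAUSSIAN)])


def _bernoulli_dataset(seed, n=100, logor=0.8):
    rng = np.random.default_rng(seed)
    b1 = rng.binomial(1, 0.5, n).astype(float)
    p = 1.0 / (1.0 + np.exp(-(-0.2 + logor * b1)))
    b2 = rng.binomial(1, p).astype(float)
    if len(set(b1)) < 2 or len(set(b2)) < 2:  # pragma: no cover
        return _bernoulli_dataset(seed + 1000, n, logor)
    frame = pd.DataFrame({"b1": b1, "b2": b2})
    return Dataset(frame, [VariableSpec("b1", Family.BERNOULLI),
                           VariableSpec("b2", Family.BERNOULLI)])


class TestLaplaceAgainstOracles:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_gaussian_empty_parent_set_matches_conjugate_evidence(self, seed):
        ds = _gaussian_dataset(seed)
        score = score_node(ds, "g1", [])
        X = np.ones((ds.n, 1))
        exact = conjugate_gaussian_evidence(ds.column("g1"), X)
        assert abs(score - exact) < 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gaussian_with_parent_matches_conjugate_evidence(self, seed):
        ds = _gaussian_dataset(seed, slope=0.6)
        score = score_node(ds, "g2", ["g1"])
        X = np.column_stack([np.ones(ds.n), ds.column("g1")])
        exact = conjugate_gaussian_evidence(ds.column("g2"), X)
        assert abs(score - exact) < 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bernoulli_matches_quadrature(self, seed):
        ds = _bernoulli_dataset(seed)
        score = score_node(ds, "b2", ["b1"])
        X = np.column_stack([np.ones(ds.n), ds.column("b1")])
        oracle = quadrature_bernoulli_evidence(ds.column("b2"), X)
        assert abs(score - oracle) < 0.5

    def test_deterministic_repeat(self):
        ds = _bernoulli_dataset(5)
        assert score_node(ds, "b2", ["b1"]) == score_node(ds, "b2", ["b1"])

    @given(st.integers(0, 10_000))
    def test_row_permutation_leaves_scores_unchanged(self, seed):
        ds = _gaussian_dataset(17, n=80, slope=0.4)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(ds.n)
        shuffled = Dataset(ds.frame.iloc[perm].reset_index(drop=True), ds.specs)
        for parents in ([], ["g1"]):
            assert abs(score_node(ds, "g2", parents)
                       - score_node(shuffled, "g2", parents)) < 1e-8

    def test_approximate_likelihood_equivalence_two_gaussians(self):
        # a->b and b->a fit standardized bivariate-normal data equally well;
        # the direction gap must be negligible next to the dependence signal
        ds = _gaussian_dataset(23, n=300, slope=0.7).standardize()
        cache = build_score_cache(ds)
        fwd = network_score(DAG(ds.names, [("g1", "g2")]), cache)
        rev = network_score(DAG(ds.names, [("g2", "g1")]), cache)
        empty = network_score(DAG(ds.names), cache)
        assert abs(fwd - rev) < 0.05 * abs(fwd - empty)
        assert fwd - empty > 10  # the dependence itself is decisive


class TestScoringErrors:
    def test_collinear_parents_flagged(self):
        rng = np.random.default_rng(3)
        g1 = rng.normal(size=50)
        frame = pd.DataFrame({"g1": g1, "g2": 2.0 * g1, "g3": rng.normal(size=50)})
        ds = Dataset(frame, [VariableSpec(n, Family.GAUSSIAN) for n in frame])
        with pytest.raises(ScoringError, match="collinear"):
            score_node(ds, "g3", ["g1", "g2"])

    def test_child_cannot_be_own_parent(self, tiny_mixed_dataset):
        with pytest.raises(Exception, match="own parent"):
            score_node(tiny_mixed_dataset, "g1", ["g1"])


class TestScoreCache:
    def test_counting_three_nodes(self, tiny_mixed_dataset):
        cache = build_score_cache(tiny_mixed_dataset,
                                  SearchConstraints(max_parents=2))
        assert len(cache) == 12  # 3 children x (1 + 2 + 1) parent sets

    def test_counting_max_parents_one(self, six_node_data):
        cache = build_score_cache(six_node_data, SearchConstraints(max_parents=1))
        assert len(cache) == 6 * 6  # empty set + 5 single parents, per child

    def test_banned_arc_excluded_from_keys(self, tiny_mixed_dataset):
        cons = SearchConstraints(banned_arcs={("g1", "b1")})
        cache = build_score_cache(tiny_mixed_dataset, cons)
        assert all("g1" not in ps for (c, ps) in cache.entries() if c == "b1")
        assert ("b1", frozenset()) in cache.entries()

    def test_cache_cap_refusal(self, six_node_data):
        with pytest.raises(Exception, match="cap"):
            build_score_cache(six_node_data, cache_cap=10)

    def test_csv_round_trip(self, tiny_mixed_dataset, tmp_path):
        cache = build_score_cache(tiny_mixed_dataset)
        path = tmp_path / "cache.csv"
        cache.write_csv(path)
        families = {s.name: s.family for s in tiny_mixed_dataset.specs}
        back = ScoreCache.read_csv(path, tiny_mixed_dataset.names, families)
        for key, val in cache.entries().items():
            assert back.score(*key) == pytest.approx(val, abs=1e-9)


class TestNetworkScore:
    def test_additivity_empty_and_single_arc(self, tiny_mixed_dataset):
        ds = tiny_mixed_dataset
        cache = build_score_cache(ds)
        empty = network_score(DAG(ds.names), cache)
        assert empty == pytest.approx(
            sum(cache.score(c, []) for c in ds.names))
        dag = DAG(ds.names, [("g1", "g2")])
        assert network_score(dag, cache) == pytest.approx(
            cache.score("g1", []) + cache.score("b1", [])
            + cache.score("g2", ["g1"]))

    def test_matches_recomputation_without_cache(self, tiny_mixed_dataset):
        ds = tiny_mixed_dataset
        cache = build_score_cache(ds)
        dag = DAG(ds.names, [("g1", "b1"), ("g1", "g2")])
        direct = sum(score_node(ds, c, dag.parents(c)) for c in ds.names)
        assert network_score(dag, cache) == pytest.approx(direct, abs=1e-9)

    def test_missing_entry_is_contract_error(self, tiny_mixed_dataset):
        cache = build_score_cache(tiny_mixed_dataset,
                                  SearchConstraints(max_parents=1))
        dag = DAG(tiny_mixed_dataset.names, [("g1", "g2"), ("b1", "g2")])
        with pytest.raises(KeyError):
            network_score(dag, cache)


class TestCompareEvidence:
    def test_worked_contrast_very_strong(self):
        report = compare_evidence(-8311.6, -8664.4)
        assert report.difference == pytest.approx(352.8)
        assert report.category == "very strong"
        assert report.favoured == 1

    def test_tie_is_none(self):
        report = compare_evidence(-100.0, -100.0)
        assert report.difference == 0.0 and report.category == "none"
        assert report.favoured is None

    def test_difference_five_weaker_than_very_strong(self):
        report = compare_evidence(-100.0, -105.0)
        assert report.difference == pytest.approx(5.0)
        assert report.category != "very strong"

    def test_threshold_boundary(self):
        assert compare_evidence(0.0, -10.0).category != "very strong"
        assert compare_evidence(0.0, -10.001).category == "very strong"
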