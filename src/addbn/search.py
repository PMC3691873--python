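"""Structure search: exact globally-optimal DAG learning and heuristic hill climbing.

The exact engine uses the best-sink decomposition over node subsets: for any
subset W of variables, the best DAG on W ends in some sink s (a node with no
children inside W), so

    best(W) = max_{s ∈ W} [ bestparents(s, W ∖ {s}) + best(W ∖ {s}) ],

where bestparents(s, C) is the best node score of s over admissible parent
sets drawn from C.  ``bestparents`` is a subset-max (zeta) transform of the
score cache, computed with vectorised bit-mask passes; the sink recursion then
runs over all 2^V subsets.  The result is the global maximum of the network
score over every DAG admissible under the cache's constraints.

Restricting all arcs to terminate at a single response collapses the search
to best-subset selection for one generalised linear model — classical
multivariable regression selection by marginal likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
import numpy as np

from .constraints import SearchConstraints
from .data_io import DAG, ConfigurationError, Dataset
from .scoring import PriorSpec, ScoreCache, build_score_cache, network_score

logger = logging.getLogger(__name__)

__all__ = ["SearchConstraints", "SearchResult", "exact_search",
           "multivariable_search", "hill_climb", "EXACT_SEARCH_LIMIT"]

EXACT_SEARCH_LIMIT = 20  # exact search is exponential in V; heuristics beyond


@dataclass
class SearchResult:
    """A learned DAG with its score and search diagnostics."""

    dag: DAG
    score: float
    mode: str                      # "exact" or "hill-climb"
    diagnostics: dict = field(default_factory=dict)


def _check_result(dag: DAG, constraints: SearchConstraints) -> None:
    assert dag.is_acyclic(), "search returned a cyclic graph"
    assert constraints.satisfied_by(dag), "search violated its constraints"


# ---------------------------------------------------------------------------
# Exact search
# ---------------------------------------------------------------------------

def _candidate_masks(cache: ScoreCache):
    """Per child: (others tuple, score array over 2^(V-1) candidate masks)."""
    nodes = cache.nodes
    index = {n: i for i, n in enumerate(nodes)}
    per_child = {}
    for child in nodes:
        others = tuple(n for n in nodes if n != child)
        bit_of = {n: i for i, n in enumerate(others)}
        size = 1 << len(others)
        direct = np.full(size, -np.inf)
        sets_by_mask: dict[int, frozenset] = {}
        for parents, score in cache.parent_sets(child):
            mask = 0
            for p in parents:
                mask |= 1 << bit_of[p]
            direct[mask] = score
            sets_by_mask[mask] = parents
        per_child[child] = (others, direct, sets_by_mask)
    return index, per_child


def _subset_max(direct: np.ndarray, nbits: int) -> np.ndarray:
    """best[S] = max over T ⊆ S of direct[T], via nbits vectorised passes."""
    best = direct.copy()
    for i in range(nbits):
        shaped = best.reshape(-1, 2, 1 << i)
        np.maximum(shaped[:, 1, :], shaped[:, 0, :], out=shaped[:, 1, :])
    return best


def _reconstruct_parents(direct: np.ndarray, sets_by_mask: dict, mask: int,
                         target: float):
    """Among admissible parent sets within ``mask`` achieving ``target``,
    pick the fewest-arcs, lexicographically-smallest one (deterministic
    tie-break)."""
    best = None
    for m, parents in sets_by_mask.items():
        if (m & ~mask) == 0 and direct[m] == target:
            key = (len(parents), tuple(sorted(parents)))
            if best is None or key < best[0]:
                best = (key, parents)
    if best is None:  # numerical guard: fall back to the best within mask
        cand = [(direct[m], -len(p), tuple(sorted(p)), p)
                for m, p in sets_by_mask.items() if (m & ~mask) == 0]
        if not cand:
            raise ConfigurationError("no admissible parent set within subset")
        best = (None, max(cand)[3])
    return best[1]


def exact_search(cache: ScoreCache, *, limit: int = EXACT_SEARCH_LIMIT) -> SearchResult:
    """Find the DAG with globally maximal network score under the cache's constraints.

    Deterministic: among equal-scoring optima the result prefers fewer arcs,
    then lexicographically smallest parent sets.
    """
    nodes = cache.nodes
    V = len(nodes)
    if V > limit:
        raise ConfigurationError(
            f"{V} variables exceeds the exact-search limit ({limit}); "
            "use hill_climb for larger problems")
    index, per_child = _candidate_masks(cache)

    # bestparents via subset-max transform, per child over its V-1 others
    bps = {}
    for child in nodes:
        others, direct, sets_by_mask = per_child[child]
        bps[child] = _subset_max(direct, len(others))

    # project a V-bit subset (child removed) onto the child's (V-1)-bit space
    def project(mask: int, child_idx: int) -> int:
        low = mask & ((1 << child_idx) - 1)
        high = (mask >> (child_idx + 1)) << child_idx
        return low | high

    full = (1 << V) - 1
    best = np.full(1 << V, -np.inf)
    best[0] = 0.0
    best_sink = np.full(1 << V, -1, dtype=np.int32)
    bps_arr = [bps[n] for n in nodes]
    for w in range(1, full + 1):
        b = -np.inf
        sink = -1
        m = w
        while m:
            s_bit = m & -m
            s = s_bit.bit_length() - 1
            m ^= s_bit
            prev = best[w ^ s_bit]
            if prev == -np.inf:
                continue
            val = prev + bps_arr[s][project(w ^ s_bit, s)]
            if val > b:
                b, sink = val, s
        best[w] = b
        best_sink[w] = sink

    if not np.isfinite(best[full]):
        raise ConfigurationError(
            "no admissible DAG exists under the given constraints")

    # reconstruct: peel sinks, then pick each sink's parent set within the
    # remaining subset with the deterministic tie-break
    dag = DAG(nodes)
    w = full
    while w:
        s = int(best_sink[w])
        if s < 0:  # ties resolved by smallest index during the forward pass
            raise ConfigurationError("reconstruction failed")
        rest = w ^ (1 << s)
        child = nodes[s]
        others, direct, sets_by_mask = per_child[child]
        pmask = project(rest, s)
        target = bps_arr[s][pmask]
        parents = _reconstruct_parents(direct, sets_by_mask, pmask, target)
        for p in parents:
            dag.add_arc(p, child)
        w = rest

    score = network_score(dag, cache)
    result = SearchResult(dag, score, "exact",
                          {"subsets_evaluated": 1 << V, "variables": V})
    _check_result(dag, cache.constraints)
    return result


# ---------------------------------------------------------------------------
# Multivariable (single-response) search
# ---------------------------------------------------------------------------

def multivariable_search(source: ScoreCache | Dataset, response: str, *,
                         constraints: SearchConstraints | None = None,
                         prior: PriorSpec | None = None) -> SearchResult:
    """Exact search restricted to arcs terminating at ``response``.

    Accepts either a dataset (a response-restricted cache is built) or an
    existing cache whose constraints already carry the restriction.  The
    optimum has arcs only into the response — best-subset GLM selection by
    marginal likelihood — and every other node parentless.
    """
    if isinstance(source, Dataset):
        base = constraints or SearchConstraints()
        restricted = SearchConstraints(
            banned_arcs=base.banned_arcs,
            retained_arcs=frozenset(a for a in base.retained_arcs
                                    if a[1] == response),
            max_parents=base.max_parents,
            response_restriction=response)
        cache = build_score_cache(source, restricted, prior)
    else:
        cache = source
        if cache.constraints.response_restriction != response:
            raise ConfigurationError(
                "cache was not built under the matching response restriction")
    if response not in cache.nodes:
        raise ConfigurationError(f"unknown response {response!r}")

    best_parents, best_score = None, -math.inf
    for parents, score in cache.parent_sets(response):
        tie_key = (len(parents), tuple(sorted(parents)))
        if (score > best_score
                or (score == best_score
                    and tie_key < (len(best_parents), tuple(sorted(best_parents))))):
            best_parents, best_score = parents, score
    if best_parents is None:
        raise ConfigurationError(f"no admissible parent set for {response!r}")

    dag = DAG(cache.nodes, [(p, response) for p in best_parents])
    score = network_score(dag, cache)
    result = SearchResult(dag, score, "exact",
                          {"response": response,
                           "parent_sets_examined": len(cache.parent_sets(response))})
    _check_result(dag, cache.constraints)
    return result


# ---------------------------------------------------------------------------
# Hill climbing
# ---------------------------------------------------------------------------

def _random_start(cache: ScoreCache, rng: np.random.Generator) -> DAG:
    nodes = list(cache.nodes)
    constraints = cache.constraints
    order = list(rng.permutation(nodes))
    dag = DAG(cache.nodes, constraints.retained_arcs)
    p_inc = 2.0 / max(len(nodes), 2)
    maxp = constraints.max_parents
    for i, child in enumerate(order):
        for parent in order[:i]:
            if not constraints.arc_admissible(parent, child):
                continue
            if (parent, child) in dag.arcs:
                continue
            if maxp is not None and len(dag.parents(child)) >= maxp:
                break
            if rng.random() < p_inc:
                try:
                    dag.add_arc(parent, child)
                except Exception:
                    pass
    return dag


def hill_climb(cache: ScoreCache, restarts: int = 100,
               seed: int | np.random.Generator = 0) -> SearchResult:
    """Greedy local search with random restarts.

    From each random admissible start, repeatedly apply the single-arc
    addition, deletion or reversal that most improves the network score while
    preserving acyclicity and constraints, until no move improves; the best
    DAG across restarts is returned.  Reproducible given the seed.
    """
    if restarts < 1:
        raise ConfigurationError("restarts must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    constraints = cache.constraints
    maxp = constraints.max_parents

    def node_score(child, parents):
        try:
            return cache.score(child, parents)
        except (KeyError, RuntimeError):
            return None

    best_dag, best_score = None, -math.inf
    total_moves = 0
    for _ in range(restarts):
        dag = _random_start(cache, rng)
        scores = {n: node_score(n, dag.parents(n)) for n in dag.nodes}
        if any(s is None for s in scores.values()):
            continue
        improved = True
        while improved:
            improved = False
            best_move, best_gain = None, 1e-10
            arcs = sorted(dag.arcs)
            non_arcs = sorted((p, c) for p in dag.nodes for c in dag.nodes
                              if p != c and (p, c) not in dag.arcs
                              and constraints.arc_admissible(p, c))
            # additions
            for p, c in non_arcs:
                newp = dag.parents(c) | {p}
                if maxp is not None and len(newp) > maxp:
                    continue
                s = node_score(c, newp)
                if s is None:
                    continue
                gain = s - scores[c]
                if gain > best_gain:
                    cand = dag.copy()
                    try:
                        cand.add_arc(p, c)
                    except Exception:
                        continue
                    best_move, best_gain = ("add", p, c, cand), gain
            # deletions
            for p, c in arcs:
                if (p, c) in constraints.retained_arcs:
                    continue
                s = node_score(c, dag.parents(c) - {p})
                if s is None:
                    continue
                gain = s - scores[c]
                if gain > best_gain:
                    cand = dag.copy()
                    cand.remove_arc(p, c)
                    best_move, best_gain = ("del", p, c, cand), gain
            # reversals
            for p, c in arcs:
                if (p, c) in constraints.retained_arcs:
                    continue
                if not constraints.arc_admissible(c, p):
                    continue
                newp_p = dag.parents(p) | {c}
                if maxp is not None and len(newp_p) > maxp:
                    continue
                s_c = node_score(c, dag.parents(c) - {p})
                s_p = node_score(p, newp_p)
                if s_c is None or s_p is None:
                    continue
                gain = (s_c - scores[c]) + (s_p - scores[p])
                if gain > best_gain:
                    cand = dag.copy()
                    cand.remove_arc(p, c)
                    try:
                        cand.add_arc(c, p)
                    except Exception:
                        continue
                    best_move, best_gain = ("rev", p, c, cand), gain
            if best_move is not None:
                _, p, c, dag = best_move
                scores = {n: node_score(n, dag.parents(n)) for n in dag.nodes}
                total_moves += 1
                improved = True
        total = sum(scores.values())
        if total > best_score:
            best_dag, best_score = dag, total

    if best_dag is None:
        raise ConfigurationError("no admissible starting DAG could be scored")
    result = SearchResult(best_dag, best_score, "hill-climb",
                          {"restarts": restarts, "moves": total_moves})
    _check_result(best_dag, constraints)
    return result
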