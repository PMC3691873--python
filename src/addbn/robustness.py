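"""Over-fitting guards: parametric bootstrap pruning and majority-consensus graphs.

Model selection by maximum marginal likelihood will, on finite data, admit
some arcs that reflect noise rather than signal.  Two complementary guards:

* **Parametric bootstrap** — simulate replicate datasets from the model
  fitted under the chosen best DAG, re-learn structure on each replicate, and
  keep only arcs recovered in a sufficient fraction of replicates.  Recovery
  is tallied direction-blind by default because arc orientation is generally
  not identifiable from observational data (likelihood equivalence).
* **Majority consensus** — across repeated heuristic searches, keep the arcs
  appearing in more than a stated fraction of results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .constraints import SearchConstraints
from .data_io import DAG, ConfigurationError, Dataset, ValidationError
from .scoring import PriorSpec, build_score_cache, fit_node
from .search import SearchResult, exact_search, hill_climb
from .simulate import ABNSpec, simulate

logger = logging.getLogger(__name__)

__all__ = ["ArcFrequencyTable", "ConsensusResult", "parametric_bootstrap",
           "majority_consensus"]


@dataclass
class ArcFrequencyTable:
    """Per-arc support counts across replicate search results."""

    counts: dict[tuple[str, str], int]
    replicates: int

    def __post_init__(self):
        for arc, c in self.counts.items():
            if not 0 <= c <= self.replicates:
                raise ValueError(f"count for {arc} outside [0, R]")

    def fraction(self, arc: tuple[str, str]) -> float:
        return self.counts.get(arc, 0) / self.replicates

    def to_frame(self) -> pd.DataFrame:
        rows = [{"parent": p, "child": c, "count": n,
                 "fraction": n / self.replicates}
                for (p, c), n in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["parent", "child", "count", "fraction"])


def _fit_generative_model(data: Dataset, dag: DAG, prior: PriorSpec) -> ABNSpec:
    models = {}
    for node in dag.nodes:
        fit = fit_node(data, node, dag.parents(node), prior)
        models[node] = fit.to_node_model()
    return ABNSpec(dag, models)


def parametric_bootstrap(data: Dataset, best_dag: DAG, B: int,
                         seed: int = 0, threshold: float = 0.5, *,
                         constraints: SearchConstraints | None = None,
                         prior: PriorSpec | None = None,
                         direction_blind: bool = True,
                         search_mode: str = "exact",
                         restarts: int = 20) -> tuple[DAG, ArcFrequencyTable]:
    """Prune arcs of ``best_dag`` that are not recovered across bootstrap replicates.

    The node models of ``best_dag`` are fitted on ``data`` (posterior modes);
    ``B`` replicate datasets of the same n are simulated from that fitted
    model, the original structure search is re-run on each, and each arc of
    ``best_dag`` is tallied as recovered when the replicate's learned graph
    contains it — as an undirected adjacency when ``direction_blind`` (the
    default, since orientation is not identifiable), or exactly when not.
    Arcs with recovery fraction < ``threshold`` are removed.  Reproducible
    given the seed; replicates are seeded independently from the master seed
    so results do not depend on execution order.
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    if not 0.0 < threshold <= 1.0:
        raise ConfigurationError("threshold must lie in (0, 1]")
    constraints = constraints or SearchConstraints()
    prior = prior or PriorSpec()
    generative = _fit_generative_model(data, best_dag, prior)

    child_seeds = np.random.SeedSequence(seed).spawn(B)
    counts = {arc: 0 for arc in best_dag.arcs}
    skipped = 0
    for b in range(B):
        rng = np.random.default_rng(child_seeds[b])
        try:
            replicate = simulate(generative, data.n, rng)
            cache = build_score_cache(replicate, constraints, prior)
            if search_mode == "exact":
                result = exact_search(cache)
            else:
                result = hill_climb(cache, restarts=restarts, seed=rng)
        except (ValidationError, ConfigurationError, RuntimeError) as exc:
            skipped += 1
            logger.warning("bootstrap replicate %d skipped: %s", b, exc)
            continue
        learned = result.dag
        skel = learned.skeleton()
        for arc in counts:
            hit = (frozenset(arc) in skel) if direction_blind else (arc in learned.arcs)
            counts[arc] += int(hit)
    if skipped > 0.1 * B:
        raise RuntimeError(f"{skipped} of {B} bootstrap replicates failed")

    done = B - skipped
    table = ArcFrequencyTable(counts, done)
    pruned = DAG(best_dag.nodes,
                 [arc for arc in best_dag.arcs if table.fraction(arc) >= threshold])
    return pruned, table


@dataclass
class ConsensusResult:
    """Majority-consensus graph with its arc-frequency table.

    The consensus arc set can be cyclic in pathological cases; it is flagged
    (``is_acyclic``) with a suggested minimal set of lowest-support arcs to
    drop, never repaired silently.
    """

    arcs: frozenset[tuple[str, str]]
    table: ArcFrequencyTable
    nodes: tuple[str, ...]
    is_acyclic: bool
    suggested_removals: frozenset[tuple[str, str]] = frozenset()

    def as_dag(self) -> DAG:
        if not self.is_acyclic:
            raise ValidationError(
                "consensus graph is cyclic; inspect suggested_removals")
        return DAG(self.nodes, self.arcs)


def majority_consensus(dags: Sequence[DAG],
                       threshold: float = 0.5) -> ConsensusResult:
    """Arcs appearing in strictly more than ``threshold`` of the input DAGs.

    Ties at exactly the threshold are excluded (strict majority), which keeps
    the result deterministic for an even number of inputs.
    """
    if not dags:
        raise ConfigurationError("need at least one DAG")
    nodes = dags[0].nodes
    node_set = set(nodes)
    for d in dags[1:]:
        if set(d.nodes) != node_set:
            raise ConfigurationError("all DAGs must share one node set")
    counts: dict[tuple[str, str], int] = {}
    for d in dags:
        for arc in d.arcs:
            counts[arc] = counts.get(arc, 0) + 1
    table = ArcFrequencyTable(counts, len(dags))
    kept = frozenset(arc for arc, c in counts.items()
                     if c / len(dags) > threshold)

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(kept)
    acyclic = nx.is_directed_acyclic_graph(g)
    removals: set[tuple[str, str]] = set()
    if not acyclic:
        logger.warning("consensus graph is cyclic; suggesting feedback arcs "
                       "to remove (not applied)")
        h = g.copy()
        while not nx.is_directed_acyclic_graph(h):
            cycle = nx.find_cycle(h)
            weakest = min(cycle, key=lambda e: (counts[(e[0], e[1])], e))
            removals.add((weakest[0], weakest[1]))
            h.remove_edge(weakest[0], weakest[1])
    return ConsensusResult(kept, table, nodes, acyclic, frozenset(removals))
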