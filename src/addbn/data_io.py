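"""Typed datasets, DAG containers, and readers/writers for standard graph formats.

A study dataset is a rectangular table (one row per subject, one column per
variable) in which every variable belongs to exactly one of two families:
continuous (modelled as Gaussian) or binary (modelled as Bernoulli, coded
strictly 0/1).  The directed acyclic graph (DAG) is the structural hypothesis
over those variables; arcs denote statistical dependency, never causality.
"""

from __future__ import annotations

import enum
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Family",
    "VariableSpec",
    "Dataset",
    "DAG",
    "ValidationError",
    "ConfigurationError",
    "read_dataset",
    "read_distribution_spec",
    "write_dag",
    "read_dag_adjacency",
]


class ValidationError(ValueError):
    """Raised when data violate the declared variable families."""


class ConfigurationError(ValueError):
    """Raised when the inputs are inconsistently declared."""


class Family(str, enum.Enum):
    """Node family: the conditional distribution attached to a variable."""

    GAUSSIAN = "gaussian"
    BERNOULLI = "binary"

    @classmethod
    def parse(cls, text: str) -> "Family":
        t = str(text).strip().lower()
        if t in {"gaussian", "continuous", "normal", "continuous-gaussian"}:
            return cls.GAUSSIAN
        if t in {"binary", "bernoulli", "binomial", "binary-bernoulli"}:
            return cls.BERNOULLI
        raise ConfigurationError(f"unknown variable family: {text!r}")


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one variable: its name and distributional family."""

    name: str
    family: Family


class Dataset:
    """A validated, complete-case observation matrix with typed columns.

    Parameters
    ----------
    frame:
        Observations, one row per subject.  Must already be complete-case.
    specs:
        One :class:`VariableSpec` per column, in column order.
    standardized:
        Whether continuous columns have been centred and scaled to unit
        variance.  Recorded so downstream reports can state the scale
        coefficients are on.
    """

    def __init__(self, frame: pd.DataFrame, specs: Sequence[VariableSpec], *,
                 standardized: bool = False):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate variable names in spec")
        if list(frame.columns) != names:
            frame = frame[names]
        if frame.isna().any().any():
            raise ValidationError("Dataset requires complete cases; drop missing rows first")
        self._frame = frame.reset_index(drop=True).astype(float)
        self.specs = tuple(specs)
        self.standardized = standardized
        self._validate()
        if self.n < self.n_variables:
            logger.warning("fewer observations (%d) than variables (%d); "
                           "scores will be prior-dominated", self.n, self.n_variables)

    def _validate(self) -> None:
        for s in self.specs:
            col = self._frame[s.name].to_numpy()
            if s.family is Family.BERNOULLI:
                levels = set(np.unique(col))
                if not levels <= {0.0, 1.0}:
                    raise ValidationError(
                        f"binary variable {s.name!r} contains values outside {{0,1}}")
                if len(levels) < 2:
                    raise ValidationError(
                        f"binary variable {s.name!r} has a single level")
            else:
                if col.std() == 0.0:
                    raise ValidationError(
                        f"continuous variable {s.name!r} has zero variance")

    # -- basic accessors ---------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    @property
    def n(self) -> int:
        return len(self._frame)

    @property
    def n_variables(self) -> int:
        return len(self.specs)

    def family(self, name: str) -> Family:
        for s in self.specs:
            if s.name == name:
                return s.family
        raise KeyError(name)

    def column(self, name: str) -> np.ndarray:
        return self._frame[name].to_numpy()

    def fingerprint(self) -> str:
        """Stable hash of the values and declarations, for cache provenance."""
        h = hashlib.sha256()
        h.update(",".join(f"{s.name}:{s.family.value}" for s in self.specs).encode())
        h.update(np.ascontiguousarray(self._frame.to_numpy()).tobytes())
        return h.hexdigest()[:16]

    def standardize(self) -> "Dataset":
        """Centre and scale continuous columns to unit variance.

        Binary columns are left on the 0/1 scale so intercepts stay
        interpretable as baseline log odds.
        """
        if self.standardized:
            return self
        frame = self._frame.copy()
        for s in self.specs:
            if s.family is Family.GAUSSIAN:
                col = frame[s.name]
                frame[s.name] = (col - col.mean()) / col.std(ddof=0)
        return Dataset(frame, self.specs, standardized=True)

    def __repr__(self) -> str:  # pragma: no cover
        nb = sum(s.family is Family.BERNOULLI for s in self.specs)
        return (f"Dataset(n={self.n}, variables={self.n_variables} "
                f"[{nb} binary, {self.n_variables - nb} continuous])")


class DAG:
    """A directed acyclic graph over named variables.

    Acyclicity is enforced on construction and after every mutation; violating
    it raises :class:`ValidationError` and leaves the graph unchanged.
    """

    def __init__(self, nodes: Iterable[str], arcs: Iterable[tuple[str, str]] = ()):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ConfigurationError("duplicate node names")
        self._arcs: set[tuple[str, str]] = set()
        for parent, child in arcs:
            self.add_arc(parent, child)

    # -- mutation ----------------------------------------------------------
    def add_arc(self, parent: str, child: str) -> None:
        if parent not in self.nodes or child not in self.nodes:
            raise ConfigurationError(f"arc ({parent!r}, {child!r}) uses undeclared node")
        if parent == child:
            raise ValidationError(f"self-arc on {parent!r}")
        self._arcs.add((parent, child))
        if not self.is_acyclic():
            self._arcs.discard((parent, child))
            raise ValidationError(f"arc ({parent!r}, {child!r}) would create a cycle")

    def remove_arc(self, parent: str, child: str) -> None:
        self._arcs.discard((parent, child))

    # -- queries -----------------------------------------------------------
    @property
    def arcs(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._arcs)

    def parents(self, node: str) -> frozenset[str]:
        if node not in self.nodes:
            raise KeyError(node)
        return frozenset(p for p, c in self._arcs if c == node)

    def children(self, node: str) -> frozenset[str]:
        if node not in self.nodes:
            raise KeyError(node)
        return frozenset(c for p, c in self._arcs if p == node)

    def skeleton(self) -> frozenset[frozenset[str]]:
        """Undirected version of the arc set."""
        return frozenset(frozenset(a) for a in self._arcs)

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def topological_order(self) -> list[str]:
        # lexicographic tie-break keeps orderings reproducible
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self._arcs)
        return g

    def copy(self) -> "DAG":
        return DAG(self.nodes, self._arcs)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, DAG) and set(self.nodes) == set(other.nodes)
                and self._arcs == other._arcs)

    def __hash__(self) -> int:
        return hash((frozenset(self.nodes), frozenset(self._arcs)))

    def __repr__(self) -> str:  # pragma: no cover
        return f"DAG({len(self.nodes)} nodes, {len(self._arcs)} arcs)"


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_distribution_spec(spec_path: str | Path) -> dict[str, Family]:
    """Read a `{column: family}` map from a YAML/JSON file."""
    with open(spec_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigurationError("distribution spec must be a mapping {column: family}")
    return {str(k): Family.parse(v) for k, v in raw.items()}


def read_dataset(data_path: str | Path, spec_path: str | Path | None = None, *,
                 families: Mapping[str, Family | str] | None = None,
                 standardize: bool = True) -> Dataset:
    """Read a delimited study table, drop incomplete rows, and validate.

    Exactly one of ``spec_path`` and ``families`` must be given.  Missing
    cells are empty strings or ``"."``.  Rows with any missing value are
    dropped (complete-case analysis) and the count is logged.  Binary columns
    must be coded 0/1 — text codings such as yes/no are rejected rather than
    silently coerced, because miscoded epidemiological covariates should fail
    loudly.
    """
    if (spec_path is None) == (families is None):
        raise ConfigurationError("provide exactly one of spec_path or families")
    fam = (read_distribution_spec(spec_path) if spec_path is not None
           else {k: Family.parse(v) if not isinstance(v, Family) else v
                 for k, v in families.items()})

    frame = pd.read_csv(data_path, na_values=["."], keep_default_na=True)
    undeclared = [c for c in frame.columns if c not in fam]
    if undeclared:
        raise ConfigurationError(f"columns without a declared family: {undeclared}")
    absent = [c for c in fam if c not in frame.columns]
    if absent:
        raise ConfigurationError(f"declared columns absent from data: {absent}")

    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise ValidationError(
                f"column {col!r} is not numeric; binary variables must be coded 0/1")

    n_before = len(frame)
    frame = frame.dropna()
    dropped = n_before - len(frame)
    if dropped:
        logger.info("dropped %d incomplete row(s) of %d (complete-case rule)",
                    dropped, n_before)

    specs = [VariableSpec(c, fam[c]) for c in frame.columns]
    ds = Dataset(frame, specs)
    return ds.standardize() if standardize else ds


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_DOT_SHAPE = {Family.BERNOULLI: "box", Family.GAUSSIAN: "ellipse"}


def write_dag(dag: DAG, path: str | Path, fmt: str = "dot", *,
              families: Mapping[str, Family] | None = None) -> None:
    """Write a DAG as Graphviz DOT, GraphML, or a 0/1 adjacency-matrix CSV.

    In DOT output binary nodes are drawn as boxes and continuous nodes as
    ovals (the usual convention in graphical risk-factor models).  The
    adjacency CSV has one row per parent and one column per child.
    """
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "dot":
        lines = ["digraph abn {"]
        for node in dag.nodes:
            shape = _DOT_SHAPE.get(families[node], "ellipse") if families else "ellipse"
            lines.append(f'  "{node}" [shape={shape}];')
        for parent, child in sorted(dag.arcs):
            lines.append(f'  "{parent}" -> "{child}";')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "graphml":
        g = dag.to_networkx()
        if families:
            nx.set_node_attributes(
                g, {n: families[n].value for n in dag.nodes}, "family")
        nx.write_graphml(g, path)
    elif fmt in {"csv", "adjacency", "adjacency-csv"}:
        mat = pd.DataFrame(0, index=list(dag.nodes), columns=list(dag.nodes), dtype=int)
        for parent, child in dag.arcs:
            mat.loc[parent, child] = 1
        mat.to_csv(path, index_label="")
    else:
        raise ConfigurationError(f"unknown graph format {fmt!r}")


def read_dag_adjacency(path: str | Path) -> DAG:
    """Read a DAG from an adjacency-matrix CSV written by :func:`write_dag`."""
    mat = pd.read_csv(path, index_col=0)
    nodes = [str(c) for c in mat.columns]
    arcs = [(str(p), str(c)) for p in mat.index for c in mat.columns
            if int(mat.loc[p, c]) == 1]
    return DAG(nodes, arcs)
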