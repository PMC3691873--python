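"""Structure-search constraints: banned/retained arcs, parent limits, response mode."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .data_io import DAG, ConfigurationError

__all__ = ["SearchConstraints"]


@dataclass(frozen=True)
class SearchConstraints:
    """Restrictions on the admissible DAG space.

    ``response_restriction`` limits the search to graphs whose arcs all
    terminate at one named response — structure discovery then reduces
    exactly to best-subset selection for a single generalised linear model,
    i.e. classical multivariable regression.
    """

    banned_arcs: frozenset[tuple[str, str]] = frozenset()
    retained_arcs: frozenset[tuple[str, str]] = frozenset()
    max_parents: Optional[int] = None
    response_restriction: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "banned_arcs", frozenset(self.banned_arcs))
        object.__setattr__(self, "retained_arcs", frozenset(self.retained_arcs))
        if self.banned_arcs & self.retained_arcs:
            raise ConfigurationError("an arc cannot be both banned and retained")
        if self.max_parents is not None and self.max_parents < 0:
            raise ConfigurationError("max_parents must be non-negative")
        if self.response_restriction is not None:
            bad = [a for a in self.retained_arcs if a[1] != self.response_restriction]
            if bad:
                raise ConfigurationError(
                    f"retained arcs {bad} do not terminate at the response")

    def validate_against(self, nodes: tuple[str, ...]) -> None:
        """Check that every referenced variable is declared and retained arcs are jointly acyclic."""
        declared = set(nodes)
        for arc_set in (self.banned_arcs, self.retained_arcs):
            for parent, child in arc_set:
                if parent not in declared or child not in declared:
                    raise ConfigurationError(
                        f"constraint arc ({parent!r}, {child!r}) uses undeclared node")
        if self.response_restriction is not None and self.response_restriction not in declared:
            raise ConfigurationError(
                f"response {self.response_restriction!r} is not a declared variable")
        # jointly acyclic and individually admissible
        DAG(nodes, self.retained_arcs)
        for arc in self.retained_arcs:
            if not self.arc_admissible(*arc):
                raise ConfigurationError(f"retained arc {arc} is not admissible")

    def arc_admissible(self, parent: str, child: str) -> bool:
        if parent == child or (parent, child) in self.banned_arcs:
            return False
        if (self.response_restriction is not None
                and child != self.response_restriction):
            return False
        return True

    def allowed_parents(self, child: str, nodes: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(p for p in nodes if self.arc_admissible(p, child))

    def retained_parents(self, child: str) -> frozenset[str]:
        return frozenset(p for p, c in self.retained_arcs if c == child)

    def effective_max_parents(self, n_candidates: int) -> int:
        if self.max_parents is None:
            return n_candidates
        return min(self.max_parents, n_candidates)

    def satisfied_by(self, dag: DAG) -> bool:
        if not self.retained_arcs <= dag.arcs:
            return False
        for parent, child in dag.arcs:
            if not self.arc_admissible(parent, child):
                return False
            if (self.max_parents is not None
                    and len(dag.parents(child)) > self.max_parents):
                return False
        return True
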