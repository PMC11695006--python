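"""Dependency graph over the named quantities of a model.

Nodes are determined parameters, algebraic variables, state-derivative
definitions and initial-condition definitions; an edge u -> v means "the
definition of u references v".  Evaluation order for the closed-form
quantities (determined parameters, algebraic variables) is a topological
order of the acyclic subgraph they span; state variables may be referenced
freely (ODE self-dependence is the normal case) and never make a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


class CycleError(ValueError):
    """The ordered subset of the graph is cyclic."""

    def __init__(self, cycles: list[list[str]]):
        self.cycles = cycles
        pretty = "; ".join(" -> ".join(c + [c[0]]) for c in cycles)
        super().__init__(f"cyclic definitions: {pretty}")


# node roles
FREE = "free"
STATE = "state"
DETERMINED = "determined"
ALGEBRAIC = "algebraic"
DERIVATIVE = "derivative"
INITIAL = "initial"

# roles that participate in topological ordering; free parameters are leaves
# (no definitions), states/derivatives/initials are never ordered.
_ORDERED_ROLES = (FREE, DETERMINED, ALGEBRAIC)


@dataclass
class DependencyGraph:
    """Directed reference graph plus the declaration order used for ties."""

    digraph: nx.DiGraph = field(default_factory=nx.DiGraph)
    declaration_index: dict[str, int] = field(default_factory=dict)

    def add_node(self, name: str, role: str) -> None:
        self.digraph.add_node(name, role=role)
        self.declaration_index.setdefault(name, len(self.declaration_index))

    def add_edge(self, source: str, target: str) -> None:
        """``source``'s definition references ``target``."""
        self.digraph.add_edge(source, target)

    def ordered_subgraph(self) -> nx.DiGraph:
        """Subgraph over free/determined parameters and algebraic variables."""
        keep = [
            n
            for n, data in self.digraph.nodes(data=True)
            if data.get("role") in _ORDERED_ROLES
        ]
        return self.digraph.subgraph(keep).copy()

    def cycles(self) -> list[list[str]]:
        """Elementary cycles among the closed-form quantities."""
        return [list(c) for c in nx.simple_cycles(self.ordered_subgraph())]


def topological_order(graph: DependencyGraph, names: list[str] | None = None) -> list[str]:
    """Order ``names`` (default: all closed-form quantities) so that every
    name appears after everything it depends on; ties follow declaration
    order, so the output is deterministic.

    Raises :class:`CycleError` when the ordered subset is cyclic.
    """
    sub = graph.ordered_subgraph()
    if names is not None:
        sub = sub.subgraph(names).copy()
    # dependencies are edge *targets*; reversing makes them sort first
    rev = sub.reverse(copy=False)
    try:
        order = list(
            nx.lexicographical_topological_sort(
                rev, key=lambda n: graph.declaration_index.get(n, 1 << 30)
            )
        )
    except nx.NetworkXUnfeasible:
        raise CycleError(graph.cycles())
    return order
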