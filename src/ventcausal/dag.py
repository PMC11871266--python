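"""Causal DAG representation, d-separation, and backdoor adjustment sets.

The package ships a default graph encoding the clinical structure of the
mechanical-power question: baseline labs and vitals (WBC, temperature, pH,
MAP, PaCO2) and demographics feed a disease-severity score; severity drives
both the ventilator settings behind mechanical power (clinician policy
confounding) and the oxygenation trajectory (P/F ratio), which in turn
shapes ventilator-free days.  Lung compliance influences MP but is not
measured, so it is marked unobserved and can never enter an adjustment set.

A set Z satisfies the backdoor criterion for (exposure X, outcome Y) when no
member of Z is a descendant of X and Z d-separates X from Y in the graph
with X's outgoing edges removed.  Adjustment-set search is exhaustive subset
enumeration over observed non-descendants — exact, and fast at the ~20-node
scale these clinical graphs live at.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "CausalDAG",
    "AdjustmentSet",
    "CycleError",
    "NotIdentifiableError",
    "build_dag",
    "d_separated",
    "backdoor_sets",
    "load_dag",
    "save_dag",
    "default_dag",
]

ROLES = ("exposure", "outcome", "intermediary", "covariate")


class CycleError(ValueError):
    """The proposed edge set contains a directed cycle."""


class NotIdentifiableError(ValueError):
    """No observed adjustment set satisfies the backdoor criterion."""


@dataclass(frozen=True)
class AdjustmentSet:
    """An observed-variable set satisfying the backdoor criterion for a query."""

    variables: frozenset
    query: tuple
    minimal: bool = False

    def sorted_variables(self) -> tuple:
        return tuple(sorted(self.variables))


@dataclass
class CausalDAG:
    """A directed acyclic graph over named clinical variables.

    Each node carries ``observed`` (bool) and ``role`` (one of
    exposure/outcome/intermediary/covariate).  Exactly one exposure is
    required; one or more outcomes.
    """

    graph: nx.DiGraph
    exposure: str
    outcomes: tuple = field(default_factory=tuple)

    @property
    def nodes(self) -> tuple:
        return tuple(sorted(self.graph.nodes))

    @property
    def edges(self) -> tuple:
        return tuple(sorted(self.graph.edges))

    def observed_nodes(self) -> frozenset:
        return frozenset(n for n, d in self.graph.nodes(data=True) if d["observed"])

    def descendants_of_exposure(self) -> frozenset:
        return frozenset(nx.descendants(self.graph, self.exposure))

    def is_observed(self, node: str) -> bool:
        return bool(self.graph.nodes[node]["observed"])


def build_dag(
    nodes: Iterable,
    edges: Iterable,
    exposure: str,
    outcome: str | Sequence[str],
) -> CausalDAG:
    """Validate and assemble a :class:`CausalDAG`.

    ``nodes`` is an iterable of names or ``(name, observed, role)`` triples
    (bare names default to observed covariates); ``edges`` is an iterable of
    ``(parent, child)`` pairs.  Raises :class:`CycleError` (naming one
    offending cycle) if the edges are cyclic, and ``ValueError`` on duplicate
    nodes, unknown endpoints or missing roles.
    """
    g = nx.DiGraph()
    outcomes = (outcome,) if isinstance(outcome, str) else tuple(outcome)
    for spec in nodes:
        if isinstance(spec, str):
            name, observed, role = spec, True, "covariate"
        else:
            name, observed, role = spec
        if name in g:
            raise ValueError(f"duplicate node: {name!r}")
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} for node {name!r}")
        g.add_node(name, observed=bool(observed), role=role)
    for parent, child in edges:
        for end in (parent, child):
            if end not in g:
                raise ValueError(f"edge endpoint {end!r} is not a declared node")
        g.add_edge(parent, child)
    if exposure not in g:
        raise ValueError(f"exposure {exposure!r} is not a declared node")
    g.nodes[exposure]["role"] = "exposure"
    for o in outcomes:
        if o not in g:
            raise ValueError(f"outcome {o!r} is not a declared node")
        if g.nodes[o]["role"] not in ("outcome", "intermediary"):
            g.nodes[o]["role"] = "outcome"
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise CycleError(f"graph contains a cycle: {cycle}")
    return CausalDAG(graph=g, exposure=exposure, outcomes=outcomes)


def d_separated(dag: CausalDAG, a: str, b: str, given: Iterable = ()) -> bool:
    """True iff every path between ``a`` and ``b`` is blocked given the set."""
    given = frozenset(given)
    for n in {a, b} | given:
        if n not in dag.graph:
            raise ValueError(f"unknown node: {n!r}")
    if a in given or b in given:
        raise ValueError("endpoints cannot be in the conditioning set")
    return nx.is_d_separator(dag.graph, {a}, {b}, set(given))


def _satisfies_backdoor(dag: CausalDAG, z: frozenset, exposure: str, outcome: str) -> bool:
    if z & dag.descendants_of_exposure():
        return False
    proper = dag.graph.copy()
    proper.remove_edges_from(list(proper.out_edges(exposure)))
    return nx.is_d_separator(proper, {exposure}, {outcome}, set(z))


def backdoor_sets(
    dag: CausalDAG,
    exposure: str | None = None,
    outcome: str | None = None,
    minimal_only: bool = True,
) -> list:
    """All (or all minimal) observed backdoor adjustment sets for a query.

    Candidate variables are observed nodes that are neither the exposure,
    the outcome, nor descendants of the exposure.  Sets are returned in a
    deterministic order (by size, then lexicographically).  Raises
    :class:`NotIdentifiableError` when no valid observed set exists — which
    is distinct from the empty set being valid (unconfounded exposure).
    """
    exposure = exposure or dag.exposure
    outcome = outcome or dag.outcomes[0]
    candidates = sorted(
        dag.observed_nodes()
        - {exposure, outcome}
        - dag.descendants_of_exposure()
    )
    valid = []
    for r in range(len(candidates) + 1):
        for combo in combinations(candidates, r):
            z = frozenset(combo)
            if _satisfies_backdoor(dag, z, exposure, outcome):
                valid.append(z)
    if not valid:
        raise NotIdentifiableError(
            f"no observed set blocks every backdoor path {exposure!r} -> {outcome!r}"
        )
    if minimal_only:
        valid = [z for z in valid if not any(w < z for w in valid)]
    key = (exposure, outcome)
    return [
        AdjustmentSet(variables=z, query=key, minimal=minimal_only)
        for z in sorted(valid, key=lambda s: (len(s), tuple(sorted(s))))
    ]


# ---------------------------------------------------------------------------
# Plain-text graph file format:
#   node <name> observed|unobserved <role>
#   <parent> -> <child>
# Blank lines and '#' comments ignored.  Round-trips losslessly.
# ---------------------------------------------------------------------------

def load_dag(path) -> CausalDAG:
    """Read a DAG from the package's plain-text graph format."""
    nodes, edges = [], []
    exposure, outcomes = None, []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("node "):
            _, name, obs, role = line.split()
            if obs not in ("observed", "unobserved"):
                raise ValueError(f"bad observability flag in line: {raw!r}")
            nodes.append((name, obs == "observed", role))
            if role == "exposure":
                exposure = name
            elif role == "outcome":
                outcomes.append(name)
        elif "->" in line:
            parent, child = (s.strip() for s in line.split("->"))
            edges.append((parent, child))
        else:
            raise ValueError(f"unparseable graph line: {raw!r}")
    if exposure is None:
        raise ValueError("graph file declares no exposure node")
    if not outcomes:
        raise ValueError("graph file declares no outcome node")
    return build_dag(nodes, edges, exposure, outcomes)


def save_dag(dag: CausalDAG, path) -> None:
    """Write a DAG in the plain-text graph format (lossless round-trip)."""
    lines = []
    for name in dag.nodes:
        d = dag.graph.nodes[name]
        obs = "observed" if d["observed"] else "unobserved"
        lines.append(f"node {name} {obs} {d['role']}")
    for parent, child in dag.edges:
        lines.append(f"{parent} -> {child}")
    Path(path).write_text("\n".join(lines) + "\n")


def default_dag() -> CausalDAG:
    """The packaged mechanical-power → VFD28 clinical graph."""
    ref = resources.files("ventcausal.data").joinpath("mp_vfd_dag.txt")
    with resources.as_file(ref) as p:
        return load_dag(p)
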