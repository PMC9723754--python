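"""Path-model declarations.

A model is declared in a small plain-text syntax, one statement per line:

    respiration ~ active_biomass + sir_efficiency   # directed paths
    total_biomass ~~ active_biomass                 # free covariance
    group: biomass = total_biomass active_biomass   # node grouping

``#`` starts a comment. Directed edges must form a DAG; variables with no
incoming directed edge are exogenous and their covariances are free by
default (declared ``~~`` lines add further free covariances, e.g. between
disturbances of endogenous variables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


@dataclass(frozen=True)
class PathModelSpec:
    """Directed-path + correlation structure over named observed variables."""

    variables: tuple[str, ...]
    directed: tuple[tuple[str, str], ...]       # (source, target)
    correlations: tuple[tuple[str, str], ...]   # unordered, stored sorted
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        seen = set(self.variables)
        for s, t in self.directed:
            if s not in seen or t not in seen:
                raise ValueError(f"edge ({s}, {t}) uses undeclared variable")
        g = self.digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"directed paths contain a cycle: {cycle}")
        grouped: dict[str, str] = {}
        for name, members in self.groups.items():
            for v in members:
                if v in grouped:
                    raise ValueError(
                        f"variable {v!r} appears in groups {grouped[v]!r} and {name!r}"
                    )
                grouped[v] = name

    # -- derived structure -------------------------------------------------

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.directed)
        return g

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {t for _, t in self.directed}
        return tuple(v for v in self.variables if v in targets)

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {t for _, t in self.directed}
        return tuple(v for v in self.variables if v not in targets)

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(s for s, t in self.directed if t == v)

    def group_of(self, v: str) -> str | None:
        for name, members in self.groups.items():
            if v in members:
                return name
        return None


def parse_model(text: str) -> PathModelSpec:
    """Parse a plain-text model declaration into a :class:`PathModelSpec`."""
    variables: list[str] = []
    directed: list[tuple[str, str]] = []
    correlations: list[tuple[str, str]] = []
    groups: dict[str, tuple[str, ...]] = {}

    def note(v: str) -> str:
        if v not in variables:
            variables.append(v)
        return v

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("group:"):
            body = line[len("group:"):]
            if "=" not in body:
                raise ValueError(f"malformed group line: {raw!r}")
            name, members = body.split("=", 1)
            groups[name.strip()] = tuple(members.split())
            continue
        if "~~" in line:
            lhs, rhs = (s.strip() for s in line.split("~~", 1))
            for b in rhs.split("+"):
                pair = tuple(sorted((note(lhs), note(b.strip()))))
                if pair[0] == pair[1]:
                    raise ValueError(f"self-covariance declared for {lhs!r}")
                if pair not in correlations:
                    correlations.append(pair)
            continue
        if "~" in line:
            lhs, rhs = (s.strip() for s in line.split("~", 1))
            target = note(lhs)
            for src in rhs.split("+"):
                src = note(src.strip())
                if (src, target) not in directed:
                    directed.append((src, target))
            continue
        raise ValueError(f"cannot parse model line: {raw!r}")

    # groups may name variables that a reduced model omits; keep only those
    # present so every model variable maps to at most one group
    groups = {
        name: tuple(v for v in members if v in variables)
        for name, members in groups.items()
    }
    groups = {name: members for name, members in groups.items() if members}
    return PathModelSpec(
        variables=tuple(variables),
        directed=tuple(directed),
        correlations=tuple(correlations),
        groups=groups,
    )
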