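"""Data model for signed, domain-labelled causal loop diagrams (CLDs).

A CLD is a directed graph whose nodes are named system variables, each
assigned to exactly one of four biopsychosocial domains, and whose edges
are hypothesized causal connections carrying a polarity: ``positive``
(target moves with the source), ``negative`` (target moves against it),
or ``ambiguous`` (direction of the effect depends on context).

The model enforces the structural invariants used throughout the
package: unique variable ids, resolving endpoints, at most one
connection per ordered pair, and (by default) no self-loops.  The
exogenous set — variables with no incoming connections, which delimit
the system boundary and can never sit on a feedback loop — is always
derived from the edge list, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

DOMAINS: tuple[str, ...] = ("biological", "psychological", "behavioral", "social")
POLARITIES: tuple[str, ...] = ("positive", "negative", "ambiguous")


class CldValidationError(ValueError):
    """Raised when a diagram violates a structural invariant."""


@dataclass(frozen=True)
class Variable:
    """A named system variable assigned to one biopsychosocial domain."""

    id: str
    label: str
    domain: str
    definition: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise CldValidationError("variable id must be non-empty")
        if self.domain not in DOMAINS:
            raise CldValidationError(
                f"variable {self.id!r}: unknown domain {self.domain!r}; "
                f"expected one of {DOMAINS}"
            )


@dataclass(frozen=True)
class Connection:
    """A directed causal connection with a polarity.

    ``proposer_count`` records how many experts independently proposed the
    connection during elicitation; ``references`` holds citation strings.
    """

    source: str
    target: str
    polarity: str
    mechanism_note: str = ""
    references: tuple[str, ...] = ()
    proposer_count: int = 0

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise CldValidationError(
                f"connection {self.source!r}->{self.target!r}: unknown polarity "
                f"{self.polarity!r}; expected one of {POLARITIES}"
            )
        if self.proposer_count < 0:
            raise CldValidationError(
                f"connection {self.source!r}->{self.target!r}: "
                "proposer_count must be non-negative"
            )
        # references arrives as list from JSON; freeze it
        object.__setattr__(self, "references", tuple(self.references))

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_cld`."""

    rule: str
    element: str
    message: str


class CausalLoopDiagram:
    """A signed digraph of variables and causal connections plus metadata.

    Parameters
    ----------
    variables, connections:
        The diagram contents.  Endpoints must resolve to variable ids.
    name, provenance:
        Free-text metadata carried through file round-trips.
    allow_self_loops:
        Self-connections are rejected by default; when permitted they
        count as loops of length 1 and are excluded from analyses with a
        minimum loop length of 2.
    validate:
        When true (default) all invariants are checked at construction
        and the first violation raises :class:`CldValidationError`.
    """

    def __init__(
        self,
        variables: Iterable[Variable],
        connections: Iterable[Connection],
        name: str = "",
        provenance: str = "",
        allow_self_loops: bool = False,
        validate: bool = True,
    ) -> None:
        self.name = name
        self.provenance = provenance
        self.allow_self_loops = allow_self_loops
        self._variables: dict[str, Variable] = {}
        self._connections: dict[tuple[str, str], Connection] = {}
        self._duplicate_vars: list[str] = []
        self._duplicate_edges: list[tuple[str, str]] = []
        for v in variables:
            if v.id in self._variables:
                self._duplicate_vars.append(v.id)
            self._variables[v.id] = v
        for c in connections:
            if c.key in self._connections:
                self._duplicate_edges.append(c.key)
            self._connections[c.key] = c
        if validate:
            violations = validate_cld(self)
            if violations:
                first = violations[0]
                raise CldValidationError(
                    f"{first.rule}: {first.message}"
                    + (f" (+{len(violations) - 1} more)" if len(violations) > 1 else "")
                )

    # ---- accessors -------------------------------------------------

    @property
    def variables(self) -> tuple[Variable, ...]:
        return tuple(self._variables[i] for i in sorted(self._variables))

    @property
    def connections(self) -> tuple[Connection, ...]:
        return tuple(self._connections[k] for k in sorted(self._connections))

    @property
    def variable_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._variables))

    def variable(self, var_id: str) -> Variable:
        return self._variables[var_id]

    def has_variable(self, var_id: str) -> bool:
        return var_id in self._variables

    def connection(self, source: str, target: str) -> Connection:
        return self._connections[(source, target)]

    def has_connection(self, source: str, target: str) -> bool:
        return (source, target) in self._connections

    def successors(self, var_id: str) -> tuple[str, ...]:
        return tuple(sorted(t for (s, t) in self._connections if s == var_id))

    def predecessors(self, var_id: str) -> tuple[str, ...]:
        return tuple(sorted(s for (s, t) in self._connections if t == var_id))

    def in_degree(self, var_id: str) -> int:
        return sum(1 for (_, t) in self._connections if t == var_id)

    def __len__(self) -> int:
        return len(self._variables)

    def __iter__(self) -> Iterator[Variable]:
        return iter(self.variables)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalLoopDiagram):
            return NotImplemented
        return (
            self.name == other.name
            and self.provenance == other.provenance
            and self._variables == other._variables
            and self._connections == other._connections
        )

    def __repr__(self) -> str:
        return (
            f"<CausalLoopDiagram {self.name!r}: {len(self._variables)} variables, "
            f"{len(self._connections)} connections>"
        )

    def to_networkx(self) -> nx.DiGraph:
        """Export as a :class:`networkx.DiGraph` with full attributes."""
        g = nx.DiGraph(name=self.name, provenance=self.provenance)
        for v in self.variables:
            g.add_node(v.id, label=v.label, domain=v.domain, definition=v.definition)
        for c in self.connections:
            g.add_edge(
                c.source,
                c.target,
                polarity=c.polarity,
                mechanism_note=c.mechanism_note,
                references=list(c.references),
                proposer_count=c.proposer_count,
            )
        return g


def exogenous_variables(cld: CausalLoopDiagram) -> set[str]:
    """Variable ids with zero incoming connections.

    Exogenous variables influence the system without being influenced by
    it; they delimit the model boundary and cannot participate in any
    feedback loop.
    """
    targets = {c.target for c in cld.connections}
    return {v.id for v in cld.variables if v.id not in targets}


@dataclass(frozen=True)
class SummaryStats:
    """Headline counts of a diagram."""

    n_variables: int
    n_connections: int
    polarity_counts: Mapping[str, int]
    domain_counts: Mapping[str, int]
    n_exogenous: int

    def as_dict(self) -> dict:
        return {
            "n_variables": self.n_variables,
            "n_connections": self.n_connections,
            "polarity_counts": dict(self.polarity_counts),
            "domain_counts": dict(self.domain_counts),
            "n_exogenous": self.n_exogenous,
        }


def summary_stats(cld: CausalLoopDiagram) -> SummaryStats:
    """Counts of variables, connections, polarities, domains, exogenous."""
    pol = {p: 0 for p in POLARITIES}
    for c in cld.connections:
        pol[c.polarity] += 1
    dom = {d: 0 for d in DOMAINS}
    for v in cld.variables:
        dom[v.domain] += 1
    return SummaryStats(
        n_variables=len(cld),
        n_connections=len(cld.connections),
        polarity_counts=pol,
        domain_counts=dom,
        n_exogenous=len(exogenous_variables(cld)),
    )


def validate_cld(cld: CausalLoopDiagram) -> list[Violation]:
    """Check all structural invariants; return violations, never raise.

    An empty list means the diagram is valid.  Each violation names the
    offending element and the rule it breaks.
    """
    out: list[Violation] = []
    for vid in cld._duplicate_vars:
        out.append(
            Violation("duplicate-variable", vid, f"variable id {vid!r} defined more than once")
        )
    for key in cld._duplicate_edges:
        out.append(
            Violation(
                "duplicate-connection",
                f"{key[0]}->{key[1]}",
                f"more than one connection on ordered pair {key!r}; encode conflicting "
                "evidence as a single 'ambiguous' connection instead",
            )
        )
    for c in cld.connections:
        for endpoint in (c.source, c.target):
            if not cld.has_variable(endpoint):
                out.append(
                    Violation(
                        "dangling-endpoint",
                        f"{c.source}->{c.target}",
                        f"endpoint {endpoint!r} is not a variable in the diagram",
                    )
                )
        if c.source == c.target and not cld.allow_self_loops:
            out.append(
                Violation(
                    "self-loop",
                    f"{c.source}->{c.target}",
                    f"self-connection on {c.source!r} (allow_self_loops is off)",
                )
            )
    return out
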