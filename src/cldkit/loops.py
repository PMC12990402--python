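"""Feedback-loop enumeration and classification for causal loop diagrams.

A feedback loop is a directed simple cycle.  Its character follows from
the parity of negative connections along it: an odd number of negative
polarities makes the loop *balancing* (self-correcting, tending toward
equilibrium), an even number makes it *reinforcing* (amplifying, the
engine of "vicious cycles").  A loop traversing any ambiguous-polarity
connection has undetermined parity.  A loop whose member variables all
share one biopsychosocial domain is *within-scale*; one spanning several
domains is *cross-scale*.

Enumeration is a bounded-depth variant of Johnson's elementary-circuit
search: a depth-first search rooted at each vertex in lexicographic id
order, restricted to vertices ordered after the root, so every cycle is
emitted exactly once with its canonical rotation (lexicographically
smallest id first).  Loops are streamed to consumers (counters,
participation accumulators) in deterministic order rather than
materialized, which keeps long length caps tractable on dense diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Sequence

import pandas as pd

from ._util import round_half_up
from .core import CausalLoopDiagram, Connection

POLARITY_CLASSES = ("reinforcing", "balancing", "undetermined")
SCALE_CLASSES = ("within", "cross")
OVERLAY_CATEGORIES = ("homeostatic_resource", "behavioral", "clinical", "interpersonal")


@dataclass(frozen=True)
class LoopConfig:
    """Enumeration window and ranking size.

    ``max_length`` defaults to 14, the cap at which variable-participation
    rankings on diagrams of this density are observed to stabilize;
    ``top_k`` is the ranking depth used by the stabilization rule.
    """

    min_length: int = 2
    max_length: int = 14
    top_k: int = 10
    include_undetermined: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")


@dataclass(frozen=True)
class Loop:
    """A canonicalized directed simple cycle with its classification."""

    sequence: tuple[str, ...]
    edges: tuple[Connection, ...]
    polarity_class: str
    scale_class: str
    domains: frozenset[str]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_negative(self) -> int:
        return sum(1 for e in self.edges if e.polarity == "negative")

    @staticmethod
    def from_sequence(cld: CausalLoopDiagram, sequence: Sequence[str]) -> "Loop":
        """Build a loop from an ordered vertex sequence (any rotation)."""
        seq = canonical_rotation(tuple(sequence))
        edges = tuple(
            cld.connection(seq[i], seq[(i + 1) % len(seq)]) for i in range(len(seq))
        )
        domains = frozenset(cld.variable(v).domain for v in seq)
        return Loop(
            sequence=seq,
            edges=edges,
            polarity_class=_polarity_of(edges),
            scale_class="within" if len(domains) == 1 else "cross",
            domains=domains,
        )


def canonical_rotation(sequence: tuple[str, ...]) -> tuple[str, ...]:
    """Rotate a cyclic sequence to start at its lexicographically smallest id."""
    k = sequence.index(min(sequence))
    return sequence[k:] + sequence[:k]


def _polarity_of(edges: Iterable[Connection]) -> str:
    n_negative = 0
    for e in edges:
        if e.polarity == "ambiguous":
            return "undetermined"
        if e.polarity == "negative":
            n_negative += 1
    return "balancing" if n_negative % 2 == 1 else "reinforcing"


def classify_polarity(loop: Loop) -> str:
    """Parity rule: odd negatives balancing, even reinforcing,
    any ambiguous edge undetermined."""
    return _polarity_of(loop.edges)


def classify_scale(loop: Loop, cld: CausalLoopDiagram) -> str:
    """``within`` iff all member variables share one domain, else ``cross``."""
    domains = {cld.variable(v).domain for v in loop.sequence}
    return "within" if len(domains) == 1 else "cross"


# ---- enumeration ---------------------------------------------------


def iter_loops(cld: CausalLoopDiagram, config: LoopConfig | None = None) -> Iterator[Loop]:
    """Stream every simple cycle with length in the configured window.

    Single pass, deterministic order: cycles are grouped by their
    canonical starting vertex (ascending) and within a root emitted in
    depth-first lexicographic order.  Each cycle appears exactly once.
    """
    config = config or LoopConfig()
    order = {vid: i for i, vid in enumerate(cld.variable_ids)}
    succ = {vid: cld.successors(vid) for vid in cld.variable_ids}

    min_len, max_len = config.min_length, config.max_length

    for root in cld.variable_ids:
        root_rank = order[root]
        path = [root]
        on_path = {root}

        def dfs() -> Iterator[Loop]:
            current = path[-1]
            for nxt in succ[current]:
                if nxt == root:
                    if min_len <= len(path):
                        loop = Loop.from_sequence(cld, tuple(path))
                        if config.include_undetermined or loop.polarity_class != "undetermined":
                            yield loop
                elif order[nxt] > root_rank and nxt not in on_path and len(path) < max_len:
                    path.append(nxt)
                    on_path.add(nxt)
                    yield from dfs()
                    on_path.discard(path.pop())

        if max_len >= 1:
            yield from dfs()


def enumerate_loops(
    cld: CausalLoopDiagram, config: LoopConfig | None = None
) -> list[Loop]:
    """Materialize all loops in the window, sorted by (length, sequence)."""
    return sorted(iter_loops(cld, config), key=lambda l: (l.length, l.sequence))


def loop_census(cld: CausalLoopDiagram, config: LoopConfig | None = None) -> dict[int, int]:
    """Loop counts keyed by length, streaming (no materialization)."""
    config = config or LoopConfig()
    counts = {k: 0 for k in range(config.min_length, config.max_length + 1)}
    for loop in iter_loops(cld, config):
        counts[loop.length] += 1
    return counts


# ---- participation -------------------------------------------------


@dataclass(frozen=True)
class ParticipationTable:
    """Per-variable loop participation over a length window.

    ``table`` has one row per endogenous variable, sorted by descending
    percentage (lexicographic tie-break): columns ``variable``,
    ``loop_count`` and ``percentage`` (share of all loops in the window
    containing the variable, rounded half-up to one decimal; exact
    rationals are kept in ``exact_fractions``).  Percentages do not sum
    to 100 because each loop contains several variables.
    """

    table: pd.DataFrame
    total_loops: int
    min_length: int
    max_length: int
    exact_fractions: dict[str, Fraction] = field(repr=False, default_factory=dict)


def participation_table(
    cld: CausalLoopDiagram, config: LoopConfig | None = None
) -> ParticipationTable:
    """Percentage of loops (length window pooled) containing each variable.

    Exogenous variables are omitted: with no incoming connection they
    cannot sit on any cycle.
    """
    config = config or LoopConfig()
    from .core import exogenous_variables

    endogenous = sorted(set(cld.variable_ids) - exogenous_variables(cld))
    counts = {vid: 0 for vid in endogenous}
    total = 0
    for loop in iter_loops(cld, config):
        total += 1
        for vid in loop.sequence:
            counts[vid] += 1

    fractions = {
        vid: (Fraction(100 * counts[vid], total) if total else Fraction(0))
        for vid in endogenous
    }
    rows = sorted(
        (
            {
                "variable": vid,
                "loop_count": counts[vid],
                "percentage": round_half_up(fractions[vid], 1),
            }
            for vid in endogenous
        ),
        key=lambda r: (-r["percentage"], r["variable"]),
    )
    return ParticipationTable(
        table=pd.DataFrame(rows, columns=["variable", "loop_count", "percentage"]),
        total_loops=total,
        min_length=config.min_length,
        max_length=config.max_length,
        exact_fractions=fractions,
    )


@dataclass(frozen=True)
class StabilizationResult:
    """First pair of consecutive length caps with an identical top-k ranking.

    ``report_length`` is one past the stable pair — the cap at which the
    participation table is then reported.
    """

    stable_pair: tuple[int, int]
    report_length: int
    rankings: dict[int, tuple[str, ...]] = field(repr=False, default_factory=dict)


def ranking_stabilization(
    cld: CausalLoopDiagram,
    top_k: int = 10,
    max_probe_length: int = 14,
    min_length: int = 2,
) -> StabilizationResult | None:
    """Find the smallest cap L with top-k ranking identical at L-1 and L.

    The ranking at cap L orders endogenous variables by descending count
    of loops with length in [min_length, L], ties broken
    lexicographically.  Returns ``None`` if the ranking never stabilizes
    up to ``max_probe_length``.
    """
    from .core import exogenous_variables

    endogenous = sorted(set(cld.variable_ids) - exogenous_variables(cld))
    if top_k > len(endogenous):
        raise ValueError("top_k exceeds the number of endogenous variables")

    # one enumeration pass at the widest window; bucket counts by length
    by_length: dict[int, dict[str, int]] = {
        L: {vid: 0 for vid in endogenous}
        for L in range(min_length, max_probe_length + 1)
    }
    cfg = LoopConfig(min_length=min_length, max_length=max_probe_length)
    for loop in iter_loops(cld, cfg):
        bucket = by_length[loop.length]
        for vid in loop.sequence:
            bucket[vid] += 1

    rankings: dict[int, tuple[str, ...]] = {}
    cumulative = {vid: 0 for vid in endogenous}
    for L in range(min_length, max_probe_length + 1):
        for vid, n in by_length[L].items():
            cumulative[vid] += n
        ranked = sorted(endogenous, key=lambda v: (-cumulative[v], v))
        rankings[L] = tuple(ranked[:top_k])

    for L in range(min_length + 1, max_probe_length + 1):
        if rankings[L - 1] == rankings[L]:
            return StabilizationResult(
                stable_pair=(L - 1, L), report_length=L + 1, rankings=rankings
            )
    return None


# ---- focal queries -------------------------------------------------


def loops_containing(
    cld: CausalLoopDiagram,
    required: Iterable[str],
    length: int | None = None,
    config: LoopConfig | None = None,
) -> list[Loop]:
    """All loops containing every required variable, optionally of one length."""
    required = set(required)
    for vid in required:
        if not cld.has_variable(vid):
            raise KeyError(f"unknown variable id {vid!r}")
    config = config or LoopConfig()
    if length is not None:
        config = LoopConfig(
            min_length=length,
            max_length=length,
            top_k=config.top_k,
            include_undetermined=config.include_undetermined,
        )
    return [
        loop
        for loop in enumerate_loops(cld, config)
        if required <= set(loop.sequence)
    ]


def third_parties(cld: CausalLoopDiagram, pair: tuple[str, str]) -> set[str]:
    """Distinct third variables across all length-3 loops through the pair."""
    a, b = pair
    triads = loops_containing(cld, {a, b}, length=3)
    return {v for loop in triads for v in loop.sequence} - {a, b}


def bidirectional_partners(cld: CausalLoopDiagram, pair: tuple[str, str]) -> set[str]:
    """Third variables forming length-3 loops with the pair in BOTH orientations.

    For pair (a, b) and candidate v, both triangles a->b->v->a and
    a->v->b->a must exist.
    """
    a, b = pair
    out = set()
    for v in third_parties(cld, pair):
        fwd = cld.has_connection(a, b) and cld.has_connection(b, v) and cld.has_connection(v, a)
        rev = cld.has_connection(a, v) and cld.has_connection(v, b) and cld.has_connection(b, a)
        if fwd and rev:
            out.add(v)
    return out


# ---- balancing-loop overlay ----------------------------------------


@dataclass(frozen=True)
class OverlayLoop:
    """A balancing loop layered on top of the reinforcing core diagram.

    Overlay loops may pass through auxiliary variables that are not core
    CLD variables (e.g. treatment uptake); they are therefore validated
    standalone from their own polarity sequence.  ``polarities[i]`` signs
    the connection from ``sequence[i]`` to ``sequence[(i+1) % n]``.
    """

    sequence: tuple[str, ...]
    polarities: tuple[str, ...]
    category: str
    narrative: str = ""


def validate_overlay_loop(overlay: OverlayLoop) -> list[str]:
    """Check an overlay loop is simple, genuinely balancing, and categorized.

    Returns human-readable violation strings; empty means valid.  The
    parity check is strict: an even number of negative polarities means
    the loop would reinforce rather than counteract escalation.
    """
    violations: list[str] = []
    if len(overlay.sequence) < 2:
        violations.append("overlay loop must have at least 2 variables")
    if len(set(overlay.sequence)) != len(overlay.sequence):
        violations.append("overlay loop repeats a variable (not a simple cycle)")
    if len(overlay.polarities) != len(overlay.sequence):
        violations.append(
            f"{len(overlay.polarities)} polarities for {len(overlay.sequence)} connections"
        )
    unknown = [p for p in overlay.polarities if p not in ("positive", "negative")]
    if unknown:
        violations.append(
            f"overlay polarities must be positive/negative, got {sorted(set(unknown))}"
        )
    elif overlay.polarities.count("negative") % 2 == 0:
        violations.append(
            "even number of negative polarities: loop is reinforcing, not balancing"
        )
    if overlay.category not in OVERLAY_CATEGORIES:
        violations.append(
            f"category {overlay.category!r} not one of {OVERLAY_CATEGORIES}"
        )
    return violations
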