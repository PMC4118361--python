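"""Core data model: context graphs, context patterns, the clock and edge expiry.

A *context graph* is a labeled directed graph holding an agent's current
beliefs about the situation of the monitored person: nodes are concepts
(strings or URIs), edges are associations between them.  Edges optionally
expire: each carries either an absolute expiry timestamp on a logical
millisecond clock, or ``PERMANENT``.

A *context pattern* is a graph template for a known situation.  Pattern
nodes are either concrete (a concept label) or *generic* (wildcards,
written ``?`` with an index) and pattern edges carry two weights:

``characteristic``
    how strongly the edge defines the situation (in ``(0, 1]``); used to
    score partial matches.
``actionable``
    whether (and how readily) the system may itself add the edge to the
    context graph when the rest of the pattern is matched; ``>= 0``.

A pattern additionally has a *persistence*: the validity duration given to
edges inferred from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

logger = logging.getLogger("ccmatch")

#: Sentinel for edges (and persistences) that never expire.
PERMANENT = None

#: Label of generic (wildcard) pattern elements.
GENERIC = "?"

#: The empty edge label (an unnamed association).
LAMBDA = ""


class GraphConstraintError(ValueError):
    """A mutation would violate a structural constraint of the graph."""


class ClockRegressionError(ValueError):
    """The logical clock was asked to move backwards."""


class Clock:
    """Monotone logical clock in milliseconds.  Injected, never wall-clock."""

    def __init__(self, start: int = 0) -> None:
        self._now = int(start)

    @property
    def now(self) -> int:
        return self._now

    def advance_to(self, t: int) -> int:
        if t < self._now:
            raise ClockRegressionError(f"clock regression: {t} < {self._now}")
        self._now = int(t)
        return self._now


@dataclass(frozen=True)
class ContextEdge:
    """A directed labeled association ``from -label-> to``.

    ``expiry`` is an absolute logical-ms timestamp, or :data:`PERMANENT`.
    Identity (hash/equality) is the ``(frm, to, label)`` triple plus expiry;
    within a graph the triple alone is unique.
    """

    frm: str
    to: str
    label: str = LAMBDA
    expiry: int | None = PERMANENT

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.frm, self.to, self.label)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        lab = f"-{self.label}->" if self.label else "->"
        exp = "" if self.expiry is PERMANENT else f" (until {self.expiry})"
        return f"{self.frm} {lab} {self.to}{exp}"


class ContextGraph:
    """Mutable labeled directed graph with per-edge expiry.

    Node labels are unique (one concept = one node).  Between one ordered
    node pair several edges may exist but their labels must differ.  Nodes
    left isolated by an edge removal are garbage-collected by default.
    """

    def __init__(
        self,
        clock: Clock | None = None,
        *,
        gc_isolated_nodes: bool = True,
    ) -> None:
        self.clock = clock or Clock()
        self.gc_isolated_nodes = gc_isolated_nodes
        self._nodes: set[str] = set()
        self._edges: dict[tuple[str, str, str], ContextEdge] = {}
        self._adjacent: dict[str, set[tuple[str, str, str]]] = {}

    # -- queries ---------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._nodes)

    @property
    def edges(self) -> tuple[ContextEdge, ...]:
        return tuple(self._edges.values())

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, triple: tuple[str, str, str]) -> bool:
        return tuple(triple) in self._edges

    def __iter__(self) -> Iterator[ContextEdge]:
        return iter(self._edges.values())

    def get_edge(self, frm: str, to: str, label: str = LAMBDA) -> ContextEdge | None:
        return self._edges.get((frm, to, label))

    def edges_touching(self, node: str) -> tuple[ContextEdge, ...]:
        return tuple(self._edges[t] for t in self._adjacent.get(node, ()))

    # -- mutation --------------------------------------------------------

    def add_node(self, label: str) -> None:
        if not label:
            raise GraphConstraintError("node label must be non-empty")
        self._nodes.add(label)
        self._adjacent.setdefault(label, set())

    def add_edge(
        self,
        frm: str,
        to: str,
        label: str = LAMBDA,
        expiry: int | None = PERMANENT,
    ) -> ContextEdge:
        """Add ``frm -label-> to``; endpoints are created if absent.

        Raises :class:`GraphConstraintError` on a duplicate
        ``(frm, to, label)`` triple, an empty node label, or a non-permanent
        expiry not strictly in the future.
        """
        if not frm or not to:
            raise GraphConstraintError("node label must be non-empty")
        triple = (frm, to, label)
        if triple in self._edges:
            raise GraphConstraintError(
                f"duplicate edge {frm!r} -{label!r}-> {to!r}: labels must be "
                "unique between one ordered node pair"
            )
        if expiry is not PERMANENT and expiry <= self.clock.now:
            raise GraphConstraintError(
                f"expiry {expiry} is not in the future (now={self.clock.now})"
            )
        self.add_node(frm)
        self.add_node(to)
        edge = ContextEdge(frm, to, label, expiry)
        self._edges[triple] = edge
        self._adjacent[frm].add(triple)
        self._adjacent[to].add(triple)
        return edge

    def remove_edge(self, frm: str, to: str, label: str = LAMBDA) -> ContextEdge | None:
        """Remove an edge; idempotent (a missing edge logs a warning)."""
        triple = (frm, to, label)
        edge = self._edges.pop(triple, None)
        if edge is None:
            logger.warning("remove_edge: no such edge %s -%s-> %s", frm, label, to)
            return None
        for endpoint in {frm, to}:
            self._adjacent[endpoint].discard(triple)
            if self.gc_isolated_nodes and not self._adjacent[endpoint]:
                self._nodes.discard(endpoint)
                del self._adjacent[endpoint]
        return edge

    def expire(self, now: int) -> list[ContextEdge]:
        """Advance the clock and drop every edge with ``expiry <= now``."""
        self.clock.advance_to(now)
        dead = [e for e in self._edges.values()
                if e.expiry is not PERMANENT and e.expiry <= now]
        for e in dead:
            self.remove_edge(e.frm, e.to, e.label)
        return dead

    # -- invariants ------------------------------------------------------

    def check_invariants(self) -> None:
        """Assert structural invariants; cheap enough to call in tests."""
        for (f, t, l), e in self._edges.items():
            assert (f, t, l) == e.triple
            assert f in self._nodes and t in self._nodes, "dangling endpoint"
        for n, triples in self._adjacent.items():
            for tr in triples:
                assert tr in self._edges

    def copy(self) -> "ContextGraph":
        g = ContextGraph(Clock(self.clock.now),
                         gc_isolated_nodes=self.gc_isolated_nodes)
        for n in self._nodes:
            g.add_node(n)
        g._edges = dict(self._edges)
        g._adjacent = {n: set(s) for n, s in self._adjacent.items()}
        return g


# ---------------------------------------------------------------------------
# Patterns


@dataclass(frozen=True)
class PatternNode:
    """A pattern vertex: concrete (``label``, index 0) or generic (``?``, index >= 1)."""

    label: str
    index: int = 0

    def __post_init__(self) -> None:
        if self.label == GENERIC:
            if self.index < 1:
                raise GraphConstraintError("generic nodes need index >= 1")
        else:
            if self.index != 0:
                raise GraphConstraintError("concrete nodes carry index 0")
            if not self.label:
                raise GraphConstraintError("node label must be non-empty")

    @property
    def is_generic(self) -> bool:
        return self.label == GENERIC

    def __str__(self) -> str:
        return f"?^{self.index}" if self.is_generic else self.label


@dataclass(frozen=True)
class PatternEdge:
    """A pattern edge with matching label and the two weights.

    ``label`` may be :data:`GENERIC` (matches any graph label), a relation
    name, or :data:`LAMBDA`.
    """

    frm: PatternNode
    to: PatternNode
    label: str = LAMBDA
    characteristic: float = 1.0
    actionable: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.characteristic <= 1.0):
            raise GraphConstraintError(
                f"characteristic must be in (0, 1], got {self.characteristic}")
        if self.actionable < 0.0:
            raise GraphConstraintError("actionable must be >= 0")

    @property
    def is_generic_label(self) -> bool:
        return self.label == GENERIC

    def __str__(self) -> str:
        lab = self.label if self.label else "λ"
        return f"{self.frm} -{lab}-> {self.to}"


class GraphPattern:
    """A named situation template: pattern nodes, weighted edges, persistence.

    ``persistence`` (logical ms, or PERMANENT) is the validity granted to
    edges the system infers from this pattern.  The pattern graph must be
    connected so that partial matches can stay connected.
    """

    def __init__(
        self,
        name: str,
        persistence: int | None = PERMANENT,
    ) -> None:
        self.name = name
        self.persistence = persistence
        self._nodes: dict[tuple[str, int], PatternNode] = {}
        self._edges: list[PatternEdge] = []

    @property
    def nodes(self) -> tuple[PatternNode, ...]:
        return tuple(self._nodes.values())

    @property
    def edges(self) -> tuple[PatternEdge, ...]:
        return tuple(self._edges)

    def node(self, label: str, index: int = 0) -> PatternNode:
        """Return the pattern node with this (label, index), creating it."""
        key = (label, index)
        if key not in self._nodes:
            self._nodes[key] = PatternNode(label, index)
        return self._nodes[key]

    def generic(self, index: int) -> PatternNode:
        return self.node(GENERIC, index)

    def add_edge(
        self,
        frm: PatternNode | str,
        to: PatternNode | str,
        label: str = LAMBDA,
        characteristic: float = 1.0,
        actionable: float = 0.0,
    ) -> PatternEdge:
        if isinstance(frm, str):
            frm = self.node(frm)
        if isinstance(to, str):
            to = self.node(to)
        self._nodes.setdefault((frm.label, frm.index), frm)
        self._nodes.setdefault((to.label, to.index), to)
        edge = PatternEdge(frm, to, label, characteristic, actionable)
        self._edges.append(edge)
        return edge

    def total_characteristic(self) -> float:
        return sum(e.characteristic for e in self._edges)

    def neighbor_edges(self, edge: PatternEdge) -> list[PatternEdge]:
        """Pattern edges sharing at least one endpoint with ``edge``."""
        ends = {edge.frm, edge.to}
        return [e for e in self._edges
                if e is not edge and (e.frm in ends or e.to in ends)]

    def is_connected(self) -> bool:
        if not self._nodes:
            return True
        seen: set[PatternNode] = set()
        frontier = [next(iter(self._nodes.values()))]
        adj: dict[PatternNode, set[PatternNode]] = {n: set() for n in self._nodes.values()}
        for e in self._edges:
            adj[e.frm].add(e.to)
            adj[e.to].add(e.frm)
        while frontier:
            n = frontier.pop()
            if n in seen:
                continue
            seen.add(n)
            frontier.extend(adj[n] - seen)
        return len(seen) == len(self._nodes)

    def validate(self) -> None:
        if not self.is_connected():
            raise GraphConstraintError(f"pattern {self.name!r} is not connected")
        seen_triples: set[tuple[PatternNode, PatternNode, str]] = set()
        for e in self._edges:
            t = (e.frm, e.to, e.label)
            if t in seen_triples:
                raise GraphConstraintError(
                    f"pattern {self.name!r}: duplicate edge {e}")
            seen_triples.add(t)

    def __str__(self) -> str:
        return f"GraphPattern({self.name!r}, {len(self._nodes)}n/{len(self._edges)}e)"


def duration(ms: int = 0, *, s: int = 0, min: int = 0, h: int = 0) -> int:
    """Convenience constructor for logical-ms durations."""
    return ms + 1000 * (s + 60 * (min + 60 * h))


# ---------------------------------------------------------------------------
# Transactions: atomic batches of graph changes


@dataclass(frozen=True)
class Change:
    """One edge addition or removal inside a transaction."""

    op: str  # "add" | "remove"
    frm: str
    to: str
    label: str = LAMBDA
    expiry: int | None = PERMANENT

    def __post_init__(self) -> None:
        if self.op not in ("add", "remove"):
            raise ValueError(f"unknown change op {self.op!r}")
        if not self.frm or not self.to:
            raise ValueError("change endpoints must be non-empty labels")


@dataclass
class Transaction:
    """An atomic batch of edge changes applied at one engine sequence.

    The context graph stays constant during one matching pass; all changes
    of a transaction become visible together.  ``origin`` records where the
    transaction came from: sensor perception, the system's own inference,
    or the expiry sweep.
    """

    changes: list[Change] = field(default_factory=list)
    origin: str = "perception"  # perception | inference | expiry
    submitted_at: int | None = None

    def add(self, frm: str, to: str, label: str = LAMBDA,
            expiry: int | None = PERMANENT) -> "Transaction":
        self.changes.append(Change("add", frm, to, label, expiry))
        return self

    def remove(self, frm: str, to: str, label: str = LAMBDA) -> "Transaction":
        self.changes.append(Change("remove", frm, to, label))
        return self
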