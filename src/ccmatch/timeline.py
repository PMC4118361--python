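"""Timelines: state machines recognizing temporal sequences of situations.

A timeline is a second-order pattern: its nodes reference context patterns
(by name) and its edges carry temporal activation rules.  A timeline is
inactive until the pattern in its single root is matched; then the root's
outgoing edges become *enabled* and may become *active* according to their
rule.  When the pattern at the destination of an active edge is satisfied,
that node *fires*: every edge is disabled and the fired node's outgoing
edges become enabled.  When no edge is enabled or active the timeline
falls back to inactive (and may be re-activated by a fresh root match).

Edge rules (quanta are durations on the logical ms clock, measured from
the moment the edge was enabled):

========================  ==================================================
``plain`` (empty label)   active immediately, indefinitely
``next``                  active exactly in the sequence where the source
                          pattern stops matching; fires only if the
                          destination is satisfied in that same sequence
``sooner-than q``         active from enablement, disabled once more than
                          ``q`` has passed
``later-than q``          active once ``q`` has passed, indefinitely
``interval q1 q2``        active between ``q1`` and ``q2`` after enablement
``time q``                active at the first sequence at/after ``q``,
                          disabled again at the next sequence
========================  ==================================================

Nodes may declare an ``emits`` token: when the node fires, the token is
added to the sequence's satisfied set, letting one timeline act as a
composite condition for another (e.g. a near-door/undetected sequence
emitting an "in bathroom" event).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .context_model import GraphPattern
from .textgraph import parse_duration

DISABLED, ENABLED, ACTIVE = "disabled", "enabled", "active"

_RULE_KINDS = ("plain", "next", "sooner-than", "later-than", "interval", "time")


@dataclass(frozen=True)
class Rule:
    """Temporal activation rule of a timeline edge."""

    kind: str
    q1: int | None = None
    q2: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind in ("sooner-than", "later-than", "time"):
            if self.q1 is None or self.q1 <= 0:
                raise ValueError(f"rule {self.kind} needs a quantum > 0")
        if self.kind == "interval":
            if self.q1 is None or self.q2 is None or self.q1 <= 0 or self.q2 <= 0:
                raise ValueError("interval needs two quanta > 0")

    def __str__(self) -> str:
        if self.kind == "plain":
            return "->"
        if self.kind == "next":
            return "-next->"
        if self.kind == "interval":
            return f"-interval {self.q1}..{self.q2}->"
        return f"-{self.kind} {self.q1}->"


@dataclass
class TimelineNode:
    id: str
    pattern_name: str
    emits: str | None = None


@dataclass
class TimelineEdge:
    frm: str
    to: str
    rule: Rule
    state: str = DISABLED
    enabled_at: int | None = None
    time_spent: bool = False  # a 'time' edge that already had its one shot

    def enable(self, now: int) -> None:
        self.state = ENABLED
        self.enabled_at = now
        self.time_spent = False

    def disable(self) -> None:
        self.state = DISABLED
        self.enabled_at = None
        self.time_spent = False


def edge_state(
    edge: TimelineEdge,
    source_matched: bool,
    source_was_matched: bool,
    now: int,
) -> str:
    """Next state of an enabled/active edge under its rule."""
    rule = edge.rule
    elapsed = now - (edge.enabled_at or 0)
    if rule.kind == "plain":
        return ACTIVE
    if rule.kind == "next":
        return ACTIVE if (source_was_matched and not source_matched) else ENABLED
    if rule.kind == "sooner-than":
        return ACTIVE if elapsed <= rule.q1 else DISABLED
    if rule.kind == "later-than":
        return ACTIVE if elapsed >= rule.q1 else ENABLED
    if rule.kind == "interval":
        if elapsed < rule.q1:
            return ENABLED
        return ACTIVE if elapsed <= rule.q2 else DISABLED
    if rule.kind == "time":
        if edge.time_spent:
            return DISABLED
        return ACTIVE if elapsed >= rule.q1 else ENABLED
    raise AssertionError(rule.kind)


class Timeline:
    """A named timeline over pattern-referencing nodes."""

    def __init__(self, name: str, nodes: list[TimelineNode],
                 edges: list[TimelineEdge]) -> None:
        self.name = name
        self.nodes: dict[str, TimelineNode] = {n.id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise ValueError(f"timeline {name!r}: duplicate node ids")
        self.edges = edges
        self.active = False

    @property
    def root(self) -> TimelineNode:
        roots = self._roots()
        if len(roots) != 1:
            raise ValueError(f"timeline {self.name!r} has {len(roots)} roots")
        return roots[0]

    def _roots(self) -> list[TimelineNode]:
        targets = {e.to for e in self.edges}
        return [n for n in self.nodes.values() if n.id not in targets]

    def out_edges(self, node_id: str) -> list[TimelineEdge]:
        return [e for e in self.edges if e.frm == node_id]

    # -- validation ------------------------------------------------------

    def validate(self) -> list[str]:
        """Structural violations, as human-readable strings (empty = ok)."""
        problems: list[str] = []
        roots = self._roots()
        if len(roots) != 1:
            problems.append(
                f"timeline must have exactly one root (node without "
                f"incoming edges); found {len(roots)}")
        for e in self.edges:
            if e.frm not in self.nodes or e.to not in self.nodes:
                problems.append(f"edge {e.frm}->{e.to} references unknown node")
            if e.rule.kind == "interval" and not (e.rule.q1 < e.rule.q2):
                problems.append(
                    f"edge {e.frm}->{e.to}: interval needs q1 < q2 "
                    f"(got {e.rule.q1}, {e.rule.q2})")
        if len(roots) == 1 and not problems:
            reachable = {roots[0].id}
            frontier = [roots[0].id]
            while frontier:
                nid = frontier.pop()
                for e in self.out_edges(nid):
                    if e.to not in reachable:
                        reachable.add(e.to)
                        frontier.append(e.to)
            for nid in self.nodes:
                if nid not in reachable:
                    problems.append(f"node {nid!r} unreachable from the root")
        return problems

    # -- dynamics --------------------------------------------------------

    def reset(self) -> None:
        self.active = False
        for e in self.edges:
            e.disable()

    def step(
        self,
        satisfied: set[str],
        prev_satisfied: set[str],
        now: int,
    ) -> list[TimelineNode]:
        """Advance one engine sequence; returns the nodes that fired.

        ``satisfied`` / ``prev_satisfied`` are the names of patterns (and
        emitted tokens) satisfied in this and the previous sequence.
        """
        if not self.active:
            root = self.root
            if root.pattern_name in satisfied:
                self.active = True
                for e in self.edges:
                    e.disable()
                for e in self.out_edges(root.id):
                    e.enable(now)
                if not self.out_edges(root.id):
                    self.active = False
                return [root]
            return []

        # promote/demote enabled and active edges per their rules
        for e in self.edges:
            if e.state == DISABLED:
                continue
            src = self.nodes[e.frm].pattern_name
            new = edge_state(e, src in satisfied, src in prev_satisfied, now)
            if e.rule.kind == "time" and new == ACTIVE:
                e.time_spent = True
            e.state = new

        fired: list[TimelineNode] = []
        for e in self.edges:
            if e.state == ACTIVE and self.nodes[e.to].pattern_name in satisfied:
                node = self.nodes[e.to]
                if node not in fired:
                    fired.append(node)

        if fired:
            for e in self.edges:
                e.disable()
            for node in fired:
                for e in self.out_edges(node.id):
                    e.enable(now)

        if not any(e.state in (ENABLED, ACTIVE) for e in self.edges):
            self.active = False
        return fired


# ---------------------------------------------------------------------------
# Config-file loading


def _parse_rule(spec: dict) -> Rule:
    kind = spec.get("rule", "plain")
    if kind in ("plain", "next"):
        return Rule(kind)
    if kind == "interval":
        return Rule(kind, parse_duration(str(spec["q1"])),
                    parse_duration(str(spec["q2"])))
    return Rule(kind, parse_duration(str(spec["q"])))


def timeline_from_dict(spec: dict) -> Timeline:
    """Build a timeline from its config mapping (see the YAML layout)."""
    nodes = [TimelineNode(str(n["id"]), str(n["pattern"]),
                          n.get("emits")) for n in spec["nodes"]]
    edges = [TimelineEdge(str(e["from"]), str(e["to"]), _parse_rule(e))
             for e in spec.get("edges", [])]
    tl = Timeline(str(spec["name"]), nodes, edges)
    problems = tl.validate()
    if problems:
        raise ValueError(f"invalid timeline {tl.name!r}: " + "; ".join(problems))
    return tl


def load_timelines(path) -> list[Timeline]:
    """Load timelines from a YAML file::

        timelines:
          - name: bathroom
            nodes:
              - {id: root, pattern: in bathroom}
              - {id: out-soon, pattern: out of bathroom}
            edges:
              - {from: root, to: out-soon, rule: sooner-than, q: 5min}
    """
    import pathlib

    import yaml

    data = yaml.safe_load(pathlib.Path(path).read_text(encoding="utf-8"))
    return [timeline_from_dict(d) for d in data.get("timelines", [])]
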