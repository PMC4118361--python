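"""Deciding which missing actionable edges a partial match licenses.

A pattern edge with ``actionable > 0`` is one the system may add to the
context graph itself — a notification, a log entry — once the rest of the
situation is sufficiently recognized.  Two eligibility rules are offered:

``"prose"`` (default)
    an unsolved edge with actionability ``a`` is eligible when
    ``k_f >= 1 - a``: the less actionable an edge, the more complete the
    match must be, and zero-actionable edges are never inferable.
``"literal"``
    ``a >= k_f``: under this reading a highly actionable edge is eligible
    even for poor matches, and improving a match can *dis*-qualify an
    inference.  Provided for comparison; see the methods note for why the
    prose-consistent rule is the default.

An inference fires only for a match that is *otherwise complete*: every
unsolved pattern edge must be actionable and eligible.  The inferred edges
are materialized as a transaction; edges receive the pattern's persistence
as validity, and unsolved generic endpoints that carry no binding get fresh
node labels (``entry#1``, ``entry#2``, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .context_model import (
    PERMANENT,
    ContextGraph,
    PatternEdge,
    PatternNode,
    Transaction,
)
from .matcher import Match, score_kf

logger = logging.getLogger("ccmatch.actions")

ACTION_RULES = ("prose", "literal")


def _edge_eligible(kf: float, actionable: float, rule: str) -> bool:
    if rule == "prose":
        return kf >= 1.0 - actionable
    if rule == "literal":
        return actionable >= kf
    raise ValueError(f"unknown action rule {rule!r}; use one of {ACTION_RULES}")


def eligible_inferences(match: Match, rule: str = "prose") -> list[PatternEdge]:
    """Unsolved actionable edges whose weight licenses inference.

    Edges with zero actionability are never returned: on a partial match
    they cannot be acted upon, and on a complete match nothing is unsolved.
    """
    kf = score_kf(match)
    out = []
    for pe in match.unsolved_edges:
        if pe.is_generic_label:
            continue  # an edge with an unknown label cannot be materialized
        if pe.actionable > 0.0 and _edge_eligible(kf, pe.actionable, rule):
            out.append(pe)
    return out


@dataclass
class ActionDecision:
    """A concrete, applicable set of inferences derived from one match."""

    match: Match
    edges_to_add: list[PatternEdge]
    new_node_bindings: dict[PatternNode, str]
    validity: int | None  # duration (pattern persistence), or PERMANENT

    @property
    def key(self) -> tuple:
        """Identity used to fire an action at most once per live match."""
        return (self.match.pattern.name, self.match.key,
                frozenset(str(e) for e in self.edges_to_add))


class NameAllocator:
    """Fresh, deterministic labels for inferred nodes: ``base#1``, ``base#2``…"""

    def __init__(self) -> None:
        self._counters: dict[str, int] = {}

    def fresh(self, base: str) -> str:
        n = self._counters.get(base, 0) + 1
        self._counters[base] = n
        return f"{base}#{n}"


def decide(
    match: Match,
    rule: str = "prose",
    names: NameAllocator | None = None,
) -> ActionDecision | None:
    """Build an :class:`ActionDecision` if the match is otherwise complete.

    Returns ``None`` when the match is complete (nothing to add) or when
    some unsolved edge is not an eligible actionable edge (the situation is
    not yet recognized well enough to act).
    """
    unsolved = match.unsolved_edges
    if not unsolved:
        return None
    eligible = set(map(id, eligible_inferences(match, rule)))
    if any(id(pe) not in eligible for pe in unsolved):
        return None
    names = names or NameAllocator()
    bindings: dict[PatternNode, str] = {}
    for pe in unsolved:
        for pn in (pe.frm, pe.to):
            if pn.is_generic and pn not in match.node_map and pn not in bindings:
                base = _base_name_for(pn, match)
                bindings[pn] = names.fresh(base)
    return ActionDecision(match, list(unsolved), bindings,
                          match.pattern.persistence)


def _base_name_for(pn: PatternNode, match: Match) -> str:
    """Base label for a fresh node: the label of an edge pointing at it."""
    for pe in match.pattern.edges:
        if pe.to == pn and pe.label and pe.label != "?":
            return pe.label
    for pe in match.pattern.edges:
        if pe.frm == pn and pe.label and pe.label != "?":
            return pe.label
    return "node"


def apply_inference(
    graph: ContextGraph,
    decision: ActionDecision,
    now: int,
) -> Transaction:
    """Materialize a decision as an inference transaction.

    Inferred edges get ``expiry = now + persistence`` (or PERMANENT);
    endpoints bound by the match are reused, fresh bindings come from the
    decision.  Edges already present in the graph are skipped with a log
    message rather than erroring, so re-firing is harmless.
    """
    txn = Transaction(origin="inference", submitted_at=now)
    validity = decision.validity
    expiry = PERMANENT if validity is PERMANENT else now + validity
    for pe in decision.edges_to_add:
        frm = _resolve(pe.frm, decision)
        to = _resolve(pe.to, decision)
        label = pe.label
        if graph.get_edge(frm, to, label) is not None:
            logger.info("inference %s -%s-> %s already present; skipped",
                        frm, label, to)
            continue
        txn.add(frm, to, label, expiry)
    return txn


def _resolve(pn: PatternNode, decision: ActionDecision) -> str:
    if not pn.is_generic:
        return pn.label
    bound = decision.match.node_map.get(pn)
    if bound is not None:
        return bound
    return decision.new_node_bindings[pn]


# ---------------------------------------------------------------------------
# Remainder patterns: detecting "otherwise matched" situations


def remainder_pattern(pattern):
    """The non-actionable remainder of a pattern, plus an edge-index map.

    Returns ``(remainder, index_map)`` where ``remainder`` is a
    :class:`~ccmatch.context_model.GraphPattern` holding only the edges
    with zero actionability (sharing node identities with the original,
    since pattern nodes compare by value) and ``index_map`` maps remainder
    edge indexes to the original pattern's edge indexes.  A complete match
    of the remainder is exactly a match of the full pattern in which only
    actionable edges are missing.  Returns ``(None, {})`` when every edge
    is actionable (the remainder is vacuously matched).
    """
    from .context_model import GraphPattern

    passive = [(i, e) for i, e in enumerate(pattern.edges) if e.actionable == 0.0]
    if not passive:
        return None, {}
    rem = GraphPattern(pattern.name + "~remainder", pattern.persistence)
    index_map: dict[int, int] = {}
    for j, (i, e) in enumerate(passive):
        rem.add_edge(e.frm, e.to, e.label, e.characteristic, e.actionable)
        index_map[j] = i
    return rem, index_map


def lift_remainder_match(pattern, index_map: dict[int, int], rem_match: Match) -> Match:
    """Re-express a complete remainder match as a partial match of the
    full pattern (the actionable edges are the unsolved part)."""
    edge_map = {index_map[j]: triple for j, triple in rem_match.edge_map.items()}
    return Match(pattern, edge_map, dict(rem_match.node_map))


def decide_from_remainder(
    pattern,
    index_map: dict[int, int],
    rem_match: Match | None,
    rule: str = "prose",
    names: NameAllocator | None = None,
) -> ActionDecision | None:
    """Action decision for an otherwise-matched situation.

    ``rem_match`` is a complete match of the pattern's remainder (or
    ``None`` when the remainder is empty, i.e. every edge is actionable).
    Returns ``None`` if some missing actionable edge is not eligible at
    the match's ``k_f``.
    """
    if rem_match is None:
        lifted = Match(pattern, {}, {})
    else:
        lifted = lift_remainder_match(pattern, index_map, rem_match)
    unsolved = lifted.unsolved_edges
    if not unsolved:
        return None
    total = sum(e.characteristic for e in pattern.edges)
    solved = sum(pattern.edges[i].characteristic for i in lifted.edge_map)
    kf = solved / total
    for pe in unsolved:
        if pe.is_generic_label:
            return None
        if pe.actionable <= 0.0 or not _edge_eligible(kf, pe.actionable, rule):
            return None
    names = names or NameAllocator()
    bindings: dict[PatternNode, str] = {}
    for pe in unsolved:
        for pn in (pe.frm, pe.to):
            if pn.is_generic and pn not in lifted.node_map and pn not in bindings:
                bindings[pn] = names.fresh(_base_name_for(pn, lifted))
    return ActionDecision(lifted, list(unsolved), bindings, pattern.persistence)
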