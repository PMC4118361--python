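"""Matching of context patterns against context graphs.

A *match* is an injective correspondence from part of a pattern to a
connected subgraph of the context graph:

* concrete pattern nodes must map to graph nodes with the same label,
  generic (``?``) nodes may map to any node, injectively;
* a solved pattern edge must map to a graph edge between the images of its
  endpoints with the same label (any label if the pattern label is ``?``).

Partial matches are allowed: a *k-match* leaves ``k`` of the ``m_s``
pattern edges unsolved (``k in {0 .. m_s - 1}``) while the matched
subgraph stays connected and minimal.  Match quality is

    k_f = sum(characteristic of solved edges) / sum(characteristic of all edges)

so a complete match scores 1 and heavily characteristic edges dominate.

The production algorithm seeds *single-edge matches* (one pattern edge on
one graph edge; the only place where labels are compared) and grows them by
merging compatible matches until no extension remains (*maximal* matches).
:func:`brute_force_matches` is a separate exhaustive oracle used to validate
the grower on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .context_model import (
    GENERIC,
    ContextEdge,
    ContextGraph,
    GraphPattern,
    PatternEdge,
    PatternNode,
)

#: Sentinel returned by :func:`merge` for incompatible operands.
INCOMPATIBLE = None


@dataclass
class OpCounters:
    """Operation counters instrumenting the matching process.

    Label comparisons are counted only where labels are actually compared
    (single-edge match creation); growth afterwards manipulates references
    only, which is the economy the engine is designed around.
    """

    node_ref_cmp: int = 0
    node_label_cmp: int = 0
    edge_ref_cmp: int = 0
    edge_label_cmp: int = 0
    merges: int = 0

    def snapshot(self) -> dict[str, int]:
        return {
            "node_ref_cmp": self.node_ref_cmp,
            "node_label_cmp": self.node_label_cmp,
            "edge_ref_cmp": self.edge_ref_cmp,
            "edge_label_cmp": self.edge_label_cmp,
            "merges": self.merges,
        }

    def total_label_cmp(self) -> int:
        return self.node_label_cmp + self.edge_label_cmp

    def total_ref_cmp(self) -> int:
        return self.node_ref_cmp + self.edge_ref_cmp


class Match:
    """A (partial) correspondence between a pattern and a context graph.

    Immutable; identity for deduplication is the pair
    ``(solved edge assignment, node mapping)``.
    """

    __slots__ = ("pattern", "edge_map", "node_map", "_key", "_hash")

    def __init__(
        self,
        pattern: GraphPattern,
        edge_map: dict[int, tuple[str, str, str]],
        node_map: dict[PatternNode, str],
    ) -> None:
        self.pattern = pattern
        self.edge_map: dict[int, tuple[str, str, str]] = edge_map
        self.node_map: dict[PatternNode, str] = node_map
        self._key = (
            frozenset(edge_map.items()),
            frozenset(node_map.items()),
        )
        self._hash = hash(self._key)

    # -- identity --------------------------------------------------------

    @property
    def key(self):
        return self._key

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other) -> bool:
        return isinstance(other, Match) and self.pattern is other.pattern \
            and self._key == other._key

    # -- derived structure ----------------------------------------------

    @property
    def solved_edges(self) -> list[PatternEdge]:
        edges = self.pattern.edges
        return [edges[i] for i in self.edge_map]

    @property
    def unsolved_edges(self) -> list[PatternEdge]:
        edges = self.pattern.edges
        return [e for i, e in enumerate(edges) if i not in self.edge_map]

    @property
    def k(self) -> int:
        return len(self.pattern.edges) - len(self.edge_map)

    @property
    def is_complete(self) -> bool:
        return self.k == 0

    @property
    def matched_graph_edges(self) -> set[tuple[str, str, str]]:
        return set(self.edge_map.values())

    @property
    def matched_graph_nodes(self) -> set[str]:
        return set(self.node_map.values())

    @property
    def k_f(self) -> float:
        return score_kf(self)

    def describe(self) -> str:
        """Human-readable matched-vs-missing account of the match."""
        lines = [f"match of pattern {self.pattern.name!r}: "
                 f"k={self.k} k_f={self.k_f:.3f}"]
        edges = self.pattern.edges
        for i, pe in enumerate(edges):
            if i in self.edge_map:
                f, t, l = self.edge_map[i]
                lines.append(f"  solved   {pe}  ~>  {f} -{l or 'λ'}-> {t}")
            else:
                lines.append(f"  missing  {pe}")
        for pn, n in sorted(self.node_map.items(), key=lambda kv: str(kv[0])):
            if pn.is_generic:
                lines.append(f"  binding  {pn} = {n}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Match({self.pattern.name!r}, k={self.k}, "
                f"edges={sorted(self.edge_map)})")


def score_kf(match: Match) -> float:
    """Characteristic mass of solved edges over total pattern mass."""
    edges = match.pattern.edges
    if not edges:
        raise ValueError("k_f is undefined for a pattern with no edges")
    total = sum(e.characteristic for e in edges)
    solved = sum(edges[i].characteristic for i in match.edge_map)
    return solved / total


def _edge_index(pattern: GraphPattern) -> dict[int, PatternEdge]:
    return dict(enumerate(pattern.edges))


def _label_index(pattern: GraphPattern):
    """Pattern edges grouped by label (generic-label edges listed apart);
    cached on the pattern and rebuilt if edges were added since."""
    cache = getattr(pattern, "_label_index_cache", None)
    if cache is not None and cache[0] == len(pattern.edges):
        return cache[1], cache[2]
    by_label: dict[str, list[tuple[int, PatternEdge]]] = {}
    generic: list[tuple[int, PatternEdge]] = []
    for i, pe in enumerate(pattern.edges):
        if pe.is_generic_label:
            generic.append((i, pe))
        else:
            by_label.setdefault(pe.label, []).append((i, pe))
    pattern._label_index_cache = (len(pattern.edges), by_label, generic)
    return by_label, generic


def initial_matches(
    pattern: GraphPattern,
    edge: ContextEdge,
    counters: OpCounters | None = None,
) -> list[Match]:
    """All single-edge matches of ``pattern`` onto one graph edge.

    This is the only stage at which node and edge labels are compared
    (one hashed edge-label lookup, then endpoint label checks for the
    candidate pattern edges); growth afterwards operates purely on
    references.
    """
    by_label, generic = _label_index(pattern)
    if counters:
        counters.edge_label_cmp += 1  # hashed lookup of the edge label
    candidates = by_label.get(edge.label, [])
    out: list[Match] = []
    for i, pe in [*candidates, *generic]:
        # endpoint compatibility
        if pe.frm == pe.to:
            if edge.frm != edge.to:
                continue
        elif edge.frm == edge.to:
            continue  # two distinct pattern nodes cannot share one graph node
        ok = True
        for pn, gn in ((pe.frm, edge.frm), (pe.to, edge.to)):
            if not pn.is_generic:
                if counters:
                    counters.node_label_cmp += 1
                if pn.label != gn:
                    ok = False
                    break
        if not ok:
            continue
        out.append(Match(pattern,
                         {i: edge.triple},
                         {pe.frm: edge.frm, pe.to: edge.to}))
    return out


def merge(m1: Match, m2: Match, counters: OpCounters | None = None):
    """Union of two matches over the same pattern, or :data:`INCOMPATIBLE`.

    Requirements: disjoint solved pattern-edge sets, agreeing node maps,
    injectivity of the union, and a connected union subgraph (the two
    matches must share at least one mapped graph node).
    """
    if m1.pattern is not m2.pattern:
        return INCOMPATIBLE
    if counters:
        counters.edge_ref_cmp += min(len(m1.edge_map), len(m2.edge_map))
    if m1.edge_map.keys() & m2.edge_map.keys():
        return INCOMPATIBLE
    a, b = m1.node_map, m2.node_map
    if len(a) > len(b):
        a, b = b, a
    shared_graph_node = False
    if counters:
        counters.node_ref_cmp += len(a)
    for pn, gn in a.items():
        other = b.get(pn)
        if other is not None:
            if other != gn:
                return INCOMPATIBLE
            shared_graph_node = True
    merged_nodes = {**m1.node_map, **m2.node_map}
    # injectivity of the combined mapping
    if len(set(merged_nodes.values())) != len(merged_nodes):
        return INCOMPATIBLE
    if not shared_graph_node:
        # connectivity may also come through a shared graph node under
        # different pattern nodes -- but that would break injectivity,
        # so sharing a pattern node is the only way to stay connected.
        return INCOMPATIBLE
    if counters:
        counters.merges += 1
    return Match(m1.pattern, {**m1.edge_map, **m2.edge_map}, merged_nodes)


def _compatible_with(match: Match, single: Match,
                     counters: OpCounters | None = None) -> bool:
    """Compatibility test used during growth: reference operations only."""
    (i,) = single.edge_map
    if counters:
        counters.edge_ref_cmp += 1
    if i in match.edge_map:
        return False
    shared = False
    for pn, gn in single.node_map.items():
        if counters:
            counters.node_ref_cmp += 1
        have = match.node_map.get(pn)
        if have is not None:
            if have != gn:
                return False
            shared = True
        elif gn in match.matched_graph_nodes:
            return False  # injectivity
    return shared


def all_single_edge_matches(
    pattern: GraphPattern,
    graph: ContextGraph,
    counters: OpCounters | None = None,
) -> list[Match]:
    singles: list[Match] = []
    for e in graph.edges:
        singles.extend(initial_matches(pattern, e, counters))
    return singles


def grow_to_maximal(
    seeds: Iterable[Match],
    singles: Sequence[Match],
    counters: OpCounters | None = None,
    canonical_groups: Sequence[Sequence[int]] | None = None,
) -> set[Match]:
    """Grow each seed by repeated single-edge merges until maximal.

    A match is maximal when no compatible single-edge match remains.  The
    search branches Bron-Kerbosch style: at each step one addable extension
    ``e`` is picked as pivot and the branches are "add ``e``" plus "add some
    extension incompatible with ``e``" — any maximal extension must do one
    of the two.  A memo set collapses states reachable along several orders.

    ``canonical_groups`` optionally lists groups of interchangeable generic
    node indexes; bindings within one group are forced into a canonical
    order, collapsing the factorial family of automorphic matches to one
    representative per assignment (used for wide counting patterns).
    """
    results: set[Match] = set()
    seen: set[tuple] = set()

    def canonical_ok(m: Match) -> bool:
        if not canonical_groups:
            return True
        bound = {pn.index: gn for pn, gn in m.node_map.items() if pn.is_generic}
        for group in canonical_groups:
            prev = None
            for idx in group:
                gn = bound.get(idx)
                if gn is None:
                    continue
                if prev is not None and gn <= prev:
                    return False
                prev = gn
        return True

    def extensions(m: Match) -> list[Match]:
        out = []
        for s in singles:
            if _compatible_with(m, s, counters):
                merged = merge(m, s, counters)
                if merged is not INCOMPATIBLE and canonical_ok(merged):
                    out.append(merged)
        return out

    stack = [s for s in seeds if canonical_ok(s)]
    while stack:
        m = stack.pop()
        if m.key in seen:
            continue
        seen.add(m.key)
        exts = extensions(m)
        if not exts:
            results.add(m)
            continue
        pivot = exts[0]
        branch = [pivot]
        pivot_single_nodes = pivot.node_map
        for other in exts[1:]:
            # incompatible with pivot: merging their additions conflicts
            if _branches_conflict(m, pivot, other):
                branch.append(other)
        stack.extend(branch)
    # a state expanded into extensions may still be maximal if every
    # extension was pruned canonically; handled above because pruned
    # extensions are not produced at all.
    return results


def _branches_conflict(base: Match, e1: Match, e2: Match) -> bool:
    """Whether the single-edge additions behind e1 and e2 exclude each other."""
    add1 = set(e1.edge_map) - set(base.edge_map)
    add2 = set(e2.edge_map) - set(base.edge_map)
    if add1 & add2:
        return True
    new1 = {pn: gn for pn, gn in e1.node_map.items()
            if base.node_map.get(pn) != gn}
    new2 = {pn: gn for pn, gn in e2.node_map.items()
            if base.node_map.get(pn) != gn}
    for pn, gn in new1.items():
        if pn in new2 and new2[pn] != gn:
            return True
    vals1 = set(new1.values()) | set(base.node_map.values())
    for pn, gn in new2.items():
        if pn not in new1 and pn not in base.node_map and gn in set(new1.values()):
            return True
    return False


def enumerate_maximal_matches(
    pattern: GraphPattern,
    graph: ContextGraph,
    min_kf: float = 0.5,
    counters: OpCounters | None = None,
    canonical_groups: Sequence[Sequence[int]] | None = None,
) -> set[Match]:
    """All maximal (partial or complete) matches with ``k_f >= min_kf``.

    Grown from single-edge seeds exactly like the continuous engine; a
    from-scratch reference for it and the everyday one-shot entry point.
    """
    if not (0.0 < min_kf <= 1.0):
        raise ValueError("min_kf must be in (0, 1]")
    singles = all_single_edge_matches(pattern, graph, counters)
    maximal = grow_to_maximal(singles, singles, counters, canonical_groups)
    return {m for m in maximal if score_kf(m) >= min_kf}


# ---------------------------------------------------------------------------
# Exhaustive oracle


BRUTE_FORCE_NODE_GUARD = 12


def brute_force_matches(
    pattern: GraphPattern,
    graph: ContextGraph,
) -> set[Match]:
    """Exhaustively enumerate all maximal partial matches (small graphs only).

    Independent of the growth algorithm: enumerates every subset of pattern
    edges together with every injective endpoint assignment, keeps the
    structurally valid connected candidates and filters to the maximal
    ones.  Guarded to graphs of at most ``BRUTE_FORCE_NODE_GUARD`` nodes.
    """
    if len(graph.nodes) > BRUTE_FORCE_NODE_GUARD:
        raise ValueError(
            f"brute_force_matches is limited to {BRUTE_FORCE_NODE_GUARD} nodes")
    pedges = pattern.edges
    gedges = list(graph.edges)
    candidates: set[Match] = set()

    def backtrack(i: int, edge_map: dict[int, tuple[str, str, str]],
                  node_map: dict[PatternNode, str]) -> None:
        if i == len(pedges):
            if edge_map and _connected(pattern, edge_map):
                candidates.add(Match(pattern, dict(edge_map), dict(node_map)))
            return
        # skip pattern edge i
        backtrack(i + 1, edge_map, node_map)
        pe = pedges[i]
        for ge in gedges:
            assign = _try_assign(pe, ge, node_map)
            if assign is None:
                continue
            edge_map[i] = ge.triple
            node_map.update(assign)
            backtrack(i + 1, edge_map, node_map)
            del edge_map[i]
            for pn in assign:
                del node_map[pn]

    backtrack(0, {}, {})
    # keep only maximal candidates: no other candidate strictly extends them
    by_key = list(candidates)
    maximal: set[Match] = set()
    for m in by_key:
        extended = False
        for m2 in by_key:
            if m2 is m or len(m2.edge_map) <= len(m.edge_map):
                continue
            if (m.edge_map.items() <= m2.edge_map.items()
                    and m.node_map.items() <= m2.node_map.items()):
                extended = True
                break
        if not extended:
            maximal.add(m)
    return maximal


def _try_assign(
    pe: PatternEdge,
    ge: ContextEdge,
    node_map: dict[PatternNode, str],
) -> dict[PatternNode, str] | None:
    """Bindings needed for pe -> ge given current node_map, or None."""
    if not pe.is_generic_label and pe.label != ge.label:
        return None
    if (pe.frm == pe.to) != (ge.frm == ge.to):
        return None
    new: dict[PatternNode, str] = {}
    taken = set(node_map.values())
    for pn, gn in ((pe.frm, ge.frm), (pe.to, ge.to)):
        if not pn.is_generic and pn.label != gn:
            return None
        have = node_map.get(pn, new.get(pn))
        if have is not None:
            if have != gn:
                return None
            continue
        if gn in taken or gn in new.values():
            return None  # injectivity
        new[pn] = gn
    return new


def _connected(pattern: GraphPattern, edge_map: dict[int, tuple]) -> bool:
    pedges = pattern.edges
    used = [pedges[i] for i in edge_map]
    if not used:
        return False
    nodes = {used[0].frm, used[0].to}
    remaining = used[1:]
    changed = True
    while changed and remaining:
        changed = False
        for e in list(remaining):
            if e.frm in nodes or e.to in nodes:
                nodes.update((e.frm, e.to))
                remaining.remove(e)
                changed = True
    return not remaining
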