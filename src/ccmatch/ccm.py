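"""Continuous Context Matching engine.

The engine owns a *shadow* context graph that changes only through
queued transactions.  Processing one transaction is one *sequence*:

1. if any edge has expired at the transaction's timestamp, an internal
   expiry transaction is applied first (its own sequence);
2. the transaction's changes are applied atomically to the shadow graph,
   and every per-pattern matching process updates its live match set
   incrementally;
3. the satisfied-pattern set is computed, timelines are stepped, actions
   (inferred edges) are decided and enqueued as inference transactions —
   visible from the next sequence, keeping the graph constant during one
   matching pass;
4. registered receivers are notified of qualifying new matches, each
   exactly once, after the sequence completes.

Each pattern's *matching process* maintains the set of maximal matches
together with two indexes — graph edge → matches containing it and
pattern edge → matches containing it — so that removing a graph edge
invalidates its matches in O(1) index lookups per pattern, and adding an
edge only does label comparisons against the pattern's edges before
growing the new single-edge matches by reference operations alone.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .actions import (
    ActionDecision,
    NameAllocator,
    apply_inference,
    decide_from_remainder,
    remainder_pattern,
)
from .context_model import (
    PERMANENT,
    Change,
    Clock,
    ContextEdge,
    ContextGraph,
    GraphPattern,
    Transaction,
)
from .matcher import (
    INCOMPATIBLE,
    Match,
    OpCounters,
    all_single_edge_matches,
    enumerate_maximal_matches,
    grow_to_maximal,
    initial_matches,
    merge,
    score_kf,
)
from .timeline import Timeline, TimelineNode

logger = logging.getLogger("ccmatch.ccm")


def _match_sort_key(m: Match):
    return (sorted(m.edge_map.items()),
            sorted((str(pn), gn) for pn, gn in m.node_map.items()))


def _subsumes(big: Match, small: Match, counters: OpCounters | None) -> bool:
    """Whether ``small`` is contained in ``big`` with consistent mappings."""
    if counters:
        counters.edge_ref_cmp += len(small.edge_map)
        counters.node_ref_cmp += len(small.node_map)
    return (small.edge_map.items() <= big.edge_map.items()
            and small.node_map.items() <= big.node_map.items())


class MatchingProcess:
    """Incremental maintenance of one pattern's maximal matches."""

    def __init__(
        self,
        pattern: GraphPattern,
        counters: OpCounters,
        canonical_groups: Sequence[Sequence[int]] | None = None,
    ) -> None:
        pattern.validate()
        self.pattern = pattern
        self.counters = counters
        self.canonical_groups = canonical_groups
        self.singles: dict[tuple, Match] = {}
        self.singles_by_edge: dict[tuple, list[Match]] = {}
        self.matches: dict[tuple, Match] = {}
        self.by_graph_edge: dict[tuple, set[tuple]] = {}
        self.by_pattern_edge: dict[int, set[tuple]] = {}
        self._new: list[Match] = []
        self._invalidated: list[Match] = []

    # -- bookkeeping -----------------------------------------------------

    def live(self) -> list[Match]:
        return list(self.matches.values())

    def _index_add(self, m: Match) -> None:
        self.matches[m.key] = m
        # indexing a match touches each of its edges by reference
        self.counters.edge_ref_cmp += 2 * len(m.edge_map)
        for triple in m.edge_map.values():
            self.by_graph_edge.setdefault(triple, set()).add(m.key)
        for i in m.edge_map:
            self.by_pattern_edge.setdefault(i, set()).add(m.key)
        self._new.append(m)

    def _index_remove(self, key: tuple) -> Match | None:
        m = self.matches.pop(key, None)
        if m is None:
            return None
        self.counters.edge_ref_cmp += 2 * len(m.edge_map)
        for triple in m.edge_map.values():
            self.by_graph_edge.get(triple, set()).discard(key)
        for i in m.edge_map:
            self.by_pattern_edge.get(i, set()).discard(key)
        self._invalidated.append(m)
        return m

    def take_deltas(self) -> tuple[list[Match], list[Match]]:
        new, inv = self._new, self._invalidated
        self._new, self._invalidated = [], []
        return new, inv

    # -- incremental updates --------------------------------------------

    def bootstrap(self, graph: ContextGraph) -> None:
        """Initialize from an existing graph (same code path as growth)."""
        for e in graph.edges:
            self.on_add(e, graph)

    def on_add(self, edge: ContextEdge, graph: ContextGraph | None = None) -> None:
        new_singles = initial_matches(self.pattern, edge, self.counters)
        if not new_singles:
            return
        for s in new_singles:
            self.counters.edge_ref_cmp += 1  # register in the single index
            self.singles[s.key] = s
            self.singles_by_edge.setdefault(edge.triple, []).append(s)
        all_singles = list(self.singles.values())
        grown = grow_to_maximal(new_singles, all_singles, self.counters,
                                self.canonical_groups)
        if not grown:
            return
        # previously maximal matches subsumed by a grown match are stale
        for key in list(self.matches):
            old = self.matches[key]
            if any(_subsumes(g, old, self.counters) for g in grown):
                self._index_remove(key)
        for g in grown:
            if g.key not in self.matches:
                self._index_add(g)

    def on_remove(self, triple: tuple) -> None:
        self.counters.edge_ref_cmp += 1  # index lookup for the edge
        for s in self.singles_by_edge.pop(triple, []):
            self.singles.pop(s.key, None)
        affected_keys = self.by_graph_edge.pop(triple, set())
        if not affected_keys:
            return
        remnants: list[Match] = []
        for key in list(affected_keys):
            m = self._index_remove(key)
            if m is None:
                continue
            remnants.extend(self._remnant_components(m, triple))
        if not remnants:
            return
        all_singles = list(self.singles.values())
        grown = grow_to_maximal(remnants, all_singles, self.counters,
                                self.canonical_groups)
        for g in grown:
            if g.key in self.matches:
                continue
            if any(_subsumes(m, g, self.counters)
                   for m in self.matches.values()):
                continue
            self._index_add(g)

    def _remnant_components(self, m: Match, gone: tuple) -> list[Match]:
        """Connected pieces of a match after one graph edge disappears."""
        keep = {i: t for i, t in m.edge_map.items() if t != gone}
        if not keep:
            return []
        pedges = self.pattern.edges
        unvisited = set(keep)
        out: list[Match] = []
        while unvisited:
            i0 = unvisited.pop()
            comp = {i0}
            nodes = {pedges[i0].frm, pedges[i0].to}
            changed = True
            while changed:
                changed = False
                for i in list(unvisited):
                    pe = pedges[i]
                    if pe.frm in nodes or pe.to in nodes:
                        comp.add(i)
                        nodes.update((pe.frm, pe.to))
                        unvisited.discard(i)
                        changed = True
            emap = {i: keep[i] for i in comp}
            nmap = {pn: m.node_map[pn] for pn in nodes}
            out.append(Match(self.pattern, emap, nmap))
        return out

    # -- correctness contract -------------------------------------------

    def check_against_scratch(self, graph: ContextGraph) -> None:
        """Assert the live set equals a from-scratch enumeration."""
        scratch = enumerate_maximal_matches(
            self.pattern, graph, min_kf=1e-12,
            canonical_groups=self.canonical_groups)
        live_keys = set(self.matches)
        scratch_keys = {m.key for m in scratch}
        if live_keys != scratch_keys:
            raise AssertionError(
                f"incremental/from-scratch divergence for pattern "
                f"{self.pattern.name!r}: {len(live_keys)} live vs "
                f"{len(scratch_keys)} from scratch")


class CompleteMatchingProcess(MatchingProcess):
    """Maintenance restricted to complete matches (``k = 0``).

    Wide counting patterns — many interchangeable generic branches hanging
    off one hub, like the pattern counting same-date log entries — have a
    combinatorial family of partial matches that carries no information:
    only the complete match (every branch filled) triggers anything.  This
    process skips partial maintenance entirely: when an edge is added, a
    backtracking search enumerates the complete matches that contain it
    (choosing the next pattern edge by bound endpoints, candidate graph
    edges via adjacency); when an edge is removed, the complete matches
    containing it simply die, since removing an edge can never complete a
    match.  Indexes and reporting behave exactly like the general process.
    """

    def on_add(self, edge: ContextEdge, graph: ContextGraph | None = None) -> None:
        new_singles = initial_matches(self.pattern, edge, self.counters)
        if not new_singles:
            return
        for s in new_singles:
            self.singles[s.key] = s
            self.singles_by_edge.setdefault(edge.triple, []).append(s)
            self._anchor_index(s, add=True)
        found: set[Match] = set()
        for seed in new_singles:
            self._complete(seed, found)
        for m in found:
            if self._canonical_ok(m) and m.key not in self.matches:
                self._index_add(m)

    def on_remove(self, triple: tuple) -> None:
        self.counters.edge_ref_cmp += 1
        for s in self.singles_by_edge.pop(triple, []):
            self.singles.pop(s.key, None)
            self._anchor_index(s, add=False)
        for key in list(self.by_graph_edge.pop(triple, set())):
            self._index_remove(key)

    def _anchor_index(self, s: Match, add: bool) -> None:
        """Index a single-edge match under (pattern edge, each graph node)."""
        if not hasattr(self, "_by_anchor"):
            self._by_anchor: dict[tuple, list[Match]] = {}
        (i,) = s.edge_map
        for gn in set(s.node_map.values()):
            self.counters.node_ref_cmp += 1
            bucket = self._by_anchor.setdefault((i, gn), [])
            if add:
                bucket.append(s)
            else:
                try:
                    bucket.remove(s)
                except ValueError:
                    pass

    def _canonical_ok(self, m: Match) -> bool:
        if not self.canonical_groups:
            return True
        bound = {pn.index: gn for pn, gn in m.node_map.items()
                 if pn.is_generic}
        for group in self.canonical_groups:
            prev = None
            for idx in group:
                gn = bound.get(idx)
                if gn is None:
                    continue
                if prev is not None and gn <= prev:
                    return False
                prev = gn
        return True

    def _complete(self, m: Match, found: set[Match]) -> None:
        pedges = self.pattern.edges
        missing = [i for i in range(len(pedges)) if i not in m.edge_map]
        if not missing:
            found.add(m)
            return
        if not self._canonical_partial_ok(m):
            return
        # most-constrained next edge: prefer one with both endpoints bound
        def boundness(i: int) -> int:
            pe = pedges[i]
            return ((pe.frm in m.node_map) + (pe.to in m.node_map))
        i = max(missing, key=boundness)
        if boundness(i) == 0:
            return  # disconnected pattern edge: cannot anchor the search
        pe = pedges[i]
        anchor = m.node_map.get(pe.frm) or m.node_map.get(pe.to)
        by_anchor = getattr(self, "_by_anchor", {})
        for s in by_anchor.get((i, anchor), ()):
            merged = merge(m, s, self.counters)
            if merged is not INCOMPATIBLE:
                self._complete(merged, found)

    def _canonical_partial_ok(self, m: Match) -> bool:
        if not self.canonical_groups:
            return True
        bound = {pn.index: gn for pn, gn in m.node_map.items()
                 if pn.is_generic}
        for group in self.canonical_groups:
            prev = None
            for idx in group:
                gn = bound.get(idx)
                if gn is None:
                    prev = None
                    continue
                if prev is not None and gn <= prev:
                    return False
                prev = gn
        return True

    def check_against_scratch(self, graph: ContextGraph) -> None:
        scratch = enumerate_maximal_matches(
            self.pattern, graph, min_kf=1e-12,
            canonical_groups=self.canonical_groups)
        m_s = len(self.pattern.edges)
        scratch_keys = {m.key for m in scratch if len(m.edge_map) == m_s}
        if set(self.matches) != scratch_keys:
            raise AssertionError(
                f"complete-match divergence for {self.pattern.name!r}")


@dataclass
class Notification:
    sequence: int
    now: int
    pattern: str
    match: Match
    k_f: float


@dataclass
class Receiver:
    callback: Callable[[Notification], None]
    patterns: set[str] | None  # None = all
    min_kf: float = 1.0


@dataclass
class SequenceReport:
    sequence: int
    now: int
    origin: str
    new_matches: dict[str, list[Match]] = field(default_factory=dict)
    invalidated: dict[str, list[Match]] = field(default_factory=dict)
    satisfied: set[str] = field(default_factory=set)
    fired: list[tuple[str, str]] = field(default_factory=list)  # (timeline, node)
    actions: list[dict] = field(default_factory=list)
    skipped_changes: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "sequence": self.sequence,
            "t": self.now,
            "origin": self.origin,
            "new_matches": {p: [sorted(m.edge_map.values()) for m in ms]
                            for p, ms in self.new_matches.items() if ms},
            "invalidated": {p: len(ms) for p, ms in self.invalidated.items()
                            if ms},
            "satisfied": sorted(self.satisfied),
            "fired": self.fired,
            "actions": self.actions,
        }, sort_keys=True)


@dataclass
class _PatternEntry:
    pattern: GraphPattern
    process: MatchingProcess
    auto_act: bool
    remainder: GraphPattern | None          # None = every edge actionable
    remainder_map: dict[int, int]
    remainder_process: MatchingProcess | None  # None = reuse main process
    has_actionable: bool

    def remainder_complete_matches(self) -> list[Match]:
        """Complete matches of the non-actionable remainder."""
        proc = self.remainder_process or self.process
        if self.remainder is None and self.remainder_process is None \
                and self.has_actionable:
            return []  # vacuous remainder handled by caller
        target = proc.pattern
        return sorted((m for m in proc.live()
                       if len(m.edge_map) == len(target.edges)),
                      key=_match_sort_key)


class CCM:
    """The continuous context matching platform for a single agent."""

    def __init__(
        self,
        clock: Clock | None = None,
        min_kf: float = 0.5,
        action_rule: str = "prose",
        debug_check: bool = False,
    ) -> None:
        self.clock = clock or Clock()
        self.graph = ContextGraph(self.clock)
        self.min_kf = min_kf
        self.action_rule = action_rule
        self.debug_check = debug_check
        self.counters = OpCounters()
        self.sequence = 0
        self.queue: deque[Transaction] = deque()
        self.patterns: dict[str, _PatternEntry] = {}
        self.timelines: list[Timeline] = []
        self.receivers: list[Receiver] = []
        self.names = NameAllocator()
        self.action_log: list[dict] = []
        self.reports: list[SequenceReport] = []
        self.keep_reports = True
        self._prev_satisfied: set[str] = set()
        self._applied_action_keys: dict[tuple, str] = {}
        self._pending_inferences: list[Transaction] = []

    # -- registration ----------------------------------------------------

    def register_pattern(
        self,
        pattern: GraphPattern,
        auto_act: bool = False,
        canonical_groups: Sequence[Sequence[int]] | None = None,
        maintain: str = "maximal",
    ) -> MatchingProcess:
        if pattern.name in self.patterns:
            raise ValueError(f"pattern {pattern.name!r} already registered")
        if maintain not in ("maximal", "complete"):
            raise ValueError("maintain must be 'maximal' or 'complete'")
        cls = MatchingProcess if maintain == "maximal" \
            else CompleteMatchingProcess
        proc = cls(pattern, self.counters, canonical_groups)
        proc.bootstrap(self.graph)
        has_act = any(e.actionable > 0.0 for e in pattern.edges)
        rem, rem_map, rem_proc = None, {}, None
        if has_act:
            rem, rem_map = remainder_pattern(pattern)
            if rem is not None:
                if not rem.is_connected():
                    raise ValueError(
                        f"pattern {pattern.name!r}: non-actionable remainder "
                        "must be connected")
                rem_proc = cls(rem, self.counters, canonical_groups)
                rem_proc.bootstrap(self.graph)
        entry = _PatternEntry(pattern, proc, auto_act, rem, rem_map,
                              rem_proc, has_act)
        self.patterns[pattern.name] = entry
        return proc

    def register_timeline(self, tl: Timeline) -> None:
        problems = tl.validate()
        if problems:
            raise ValueError(f"invalid timeline {tl.name!r}: "
                             + "; ".join(problems))
        self.timelines.append(tl)

    def register_receiver(
        self,
        callback: Callable[[Notification], None],
        patterns: Iterable[str] | None = None,
        min_kf: float = 1.0,
    ) -> Receiver:
        r = Receiver(callback, set(patterns) if patterns is not None else None,
                     min_kf)
        self.receivers.append(r)
        return r

    # -- transaction queue ----------------------------------------------

    def enqueue(self, txn: Transaction) -> int:
        for ch in txn.changes:
            if not ch.frm or not ch.to:
                raise ValueError("malformed change in transaction")
        self.queue.append(txn)
        return len(self.queue) - 1

    def submit(self, *changes: Change, at: int | None = None,
               origin: str = "perception") -> int:
        return self.enqueue(Transaction(list(changes), origin, at))

    # -- the sequence ----------------------------------------------------

    def _all_processes(self) -> list[MatchingProcess]:
        out = []
        for e in self.patterns.values():
            out.append(e.process)
            if e.remainder_process is not None:
                out.append(e.remainder_process)
        return out

    def process_one(self) -> SequenceReport:
        if not self.queue:
            raise RuntimeError("transaction queue is empty")
        head = self.queue[0]
        now = head.submitted_at if head.submitted_at is not None \
            else self.clock.now
        expired = [e for e in self.graph.edges
                   if e.expiry is not PERMANENT and e.expiry <= now]
        if expired:
            txn = Transaction(
                [Change("remove", e.frm, e.to, e.label) for e in expired],
                origin="expiry", submitted_at=now)
        else:
            txn = self.queue.popleft()
        self.clock.advance_to(now)
        self.sequence += 1
        report = SequenceReport(self.sequence, now, txn.origin)

        processes = self._all_processes()
        for ch in txn.changes:
            if ch.op == "add":
                if self.graph.get_edge(ch.frm, ch.to, ch.label) is not None:
                    logger.info("sequence %d: edge %s -%s-> %s already "
                                "present; skipped", self.sequence, ch.frm,
                                ch.label, ch.to)
                    report.skipped_changes += 1
                    continue
                edge = self.graph.add_edge(ch.frm, ch.to, ch.label, ch.expiry)
                for proc in processes:
                    proc.on_add(edge, self.graph)
            else:
                removed = self.graph.remove_edge(ch.frm, ch.to, ch.label)
                if removed is None:
                    report.skipped_changes += 1
                    continue
                for proc in processes:
                    proc.on_remove(removed.triple)

        if self.debug_check:
            for proc in processes:
                proc.check_against_scratch(self.graph)

        for name, entry in self.patterns.items():
            new, inv = entry.process.take_deltas()
            report.new_matches[name] = sorted(new, key=_match_sort_key)
            report.invalidated[name] = sorted(inv, key=_match_sort_key)
            if entry.remainder_process is not None:
                entry.remainder_process.take_deltas()

        satisfied = self._satisfied_set()
        report.satisfied = set(satisfied)

        self._pending_inferences: list[Transaction] = []
        self._step_timelines(satisfied, now, report)
        self._auto_actions(now, report)
        # inference effects become visible at the very next sequence
        self.queue.extendleft(reversed(self._pending_inferences))
        self._pending_inferences = []
        self._prune_action_keys()
        self._prev_satisfied = satisfied

        self._notify(report)
        if self.keep_reports:
            self.reports.append(report)
        return report

    def run(self, max_sequences: int | None = None) -> list[SequenceReport]:
        out = []
        while self.queue and (max_sequences is None
                              or len(out) < max_sequences):
            out.append(self.process_one())
        return out

    # -- satisfaction, timelines, actions -------------------------------

    def _satisfied_set(self) -> set[str]:
        """Names of patterns recognized this sequence.

        A pattern is satisfied when completely matched, or when only its
        actionable edges are missing and each is eligible at the current
        k_f (the situation is recognized well enough to be completed by
        the system itself).
        """
        out: set[str] = set()
        for name, entry in self.patterns.items():
            m_s = len(entry.pattern.edges)
            if any(len(m.edge_map) == m_s for m in entry.process.live()):
                out.add(name)
                continue
            if entry.has_actionable \
                    and self._best_decision(entry, probe=True) is not None:
                out.add(name)
        return out

    def _best_decision(self, entry: _PatternEntry,
                       probe: bool = False) -> ActionDecision | None:
        # probe decisions must not consume fresh-name counters
        names = NameAllocator() if probe else self.names
        if not entry.has_actionable:
            return None
        if entry.remainder is None:
            return decide_from_remainder(entry.pattern, {}, None,
                                         self.action_rule, names)
        for rm in entry.remainder_complete_matches():
            d = decide_from_remainder(entry.pattern, entry.remainder_map,
                                      rm, self.action_rule, names)
            if d is not None:
                return d
        return None

    def _step_timelines(self, satisfied: set[str], now: int,
                        report: SequenceReport) -> None:
        current = satisfied  # tokens emitted below become visible in-order
        for tl in self.timelines:
            fired = tl.step(current, self._prev_satisfied, now)
            for node in fired:
                report.fired.append((tl.name, node.id))
                if node.emits:
                    current.add(node.emits)
                entry = self.patterns.get(node.pattern_name)
                if entry is not None and entry.has_actionable:
                    d = self._best_decision(entry)
                    if d is not None:
                        self._apply_decision(d, now, report,
                                             source=f"timeline:{tl.name}")

    def _auto_actions(self, now: int, report: SequenceReport) -> None:
        for name, entry in self.patterns.items():
            if not entry.auto_act or not entry.has_actionable:
                continue
            if entry.remainder is None:
                continue  # an all-actionable pattern needs a timeline trigger
            for rm in entry.remainder_complete_matches():
                d = decide_from_remainder(entry.pattern, entry.remainder_map,
                                          rm, self.action_rule, self.names)
                if d is None:
                    continue
                key = (name, rm.key)
                if key in self._applied_action_keys:
                    continue
                self._applied_action_keys[key] = name
                self._apply_decision(d, now, report, source="pattern")

    def _apply_decision(self, decision: ActionDecision, now: int,
                        report: SequenceReport, source: str) -> None:
        txn = apply_inference(self.graph, decision, now)
        if not txn.changes:
            return
        self._pending_inferences.append(txn)
        for ch in txn.changes:
            rec = {
                "sequence": self.sequence,
                "t": now,
                "pattern": decision.match.pattern.name,
                "edge": [ch.frm, ch.label, ch.to],
                "k_f": round(score_kf(decision.match), 6)
                if decision.match.edge_map else 0.0,
                "source": source,
            }
            report.actions.append(rec)
            self.action_log.append(rec)

    def _prune_action_keys(self) -> None:
        dead = []
        for key in self._applied_action_keys:
            name = self._applied_action_keys[key]
            entry = self.patterns.get(name)
            if entry is None:
                dead.append(key)
                continue
            proc = entry.remainder_process or entry.process
            if key[1] not in proc.matches:
                dead.append(key)
        for key in dead:
            del self._applied_action_keys[key]

    # -- notifications ---------------------------------------------------

    def _notify(self, report: SequenceReport) -> None:
        for r in self.receivers:
            for pname, matches in report.new_matches.items():
                if r.patterns is not None and pname not in r.patterns:
                    continue
                for m in matches:
                    kf = score_kf(m)
                    if kf >= r.min_kf:
                        r.callback(Notification(report.sequence, report.now,
                                                pname, m, kf))
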