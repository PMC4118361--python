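"""Linear text representation of context graphs and patterns.

Graphs are written as trees of right-pointing edges; branches of a node
with several children are parenthesized except the last one, cycles and
cross-references use ``*``::

    A -> B -> C -> *A          a three-node cycle (unlabeled edges)
    A(-1->B)-2->C              root A, edge "1" to B, edge "2" to C

Grammar (the concrete syntax of this package):

* node name: any run of characters except ``( ) - > * ?`` and newline,
  trimmed; must be non-empty.
* edge: ``-label->`` with the empty (λ) label written ``->``.  In patterns
  a label may carry annotations, in this order: ``^<float>`` sets the
  characteristic weight, ``/<float>`` the actionable weight, e.g.
  ``-entry/3->`` or ``-near^0.5->``.  A generic edge label is ``?``.
* generic pattern node: ``?`` (fresh index) or ``?^<int>``; repeating
  ``?^<int>`` refers to the same node.
* reference to an already-introduced node: ``*name`` (or ``*?^<int>``); a
  tree may also be rooted at a reference so one document can cover any
  graph.
* a document is one or more whitespace-separated trees; ``#`` starts a
  comment line.

Serialization is deterministic (longest continuation first, ties and
side branches in lexicographic order) so equal graphs produce identical
text, and ``parse(serialize(g))`` reproduces ``g`` exactly.
"""

from __future__ import annotations

import re
from typing import Iterable

from .context_model import (
    GENERIC,
    LAMBDA,
    PERMANENT,
    ContextGraph,
    GraphPattern,
    PatternNode,
)

_NODE_STOP = set("()->*?\n")
_DURATION_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(ms|s|min|h)\s*$")
_DURATION_MS = {"ms": 1, "s": 1000, "min": 60_000, "h": 3_600_000}


class ParseError(ValueError):
    def __init__(self, message: str, pos: int) -> None:
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


def parse_duration(text: str) -> int | None:
    """``"5min"`` -> logical ms; ``"permanent"`` -> PERMANENT."""
    if text.strip().lower() == "permanent":
        return PERMANENT
    m = _DURATION_RE.match(text)
    if not m:
        raise ValueError(f"bad duration {text!r}: use <n>ms|s|min|h")
    return int(float(m.group(1)) * _DURATION_MS[m.group(2)])


class _Parser:
    def __init__(self, text: str, kind: str) -> None:
        if kind not in ("graph", "pattern"):
            raise ValueError("kind must be 'graph' or 'pattern'")
        self.kind = kind
        self.text = "\n".join(
            line for line in text.splitlines()
            if not line.lstrip().startswith("#"))
        self.i = 0
        self.next_generic = 1
        if kind == "graph":
            self.out: ContextGraph | GraphPattern = ContextGraph()
        else:
            self.out = GraphPattern("anonymous")
        self.introduced: set[str] = set()   # concrete node labels seen
        self.generic_nodes: dict[int, PatternNode] = {}

    # -- scanning --------------------------------------------------------

    def _ws(self) -> None:
        while self.i < len(self.text) and self.text[self.i] in " \t\n\r":
            self.i += 1

    def peek(self) -> str:
        return self.text[self.i] if self.i < len(self.text) else ""

    def error(self, msg: str) -> ParseError:
        return ParseError(msg, self.i)

    # -- productions -----------------------------------------------------

    def parse(self):
        self._ws()
        while self.peek():
            root = self.parse_node(allow_ref_root=True)
            self.parse_tail(root)
            self._ws()
        if isinstance(self.out, GraphPattern):
            self.out.validate()
        return self.out

    def parse_node(self, allow_ref_root: bool = False):
        """Returns a node handle: str for graphs, PatternNode for patterns."""
        self._ws()
        c = self.peek()
        if c == "*":
            self.i += 1
            return self._resolve_reference()
        if c == "?":
            if self.kind == "graph":
                raise self.error("generic node '?' not allowed in a graph")
            return self._generic_node()
        name = self._scan_name()
        if self.kind == "graph":
            self.out.add_node(name)  # type: ignore[union-attr]
            self.introduced.add(name)
            return name
        if name in self.introduced:
            raise self.error(
                f"node {name!r} introduced twice; use '*{name}' to refer back")
        self.introduced.add(name)
        return self.out.node(name)  # type: ignore[union-attr]

    def _scan_name(self) -> str:
        start = self.i
        while self.i < len(self.text) and self.text[self.i] not in _NODE_STOP:
            self.i += 1
        name = self.text[start:self.i].strip()
        if not name:
            raise self.error("expected a node name")
        return name

    def _generic_node(self) -> PatternNode:
        assert self.peek() == "?"
        self.i += 1
        if self.peek() == "^":
            self.i += 1
            start = self.i
            while self.peek().isdigit():
                self.i += 1
            if start == self.i:
                raise self.error("expected an index after '?^'")
            idx = int(self.text[start:self.i])
        else:
            idx = self.next_generic
        self.next_generic = max(self.next_generic, idx + 1)
        if idx not in self.generic_nodes:
            self.generic_nodes[idx] = self.out.generic(idx)  # type: ignore
        return self.generic_nodes[idx]

    def _resolve_reference(self):
        if self.peek() == "?":
            self.i += 1
            if self.peek() != "^":
                raise self.error("generic reference must be '*?^<int>'")
            self.i += 1
            start = self.i
            while self.peek().isdigit():
                self.i += 1
            idx = int(self.text[start:self.i])
            if idx not in self.generic_nodes:
                raise self.error(f"dangling reference '*?^{idx}'")
            return self.generic_nodes[idx]
        name = self._scan_name()
        if name not in self.introduced:
            raise self.error(f"dangling reference '*{name}'")
        if self.kind == "graph":
            return name
        return self.out.node(name)  # type: ignore[union-attr]

    def parse_tail(self, node) -> None:
        """Zero or more branches and a continuation hanging off ``node``."""
        while True:
            self._ws()
            c = self.peek()
            if c == "(":
                self.i += 1
                self.parse_edge_and_subtree(node)
                self._ws()
                if self.peek() != ")":
                    raise self.error("unbalanced parenthesis: expected ')'")
                self.i += 1
            elif c == "-":
                self.parse_edge_and_subtree(node)
                return
            else:
                return

    def parse_edge_and_subtree(self, source) -> None:
        self._ws()
        if self.peek() != "-":
            raise self.error("expected an edge '-label->'")
        end = self.text.find("->", self.i)
        if end < 0:
            raise self.error("unterminated edge: missing '->'")
        raw = self.text[self.i + 1:end].strip()
        if any(ch in raw for ch in "()"):
            raise self.error(f"malformed edge label {raw!r}")
        self.i = end + 2
        label, characteristic, actionable = self._split_annotations(raw)
        target = self.parse_node()
        if self.kind == "graph":
            self.out.add_edge(source, target, label)  # type: ignore
        else:
            self.out.add_edge(source, target, label,  # type: ignore
                              characteristic=characteristic,
                              actionable=actionable)
        self.parse_tail(target)

    def _split_annotations(self, raw: str) -> tuple[str, float, float]:
        actionable = 0.0
        characteristic = 1.0
        if "/" in raw:
            raw, _, act = raw.rpartition("/")
            try:
                actionable = float(act)
            except ValueError:
                raise self.error(f"bad actionable annotation /{act!r}")
        if "^" in raw:
            raw, _, ch = raw.rpartition("^")
            try:
                characteristic = float(ch)
            except ValueError:
                raise self.error(f"bad characteristic annotation ^{ch!r}")
        if (actionable or characteristic != 1.0) and self.kind == "graph":
            raise self.error("weight annotations are only allowed in patterns")
        label = raw.strip()
        if label == GENERIC:
            if self.kind == "graph":
                raise self.error("generic edge label '?' not allowed in a graph")
            return GENERIC, characteristic, actionable
        return label, characteristic, actionable


def parse(text: str, kind: str = "graph"):
    """Parse a textual document into a :class:`ContextGraph` or
    :class:`GraphPattern` according to ``kind``."""
    return _Parser(text, kind).parse()


def parse_pattern(text: str, name: str = "anonymous",
                  persistence: int | None = PERMANENT) -> GraphPattern:
    pat = parse(text, "pattern")
    pat.name = name
    pat.persistence = persistence
    return pat


# ---------------------------------------------------------------------------
# Serialization


def _fmt_weight(x: float) -> str:
    s = f"{x:g}"
    return s


def _edge_text(label: str, characteristic: float = 1.0,
               actionable: float = 0.0) -> str:
    if label == LAMBDA and characteristic == 1.0 and actionable == 0.0:
        return " -> "
    body = label
    if characteristic != 1.0:
        body += f"^{_fmt_weight(characteristic)}"
    if actionable != 0.0:
        body += f"/{_fmt_weight(actionable)}"
    return f"-{body}->"


def serialize(obj: ContextGraph | GraphPattern) -> str:
    """Deterministic linearization; ``parse(serialize(g))`` equals ``g``.

    The continuation of each node is the branch that covers the most not
    yet emitted edges (ties broken lexicographically last, matching the
    longest-path style of the format); other branches are parenthesized in
    lexicographic order of (edge label, target).
    """
    if isinstance(obj, GraphPattern):
        return _serialize_pattern(obj)
    return _serialize_graph(obj)


def _serialize_graph(graph: ContextGraph) -> str:
    edges = [(e.frm, e.to, e.label, 1.0, 0.0) for e in graph.edges]
    nodes = set(graph.nodes)
    return _linearize(nodes, edges, name_of=lambda n: n)


def _serialize_pattern(pattern: GraphPattern) -> str:
    edges = [(e.frm, e.to, e.label, e.characteristic, e.actionable)
             for e in pattern.edges]
    nodes = set(pattern.nodes)
    return _linearize(nodes, edges, name_of=str)


def _linearize(nodes: set, edges: list, name_of) -> str:
    unused: set[int] = set(range(len(edges)))
    out_by_node: dict = {}
    in_deg: dict = {n: 0 for n in nodes}
    for i, (f, t, *_rest) in enumerate(edges):
        out_by_node.setdefault(f, []).append(i)
        in_deg[t] = in_deg.get(t, 0) + 1
    visited: set = set()
    parts: list[str] = []

    def reach_count(start) -> int:
        # number of unused edges reachable from start; continuation metric
        seen_n = {start}
        count = 0
        frontier = [start]
        while frontier:
            n = frontier.pop()
            for i in out_by_node.get(n, ()):
                if i in unused:
                    count += 1
                    t = edges[i][1]
                    if t not in seen_n:
                        seen_n.add(t)
                        frontier.append(t)
        return count

    def branch_key(i: int):
        f, t, label, ch, act = edges[i]
        return (_edge_text(label, ch, act), name_of(t))

    def emit_node(n, buf: list[str]) -> None:
        if n in visited:
            buf.append("*" + name_of(n))
            return
        visited.add(n)
        buf.append(name_of(n))
        emit_tail(n, buf)

    def emit_tail(n, buf: list[str]) -> None:
        while True:
            pending = sorted((i for i in out_by_node.get(n, ()) if i in unused),
                             key=branch_key)
            if not pending:
                return
            # continuation: most onward coverage, lexicographically last tie
            def cont_key(i: int):
                t = edges[i][1]
                onward = 0 if t in visited else reach_count(t)
                return (onward, branch_key(i))
            cont = max(pending, key=cont_key)
            for i in pending:
                if i == cont:
                    continue
                unused.discard(i)
                f, t, label, ch, act = edges[i]
                sub: list[str] = [_edge_text(label, ch, act)]
                emit_node(t, sub)
                buf.append("(" + "".join(sub) + ")")
            unused.discard(cont)
            f, t, label, ch, act = edges[cont]
            buf.append(_edge_text(label, ch, act))
            if t in visited:
                buf.append("*" + name_of(t))
                return
            visited.add(t)
            buf.append(name_of(t))
            n = t

    while unused or (nodes - visited):
        candidates = sorted(
            (n for n in nodes
             if any(i in unused for i in out_by_node.get(n, ()))),
            key=name_of)
        if candidates:
            fresh_roots = [n for n in candidates if n not in visited]
            roots = [n for n in fresh_roots
                     if not _has_unused_in(n, edges, unused)]
            if roots:
                start = roots[0]
            elif fresh_roots:
                start = fresh_roots[0]
            else:
                start = candidates[0]
            buf: list[str] = []
            emit_node(start, buf)
            parts.append("".join(buf))
        else:
            # isolated nodes with no edges at all
            for n in sorted(nodes - visited, key=name_of):
                visited.add(n)
                parts.append(name_of(n))
            break
    return "\n".join(parts)


def _has_unused_in(n, edges, unused) -> bool:
    return any(edges[i][1] == n for i in unused)


# ---------------------------------------------------------------------------
# File I/O (.ctg graphs, .ctp patterns)


def load_pattern_file(path, name: str | None = None) -> GraphPattern:
    """Read a ``.ctp`` file: ``#`` comments, optional ``@persistence <dur>``
    directive, then one pattern document."""
    import pathlib

    p = pathlib.Path(path)
    persistence = PERMANENT
    body: list[str] = []
    for line in p.read_text(encoding="utf-8").splitlines():
        stripped = line.strip()
        if stripped.startswith("@persistence"):
            persistence = parse_duration(stripped.split(None, 1)[1])
        else:
            body.append(line)
    return parse_pattern("\n".join(body), name or p.stem, persistence)


def load_graph_file(path) -> ContextGraph:
    import pathlib

    return parse(pathlib.Path(path).read_text(encoding="utf-8"), "graph")


def save(obj, path) -> None:
    import pathlib

    pathlib.Path(path).write_text(serialize(obj) + "\n", encoding="utf-8")
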