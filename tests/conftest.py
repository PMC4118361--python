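import random

import pytest

from ccmatch import ContextGraph, GraphConstraintError, GraphPattern, PatternNode
from ccmatch.scenario_sim import (
    ActivitySchedule,
    DayConfig,
    ScheduleEntry,
    build_engine,
    emit_events,
    trace_from_reports,
)

LABELS = ("", "r", "s", "is-in")
PATTERN_LABELS = ("", "r", "s", "?")


def random_graph(rng: random.Random, n_nodes: int, n_edges: int) -> ContextGraph:
    g = ContextGraph()
    names = [f"N{i}" for i in range(n_nodes)]
    for _ in range(30 * n_edges + 30):
        if len(g) >= n_edges:
            break
        f, t = rng.choice(names), rng.choice(names)
        if f == t:
            continue
        try:
            g.add_edge(f, t, rng.choice(LABELS))
        except GraphConstraintError:
            pass
    return g


def random_pattern(rng: random.Random, n_edges: int,
                   n_generic: int) -> GraphPattern | None:
    """A random connected pattern, or None if the dice never produced one."""
    p = GraphPattern("random")
    pool = [PatternNode(f"N{i}") for i in range(5)]
    pool += [PatternNode("?", i + 1) for i in range(n_generic)]
    for _ in range(40 * n_edges + 40):
        if len(p.edges) >= n_edges:
            break
        if p.edges:
            anchored = [e.frm for e in p.edges] + [e.to for e in p.edges]
            f = rng.choice(anchored)  # stay connected
        else:
            f = rng.choice(pool)
        t = rng.choice(pool)
        if f == t:
            continue
        if rng.random() < 0.5:
            f, t = t, f
        lab = rng.choice(PATTERN_LABELS)
        if any(e.frm == f and e.to == t and e.label == lab for e in p.edges):
            continue
        p.add_edge(f, t, lab,
                   characteristic=rng.choice([1.0, 0.9, 0.5]))
    if not p.edges or not p.is_connected():
        return None
    return p


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20140625)


@pytest.fixture
def shopping_pattern() -> GraphPattern:
    """The going-out-for-shopping situation: four associations."""
    p = GraphPattern("going out for shopping")
    p.add_edge("Emily", "city clothes", "is-dressed-in")
    p.add_edge("Emily", "wallet", "has")
    p.add_edge("Emily", "keys", "has")
    p.add_edge("Emily", "shopping bag", "has")
    return p


def run_script(entries: list[ScheduleEntry], cfg: DayConfig | None = None,
               until: int | None = None):
    """Drive the scenario engine over a handcrafted schedule."""
    cfg = cfg or DayConfig(milk_episode=None, night_visit_prob=0.0)
    engine = build_engine(cfg)
    txns = emit_events(ActivitySchedule(0, entries), cfg=cfg)
    if until is not None:
        txns = [t for t in txns if t.submitted_at <= until]
    for t in txns:
        engine.enqueue(t)
    engine.run()
    return engine, trace_from_reports(engine.reports)
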