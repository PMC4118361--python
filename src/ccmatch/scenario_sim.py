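"""Synthetic ambient-assisted-living scenario: one day of a single person
(Emily) in a four-zone studio apartment, watched by three location sensors
(living room, hall, kitchen — none in the bathroom), a bathroom-door
proximity indicator and RFID readers (apartment door, fridge, kitchen
door, trash).

The module provides:

* :func:`generate_day` — a seeded activity schedule (sleeping, meals,
  bathroom, shower, wandering, idle) with per-activity duration ranges and
  a meal hazard that is zero for three hours after a meal and then ramps
  up; showers are uninterruptible, meals are interrupted-and-resumed by
  bathroom visits, wandering is simply dropped.
* :func:`emit_events` — the sensor-level transaction stream for a
  schedule: location edges, the near-bathroom indication, the
  detection-status edge while Emily is invisible to the sensors, fridge /
  trash RFID events for the milk scenario, and one engine tick per minute
  so time-based timeline rules can fire between sensor events.
* :func:`build_engine` — a CCM engine loaded with the initial context
  graph (apartment, objects, dates) and the bathroom and milk scenarios'
  patterns and timelines.
* :func:`evaluate` — comparison of the engine's detections with the
  generated ground truth, including the two confusion classes this sensor
  set cannot avoid (shower vs. bathroom, kitchen-sitting vs. meal).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace

from .ccm import CCM, SequenceReport
from .context_model import (
    PERMANENT,
    Change,
    GraphPattern,
    PatternNode,
    Transaction,
    duration,
)
from .timeline import Rule, Timeline, TimelineEdge, TimelineNode

logger = logging.getLogger("ccmatch.scenario")

MIN = duration(min=1)
HOUR = duration(h=1)

EMILY = "Emily"
ZONES = ("Living Room", "Hall", "Kitchen", "Bathroom")

ACTIVITIES = ("sleeping", "meal", "bathroom", "shower", "wander", "idle")


@dataclass(frozen=True)
class ApartmentLayout:
    """Zones and (purely descriptive) sensor placement."""

    zones: tuple[str, ...] = ZONES
    location_sensors: tuple[str, ...] = ("Living Room", "Hall", "Kitchen")
    proximity_indicator: str = "Bathroom"
    rfid_readers: tuple[str, ...] = ("apartment door", "fridge",
                                     "kitchen door", "trash")

    def __post_init__(self) -> None:
        assert "Bathroom" not in self.location_sensors, \
            "there is no location sensor in the bathroom"


@dataclass
class DayConfig:
    """Study conditions for one simulated day (all durations logical ms)."""

    wake: int = 7 * HOUR
    bed: int = 22 * HOUR
    # meals: none for 3 h after the last one, then the hazard ramps and a
    # meal is forced before the gap reaches 5.5 h; 2-3 meals per day result
    meal_gap_min: int = 3 * HOUR
    meal_gap_ramp: int = 2 * HOUR
    meal_gap_max: int = int(5.5 * HOUR)
    meal_latest: int = int(20.5 * HOUR)
    max_meals: int = 3
    meal_duration: tuple[int, int] = (20 * MIN, 40 * MIN)
    meal_interrupt_prob: float = 0.25
    bathroom_duration: tuple[int, int] = (3 * MIN, 10 * MIN)
    bathroom_weight: float = 0.5
    shower_duration: tuple[int, int] = (15 * MIN, 25 * MIN)
    shower_prob: float = 0.7
    wander_duration: tuple[int, int] = (5 * MIN, 20 * MIN)
    wander_weight: float = 0.5
    idle_duration: tuple[int, int] = (10 * MIN, 40 * MIN)
    idle_weight: float = 0.9
    idle_kitchen_prob: float = 0.35  # sitting at the kitchen window
    night_visit_prob: float = 0.5
    forced_bathroom_at: tuple[int, ...] = ()  # deterministic test hook
    allow_interruptions: bool = True
    # event emission
    near_door_lead: int = 20_000        # near-bathroom indication before entry
    transit_time: int = 20_000          # living-room transit after the bathroom
    tick_every: int = 60_000            # engine heartbeat
    # milk scenario episode: None, or (start, outcome, delay) with outcome
    # in {"trash", "return", "forgot"}
    milk_episode: tuple[int, str, int] | None = (14 * HOUR, "trash", 10 * MIN)
    # recognition settings
    short_visit_max: int = 5 * MIN
    emergency_after: int = 1 * HOUR
    many_visits_threshold: int = 8
    food_out_after: int = 30 * MIN


@dataclass
class ScheduleEntry:
    activity: str
    start: int
    end: int
    zone: str
    interrupted_by: str | None = None  # activity that cut this tile short

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class ActivitySchedule:
    seed: int
    entries: list[ScheduleEntry]

    def tiles(self, activity: str) -> list[ScheduleEntry]:
        return [e for e in self.entries if e.activity == activity]


@dataclass
class GroundTruth:
    """Expected detections, derived deterministically from the schedule."""

    bathroom_visits: list[tuple[int, int]]   # includes night visits
    showers: list[tuple[int, int]]
    meals: list[tuple[int, int]]             # interruption-merged intervals
    kitchen_idle: list[tuple[int, int]]      # idle spent at the kitchen window
    short_visits: list[tuple[int, int]]      # bathroom visits under the limit


def _zone_for(activity: str, rng: random.Random, cfg: DayConfig) -> str:
    if activity in ("bathroom", "shower"):
        return "Bathroom"
    if activity == "meal":
        return "Kitchen"
    if activity == "sleeping":
        return "Living Room"
    if activity == "idle":
        return "Kitchen" if rng.random() < cfg.idle_kitchen_prob \
            else "Living Room"
    return "Hall"  # wandering is represented by zone hopping from the hall


def generate_day(seed: int, cfg: DayConfig | None = None
                 ) -> tuple[ActivitySchedule, GroundTruth]:
    """One reproducible 24-hour schedule honoring the activity rules."""
    cfg = cfg or DayConfig()
    if not (0 < cfg.wake < cfg.bed <= 24 * HOUR):
        raise ValueError("infeasible day boundaries")
    for lo, hi in (cfg.meal_duration, cfg.bathroom_duration,
                   cfg.shower_duration, cfg.wander_duration,
                   cfg.idle_duration):
        if not (0 < lo <= hi) or hi > cfg.bed - cfg.wake:
            raise ValueError("infeasible activity duration range")
    rng = random.Random(seed)
    entries: list[ScheduleEntry] = []

    # night: sleep from midnight, with an optional bathroom visit
    night_visit = rng.random() < cfg.night_visit_prob
    if night_visit:
        nv_start = int(rng.uniform(2 * HOUR, 5 * HOUR))
        nv_len = rng.randint(*cfg.bathroom_duration)
        entries.append(ScheduleEntry("sleeping", 0, nv_start, "Living Room",
                                     interrupted_by="bathroom"))
        entries.append(ScheduleEntry("bathroom", nv_start, nv_start + nv_len,
                                     "Bathroom"))
        entries.append(ScheduleEntry("sleeping", nv_start + nv_len, cfg.wake,
                                     "Living Room"))
    else:
        entries.append(ScheduleEntry("sleeping", 0, cfg.wake, "Living Room"))

    t = cfg.wake
    last_meal = cfg.wake - 2 * HOUR
    meals = 0
    had_shower = False
    first = True
    while t < cfg.bed:
        gap = t - last_meal
        if meals < cfg.max_meals and t <= cfg.meal_latest \
                and gap >= cfg.meal_gap_max:
            activity = "meal"  # the hazard has saturated: Emily is hungry
        elif first and rng.random() < 0.8:
            activity = "bathroom"  # morning routine
        else:
            weights = {
                "meal": 0.0,
                "bathroom": cfg.bathroom_weight,
                "shower": cfg.shower_prob
                if (not had_shower and t < 12 * HOUR) else 0.0,
                "wander": cfg.wander_weight,
                "idle": cfg.idle_weight,
            }
            if meals < cfg.max_meals and t <= cfg.meal_latest \
                    and gap > cfg.meal_gap_min:
                ramp = (gap - cfg.meal_gap_min) / cfg.meal_gap_ramp
                weights["meal"] = 3.0 * min(1.0, ramp)
            total = sum(weights.values())
            pick = rng.uniform(0, total)
            acc = 0.0
            activity = "idle"
            for a, w in weights.items():
                acc += w
                if pick <= acc:
                    activity = a
                    break
        first = False
        dur_range = getattr(cfg, f"{activity}_duration")
        length = rng.randint(*dur_range)
        end = min(t + length, cfg.bed)
        zone = _zone_for(activity, rng, cfg)
        if activity == "meal":
            meals += 1
            last_meal = end
            if cfg.allow_interruptions and end - t > 10 * MIN \
                    and rng.random() < cfg.meal_interrupt_prob:
                # a bathroom visit interrupts the meal; the meal resumes
                cut = t + int(rng.uniform(5 * MIN, (end - t) - 3 * MIN))
                bl = rng.randint(*cfg.bathroom_duration)
                entries.append(ScheduleEntry("meal", t, cut, zone,
                                             interrupted_by="bathroom"))
                entries.append(ScheduleEntry("bathroom", cut, cut + bl,
                                             "Bathroom"))
                end = min(end + bl, cfg.bed)
                entries.append(ScheduleEntry("meal", cut + bl, end, zone))
                last_meal = end
                t = end
                continue
        if activity == "shower":
            had_shower = True
        entries.append(ScheduleEntry(activity, t, end, zone))
        t = end
    entries.append(ScheduleEntry("sleeping", cfg.bed, 24 * HOUR,
                                 "Living Room"))

    entries = _apply_forced_bathroom(entries, cfg, rng)
    return ActivitySchedule(seed, entries), _derive_truth(entries, cfg)


def _apply_forced_bathroom(entries: list[ScheduleEntry], cfg: DayConfig,
                           rng: random.Random) -> list[ScheduleEntry]:
    """Insert externally forced bathroom visits (test hook), honoring
    interruptibility: meals resume, wander/idle are dropped, showers are
    never interrupted — the visit is deferred until the shower ends."""
    for ft in cfg.forced_bathroom_at:
        length = cfg.bathroom_duration[0]
        idx = next((i for i, e in enumerate(entries)
                    if e.start <= ft < e.end), None)
        if idx is None:
            continue
        tile = entries[idx]
        if tile.activity in ("shower", "bathroom") \
                or not cfg.allow_interruptions:
            ft = tile.end  # deferred: uninterruptible activity in progress
            idx += 1
        tile = entries[idx - 1] if idx > 0 else None
        visit = ScheduleEntry("bathroom", ft, ft + length, "Bathroom")
        out: list[ScheduleEntry] = []
        for i, e in enumerate(entries):
            if not (e.start <= ft < e.end or (ft == e.start and i == idx)):
                out.append(e)
                continue
            if e.activity in ("meal", "sleeping"):
                if ft > e.start:
                    out.append(replace(e, end=ft, interrupted_by="bathroom"))
                out.append(visit)
                if e.end > ft + length or e.activity == "sleeping":
                    out.append(replace(e, start=ft + length,
                                       end=max(e.end, ft + length)))
            else:  # wander/idle: dropped, not resumed
                if ft > e.start:
                    out.append(replace(e, end=ft, interrupted_by="bathroom"))
                out.append(visit)
        # shift is intentionally not propagated: the forced visit overlays
        # the tail of the interrupted tile
        entries = sorted(out, key=lambda e: e.start)
    return entries


def _derive_truth(entries: list[ScheduleEntry], cfg: DayConfig) -> GroundTruth:
    bathroom = [(e.start, e.end) for e in entries if e.activity == "bathroom"]
    showers = [(e.start, e.end) for e in entries if e.activity == "shower"]
    kitchen_idle = [(e.start, e.end) for e in entries
                    if e.activity == "idle" and e.zone == "Kitchen"]
    meals: list[tuple[int, int]] = []
    for e in entries:
        if e.activity != "meal":
            continue
        if meals and abs(meals[-1][1] - e.start) <= cfg.bathroom_duration[1]:
            meals[-1] = (meals[-1][0], e.end)  # resumed after interruption
        else:
            meals.append((e.start, e.end))
    short = [(s, t) for s, t in bathroom if t - s < cfg.short_visit_max]
    return GroundTruth(bathroom, showers, meals, kitchen_idle, short)


# ---------------------------------------------------------------------------
# Initial context graph and event emission


def initial_context_graph_transaction(cfg: DayConfig | None = None,
                                      date: str = "day-1") -> Transaction:
    """The agent's startup beliefs: apartment layout, sensors, objects,
    people and the current-date device, as one perception transaction."""
    txn = Transaction(origin="perception", submitted_at=0)
    for z in ZONES:
        txn.add("Apartment", z, "contains")
    for z in ("Living Room", "Hall", "Kitchen"):
        txn.add(f"sensor {z}", z, "covers")
    txn.add("proximity indicator", "Bathroom", "covers")
    for r in ("apartment door", "fridge", "kitchen door", "trash"):
        txn.add(f"RFID {r}", r.title() if r == "trash" else r, "reads")
    txn.add(EMILY, "Person", "isa")
    txn.add(EMILY, "Living Room", "is-in")
    txn.add("System", "System Log", "")
    for a in ("Sleeping", "Meal", "Bathroom visit", "Shower", "Wandering"):
        txn.add(a, "Activity", "isa")
    txn.add("Fridge", "Kitchen", "is-in")
    txn.add("Trash", "Kitchen", "is-in")
    for crate in ("crate1", "crate2"):
        txn.add("Fridge", crate, "contains")
        txn.add(crate, "Milk", "is")
    txn.add("Shopping List", "System", "kept-by")
    txn.add(date, "today", "")
    return txn


def emit_events(schedule: ActivitySchedule,
                layout: ApartmentLayout | None = None,
                cfg: DayConfig | None = None) -> list[Transaction]:
    """Sensor-level transaction stream for a schedule.

    Location sensing emits ``Emily -is-in-> zone`` edges, replacing the
    previous one atomically.  The bathroom has no sensor: entering it
    emits a near-door indication shortly before, then the loss of
    detection; leaving it puts Emily back in the living room (the zone the
    bathroom door opens into) for a short transit before the next
    activity's zone.  Engine ticks are emitted every minute.
    """
    cfg = cfg or DayConfig()
    layout = layout or ApartmentLayout()
    txns: list[Transaction] = []
    current_zone = "Living Room"
    hidden = False

    def at(t: int) -> Transaction:
        txn = Transaction(origin="perception", submitted_at=t)
        txns.append(txn)
        return txn

    def move(t: int, zone: str) -> None:
        nonlocal current_zone, hidden
        if hidden or zone != current_zone:
            txn = at(t)
            if hidden:
                txn.remove("System", "not detected", "detection-status")
                hidden = False
            else:
                txn.remove(EMILY, current_zone, "is-in")
            txn.add(EMILY, zone, "is-in")
            current_zone = zone

    def enter_bathroom(t: int) -> None:
        nonlocal current_zone, hidden
        at(max(0, t - cfg.near_door_lead)).add(EMILY, "Bathroom", "near")
        txn = at(t)
        txn.remove(EMILY, "Bathroom", "near")
        txn.remove(EMILY, current_zone, "is-in")
        txn.add("System", "not detected", "detection-status")
        hidden = True

    for e in schedule.entries:
        if e.activity in ("bathroom", "shower"):
            enter_bathroom(e.start)
            # exit into the living room, brief transit
            move(e.end, "Living Room")
            current_zone = "Living Room"
        elif e.activity == "wander":
            # hop through the zones with a location sensor
            hops = ["Hall", "Kitchen", "Hall", "Living Room"]
            step = max(30_000, e.duration // (len(hops) + 1))
            tt = e.start
            for z in hops:
                if tt >= e.end:
                    break
                move(tt, z)
                tt += step
        else:
            start = e.start
            if txns and txns[-1].submitted_at == e.start \
                    and current_zone == "Living Room" and e.zone != "Living Room":
                start = e.start + cfg.transit_time  # transit after a bathroom
            move(start, e.zone)

    if cfg.milk_episode is not None:
        t0, outcome, delay = cfg.milk_episode
        at(t0).remove("Fridge", "crate1", "contains")
        if outcome == "trash":
            at(t0 + delay).add("Trash", "crate1", "contains")
        elif outcome == "return":
            at(t0 + delay).add("Fridge", "crate1", "contains")
        elif outcome != "forgot":
            raise ValueError(f"unknown milk outcome {outcome!r}")

    for t in range(0, 24 * HOUR + 1, cfg.tick_every):
        txns.append(Transaction([], origin="perception", submitted_at=t))
    txns.sort(key=lambda x: (x.submitted_at, 0 if x.changes else 1))
    return txns


# ---------------------------------------------------------------------------
# Scenario patterns and timelines


def _pat(name: str, persistence=PERMANENT) -> GraphPattern:
    return GraphPattern(name, persistence)


def scenario_patterns(cfg: DayConfig | None = None) -> dict[str, dict]:
    """The bathroom and milk scenarios' patterns with their registration
    options (``auto_act``, ``canonical_groups``)."""
    cfg = cfg or DayConfig()
    out: dict[str, dict] = {}

    p = _pat("near bathroom")
    p.add_edge(EMILY, "Bathroom", "near")
    out[p.name] = {"pattern": p}

    p = _pat("not detected")
    p.add_edge("System", "not detected", "detection-status")
    out[p.name] = {"pattern": p}

    p = _pat("out of bathroom")
    p.add_edge(EMILY, "Living Room", "is-in")
    out[p.name] = {"pattern": p}

    p = _pat("taking meal")
    p.add_edge(EMILY, "Kitchen", "is-in")
    out[p.name] = {"pattern": p}

    p = _pat("log short bathroom visit")  # log entries are permanent
    entry = p.generic(1)
    date = p.generic(2)
    p.add_edge("System Log", entry, "entry", actionable=3.0)
    p.add_edge(entry, "short bathroom visit", "type", actionable=3.0)
    p.add_edge(entry, date, "date", actionable=3.0)
    p.add_edge(date, "today", "")
    out[p.name] = {"pattern": p}

    n = cfg.many_visits_threshold
    p = _pat("many bathroom visits", persistence=HOUR)
    date = p.generic(1)
    p.add_edge("System", "System Log", "")
    for i in range(2, 2 + n):
        slot = p.generic(i)
        p.add_edge("System Log", slot, "entry")
        p.add_edge(slot, "short bathroom visit", "type")
        p.add_edge(slot, date, "date")
    p.add_edge("System", "many bathroom visits", "notification",
               actionable=1.0)
    out[p.name] = {"pattern": p, "auto_act": True,
                   "canonical_groups": [list(range(2, 2 + n))],
                   "maintain": "complete"}

    p = _pat("potential emergency", persistence=HOUR)
    p.add_edge("System", "bathroom emergency", "notification", actionable=1.0)
    out[p.name] = {"pattern": p}

    p = _pat("2milk")
    c1, c2 = p.generic(1), p.generic(2)
    p.add_edge("Fridge", c1, "contains")
    p.add_edge(c1, "Milk", "is")
    p.add_edge("Fridge", c2, "contains")
    p.add_edge(c2, "Milk", "is")
    out[p.name] = {"pattern": p, "canonical_groups": [[1, 2]]}

    p = _pat("1milk")
    c1 = p.generic(1)
    p.add_edge("Fridge", c1, "contains")
    p.add_edge(c1, "Milk", "is")
    out[p.name] = {"pattern": p}

    p = _pat("crate in trash")
    p.add_edge("Trash", p.generic(1), "contains")
    out[p.name] = {"pattern": p}

    p = _pat("buy milk")
    p.add_edge("Shopping List", "Milk", "buy", actionable=1.0)
    out[p.name] = {"pattern": p}

    p = _pat("food out", persistence=HOUR)
    p.add_edge("System", "Food out of the fridge", "notification",
               actionable=1.0)
    out[p.name] = {"pattern": p}

    return out


def scenario_timelines(cfg: DayConfig | None = None) -> list[Timeline]:
    cfg = cfg or DayConfig()
    # composite condition: near the bathroom door, then not detected
    in_bath = Timeline("in-bathroom", [
        TimelineNode("near", "near bathroom"),
        TimelineNode("gone", "not detected", emits="in bathroom"),
    ], [
        TimelineEdge("near", "gone", Rule("next")),
    ])
    bathroom = Timeline("bathroom", [
        TimelineNode("root", "in bathroom"),
        TimelineNode("out-soon", "out of bathroom"),
        TimelineNode("log", "log short bathroom visit"),
        TimelineNode("out", "out of bathroom"),
        TimelineNode("emergency", "potential emergency"),
    ], [
        TimelineEdge("root", "out-soon",
                     Rule("sooner-than", cfg.short_visit_max)),
        TimelineEdge("out-soon", "log", Rule("next")),
        TimelineEdge("root", "out", Rule("plain")),
        TimelineEdge("root", "emergency",
                     Rule("later-than", cfg.emergency_after)),
    ])
    milk = Timeline("milk", [
        TimelineNode("two", "2milk"),
        TimelineNode("one", "1milk"),
        TimelineNode("back", "2milk"),
        TimelineNode("trash", "crate in trash"),
        TimelineNode("buy", "buy milk"),
        TimelineNode("forgot", "food out"),
    ], [
        TimelineEdge("two", "one", Rule("next")),
        TimelineEdge("one", "back", Rule("plain")),
        TimelineEdge("one", "trash", Rule("plain")),
        TimelineEdge("one", "forgot", Rule("later-than", cfg.food_out_after)),
        TimelineEdge("trash", "buy", Rule("plain")),
    ])
    return [in_bath, bathroom, milk]


def build_engine(cfg: DayConfig | None = None,
                 min_kf: float = 0.5,
                 action_rule: str = "prose",
                 keep_reports: bool = True,
                 with_initial_graph: bool = True) -> CCM:
    """A CCM engine loaded with the scenario patterns, timelines and
    (optionally) the initial context graph applied at t = 0."""
    cfg = cfg or DayConfig()
    engine = CCM(min_kf=min_kf, action_rule=action_rule)
    engine.keep_reports = keep_reports
    for spec in scenario_patterns(cfg).values():
        engine.register_pattern(spec["pattern"],
                                auto_act=spec.get("auto_act", False),
                                canonical_groups=spec.get("canonical_groups"),
                                maintain=spec.get("maintain", "maximal"))
    for tl in scenario_timelines(cfg):
        engine.register_timeline(tl)
    if with_initial_graph:
        engine.enqueue(initial_context_graph_transaction(cfg))
        engine.run()
        logger.info("initial context graph: %d nodes, %d edges",
                    len(engine.graph.nodes), len(engine.graph))
    return engine


# ---------------------------------------------------------------------------
# End-to-end run and evaluation


@dataclass
class DetectionTrace:
    """What the engine reported over a run, in evaluable form."""

    bathroom_entries: list[int] = field(default_factory=list)  # entry times
    bathroom_exits: list[int] = field(default_factory=list)
    short_visit_logs: list[int] = field(default_factory=list)
    emergencies: list[int] = field(default_factory=list)
    many_visit_alerts: list[int] = field(default_factory=list)
    meal_intervals: list[tuple[int, int]] = field(default_factory=list)
    shopping_added: list[int] = field(default_factory=list)
    food_out_alerts: list[int] = field(default_factory=list)


def trace_from_reports(reports: list[SequenceReport]) -> DetectionTrace:
    tr = DetectionTrace()
    meal_open: int | None = None
    for rep in reports:
        for tl_name, node_id in rep.fired:
            if tl_name == "in-bathroom" and node_id == "gone":
                tr.bathroom_entries.append(rep.now)
            if tl_name == "bathroom" and node_id in ("out", "out-soon") \
                    and (not tr.bathroom_exits
                         or tr.bathroom_exits[-1] != rep.now):
                tr.bathroom_exits.append(rep.now)
        for act in rep.actions:
            f, label, t = act["edge"]
            if label == "entry":
                tr.short_visit_logs.append(rep.now)
            elif label == "notification" and t == "bathroom emergency":
                tr.emergencies.append(rep.now)
            elif label == "notification" and t == "many bathroom visits":
                tr.many_visit_alerts.append(rep.now)
            elif label == "notification" and t == "Food out of the fridge":
                tr.food_out_alerts.append(rep.now)
            elif label == "buy":
                tr.shopping_added.append(rep.now)
        meal_new = rep.new_matches.get("taking meal", [])
        meal_gone = rep.invalidated.get("taking meal", [])
        if meal_new and meal_open is None:
            meal_open = rep.now
        if meal_gone and meal_open is not None:
            tr.meal_intervals.append((meal_open, rep.now))
            meal_open = None
    if meal_open is not None:
        tr.meal_intervals.append((meal_open, reports[-1].now))
    return tr


def run_day(seed: int, cfg: DayConfig | None = None
            ) -> tuple[CCM, ActivitySchedule, GroundTruth, DetectionTrace]:
    cfg = cfg or DayConfig()
    schedule, truth = generate_day(seed, cfg)
    engine = build_engine(cfg)
    for txn in emit_events(schedule, cfg=cfg):
        engine.enqueue(txn)
    engine.run()
    return engine, schedule, truth, trace_from_reports(engine.reports)


def _overlaps(iv: tuple[int, int], times: list[int], slack: int) -> bool:
    lo, hi = iv
    return any(lo - slack <= t <= hi + slack for t in times)


def evaluate(trace: DetectionTrace, truth: GroundTruth,
             cfg: DayConfig | None = None) -> dict:
    """Per-activity detection summary, including the two confusion classes
    that pure location sensing cannot separate: showers are reported as
    bathroom stays, and sitting in the kitchen is reported as a meal."""
    cfg = cfg or DayConfig()
    slack = 2 * MIN
    bath_detected = sum(_overlaps(iv, trace.bathroom_entries, slack)
                        for iv in truth.bathroom_visits)
    showers_as_bathroom = sum(_overlaps(iv, trace.bathroom_entries, slack)
                              for iv in truth.showers)
    meals_detected = sum(
        any(lo - slack <= s <= hi + slack or s <= lo <= e
            for s, e in trace.meal_intervals)
        for lo, hi in truth.meals)
    kitchen_idle_as_meal = sum(
        any(s <= lo <= e or lo <= s <= hi for s, e in trace.meal_intervals)
        for lo, hi in truth.kitchen_idle)
    return {
        "bathroom": {"true": len(truth.bathroom_visits),
                     "detected": bath_detected,
                     "missed": len(truth.bathroom_visits) - bath_detected},
        "shower": {"true": len(truth.showers),
                   "reported_as_bathroom": showers_as_bathroom},
        "meal": {"true": len(truth.meals), "detected": meals_detected},
        "kitchen_idle": {"true": len(truth.kitchen_idle),
                         "confused_as_meal": kitchen_idle_as_meal},
        "short_visits": {"true": len(truth.short_visits),
                         "logged": len(trace.short_visit_logs)},
        "emergencies": len(trace.emergencies),
        "many_visit_alerts": len(trace.many_visit_alerts),
    }
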