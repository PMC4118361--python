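import random

import pytest

from ccmatch import (
    CCM,
    Change,
    GraphPattern,
    Transaction,
    parse_pattern,
)

from conftest import random_graph, random_pattern


def engine_with(pattern_texts, **kw):
    eng = CCM(**kw)
    for i, text in enumerate(pattern_texts):
        eng.register_pattern(parse_pattern(text, name=f"p{i}"))
    return eng


class TestQueueAndSequence:
    def test_sequence_advances_once_per_transaction(self):
        eng = engine_with(["A-r->B"])
        for t in (10, 20, 30):
            eng.submit(Change("add", "A", f"N{t}", "x"), at=t)
        eng.run()
        assert eng.sequence == 3

    def test_add_and_remove_in_one_transaction_is_net_noop(self):
        eng = engine_with(["A-r->B"])
        txn = Transaction(submitted_at=5)
        txn.add("A", "B", "r").remove("A", "B", "r")
        eng.enqueue(txn)
        (rep,) = eng.run()
        assert len(eng.graph) == 0
        assert rep.new_matches["p0"] == [] or rep.invalidated["p0"] != []

    def test_malformed_change_rejected_at_enqueue(self):
        eng = engine_with(["A-r->B"])
        with pytest.raises(ValueError):
            eng.enqueue(Transaction([Change("add", "", "B", "r")]))

    def test_expiry_runs_as_its_own_sequence(self):
        eng = engine_with(["A-r->B"])
        eng.submit(Change("add", "A", "B", "r", expiry=100), at=10)
        eng.submit(Change("add", "C", "D", "x"), at=200)
        reports = eng.run()
        assert [r.origin for r in reports] == ["perception", "expiry",
                                               "perception"]
        assert ("A", "B", "r") not in eng.graph

    def test_process_one_on_empty_queue_raises(self):
        with pytest.raises(RuntimeError):
            engine_with([]).process_one()


class TestMatchMaintenance:
    def test_final_edge_completes_the_match(self):
        eng = engine_with(["A-r->B-s->C"])
        eng.submit(Change("add", "A", "B", "r"), at=1)
        eng.run()
        eng.submit(Change("add", "B", "C", "s"), at=2)
        (rep,) = eng.run()
        complete = [m for m in rep.new_matches["p0"] if m.is_complete]
        assert len(complete) == 1 and complete[0].k_f == 1.0

    def test_removing_matched_edge_invalidates_match(self):
        eng = engine_with(["A-r->B-s->C"])
        eng.submit(Change("add", "A", "B", "r"), at=1)
        eng.submit(Change("add", "B", "C", "s"), at=2)
        eng.run()
        eng.submit(Change("remove", "B", "C", "s"), at=3)
        (rep,) = eng.run()
        assert rep.invalidated["p0"]
        live = eng.patterns["p0"].process.live()
        assert all(("B", "C", "s") not in m.edge_map.values() for m in live)

    def test_incremental_equals_from_scratch_over_random_stream(self):
        rng = random.Random(99)
        eng = CCM(debug_check=True)  # asserts the contract every sequence
        for k in range(3):
            p = None
            while p is None:
                p = random_pattern(rng, rng.randint(1, 5), rng.randint(0, 2))
            p.name = f"p{k}"
            eng.register_pattern(p)
        present = set()
        t = 0
        applied = 0
        while applied < 150:
            t += 10
            if present and rng.random() < 0.35:
                triple = rng.choice(sorted(present))
                present.discard(triple)
                eng.submit(Change("remove", *triple), at=t)
            else:
                f, to = (f"N{rng.randint(0, 7)}" for _ in range(2))
                lab = rng.choice(["", "r", "s"])
                if f == to or (f, to, lab) in present:
                    continue
                present.add((f, to, lab))
                eng.submit(Change("add", f, to, lab), at=t)
            eng.process_one()
            applied += 1

    def test_removal_cost_constant_in_graph_size(self):
        def removal_cost(n_unrelated: int) -> int:
            eng = engine_with(["A-r->B"])
            txn = Transaction(submitted_at=1)
            txn.add("A", "B", "r")
            for i in range(n_unrelated):
                txn.add(f"U{i}", f"V{i}", "unrelated")
            eng.enqueue(txn)
            eng.run()
            before = eng.counters.snapshot()
            eng.submit(Change("remove", "A", "B", "r"), at=2)
            eng.run()
            after = eng.counters.snapshot()
            return sum(after.values()) - sum(before.values())

        assert removal_cost(20) == removal_cost(200)

    def test_identical_streams_give_identical_reports(self):
        def run():
            eng = engine_with(["A-r->?^1", "?^1-s->C"])
            for t, (op, f, to, lab) in enumerate([
                    ("add", "A", "X", "r"), ("add", "X", "C", "s"),
                    ("add", "A", "Y", "r"), ("remove", "A", "X", "r")],
                    start=1):
                eng.submit(Change(op, f, to, lab), at=t * 10)
            return [r.to_json() for r in eng.run()]

        assert run() == run()


class TestReceivers:
    def test_min_kf_gates_notifications(self):
        eng = engine_with(["A(-r->B)-s->C"])
        complete_only, any_match = [], []
        eng.register_receiver(complete_only.append, min_kf=1.0)
        eng.register_receiver(any_match.append, min_kf=0.4)
        eng.submit(Change("add", "A", "B", "r"), at=1)
        eng.submit(Change("add", "A", "C", "s"), at=2)
        eng.run()
        assert [n.k_f for n in complete_only] == [1.0]
        assert [round(n.k_f, 2) for n in any_match] == [0.5, 1.0]

    def test_each_receiver_sees_each_match_exactly_once(self):
        eng = engine_with(["A-r->B"])
        seen = []
        eng.register_receiver(seen.append, min_kf=1.0)
        eng.submit(Change("add", "A", "B", "r"), at=1)
        eng.submit(Change("add", "Z", "W", "q"), at=2)  # unrelated sequence
        eng.run()
        assert len(seen) == 1
        assert seen[0].pattern == "p0" and seen[0].sequence == 1

    def test_pattern_selector_filters(self):
        eng = engine_with(["A-r->B", "C-s->D"])
        seen = []
        eng.register_receiver(seen.append, patterns=["p1"], min_kf=1.0)
        eng.submit(Change("add", "A", "B", "r"), at=1)
        eng.submit(Change("add", "C", "D", "s"), at=2)
        eng.run()
        assert [n.pattern for n in seen] == ["p1"]


class TestActionsInTheLoop:
    def test_pure_recognition_mode_never_mutates(self):
        eng = engine_with(["A-r->B-s->C"])  # no actionable edges anywhere
        eng.submit(Change("add", "A", "B", "r"), at=1)
        eng.submit(Change("add", "B", "C", "s"), at=2)
        eng.run()
        assert eng.action_log == []
        assert {e.triple for e in eng.graph.edges} == {
            ("A", "B", "r"), ("B", "C", "s")}

    def test_inference_lands_in_the_next_sequence(self):
        eng = CCM()
        p = parse_pattern("A(-r->B)-act/1->Alert", name="p")
        eng.register_pattern(p, auto_act=True)
        eng.submit(Change("add", "A", "B", "r"), at=10)
        rep1 = eng.process_one()
        assert [a["edge"] for a in rep1.actions] == [["A", "act", "Alert"]]
        assert ("A", "Alert", "act") not in eng.graph  # not yet applied
        rep2 = eng.process_one()  # the enqueued inference transaction
        assert rep2.origin == "inference"
        assert ("A", "Alert", "act") in eng.graph

    def test_action_fires_once_while_match_lives(self):
        eng = CCM()
        p = parse_pattern("A(-r->B)-act/1->Alert", name="p")
        eng.register_pattern(p, auto_act=True)
        eng.submit(Change("add", "A", "B", "r"), at=10)
        eng.submit(Change("add", "Z", "W", "q"), at=20)
        eng.submit(Change("add", "Z2", "W2", "q"), at=30)
        eng.run()
        assert len(eng.action_log) == 1
        # invalidate the supporting match and undo the inference, then
        # re-create the situation: the action fires again
        eng.submit(Change("remove", "A", "B", "r"), at=40)
        eng.submit(Change("remove", "A", "Alert", "act"), at=45)
        eng.submit(Change("add", "A", "B", "r"), at=50)
        eng.run()
        assert len(eng.action_log) == 2
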