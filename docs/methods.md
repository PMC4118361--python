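# Methods

This note records the model `ccmatch` implements, the choices made where
the design was genuinely open, and what the synthetic scenario does and
does not show.

## Context graphs and patterns

The context graph is a labeled directed multigraph: node labels are
unique (one concept, one node), several edges may connect an ordered node
pair provided their labels differ, and the empty label λ denotes a bare
association. Each edge carries either an absolute expiry timestamp on an
injected logical millisecond clock or `PERMANENT`; an edge expires when
`now ≥ expiry` (the boundary is inclusive — one unambiguous rule, tested
at the boundary). The clock is simulation time, never wall time, so every
run is reproducible. Nodes isolated by an edge removal are
garbage-collected by default (`gc_isolated_nodes=False` turns this off),
keeping the graph minimal in the same spirit as match minimality.

Patterns are connected graph templates. Generic nodes (`?^i`) match any
graph node under a globally injective mapping; generic edge labels match
any label. Edge weights: `characteristic ∈ (0, 1]` sets an edge's share
of the match quality `k_f`; `actionable ≥ 0` marks edges the system may
materialize itself. A pattern's `persistence` is the validity stamped on
edges inferred from it.

## Action eligibility: why `k_f ≥ 1 − a`

Two readings of the actionability test exist. The literal inequality
`a ≥ k_f` would make a highly actionable edge fire on arbitrarily poor
matches, and *improving* a match could disqualify an inference, while
zero-actionable edges would fire on weak matches too. The package
defaults to the complementary rule `k_f ≥ 1 − a`, which has the intended
monotonicity: the less actionable an edge, the more complete the match
must be; zero-actionability edges are never inferable; weights ≥ 1 (the
`/1` and `/3` annotations used in the scenarios) are eligible at any
quality. The literal rule remains available via
`CCM(action_rule="literal")` and `eligible_inferences(..., rule="literal")`.

An inference fires only for an *otherwise-complete* match: every unsolved
edge must be actionable and eligible. Internally this is detected by
completely matching the pattern's non-actionable *remainder* (a pattern
whose every edge is actionable has a vacuous remainder and is triggered
by timelines only). Unsolved generic endpoints with no binding receive
fresh labels (`entry#1`, `entry#2`, …) from a deterministic allocator.
An action fires once per (pattern, remainder match) while that match
lives; inferred edges already present are skipped with a log line.

## Matching

Growth follows the production scheme: *single-edge matches* are created
when a graph edge arrives — the only point where node and edge labels are
compared, via a hashed index of pattern edges by label — and are merged
into larger matches by reference operations alone. Two matches merge when
their solved pattern-edge sets are disjoint, their node mappings agree
and stay injective, and they share a mapped node (which keeps the matched
subgraph connected). *Maximality* is defined operationally: no compatible
single-edge extension remains; this is equivalent to subset-maximality
because any mergeable match contributes an addable single edge. The
grower enumerates maximal matches by a pivot search (either the chosen
extension is taken, or some extension incompatible with it), with a memo
on visited states. Matches are deduplicated by the full mapping, so
automorphic matches — same subgraph, different `f_v` — are all reported,
e.g. both orderings of two milk crates.

`brute_force_matches` is an independent oracle (exhaustive assignment of
every pattern-edge subset, guarded to 12 graph nodes) used to validate
the grower on hundreds of random instances per test run; a further
cross-check compares complete-match counts with networkx's subgraph
monomorphisms on instances without parallel edges.

Two per-pattern engine options tame combinatorial patterns:

* `canonical_groups` declares groups of interchangeable generic nodes
  (e.g. the eight entry slots of the too-many-visits counter); bindings
  within a group are forced into lexicographic order, keeping one
  representative per orbit instead of up to 8! automorphic copies.
* `maintain="complete"` keeps only complete matches for patterns whose
  partial matches carry no information (wide counting patterns): each
  added edge seeds a backtracking completion over an anchor-indexed
  single-edge table, and a removal simply kills the complete matches
  containing it — removing an edge can never complete a match.

Both are opt-in; the default process maintains every maximal partial
match and, after each transaction, equals a from-scratch re-enumeration
(asserted continuously in `debug_check` mode and in the test suite).

## The engine

All mutation flows through FIFO-queued transactions; one transaction
applied atomically is one *sequence*, so the graph is constant during a
matching pass. Expired edges are swept lazily: when a transaction's
timestamp would strand expired edges, an internal expiry transaction runs
first as its own sequence. Actions decided in a sequence are enqueued as
inference transactions at the queue front — their effects are visible
from the next sequence, which makes cascades (log entry → entry counter →
alert) well-defined. Receivers are notified after a sequence completes,
exactly once per qualifying new match, gated by a per-receiver `min_kf`
(all maximal matches are maintained regardless; thresholds gate
notification only). A match survives sequences until one of its graph
edges is removed; "new" matches are those absent the sequence before,
which is what the timelines' `next` rule consumes. Delivery is
single-threaded and deterministic: identical queued streams produce
identical sequence reports.

Operation counters (node/edge label comparisons, node/edge reference
comparisons including index maintenance, merges) instrument every run;
over a simulated day, label comparisons stay well below reference
comparisons, and the removal of an edge costs the same whether the
surrounding graph has 30 or 300 unrelated edges.

## Timelines

Timeline nodes are instances (an id plus a pattern reference), so the
same pattern may appear on several branches. All temporal quanta are
measured from the moment an edge was *enabled*; for root-outgoing edges
this coincides with timeline activation, and it is the only consistent
choice for deeper edges. A node whose pattern's unsolved part consists
entirely of eligible actionable edges counts as satisfied (an
*action node*): firing it applies the inference — required for nodes like
"log the short visit" that can never match before their own action runs.
Simultaneous firings all take effect and their enabled sets are unioned.
A timeline with no enabled or active edges goes inactive and may be
re-activated by a fresh root match (daily repetition depends on this). A
node may declare an `emits` token added to the satisfied set when it
fires, letting one timeline serve as a composite condition for another;
the bathroom scenario uses a two-node timeline (near the door → no longer
detected) emitting "in bathroom" for the main timeline's root. Timelines
step in registration order, so emitters are registered before consumers.

`next` is strict: the edge is active exactly in the sequence where the
source stops matching, and fires only if the destination is satisfied in
that same sequence (the scenario's event emission keeps the relevant
changes in one transaction for this reason).

## The synthetic day

The generator emulates one day of a single person in a four-zone studio:
sleep 22:00–07:00 (optionally one night bathroom visit), two or three
meals enforced by a hazard that is zero for 3 h after a meal, ramps
linearly over the next 2 h and forces a meal before the gap reaches
5.5 h; bathroom visits 3–10 min; at most one shower, 15–25 min,
uninterruptible (a forced visit is deferred to the shower's end); meals
20–40 min, interruptible and resumed; wandering 5–20 min, dropped if
interrupted; idle 10–40 min, sometimes sitting at the kitchen window.
Durations are sampled uniformly; everything derives deterministically
from the seed.

Emission mirrors the sensor set: location edges for the three covered
zones, a near-door indication 20 s before a bathroom entry, loss of
detection while inside (there is no bathroom sensor), exit into the
living room with a short transit, engine ticks every 60 s so time-based
rules can fire between events, and fridge/trash RFID edges for the milk
episode. The initial belief graph (apartment, sensors, objects, the
date → `today` device) is built in code and applied as the first
transaction (~35 nodes).

Because recognition uses location only, two confusions are intrinsic and
the evaluation reports them as such: a shower is indistinguishable from a
bathroom visit, and sitting in the kitchen is indistinguishable from a
meal. Passing tests therefore show that the engine recognizes what this
sensor set can express — not that activity recognition is solved; real
deployments add sensors or richer patterns. The generator also omits
sensor noise (dropouts, misreads) and multi-person households.

The too-many-visits threshold is eight entries per date (configurable);
alert patterns carry a persistence of one hour so notifications age out;
log entries are permanent.

## Problem sizes and tolerances

Randomized validation uses graphs of ≤ 10 nodes against patterns of ≤ 5
edges with ≤ 2 generic nodes (500 pairs for the oracle comparison, 150
transactions for the engine contract) and ≤ 30-node graphs for 1000
text-format round trips; the weighted `k_f` boundary case is checked to
1e-12. A full simulated day is ~1500 sequences and runs in a few seconds
on one CPU. Serialization is byte-deterministic: the continuation of a
node is the branch covering the most unemitted edges (ties broken
lexicographically last), other branches are parenthesized in
lexicographic order, and re-serializing a parsed document reproduces it
exactly.

## Known limitations

Negative conditions ("no match for P") cannot be expressed; the
not-detected edge emulates one case by reifying absence as a positive
edge. Absolute-calendar constraints and frequencies are outside the
timeline rule set. Generic bindings are not shared across the patterns of
one timeline (the milk timeline's ?-crate in one node is independent of
the next node's). Matching is exact on labels; there is no similarity or
taxonomy reasoning beyond explicit `isa` edges.
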