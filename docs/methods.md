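# Methods

## Model

The combinatorial substrate is the Chinese Clock: the cyclic order
LU, LI, ST, SP, HT, SI, BL, KI, PC, TE, GB, LR of the 12 principal
meridians, indexed by 1-based clock positions. Polarity (yin/yang) and
limb (hand/foot) repeat with period 4 around the cycle (yin, yang, yang,
yin and hand, hand, foot, foot), which the package checks exhaustively.
Stage names (Hand Tai Yin, Foot Tai Yang, …) are carried as reference
data.

### Conventions

* **Orientation.** "Clockwise" is increasing clock position. This is
  fixed by the interior–exterior relation: step 1 clockwise from LU is
  LI. (The replayed case's narrative uses the
  opposite sign for the SI→ST step; step magnitudes are unaffected and
  the LU→LI convention is kept throughout.)
* **Signed steps.** A step value lies in {−5…−1, 0, +1…+6}. The
  half-turn is always written +6, never −6, so each unordered pair of
  meridians has exactly one signed-step representation, and
  `step_between(a, b) = −step_between(b, a)` except at magnitude 6.

### Intrinsic rules

A pairing system is a perfect matching of the 12 positions into 6 pairs.
The filter keeps a matching iff:

1. it is invariant under rotation by r ∈ {1, 2, 4} positions. The
   stated symmetries are 30°, 60° and 120°, and 12 positions span 360°,
   so these are the literal readings. Admitting 180° (r = 6) as well
   would admit six extra pure step-3 matchings and break the published
   classification (2 three-step systems), so r = 6 alone does not
   qualify — though many surviving systems are *also* invariant under
   larger rotations, which the recorded `symmetry_periods` show.
2. it uses at most 2 distinct step magnitudes. Under rule 1 a two-step
   system automatically alternates its steps around the clock, so no
   separate adjacency-alternation test is needed.
3. its polarity profile is 6 yin–yang pairs or 3 yin–yin + 3 yang–yang
   pairs. Empirically this rule never discriminates: every matching
   passing rules 1, 2 and 4 also passes it (the test suite checks this
   over all 10 395 matchings). It is kept as an explicit rule because it
   is part of the historical characterization, and the rule-by-rule
   report makes its (non-)effect visible.
4. step-5 purity: a matching containing a step-5 pair must use step 5
   only. This encodes the traditional assertion that step 5 cannot combine
   with another step under the intrinsic rules. The assertion is *not* a
   consequence of rules 1–3: the matching
   {(1,2),(3,8),(5,6),(7,12),(9,10),(4,11)} alternates steps 1 and 5,
   is 120°-symmetric and polarity-valid. Purity is therefore enforced
   as its own rule, and the report flags it separately.

Brute force over all matchings (11!! = 10 395; the recursion always
pairs the lowest unmatched position first, so each matching appears
exactly once and in canonical sorted-pairs form) leaves 19 systems with
the step-signature histogram {1}: 2, {1,3}: 4, {2}: 4, {2,6}: 4, {3}: 2,
{5}: 2, {6}: 1. The seven historically named systems are attached by
pair-set identity against embedded reference matchings.

### Balance graph

The non-step-5 systems' pair sets union into a simple graph on the 12
meridians: uniform degree 7, 42 edges, and the edge set equals exactly
the pairs at circular distance 1, 2, 3 or 6 — an independent check the
tests recompute from clock positions alone. Each edge records the
systems supporting it. With the two step-5 systems included the merge
gains all 12 distance-5 pairs (degree 9, 54 edges): the two step-5
systems are the two alternating matchings of the 12-cycle generated by
+5 steps, and together they cover both distance-5 partners of every
meridian. The step-5-excluded graph is the default everywhere because
step-5 pairs (the extraordinary-vessel combinations) risk imbalance in
multi-meridian use.

### Patterns

An ideally balanced 4-set has all six member pairs on the balance graph.
Three independent constructions are implemented and required to agree:

* brute force over all C(12,4) = 495 subsets;
* instantiation of the five per-focus step templates at all 12 meridians;
* completion of the 48 balanced triples by their shared balancers.

All yield the same 15 sets: 12 consecutive-window patterns and 3
every-third patterns, each with 2 yin + 2 yang and 2 hand + 2 foot
members. Pattern identity is the member set (canonical form: members
sorted by clock position); template signatures are reported per focus
meridian, since the same set serves four foci — the source of the
60 → 15 collapse. The every-third template (x, +3, 6, −3) is read as the
set {x, x+3, x+6, x+9}.

**Documented discrepancy.** The original derivation narrative puts the
triple → quad completion split at 12 triples with two shared balancers
and 48 with one, which sums to 72, not to the 60 quad options it also
reports. Direct computation gives 12 triples with 2 completions (exactly
the window-center triples {x, x+1, x+2}) and 36 with 1, summing to 60.
The package reports the derived split {2: 12, 1: 36} and asserts nothing
about 48.

A second count not asserted anywhere: the original account holds that
the twelve window patterns draw each pairwise balance from two or three
of the enumerated systems while the three every-third patterns rest on a
single system per pair; the counting convention behind that claim is not
recoverable, so per-edge supporting-system lists are exported instead.

## Protocol engine

The point-selection protocol is a deterministic state machine over a
session:

* **State.** The presentation (affected meridian, side, painful region,
  VAS 0–10), the ordered treatment steps, and the VAS history.
  Extremities are keyed by meridian limb type (arm = hand meridians,
  leg = foot meridians) and side; trunk/neck/face segments of a meridian
  belong to its limb's extremity.
* **Candidates.** For a target extremity, candidates are the meridians
  of that limb type balancing the affected meridian *and* every meridian
  already treated. The yin/yang girdle rule is enforced uniformly: each
  girdle (arms, legs) may carry at most one yin and one yang treated
  meridian, and the affected meridian counts toward its own girdle from
  the start — which reproduces the contralateral-limb opposite-polarity
  rule as a special case. A free polarity choice exists only while the
  target girdle is empty.
* **Selection.** Palpation findings (tenderness 0–10 per meridian ×
  side × region) are admissible if they lie on candidates, on a free
  side, and in the painful region or one of its somatotopic
  correspondents (the painful region itself is admissible, mirroring the
  left–right projection used in the replayed case). Tenderness 0 means
  no Ashi point. The most tender finding wins; ties break to the lower
  clock position, then to the side contralateral to the pain. Tenderness
  is modeled as an ordinal 0–10; only qualitative grades (from very
  mild to severe) are attested, and the mapping is configurable.
* **Completion.** A session completes on VAS 0 (no further needles), or
  after the three non-affected extremities plus the optional
  affected-meridian step (taken or declined). The affected-meridian step
  is taken when the residual VAS exceeds the `treat_affected_above_vas`
  threshold, default 0 — i.e. whenever pain remains — because the
  replayed case treats the affected meridian even at VAS 1, although the
  step is nominally conditional on insufficient relief. The threshold is
  a config parameter, not a guess baked into the engine.
* **Closure.** Because candidates are always common balancers of
  everything involved, a completed 4-meridian session is an ideally
  balanced set containing the affected meridian, hence one of its five
  patterns. The test suite walks *every* rule-consistent choice sequence
  for all 12 affected meridians and finds no dead end and no escape from
  the 15-pattern universe. Early-stopped sessions are reported as
  partial member sets, not errors; whether the affected meridian would
  always have joined the final four is then moot and left unstated.

### Somatotopic map

The shipped map contains the text-attested correspondences (knee ↔ elbow/chest/eyes/nose; shoulder ↔ hip; shoulder ↔
ankle/knee and shoulder ↔ wrist/elbow from the replayed case; wrist ↔
ankle and hand ↔ foot from the stated arm-onto-leg image projection),
tagged `provenance="text"`. The full pictorial correspondence set is
not recoverable from text, and several regions (abdomen, back,
neck, upper arm, thigh, lower leg) would otherwise have no correspondent,
so the standard upright image projection is completed with
`provenance="extension"` entries (upper_arm ↔ thigh, forearm ↔
lower_leg, abdomen/back onto the matching limb segments, neck ↔
wrist/ankle). Users can extend or override the map from a JSON/YAML
config; user entries are tagged `provenance="user"`.

### Synthetic cohort

The simulator emulates the single-case clinical setting at cohort scale:
presentations are drawn uniformly over meridians and sides, the painful
region uniformly over the affected limb's regions, and the intake VAS
uniformly on 3–9 (bracketing the replayed case's 9). Tenderness fields
are uniform on 0–10 with a guaranteed tender point per stage (re-rolled
if all findings are 0, since the protocol would otherwise re-palpate);
each treatment removes a uniform 30–70 % of the current VAS, echoing the
roughly halving trajectory of the replayed case (9 → 5 → 3 → 1). All
randomness flows from a single seeded generator, so traces are exactly
reproducible. What the simulator does *not* model: real tenderness
correlations between meridians and regions, non-monotone pain courses,
relapse between sessions, and any true treatment effect — passing
cohort tests therefore shows the engine's rule-consistency, determinism
and pattern closure, not clinical validity.

## Numerical and design notes

* All counts are exact integers from exhaustive enumeration; there are
  no tolerances, iterative fits or floating-point concerns. The largest
  enumeration (10 395 matchings) runs in well under a second.
* Option counts (84, 144, 60) are with-multiplicity counts defined
  exactly as the derivation narrative constructs them (per meridian, per
  pair, per focus); unique counts are set cardinalities after canonical
  deduplication.
* VAS values are numbers rather than strict integers so the replayed
  endpoint "<1" can be encoded (as 0.5).
* Degenerate inputs raise early with field-level messages: non-matchings,
  unknown meridian codes or regions, out-of-scale VAS/tenderness,
  unbalanced sets (naming the offending pair), occupied extremities, and
  girdle-polarity violations.

## Problem sizes

Tests and the acceptance script enumerate the full spaces they assert
about: all 10 395 matchings, all 220 triples and 495 quadruples, every
rule-consistent protocol walk for all 12 affected meridians (a few
thousand sequences), and simulated cohorts of 10–60 patients — the
natural, desk-scale sizes of the problem.
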