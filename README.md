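# meridian-balance

Combinatorics of balanced acupuncture-meridian combinations on the
Chinese Clock, and a rule-based, replayable engine for the individualized
point-selection protocol built on them.

## The problem

Traditional Chinese medicine orders the 12 principal meridians in a fixed
cycle — LU, LI, ST, SP, HT, SI, BL, KI, PC, TE, GB, LR — the *Chinese
Clock* (CC). Historical balancing systems (interior–exterior,
neighbouring channels, the 6-stage systems, opposite-clock needling) all
pair the 12 meridians into 6 pairs, and all obey the same *intrinsic
rules*:

* a perfect pairing (every meridian paired with exactly one other);
* rotation symmetry of 30°, 60° or 120° on the clock (invariance under
  rotation by 1, 2 or 4 positions);
* at most 2 distinct step magnitudes, where the *step* of a pair is its
  cyclic distance 1–6 (a system using the half-clock step 5 uses it
  alone);
* a polarity profile of either 6 yin–yang pairs or 3 yin–yin plus 3
  yang–yang pairs.

This package answers, by exhaustive computation, three nested questions:

1. **Which pairing systems satisfy the rules?** Brute force over all
   11!! = 10 395 perfect matchings of the 12 positions leaves exactly
   **19 systems** (2 one-step, 4 one/three-step alternating, 4 two-step,
   4 two/six-step alternating, 2 three-step, 2 five-step, 1 six-step).
2. **Which meridians can balance which?** Merging the pair sets of the
   non-step-5 systems gives every meridian exactly **7 balancing
   options** — steps ±1, ±2, ±3 and 6 — for 42 balanced pairs in total;
   step 4 never balances, and no perfect matching can be built from
   step-4 pairs at all.
3. **Which 4-meridian sets are *ideally balanced*** (every member
   balancing every other)? The cascade runs 12 × 7 = 84 pair options →
   42 unique pairs → 144 triple options → 48 unique triples → 60 quad
   options → **15 distinct patterns**: 12 windows of four consecutive
   clock positions and 3 every-third-position sets. Each pattern carries
   2 yin + 2 yang and 2 hand + 2 foot meridians, and every meridian owns
   exactly 5 of the 15, matching the five per-focus step templates
   (−1, x, +1, +2), (−2, −1, x, +1), (x, +1, +2, +3), (x, −1, −2, −3),
   (x, +3, 6, −3).

On top of the 15-pattern universe sits the **point-selection protocol**
for localized pain: identify the affected meridian and rate the pain on a
0–10 visual analog scale (VAS); then treat one balancing meridian on each
non-affected extremity — chosen by palpating tender *Ashi* points in
somatotopically corresponding regions (the Image and Mirror concept) —
keeping arms and legs each in yin/yang balance; optionally finish on the
affected meridian itself. The engine proves the protocol closed: every
rule-consistent session terminates in one of the affected meridian's five
patterns, with no dead ends.

## Worked example

```pycon
>>> from meridian_balance import (meridian_by_code, merged_balance_graph,
...                               counting_cascade, patterns_for_meridian)
>>> g = merged_balance_graph()          # 19 systems, step-5 excluded
>>> lu = meridian_by_code("LU")
>>> sorted(m.code for m in g.neighbors(lu))
['BL', 'GB', 'LI', 'LR', 'SP', 'ST', 'TE']
>>> counting_cascade(g).to_dict()
{'pairs_with_multiplicity': 84, 'pairs_unique': 42,
 'shared_balancer_histogram': {4: 24, 3: 12, 2: 6},
 'triple_options': 144, 'triples_unique': 48,
 'completion_histogram': {2: 12, 1: 36},
 'quad_options': 60, 'quads_unique': 15, 'patterns_per_meridian': 5}
>>> [p.member_codes for p in patterns_for_meridian(meridian_by_code("SI"), g)]
[('HT', 'SI', 'BL', 'KI'), ('SP', 'HT', 'SI', 'BL'), ('SI', 'BL', 'KI', 'PC'),
 ('ST', 'SP', 'HT', 'SI'), ('ST', 'SI', 'PC', 'LR')]
```

LU's seven balancing options are the meridians at steps ±1, ±2, ±3 and 6;
the cascade dict is the full 84 → 42 → 144 → 48 → 60 → 15 derivation; and
SI (small intestine) owns five ideally balanced patterns — four
consecutive windows and one every-third set.

Replaying the built-in shoulder-pain case (severe right-shoulder pain on
the SI meridian, VAS 9):

```pycon
>>> from meridian_balance import replay_case
>>> t = replay_case()
>>> t.treated_sequence
('BL', 'SP', 'HT', 'SI')
>>> t.vas_history
(9.0, 5.0, 3.0, 1.0, 0.5)
>>> t.members, t.pattern_class
(('SP', 'HT', 'SI', 'BL'), 'consecutive_window')
```

The engine offers {BL, ST} on the first leg, {KI, SP} on the second,
the sole candidate {HT} on the free arm, then the affected SI itself —
realizing the SP–HT–SI–BL window pattern while the VAS falls
9 → 5 → 3 → 1 → <1.

The same functionality is on the command line:

```bash
meridian-balance balance SI                 # 7 options + 5 patterns
meridian-balance enumerate-systems          # the 19 systems (JSON)
meridian-balance enumerate-patterns         # cascade + 15 patterns
meridian-balance replay                     # the built-in case trace
meridian-balance simulate --seed 7 --n 50   # synthetic cohort
meridian-balance protocol --case my_case.json
meridian-balance export-reference           # 12-meridian table (CSV)
```

## Scope

The package models meridian-level combinatorics and protocol decisions.
Acupoint-level localization, needling technique (depth, gauge,
stimulation), time-of-day organ-clock semantics and any claims of
clinical efficacy are out of scope; VAS responses are inputs (scripted or
synthetic), never predictions. See `docs/methods.md` for the model,
conventions, and known limitations.
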