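"""Balanced 2-, 3- and 4-meridian combinations and the 15 ideal patterns.

An *ideal balance* is a set of meridians in which every member balances
every other member, i.e. every pair is an edge of the (step-5-excluded)
balance graph.  The counting cascade runs:

* 12 × 7 = 84 ordered 2-meridian options → 42 unique balanced pairs;
* each pair extended by its shared balancers (24 pairs have 4, 12 have 3,
  6 have 2) → 144 triple options → 48 unique balanced triples;
* each triple completed to a 4-set (12 triples admit 2 completions, 36
  admit 1) → 60 quad options → 15 distinct ideally balanced 4-meridian
  patterns.

Each of the 15 patterns is geometrically one of two classes: four
consecutive clock positions (12 patterns) or every third position
(3 patterns).  Seen from any focus meridian x, a pattern matches one of
five step templates — (−1, x, +1, +2), (−2, −1, x, +1), (x, +1, +2, +3),
(x, −1, −2, −3) or (x, +3, 6, −3) — so every meridian owns exactly 5
patterns, and 12 × 5 = 60 collapses to 15 by overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .clock import MERIDIANS, Meridian, advance, step_between
from .systems import BalanceGraph, merged_balance_graph

__all__ = [
    "TEMPLATE_SIGNATURES",
    "BalancedPattern",
    "EnumerationReport",
    "partition_count",
    "balanced_pairs",
    "shared_balancers",
    "balanced_triples",
    "balanced_quads",
    "patterns_for_meridian",
    "classify_pattern",
    "counting_cascade",
]

# The five per-focus step templates (0 marks the focus meridian x; the
# half-clock member of the every-third template is the canonical +6).
TEMPLATE_SIGNATURES: tuple[tuple[int, ...], ...] = (
    (-1, 0, 1, 2),
    (-2, -1, 0, 1),
    (0, 1, 2, 3),
    (0, -1, -2, -3),
    (0, 3, 6, -3),
)


def partition_count(n: int, k: int, groups: int) -> int:
    """Number of unordered partitions of ``n`` items into equal groups.

    ``∏ C(n − ik, k) / groups!`` — e.g. 12 meridians into 3 groups of 4
    gives C(12,4)·C(8,4)·C(4,4)/3! = 5775.
    """
    if n != k * groups:
        raise ValueError(f"n must equal k*groups, got n={n}, k={k}, groups={groups}")
    total = 1
    for i in range(groups):
        total *= math.comb(n - i * k, k)
    return total // math.factorial(groups)


def _check_pairwise_balanced(
    g: BalanceGraph, members: Iterable[Meridian]
) -> list[tuple[Meridian, Meridian]]:
    """Return the unbalanced pairs within ``members`` (empty = all balanced)."""
    return [
        (a, b)
        for a, b in combinations(sorted(set(members)), 2)
        if not g.balances(a, b)
    ]


@dataclass(frozen=True)
class BalancedPattern:
    """An ideally balanced 4-meridian set.

    ``members`` are stored sorted by clock position.  ``pattern_class`` is
    ``consecutive_window`` (4 consecutive positions, cyclically) or
    ``every_third`` (positions p, p+3, p+6, p+9).  ``templates`` maps each
    member, taken as the focus x, to its step-template signature.
    """

    members: tuple[Meridian, ...]
    pattern_class: str
    templates: dict[str, tuple[int, ...]]

    def __hash__(self) -> int:
        return hash(self.members)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BalancedPattern) and self.members == other.members

    @property
    def member_codes(self) -> tuple[str, ...]:
        return tuple(m.code for m in self.members)

    def __contains__(self, m: Meridian) -> bool:
        return m in self.members

    def to_dict(self) -> dict[str, object]:
        return {
            "members": list(self.member_codes),
            "positions": [m.clock_position for m in self.members],
            "pattern_class": self.pattern_class,
            "templates": {k: list(v) for k, v in self.templates.items()},
        }


@dataclass(frozen=True)
class EnumerationReport:
    """The counting cascade from pairs to the 15 distinct patterns."""

    pairs_with_multiplicity: int
    pairs_unique: int
    shared_balancer_histogram: dict[int, int]
    triple_options: int
    triples_unique: int
    completion_histogram: dict[int, int]
    quad_options: int
    quads_unique: int
    patterns_per_meridian: int

    def to_dict(self) -> dict[str, object]:
        return {
            "pairs_with_multiplicity": self.pairs_with_multiplicity,
            "pairs_unique": self.pairs_unique,
            "shared_balancer_histogram": dict(self.shared_balancer_histogram),
            "triple_options": self.triple_options,
            "triples_unique": self.triples_unique,
            "completion_histogram": dict(self.completion_histogram),
            "quad_options": self.quad_options,
            "quads_unique": self.quads_unique,
            "patterns_per_meridian": self.patterns_per_meridian,
        }


def balanced_pairs(
    g: BalanceGraph | None = None,
) -> tuple[list[tuple[Meridian, Meridian]], int]:
    """Unique balanced pairs and the with-multiplicity (ordered) count.

    Every meridian has 7 balancing options, so the ordered count is
    12 × 7 = 84; deduplication halves it to 42 unique pairs.
    """
    if g is None:
        g = merged_balance_graph()
    with_multiplicity = sum(g.degree(m) for m in MERIDIANS)
    return g.edges(), with_multiplicity


def shared_balancers(
    ms: Iterable[Meridian],
    g: BalanceGraph | None = None,
    polarity: str | None = None,
    limb: str | None = None,
) -> set[Meridian]:
    """Meridians outside ``ms`` that balance every member of ``ms``.

    Optional ``polarity`` ('yin'/'yang') and ``limb`` ('hand'/'foot')
    filters narrow the result, as the point-selection protocol requires.
    Raises if ``ms`` itself is not pairwise balanced.
    """
    members = set(ms)
    if not members:
        raise ValueError("need at least one meridian")
    if g is None:
        g = merged_balance_graph()
    bad = _check_pairwise_balanced(g, members)
    if bad:
        pairs = ", ".join(f"{a.code}-{b.code}" for a, b in bad)
        raise ValueError(f"input set is not a balanced combination: {pairs}")
    common: set[Meridian] | None = None
    for m in members:
        nbrs = g.neighbors(m)
        common = nbrs if common is None else common & nbrs
    assert common is not None
    common -= members
    if polarity is not None:
        common = {m for m in common if m.polarity == polarity}
    if limb is not None:
        common = {m for m in common if m.limb == limb}
    return common


def balanced_triples(
    g: BalanceGraph | None = None,
) -> tuple[list[frozenset[Meridian]], int]:
    """Unique balanced 3-sets and the with-multiplicity option count.

    The option count sums, over the 42 unique pairs, the number of shared
    balancers of that pair (the cascade's 144).
    """
    if g is None:
        g = merged_balance_graph()
    pairs, _ = balanced_pairs(g)
    options = sum(len(shared_balancers(pair, g)) for pair in pairs)
    triples = [
        frozenset(combo)
        for combo in combinations(MERIDIANS, 3)
        if not _check_pairwise_balanced(g, combo)
    ]
    return triples, options


def balanced_quads(
    g: BalanceGraph | None = None,
) -> tuple[list[BalancedPattern], int]:
    """The distinct ideally balanced 4-sets and the per-focus option count.

    The option count counts each distinct 4-set once per member (the
    cascade's 60 = 15 × 4); brute force over all C(12,4) = 495 subsets
    yields the 15 distinct patterns.
    """
    if g is None:
        g = merged_balance_graph()
    quads = [
        classify_pattern(combo, g)
        for combo in combinations(MERIDIANS, 4)
        if not _check_pairwise_balanced(g, combo)
    ]
    options = sum(sum(1 for q in quads if m in q) for m in MERIDIANS)
    return quads, options


def _focus_signature(members: Sequence[Meridian], focus: Meridian) -> tuple[int, ...]:
    return tuple(sorted(step_between(focus, m).value for m in members))


def classify_pattern(
    p: Iterable[Meridian], g: BalanceGraph | None = None
) -> BalancedPattern:
    """Validate a 4-set as ideally balanced and classify its geometry."""
    members = tuple(sorted(set(p), key=lambda m: m.clock_position))
    if len(members) != 4:
        raise ValueError(f"a balanced pattern has 4 distinct meridians, got {len(members)}")
    if g is None:
        g = merged_balance_graph()
    bad = _check_pairwise_balanced(g, members)
    if bad:
        pairs = ", ".join(f"{a.code}-{b.code}" for a, b in bad)
        raise ValueError(f"not an ideally balanced set; unbalanced pair(s): {pairs}")
    positions = {m.clock_position for m in members}
    if any({(q - 1 + 3 * i) % 12 + 1 for i in range(4)} == positions for q in positions):
        pattern_class = "every_third"
    elif any({(q - 1 + i) % 12 + 1 for i in range(4)} == positions for q in positions):
        pattern_class = "consecutive_window"
    else:  # unreachable for balanced sets; guards future graph variants
        raise ValueError(f"balanced set with unrecognized geometry: {sorted(positions)}")
    templates = {m.code: _focus_signature(members, m) for m in members}
    return BalancedPattern(members=members, pattern_class=pattern_class, templates=templates)


def patterns_for_meridian(
    m: Meridian, g: BalanceGraph | None = None
) -> list[BalancedPattern]:
    """The five ideally balanced patterns owned by focus meridian ``m``.

    Instantiates each of the five step templates at ``m``; each result is
    validated against the balance graph.
    """
    if g is None:
        g = merged_balance_graph()
    out = []
    for signature in TEMPLATE_SIGNATURES:
        members = [advance(m, s) for s in signature]
        out.append(classify_pattern(members, g))
    return out


def counting_cascade(g: BalanceGraph | None = None) -> EnumerationReport:
    """Recompute the whole pair → triple → quad counting cascade."""
    if g is None:
        g = merged_balance_graph()
    pairs, pair_options = balanced_pairs(g)
    shared_hist: dict[int, int] = {}
    for pair in pairs:
        k = len(shared_balancers(pair, g))
        shared_hist[k] = shared_hist.get(k, 0) + 1
    triples, triple_options = balanced_triples(g)
    completion_hist: dict[int, int] = {}
    for triple in triples:
        k = len(shared_balancers(triple, g))
        completion_hist[k] = completion_hist.get(k, 0) + 1
    quads, quad_options = balanced_quads(g)
    per_meridian = {
        m.code: sum(1 for q in quads if m in q) for m in MERIDIANS
    }
    counts = set(per_meridian.values())
    return EnumerationReport(
        pairs_with_multiplicity=pair_options,
        pairs_unique=len(pairs),
        shared_balancer_histogram=dict(sorted(shared_hist.items(), reverse=True)),
        triple_options=triple_options,
        triples_unique=len(triples),
        completion_histogram=dict(sorted(completion_hist.items(), reverse=True)),
        quad_options=quad_options,
        quads_unique=len(quads),
        patterns_per_meridian=counts.pop() if len(counts) == 1 else -1,
    )
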