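"""Enumeration of balanced meridian-pairing systems on the Chinese Clock.

A *pairing system* is a perfect matching of the 12 meridians into 6 pairs.
Historical acupuncture balancing systems (interior–exterior, neighbouring
channels, the 6-stage systems, opposite-clock needling) all satisfy four
intrinsic rules:

1. every meridian pairs with exactly one other (perfect matching);
2. the pair set has a rotation symmetry of 30°, 60° or 120° on the clock —
   i.e. it is invariant under rotation by 1, 2 or 4 positions;
3. at most two distinct step magnitudes are used (and a system using the
   half-clock step 5 uses it alone: step 5 cannot be mixed with another
   step without breaking the other rules, which is encoded here as an
   explicit purity rule);
4. the polarity profile is either six yin–yang pairs or three yin–yin plus
   three yang–yang pairs.

Brute force over all 10395 perfect matchings of 12 positions filtered by
these rules yields exactly 19 systems.  Merging the pair sets of the
non-step-5 systems gives the *balance graph*: every meridian acquires
exactly 7 balancing partners (steps ±1, ±2, ±3 and 6), for 42 edges in
total.  Pairs at distance 4 never balance, and no perfect matching can be
built from distance-4 pairs alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .clock import (
    MERIDIANS,
    Meridian,
    SignedStep,
    circular_distance,
    meridian_at,
    step_between,
)

__all__ = [
    "Matching",
    "RuleReport",
    "PairingSystem",
    "BalanceGraph",
    "HISTORICAL_SYSTEMS",
    "all_perfect_matchings",
    "passes_intrinsic_rules",
    "enumerate_systems",
    "step_signature_histogram",
    "name_historical",
    "merged_balance_graph",
]

# A matching is a canonical tuple of 6 (low, high) position pairs sorted by
# first element; positions are 1..12.
Pair = tuple[int, int]
Matching = tuple[Pair, ...]

ALLOWED_ROTATIONS = (1, 2, 4)  # 30°, 60°, 120° at 30° per clock position

# Reference pair sets for the historically described systems.
# 6-stage pairings follow the stage names: e.g. 6-stage I pairs the two
# meridians of each stage (Hand Tai Yin LU with Foot Tai Yin SP, ...).
HISTORICAL_SYSTEMS: dict[str, frozenset[Pair]] = {
    "interior-exterior": frozenset({(1, 2), (3, 4), (5, 6), (7, 8), (9, 10), (11, 12)}),
    "neighbouring channels": frozenset({(2, 3), (4, 5), (6, 7), (8, 9), (10, 11), (1, 12)}),
    "6-stage I": frozenset({(1, 4), (2, 3), (5, 8), (6, 7), (9, 12), (10, 11)}),
    "6-stage II": frozenset({(1, 3), (2, 4), (5, 7), (6, 8), (9, 11), (10, 12)}),
    "6-stage III": frozenset({(4, 6), (1, 7), (3, 9), (2, 12), (8, 10), (5, 11)}),
    "opposite clock": frozenset({(1, 7), (2, 8), (3, 9), (4, 10), (5, 11), (6, 12)}),
    "6-stage IV": frozenset({(6, 12), (7, 9), (2, 8), (3, 5), (4, 10), (1, 11)}),
}


def _canonical(pairs: Iterable[Sequence[int]]) -> Matching:
    return tuple(sorted(tuple(sorted(p)) for p in pairs))


def _pair_distance(p: Pair) -> int:
    return circular_distance(meridian_at(p[0]), meridian_at(p[1]))


def all_perfect_matchings() -> list[Matching]:
    """All 10395 (= 11!!) perfect matchings of the 12 clock positions.

    Each matching is produced exactly once in canonical form: the lowest
    unmatched position is always paired first, so the pair list is sorted.
    """
    results: list[Matching] = []

    def extend(remaining: tuple[int, ...], acc: list[Pair]) -> None:
        if not remaining:
            results.append(tuple(acc))
            return
        first, rest = remaining[0], remaining[1:]
        for i, partner in enumerate(rest):
            acc.append((first, partner))
            extend(rest[:i] + rest[i + 1 :], acc)
            acc.pop()

    extend(tuple(range(1, 13)), [])
    return results


def _rotate(matching: Iterable[Pair], r: int) -> Matching:
    return _canonical(
        ((a - 1 + r) % 12 + 1, (b - 1 + r) % 12 + 1) for a, b in matching
    )


def _symmetry_periods(matching: Matching) -> frozenset[int]:
    return frozenset(r for r in range(1, 12) if _rotate(matching, r) == matching)


def _polarity_profile(matching: Matching) -> str | None:
    """``all_mixed``, ``three_three`` or None when neither rule fits."""
    mixed = sum(
        1
        for a, b in matching
        if meridian_at(a).polarity != meridian_at(b).polarity
    )
    if mixed == 6:
        return "all_mixed"
    if mixed == 0:
        yin_pairs = sum(
            1 for a, b in matching if meridian_at(a).polarity == "yin"
        )
        if yin_pairs == 3:
            return "three_three"
    return None


@dataclass(frozen=True)
class RuleReport:
    """Rule-by-rule verdict of the intrinsic-rule filter for one matching."""

    matching: Matching
    rotation_symmetric: bool
    symmetry_periods: frozenset[int]
    at_most_two_steps: bool
    step_signature: tuple[int, ...]
    polarity_ok: bool
    polarity_profile: str | None
    step5_pure: bool

    @property
    def passed(self) -> bool:
        return (
            self.rotation_symmetric
            and self.at_most_two_steps
            and self.polarity_ok
            and self.step5_pure
        )

    def failures(self) -> list[str]:
        out = []
        if not self.rotation_symmetric:
            out.append("no 30°/60°/120° rotation symmetry")
        if not self.at_most_two_steps:
            out.append(f"more than 2 distinct steps {self.step_signature}")
        if not self.polarity_ok:
            out.append("polarity profile is neither 6 yin-yang nor 3+3 same-polarity")
        if not self.step5_pure:
            out.append("step 5 mixed with another step")
        return out


def passes_intrinsic_rules(matching: Iterable[Sequence[int]]) -> RuleReport:
    """Evaluate one perfect matching against the four intrinsic rules."""
    m = _canonical(matching)
    flat = [p for pair in m for p in pair]
    if sorted(flat) != list(range(1, 13)):
        raise ValueError(
            "input is not a perfect matching of positions 1..12: "
            f"{sorted(flat)}"
        )
    periods = _symmetry_periods(m)
    signature = tuple(sorted({_pair_distance(p) for p in m}))
    profile = _polarity_profile(m)
    return RuleReport(
        matching=m,
        rotation_symmetric=bool(periods & set(ALLOWED_ROTATIONS)),
        symmetry_periods=periods,
        at_most_two_steps=len(signature) <= 2,
        step_signature=signature,
        polarity_ok=profile is not None,
        polarity_profile=profile,
        step5_pure=(5 not in signature) or signature == (5,),
    )


@dataclass(frozen=True)
class PairingSystem:
    """A perfect pairing of the 12 meridians satisfying the intrinsic rules."""

    pairs: Matching
    step_signature: tuple[int, ...]
    symmetry_periods: frozenset[int]
    polarity_profile: str
    names: tuple[str, ...] = ()

    @property
    def meridian_pairs(self) -> list[tuple[Meridian, Meridian]]:
        return [(meridian_at(a), meridian_at(b)) for a, b in self.pairs]

    def contains_pair(self, a: Meridian, b: Meridian) -> bool:
        pair = tuple(sorted((a.clock_position, b.clock_position)))
        return pair in self.pairs

    @property
    def label(self) -> str:
        if self.names:
            return self.names[0]
        steps = "-".join(str(s) for s in self.step_signature)
        return f"calculated {steps}-step system {self.pairs}"

    def to_dict(self) -> dict[str, object]:
        return {
            "pairs": [
                [meridian_at(a).code, meridian_at(b).code] for a, b in self.pairs
            ],
            "positions": [list(p) for p in self.pairs],
            "step_signature": list(self.step_signature),
            "symmetry_periods": sorted(self.symmetry_periods),
            "polarity_profile": self.polarity_profile,
            "names": list(self.names),
        }


def name_historical(system: PairingSystem | Matching) -> list[str]:
    """Historical names of a system, by pair-set identity; [] if unnamed."""
    pairs = system.pairs if isinstance(system, PairingSystem) else _canonical(system)
    pair_set = frozenset(pairs)
    return [name for name, ref in HISTORICAL_SYSTEMS.items() if ref == pair_set]


def enumerate_systems() -> list[PairingSystem]:
    """All pairing systems satisfying the intrinsic rules (exactly 19).

    Brute force over the 10395 perfect matchings; each survivor is
    canonical, so set identity is free of duplicates.  Sorted by step
    signature then pair list for stable output.
    """
    systems: list[PairingSystem] = []
    for matching in all_perfect_matchings():
        report = passes_intrinsic_rules(matching)
        if not report.passed:
            continue
        assert report.polarity_profile is not None
        systems.append(
            PairingSystem(
                pairs=report.matching,
                step_signature=report.step_signature,
                symmetry_periods=report.symmetry_periods,
                polarity_profile=report.polarity_profile,
                names=tuple(name_historical(report.matching)),
            )
        )
    systems.sort(key=lambda s: (s.step_signature, s.pairs))
    return systems


def step_signature_histogram(
    systems: Iterable[PairingSystem],
) -> dict[tuple[int, ...], int]:
    """Count of systems per step signature (the published classification)."""
    return dict(Counter(s.step_signature for s in systems))


@dataclass
class BalanceGraph:
    """The merged graph of 2-meridian balancing options.

    Vertices are the 12 meridian codes; an edge joins two meridians that
    are paired in at least one enumerated system.  With step-5 systems
    excluded (the default — step-5 pairs belong to the extraordinary
    vessels and risk imbalance in multi-meridian combinations) the edge
    set is exactly the pairs at circular distance 1, 2, 3 or 6: degree 7
    everywhere, 42 edges.
    """

    graph: nx.Graph
    step5_excluded: bool
    systems: tuple[PairingSystem, ...] = field(default_factory=tuple)

    @property
    def meridians(self) -> tuple[Meridian, ...]:
        return MERIDIANS

    def neighbors(self, m: Meridian) -> set[Meridian]:
        from .clock import meridian_by_code

        return {meridian_by_code(c) for c in self.graph.neighbors(m.code)}

    def balances(self, a: Meridian, b: Meridian) -> bool:
        return self.graph.has_edge(a.code, b.code)

    def degree(self, m: Meridian) -> int:
        return self.graph.degree[m.code]

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[Meridian, Meridian]]:
        from .clock import meridian_by_code

        out = []
        for a, b in self.graph.edges:
            ma, mb = sorted(
                (meridian_by_code(a), meridian_by_code(b)),
                key=lambda m: m.clock_position,
            )
            out.append((ma, mb))
        out.sort(key=lambda e: (e[0].clock_position, e[1].clock_position))
        return out

    def supporting_systems(self, a: Meridian, b: Meridian) -> list[PairingSystem]:
        """The enumerated systems whose pair set contains the edge (a, b)."""
        if not self.graph.has_edge(a.code, b.code):
            return []
        return list(self.graph.edges[a.code, b.code]["systems"])

    def edge_step(self, a: Meridian, b: Meridian) -> SignedStep:
        return step_between(a, b)


def merged_balance_graph(
    exclude_step5: bool = True,
    systems: Sequence[PairingSystem] | None = None,
) -> BalanceGraph:
    """Merge the enumerated systems' pair sets into the balance graph.

    ``exclude_step5`` drops the two pure step-5 systems before merging
    (the default), reproducing the 7-options-per-meridian result.
    """
    if systems is None:
        systems = enumerate_systems()
    kept = [
        s for s in systems if not (exclude_step5 and 5 in s.step_signature)
    ]
    g = nx.Graph()
    g.add_nodes_from(m.code for m in MERIDIANS)
    for system in kept:
        for a, b in system.pairs:
            ma, mb = meridian_at(a), meridian_at(b)
            if g.has_edge(ma.code, mb.code):
                g.edges[ma.code, mb.code]["systems"].append(system)
            else:
                g.add_edge(
                    ma.code,
                    mb.code,
                    systems=[system],
                    step=step_between(ma, mb).value,
                    distance=circular_distance(ma, mb),
                )
    return BalanceGraph(graph=g, step5_excluded=exclude_step5, systems=tuple(systems))
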