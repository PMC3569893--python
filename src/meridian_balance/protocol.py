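"""Rule-based individualized point-selection protocol for localized pain.

The protocol treats localized pain by needling *balancing* meridians (per
the merged balance graph) in *somatotopically corresponding* body regions
(the Image and Mirror concept), guided by palpation for tender Ashi
points.  A session runs as a deterministic state machine:

1. identify the affected meridian, side, painful region and VAS (0-10);
2. pick an untreated extremity; the balancing candidates there are the
   meridians of the matching limb type that balance the affected meridian
   and every meridian already treated, restricted so that arms and legs
   each end up carrying one yin and one yang meridian (the affected
   meridian counts toward its own limb girdle);
3. palpate candidates in corresponding regions; treat the most tender
   finding; re-check VAS — stop early on complete relief;
4. after all three non-affected extremities, optionally treat the
   affected meridian itself.

Because candidates are always common balancers of everything already
involved, a completed 4-meridian session realizes one of the five ideally
balanced patterns of the affected meridian — the state machine cannot
leave the 15-pattern universe and never dead-ends.

The module also ships the somatotopic correspondence map, a scripted-case
replay runner (including the built-in shoulder-pain case), and a
synthetic-patient cohort simulator.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .clock import MERIDIANS, Meridian, meridian_by_code
from .patterns import BalancedPattern, classify_pattern
from .systems import BalanceGraph, merged_balance_graph

__all__ = [
    "REGION_ZONES",
    "Correspondence",
    "SomatotopicMap",
    "default_somatotopic_map",
    "corresponding_regions",
    "PatientPresentation",
    "AshiFinding",
    "TreatmentStep",
    "ProtocolState",
    "ProtocolError",
    "DeadEndError",
    "new_session",
    "untreated_extremities",
    "candidate_meridians",
    "select_treatment",
    "apply_step",
    "decline_affected",
    "is_complete",
    "final_pattern",
    "FinalReport",
    "StageScript",
    "CaseScript",
    "StageRecord",
    "ProtocolTrace",
    "run_scripted_case",
    "carpenter_case",
    "replay_case",
    "SimulationConfig",
    "simulate_cohort",
]

Side = Literal["left", "right"]
Zone = Literal["arm", "leg"]

# Fixed, versioned body-region vocabulary with its limb zone.
REGION_ZONES: dict[str, str] = {
    "shoulder": "arm",
    "upper_arm": "arm",
    "elbow": "arm",
    "forearm": "arm",
    "wrist": "arm",
    "hand": "arm",
    "hip": "leg",
    "thigh": "leg",
    "knee": "leg",
    "lower_leg": "leg",
    "ankle": "leg",
    "foot": "leg",
    "chest": "trunk",
    "abdomen": "trunk",
    "back": "trunk",
    "neck": "head",
    "face_eyes": "head",
    "face_nose": "head",
}

Region = Literal[
    "shoulder", "upper_arm", "elbow", "forearm", "wrist", "hand",
    "hip", "thigh", "knee", "lower_leg", "ankle", "foot",
    "chest", "abdomen", "back", "neck", "face_eyes", "face_nose",
]

SOMATOTOPIC_MAP_VERSION = "1.0"


def zone_of(m: Meridian) -> Zone:
    """Limb girdle of a meridian: hand meridians → arm, foot → leg."""
    return "arm" if m.limb == "hand" else "leg"


@dataclass(frozen=True)
class Correspondence:
    """One symmetric somatotopic link between two body regions.

    ``kind`` is ``image`` (upright projection of one body part onto
    another) or ``mirror`` (upside-down projection).  ``provenance`` is
    ``text`` for links stated in the source prose and ``extension`` for
    links completed from the standard upright arm↔leg/trunk projection.
    """

    regions: frozenset[str]
    kind: str
    provenance: str = "text"


# Upright image projection of the arm onto the leg (shoulder↔hip ...
# hand↔foot), the knee↔elbow/chest/face correspondents, the mirror
# (inverted) projections used for shoulder pain, and extension entries
# completing coverage of the trunk/neck regions.
_DEFAULT_CORRESPONDENCES: tuple[tuple[str, str, str, str], ...] = (
    ("shoulder", "hip", "image", "text"),
    ("upper_arm", "thigh", "image", "extension"),
    ("elbow", "knee", "image", "text"),
    ("forearm", "lower_leg", "image", "extension"),
    ("wrist", "ankle", "image", "text"),
    ("hand", "foot", "image", "text"),
    ("knee", "chest", "image", "text"),
    ("knee", "face_eyes", "mirror", "text"),
    ("knee", "face_nose", "mirror", "text"),
    ("shoulder", "ankle", "mirror", "text"),
    ("shoulder", "knee", "mirror", "text"),
    ("shoulder", "wrist", "mirror", "text"),
    ("shoulder", "elbow", "mirror", "text"),
    ("abdomen", "forearm", "image", "extension"),
    ("abdomen", "lower_leg", "image", "extension"),
    ("back", "upper_arm", "image", "extension"),
    ("back", "thigh", "image", "extension"),
    ("neck", "wrist", "mirror", "extension"),
    ("neck", "ankle", "mirror", "extension"),
)


@dataclass(frozen=True)
class SomatotopicMap:
    """Symmetric relation of somatotopically corresponding body regions."""

    correspondences: tuple[Correspondence, ...]
    version: str = SOMATOTOPIC_MAP_VERSION

    def corresponding(self, region: str) -> set[str]:
        if region not in REGION_ZONES:
            raise ValueError(
                f"unknown body region {region!r}; "
                f"expected one of {sorted(REGION_ZONES)}"
            )
        out: set[str] = set()
        for c in self.correspondences:
            if region in c.regions:
                out |= c.regions - {region}
        return out

    def extended(
        self, extra: Sequence[tuple[str, str, str]]
    ) -> "SomatotopicMap":
        """New map with user-supplied (region_a, region_b, kind) links."""
        added = []
        for a, b, kind in extra:
            for r in (a, b):
                if r not in REGION_ZONES:
                    raise ValueError(f"unknown body region {r!r}")
            if kind not in ("image", "mirror"):
                raise ValueError(f"correspondence kind must be image|mirror, got {kind!r}")
            added.append(Correspondence(frozenset({a, b}), kind, "user"))
        return SomatotopicMap(self.correspondences + tuple(added), self.version)


def default_somatotopic_map() -> SomatotopicMap:
    return SomatotopicMap(
        tuple(
            Correspondence(frozenset({a, b}), kind, prov)
            for a, b, kind, prov in _DEFAULT_CORRESPONDENCES
        )
    )


def corresponding_regions(
    region: str, smap: SomatotopicMap | None = None
) -> set[str]:
    """All image and mirror correspondents of ``region``."""
    return (smap or default_somatotopic_map()).corresponding(region)


# --------------------------------------------------------------------------
# Session data types

class PatientPresentation(BaseModel):
    """The step-1 intake: affected meridian, side, painful region, VAS."""

    model_config = ConfigDict(frozen=True)

    affected_meridian: str
    side: Side
    painful_region: Region
    vas: float = Field(ge=0, le=10)

    @property
    def meridian(self) -> Meridian:
        return meridian_by_code(self.affected_meridian)


class AshiFinding(BaseModel):
    """A palpation finding: tenderness (ordinal 0-10) at a region/meridian."""

    model_config = ConfigDict(frozen=True)

    meridian: str
    side: Side
    region: Region
    tenderness: float = Field(ge=0, le=10)


class TreatmentStep(BaseModel):
    """One needling decision: which meridian, side and region were treated."""

    model_config = ConfigDict(frozen=True)

    meridian: str
    side: Side
    region: Region
    needle_note: str = ""

    @property
    def meridian_obj(self) -> Meridian:
        return meridian_by_code(self.meridian)


class ProtocolError(ValueError):
    """A session request violating the protocol rules or state."""


class DeadEndError(ProtocolError):
    """No candidate meridian satisfies the constraints (must not occur)."""


@dataclass(frozen=True)
class ProtocolState:
    """Immutable snapshot of a protocol session."""

    presentation: PatientPresentation
    steps_taken: tuple[TreatmentStep, ...] = ()
    vas_history: tuple[float, ...] = ()
    affected_treated: bool = False
    affected_declined: bool = False

    @property
    def affected(self) -> Meridian:
        return self.presentation.meridian

    @property
    def affected_extremity(self) -> tuple[Zone, Side]:
        return (zone_of(self.affected), self.presentation.side)

    @property
    def balancing_steps(self) -> tuple[TreatmentStep, ...]:
        """Steps on non-affected extremities (excludes the affected-meridian step)."""
        return tuple(
            s for s in self.steps_taken if s.meridian != self.presentation.affected_meridian
        )

    @property
    def extremities_treated(self) -> set[tuple[Zone, Side]]:
        return {
            (zone_of(s.meridian_obj), s.side) for s in self.balancing_steps
        }

    @property
    def involved(self) -> set[Meridian]:
        return {self.affected} | {s.meridian_obj for s in self.steps_taken}

    def polarity_ledger(self) -> dict[Zone, list[str]]:
        """Per limb girdle, the polarities it carries (affected included)."""
        ledger: dict[Zone, list[str]] = {"arm": [], "leg": []}
        ledger[zone_of(self.affected)].append(self.affected.polarity)
        for s in self.balancing_steps:
            ledger[zone_of(s.meridian_obj)].append(s.meridian_obj.polarity)
        return ledger

    @property
    def current_vas(self) -> float:
        return self.vas_history[-1] if self.vas_history else self.presentation.vas

    @property
    def complete(self) -> bool:
        if self.current_vas <= 0:
            return True
        return len(self.balancing_steps) == 3 and (
            self.affected_treated or self.affected_declined
        )


def new_session(presentation: PatientPresentation) -> ProtocolState:
    """Open a session; the VAS history starts with the intake rating."""
    return ProtocolState(
        presentation=presentation, vas_history=(presentation.vas,)
    )


def is_complete(state: ProtocolState) -> bool:
    return state.complete


def untreated_extremities(state: ProtocolState) -> list[tuple[Zone, Side]]:
    """Non-affected extremities still available for a balancing step."""
    all_ext = [(z, s) for z in ("arm", "leg") for s in ("left", "right")]
    done = state.extremities_treated | {state.affected_extremity}
    return [e for e in all_ext if e not in done]


def _required_polarity(state: ProtocolState, zone: Zone) -> str | None:
    """Polarity forced on ``zone`` by the per-girdle yin/yang balance."""
    carried = state.polarity_ledger()[zone]
    if not carried:
        return None
    if len(carried) >= 2:
        raise ProtocolError(f"the {zone} girdle already carries two meridians")
    return "yin" if carried[0] == "yang" else "yang"


def _allowed_sides(
    state: ProtocolState, zone: Zone, side: Side | Literal["either"]
) -> list[Side]:
    occupied = {s for z, s in state.extremities_treated if z == zone}
    if zone == state.affected_extremity[0]:
        occupied.add(state.affected_extremity[1])
    sides: list[Side] = ["left", "right"] if side == "either" else [side]
    free = [s for s in sides if s not in occupied]
    if not free:
        raise ProtocolError(
            f"no free {zone} extremity for side={side!r} "
            f"(occupied: {sorted(occupied)})"
        )
    return free


def candidate_meridians(
    state: ProtocolState,
    target: tuple[Zone, Side | Literal["either"]],
    polarity_choice: Optional[str] = None,
    g: BalanceGraph | None = None,
) -> set[Meridian]:
    """Balancing candidates for the target extremity.

    Candidates have the limb type of the target zone, balance the
    affected meridian and every previously treated meridian, and respect
    the yin/yang girdle balance: once a girdle carries a polarity
    (the affected meridian counts for its own girdle), the other
    extremity of that girdle must take the opposite polarity.  The free
    ``polarity_choice`` applies only while the girdle is empty.

    The target extremity taken as the affected one itself is the optional
    final step: it yields {affected} once the three balancing steps are
    done.
    """
    if state.complete:
        raise ProtocolError("session is complete; no further candidates")
    zone, side = target
    if zone not in ("arm", "leg"):
        raise ProtocolError(f"target zone must be arm|leg, got {zone!r}")
    if g is None:
        g = merged_balance_graph()

    aff_zone, aff_side = state.affected_extremity
    if zone == aff_zone and side == aff_side:
        if len(state.balancing_steps) == 3 and not state.affected_treated:
            return {state.affected}
        raise ProtocolError(
            "the affected extremity may only be treated (with the affected "
            "meridian itself) after all three other extremities"
        )

    _allowed_sides(state, zone, side)  # raises if the extremity is occupied

    required = _required_polarity(state, zone)
    if polarity_choice is not None and polarity_choice not in ("yin", "yang"):
        raise ProtocolError(f"polarity must be yin|yang, got {polarity_choice!r}")
    if required is not None and polarity_choice not in (None, required):
        raise ProtocolError(
            f"the {zone} girdle already carries a {'yin' if required == 'yang' else 'yang'} "
            f"meridian; the next {zone} treatment must be {required}"
        )
    polarity = required or polarity_choice

    limb = "hand" if zone == "arm" else "foot"
    involved = state.involved
    candidates = {
        m
        for m in MERIDIANS
        if m.limb == limb
        and m not in involved
        and all(g.balances(m, other) for other in involved)
    }
    if polarity is not None:
        candidates = {m for m in candidates if m.polarity == polarity}
    if not candidates:
        raise DeadEndError(
            f"no balancing candidate for target {target} with polarity "
            f"{polarity}; involved: {sorted(m.code for m in involved)}"
        )
    return candidates


def select_treatment(
    state: ProtocolState,
    findings: Sequence[AshiFinding],
    target: tuple[Zone, Side | Literal["either"]],
    polarity_choice: Optional[str] = None,
    g: BalanceGraph | None = None,
    smap: SomatotopicMap | None = None,
) -> TreatmentStep:
    """Choose the treatment from palpation findings: most tender wins.

    Findings must lie on current candidate meridians, on a free side of
    the target, and in the painful region or one of its somatotopic
    correspondents.  Zero-tenderness findings are no Ashi at all.  Ties
    break deterministically: lower clock position first, then the side
    contralateral to the pain.
    """
    if g is None:
        g = merged_balance_graph()
    smap = smap or default_somatotopic_map()
    candidates = candidate_meridians(state, target, polarity_choice, g)
    zone, side = target
    aff_zone, aff_side = state.affected_extremity
    if zone == aff_zone and side == aff_side:
        sides: list[Side] = [aff_side]
    else:
        sides = _allowed_sides(state, zone, side)
    allowed_regions = {state.presentation.painful_region} | smap.corresponding(
        state.presentation.painful_region
    )
    codes = {m.code for m in candidates}
    for f in findings:
        if f.meridian not in codes:
            raise ProtocolError(
                f"finding on {f.meridian} is outside the candidate set {sorted(codes)}"
            )
        if f.side not in sides:
            raise ProtocolError(
                f"finding on the {f.side} {zone} but free side(s) are {sides}"
            )
        if f.region not in allowed_regions:
            raise ProtocolError(
                f"region {f.region!r} does not correspond to the painful region "
                f"{state.presentation.painful_region!r} "
                f"(allowed: {sorted(allowed_regions)})"
            )
    tender = [f for f in findings if f.tenderness > 0]
    if not tender:
        raise ProtocolError(
            "no tender Ashi findings; palpate other corresponding regions"
        )
    best = min(
        tender,
        key=lambda f: (
            -f.tenderness,
            meridian_by_code(f.meridian).clock_position,
            0 if f.side != state.presentation.side else 1,
        ),
    )
    return TreatmentStep(meridian=best.meridian, side=best.side, region=best.region)


def apply_step(
    state: ProtocolState,
    step: TreatmentStep,
    vas_after: float,
    g: BalanceGraph | None = None,
) -> ProtocolState:
    """Record a treatment step and the re-checked VAS; returns a new state."""
    if state.complete:
        raise ProtocolError("session is complete")
    if not 0 <= vas_after <= 10:
        raise ProtocolError(f"VAS must be in 0..10, got {vas_after}")
    if g is None:
        g = merged_balance_graph()
    m = step.meridian_obj
    if m == state.affected:
        if (zone_of(m), step.side) != state.affected_extremity:
            raise ProtocolError("the affected meridian is treated on the affected side")
        if len(state.balancing_steps) != 3 or state.affected_treated:
            raise ProtocolError(
                "the affected meridian may only be treated once, after all "
                "three other extremities"
            )
        new = replace(
            state,
            steps_taken=state.steps_taken + (step,),
            vas_history=state.vas_history + (vas_after,),
            affected_treated=True,
        )
        return new
    allowed = candidate_meridians(state, (zone_of(m), step.side), None, g)
    if m not in allowed:
        raise ProtocolError(
            f"{m.code} is not an admissible treatment for the {step.side} "
            f"{zone_of(m)} (candidates: {sorted(c.code for c in allowed)})"
        )
    return replace(
        state,
        steps_taken=state.steps_taken + (step,),
        vas_history=state.vas_history + (vas_after,),
    )


def decline_affected(state: ProtocolState) -> ProtocolState:
    """Close the session without the optional affected-meridian step."""
    if len(state.balancing_steps) != 3:
        raise ProtocolError(
            "the affected-meridian step can only be declined after all "
            "three other extremities are treated"
        )
    return replace(state, affected_declined=True)


@dataclass(frozen=True)
class FinalReport:
    """Outcome of a session: the realized pattern, or a partial set."""

    members: tuple[str, ...]
    pattern: Optional[BalancedPattern]
    partial: bool

    def to_dict(self) -> dict[str, object]:
        return {
            "members": list(self.members),
            "pattern": self.pattern.to_dict() if self.pattern else None,
            "partial": self.partial,
        }


def final_pattern(
    state: ProtocolState, g: BalanceGraph | None = None
) -> FinalReport:
    """Classify the meridians of a finished session against the 15 patterns."""
    members = sorted(state.involved, key=lambda m: m.clock_position)
    codes = tuple(m.code for m in members)
    if len(members) < 4:
        return FinalReport(members=codes, pattern=None, partial=True)
    pattern = classify_pattern(members, g or merged_balance_graph())
    return FinalReport(members=codes, pattern=pattern, partial=False)


# --------------------------------------------------------------------------
# Scripted cases and replay

class StageScript(BaseModel):
    """One scripted stage: the target, the palpation findings, the VAS after."""

    model_config = ConfigDict(frozen=True)

    target_zone: Literal["arm", "leg", "affected"]
    target_side: Literal["left", "right", "either"] = "either"
    polarity: Optional[Literal["yin", "yang"]] = None
    findings: tuple[AshiFinding, ...]
    vas_after: float = Field(ge=0, le=10)


class CaseScript(BaseModel):
    """A fully scripted protocol session (replayable, deterministic)."""

    model_config = ConfigDict(frozen=True)

    schema_version: str = "1.0"
    presentation: PatientPresentation
    stages: tuple[StageScript, ...]


class StageRecord(BaseModel):
    """What happened at one stage of an executed session."""

    model_config = ConfigDict(frozen=True)

    target_zone: str
    target_side: str
    polarity: Optional[str]
    candidates: tuple[str, ...]
    step: TreatmentStep
    vas_after: float


class ProtocolTrace(BaseModel):
    """Full record of an executed session."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    presentation: PatientPresentation
    stages: tuple[StageRecord, ...]
    vas_history: tuple[float, ...]
    members: tuple[str, ...]
    pattern_class: Optional[str]
    partial: bool

    @property
    def treated_sequence(self) -> tuple[str, ...]:
        return tuple(s.step.meridian for s in self.stages)

    def to_dict(self) -> dict[str, object]:
        return self.model_dump(mode="json")


def run_scripted_case(
    script: CaseScript,
    g: BalanceGraph | None = None,
    smap: SomatotopicMap | None = None,
) -> ProtocolTrace:
    """Execute a scripted case through the protocol state machine."""
    if g is None:
        g = merged_balance_graph()
    smap = smap or default_somatotopic_map()
    state = new_session(script.presentation)
    records: list[StageRecord] = []
    for stage in script.stages:
        if state.complete:
            raise ProtocolError("script continues past session completion")
        if stage.target_zone == "affected":
            target = state.affected_extremity
        else:
            target = (stage.target_zone, stage.target_side)
        cands = candidate_meridians(state, target, stage.polarity, g)
        step = select_treatment(
            state, list(stage.findings), target, stage.polarity, g, smap
        )
        state = apply_step(state, step, stage.vas_after, g)
        records.append(
            StageRecord(
                target_zone=target[0],
                target_side=stage.target_side,
                polarity=stage.polarity,
                candidates=tuple(sorted(m.code for m in cands)),
                step=step,
                vas_after=stage.vas_after,
            )
        )
    report = final_pattern(state, g)
    return ProtocolTrace(
        presentation=script.presentation,
        stages=tuple(records),
        vas_history=state.vas_history,
        members=report.members,
        pattern_class=report.pattern.pattern_class if report.pattern else None,
        partial=report.partial,
    )


def carpenter_case() -> CaseScript:
    """The built-in shoulder-pain replay fixture.

    A carpenter with severe right-shoulder pain (VAS 9) on the SI
    meridian: legs first with a yang meridian (candidates ST and BL;
    tender Ashi at the left ankle on BL), then the right leg with a yin
    meridian (candidates KI and SP; tender at the right ankle on SP),
    then the left arm (sole candidate HT; tender at the elbow), and
    finally the affected SI meridian itself at the wrist.  VAS runs
    9 → 5 → 3 → 1 → <1.
    """
    f = AshiFinding
    return CaseScript(
        presentation=PatientPresentation(
            affected_meridian="SI", side="right", painful_region="shoulder", vas=9
        ),
        stages=(
            StageScript(
                target_zone="leg",
                target_side="either",
                polarity="yang",
                findings=(
                    f(meridian="ST", side="left", region="ankle", tenderness=0),
                    f(meridian="ST", side="right", region="ankle", tenderness=0),
                    f(meridian="BL", side="left", region="knee", tenderness=2),
                    f(meridian="BL", side="left", region="ankle", tenderness=8),
                    f(meridian="BL", side="right", region="ankle", tenderness=4),
                ),
                vas_after=5,
            ),
            StageScript(
                target_zone="leg",
                target_side="right",
                polarity="yin",
                findings=(
                    f(meridian="KI", side="right", region="ankle", tenderness=0),
                    f(meridian="SP", side="right", region="knee", tenderness=2),
                    f(meridian="SP", side="right", region="ankle", tenderness=7),
                ),
                vas_after=3,
            ),
            StageScript(
                target_zone="arm",
                target_side="left",
                polarity="yin",
                findings=(
                    f(meridian="HT", side="left", region="shoulder", tenderness=2),
                    f(meridian="HT", side="left", region="elbow", tenderness=8),
                ),
                vas_after=1,
            ),
            StageScript(
                target_zone="affected",
                findings=(
                    f(meridian="SI", side="right", region="wrist", tenderness=7),
                    f(meridian="SI", side="right", region="elbow", tenderness=3),
                ),
                vas_after=0.5,
            ),
        ),
    )


def replay_case(
    g: BalanceGraph | None = None, smap: SomatotopicMap | None = None
) -> ProtocolTrace:
    """Replay the built-in shoulder-pain case through the engine."""
    return run_scripted_case(carpenter_case(), g, smap)


# --------------------------------------------------------------------------
# Synthetic-patient simulator

class SimulationConfig(BaseModel):
    """Knobs of the synthetic cohort generator.

    Tenderness is drawn uniformly on the 0-10 ordinal scale; each
    treatment removes a uniform fraction of the current VAS in
    [relief_min, relief_max], echoing the roughly-halving trajectory of
    the built-in case.  The affected meridian itself is treated whenever
    the residual VAS exceeds ``treat_affected_above_vas``.
    """

    model_config = ConfigDict(frozen=True)

    vas_min: int = Field(default=3, ge=1, le=10)
    vas_max: int = Field(default=9, ge=1, le=10)
    relief_min: float = Field(default=0.3, ge=0.0, le=1.0)
    relief_max: float = Field(default=0.7, ge=0.0, le=1.0)
    treat_affected_above_vas: float = Field(default=0.0, ge=0.0, le=10.0)
    max_tenderness: int = Field(default=10, ge=1, le=10)

    def validated(self) -> "SimulationConfig":
        if self.vas_min > self.vas_max:
            raise ValueError("vas_min must not exceed vas_max")
        if self.relief_min > self.relief_max:
            raise ValueError("relief_min must not exceed relief_max")
        return self


def _simulate_one(
    rng: random.Random,
    config: SimulationConfig,
    g: BalanceGraph,
    smap: SomatotopicMap,
) -> ProtocolTrace:
    affected = rng.choice(MERIDIANS)
    side: Side = rng.choice(["left", "right"])
    zone = zone_of(affected)
    region = rng.choice(
        sorted(r for r, z in REGION_ZONES.items() if z == zone)
    )
    presentation = PatientPresentation(
        affected_meridian=affected.code,
        side=side,
        painful_region=region,
        vas=rng.randint(config.vas_min, config.vas_max),
    )
    state = new_session(presentation)
    records: list[StageRecord] = []
    regions = sorted({region} | smap.corresponding(region))
    extremities = untreated_extremities(state)
    rng.shuffle(extremities)
    for target in extremities:
        if state.complete:
            break
        polarity = None
        if _required_polarity(state, target[0]) is None:
            polarity = rng.choice(["yin", "yang"])
        cands = candidate_meridians(state, target, polarity, g)
        findings = [
            AshiFinding(
                meridian=c.code,
                side=target[1],
                region=r,
                tenderness=rng.randint(0, config.max_tenderness),
            )
            for c in sorted(cands, key=lambda m: m.clock_position)
            for r in regions
        ]
        if all(f.tenderness == 0 for f in findings):
            bumped = findings[rng.randrange(len(findings))]
            findings[findings.index(bumped)] = bumped.model_copy(
                update={"tenderness": float(rng.randint(1, config.max_tenderness))}
            )
        step = select_treatment(state, findings, target, polarity, g, smap)
        relief = rng.uniform(config.relief_min, config.relief_max)
        vas_after = round(state.current_vas * (1 - relief))
        state = apply_step(state, step, vas_after, g)
        records.append(
            StageRecord(
                target_zone=target[0],
                target_side=target[1],
                polarity=polarity,
                candidates=tuple(sorted(m.code for m in cands)),
                step=step,
                vas_after=vas_after,
            )
        )
    if not state.complete and state.current_vas > config.treat_affected_above_vas:
        target = state.affected_extremity
        step = TreatmentStep(
            meridian=affected.code, side=presentation.side, region=rng.choice(regions)
        )
        relief = rng.uniform(config.relief_min, config.relief_max)
        vas_after = round(state.current_vas * (1 - relief))
        state = apply_step(state, step, vas_after, g)
        records.append(
            StageRecord(
                target_zone=target[0],
                target_side=target[1],
                polarity=None,
                candidates=(affected.code,),
                step=step,
                vas_after=vas_after,
            )
        )
    elif not state.complete:
        state = decline_affected(state)
    report = final_pattern(state, g)
    return ProtocolTrace(
        presentation=presentation,
        stages=tuple(records),
        vas_history=state.vas_history,
        members=report.members,
        pattern_class=report.pattern.pattern_class if report.pattern else None,
        partial=report.partial,
    )


def simulate_cohort(
    seed: int,
    n: int,
    config: SimulationConfig | None = None,
    g: BalanceGraph | None = None,
    smap: SomatotopicMap | None = None,
) -> tuple[list[ProtocolTrace], dict[str, object]]:
    """Run ``n`` synthetic patients through the protocol, reproducibly.

    Returns the traces and a summary tabulating the emitted 4-meridian
    patterns (always among the 15) and any early-stopped partial traces.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    config = (config or SimulationConfig()).validated()
    if g is None:
        g = merged_balance_graph()
    smap = smap or default_somatotopic_map()
    rng = random.Random(seed)
    traces = [_simulate_one(rng, config, g, smap) for _ in range(n)]
    pattern_counts = Counter(
        "-".join(t.members) for t in traces if not t.partial
    )
    summary: dict[str, object] = {
        "n": n,
        "complete_patterns": dict(sorted(pattern_counts.items())),
        "distinct_patterns": len(pattern_counts),
        "partial": sum(1 for t in traces if t.partial),
        "mean_final_vas": sum(t.vas_history[-1] for t in traces) / n,
    }
    return traces, summary
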