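"""The Chinese Clock: the 12 acupuncture meridians in their cyclic order.

Traditional Chinese medicine postulates a continuous circulation of Qi
through the 12 principal meridians in a fixed order — LU, LI, ST, SP, HT,
SI, BL, KI, PC, TE, GB, LR — known as the Chinese Clock (CC).  Every
combinatorial construction in this package reduces to step arithmetic on
that cycle, so this module pins down the conventions once:

* clock positions are 1-based in the order above;
* "clockwise" means increasing position (step 1 clockwise from LU is LI,
  the interior–exterior partner);
* the opposite-clock step is canonicalized to +6, so every unordered pair
  of meridians has exactly one signed-step representation.

Polarity (yin/yang) and limb (hand/foot) both repeat with period 4 around
the clock: yin, yang, yang, yin and hand, hand, foot, foot.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "Meridian",
    "SignedStep",
    "MERIDIANS",
    "CODES",
    "meridian_at",
    "meridian_by_code",
    "advance",
    "step_between",
    "circular_distance",
    "reference_table",
    "export_reference",
]

CODES = ("LU", "LI", "ST", "SP", "HT", "SI", "BL", "KI", "PC", "TE", "GB", "LR")

# Period-4 cycles around the clock, anchored at position 1 (LU).
_POLARITY_CYCLE = ("yin", "yang", "yang", "yin")
_LIMB_CYCLE = ("hand", "hand", "foot", "foot")

_STAGE_NAMES = {
    "LU": "Hand Tai Yin",
    "LI": "Hand Yang Ming",
    "ST": "Foot Yang Ming",
    "SP": "Foot Tai Yin",
    "HT": "Hand Shao Yin",
    "SI": "Hand Tai Yang",
    "BL": "Foot Tai Yang",
    "KI": "Foot Shao Yin",
    "PC": "Hand Jue Yin",
    "TE": "Hand Shao Yang",
    "GB": "Foot Shao Yang",
    "LR": "Foot Jue Yin",
}


@dataclass(frozen=True, order=True)
class Meridian:
    """One of the 12 principal meridians, with its clock attributes.

    Sort order is clock order (``clock_position`` is the first field).
    """

    clock_position: int
    code: str
    polarity: str
    limb: str
    stage_name: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


MERIDIANS: tuple[Meridian, ...] = tuple(
    Meridian(
        clock_position=i + 1,
        code=code,
        polarity=_POLARITY_CYCLE[i % 4],
        limb=_LIMB_CYCLE[i % 4],
        stage_name=_STAGE_NAMES[code],
    )
    for i, code in enumerate(CODES)
)

_BY_CODE = {m.code: m for m in MERIDIANS}


@dataclass(frozen=True)
class SignedStep:
    """A signed step on the Chinese Clock.

    ``value`` ranges over {-5..-1, 0, +1..+6}; positive is clockwise.  The
    half-turn (opposite clock) is always +6, never -6, so each unordered
    meridian pair maps to a unique signed step.
    """

    value: int

    def __post_init__(self) -> None:
        if not -5 <= self.value <= 6:
            raise ValueError(
                f"step value must be in -5..+6 (got {self.value}); "
                "the opposite-clock step is canonicalized to +6"
            )

    @property
    def magnitude(self) -> int:
        return abs(self.value)

    def __neg__(self) -> "SignedStep":
        if self.value == 6:
            return self
        return SignedStep(-self.value)

    def __int__(self) -> int:
        return self.value


def meridian_at(position: int) -> Meridian:
    """Return the meridian at a 1-based clock position."""
    if not isinstance(position, int) or isinstance(position, bool):
        raise TypeError(f"position must be an integer, got {position!r}")
    if not 1 <= position <= 12:
        raise ValueError(f"clock position must be in 1..12, got {position}")
    return MERIDIANS[position - 1]


def meridian_by_code(code: str) -> Meridian:
    """Return the meridian with the given two-letter code (e.g. ``"LU"``)."""
    try:
        return _BY_CODE[code.upper()]
    except KeyError:
        raise ValueError(
            f"unknown meridian code {code!r}; expected one of {', '.join(CODES)}"
        ) from None


def advance(m: Meridian, s: SignedStep | int) -> Meridian:
    """Move ``s`` steps around the clock from ``m`` (clockwise positive)."""
    value = int(s) if isinstance(s, SignedStep) else SignedStep(s).value
    return MERIDIANS[(m.clock_position - 1 + value) % 12]


def step_between(a: Meridian, b: Meridian) -> SignedStep:
    """The minimal-magnitude signed step carrying ``a`` to ``b``.

    At distance 6 both directions tie; the canonical +6 is returned.
    """
    d = (b.clock_position - a.clock_position) % 12
    if d == 6:
        return SignedStep(6)
    return SignedStep(d) if d < 6 else SignedStep(d - 12)


def circular_distance(a: Meridian, b: Meridian) -> int:
    """Unsigned clock distance between two meridians, 0..6."""
    d = abs(a.clock_position - b.clock_position)
    return min(d, 12 - d)


def reference_table() -> list[dict[str, object]]:
    """The embedded meridian reference data as a list of plain records."""
    return [
        {
            "code": m.code,
            "position": m.clock_position,
            "polarity": m.polarity,
            "limb": m.limb,
            "stage_name": m.stage_name,
        }
        for m in MERIDIANS
    ]


def export_reference(fmt: str = "json") -> str:
    """Serialize the reference table as ``json`` or ``csv`` text."""
    rows = reference_table()
    if fmt == "json":
        return json.dumps(rows, indent=2)
    if fmt == "csv":
        buf = _io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
        return buf.getvalue()
    raise ValueError(f"unsupported format {fmt!r}; expected 'json' or 'csv'")


def iter_pairs() -> Iterator[tuple[Meridian, Meridian]]:
    """All 66 unordered meridian pairs in clock order."""
    for i, a in enumerate(MERIDIANS):
        for b in MERIDIANS[i + 1 :]:
            yield a, b
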