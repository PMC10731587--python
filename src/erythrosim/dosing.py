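"""Dose events and regimen expansion.

Patterns follow trial shorthand: QD (daily), QW (weekly), Q2W (biweekly),
TIW (three times weekly, Mon/Wed/Fri convention: days 0, 2, 4 of each week),
or an explicit list of within-week offsets in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import units
from .drugs import DrugSpec

ROUTES = ("SC", "IV", "oral")

#: dosing-time offsets (h) within one repeating block, and the block length (h)
_PATTERNS = {
    "QD": ((0.0,), 24.0),
    "QW": ((0.0,), 168.0),
    "Q2W": ((0.0,), 336.0),
    "TIW": ((0.0, 48.0, 96.0), 168.0),
}


@dataclass(frozen=True)
class DoseEvent:
    time: float          # h
    drug: str
    amount: float        # in the drug's labelled unit (IU, ug or mg)
    route: str = "SC"

    def __post_init__(self):
        if self.amount < 0:
            raise ValueError("dose amount must be non-negative")
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")


@dataclass
class Regimen:
    drug: DrugSpec
    pattern: str                 # QD / QW / Q2W / TIW / custom
    dose: float                  # per-administration amount (drug units)
    start: float = 0.0           # h
    duration_weeks: float = 0.0
    route: str | None = None     # default: oral for PHI, SC for ESA
    per_kg: bool = False
    body_weight_kg: float = 70.0
    custom_offsets: Sequence[float] | None = None   # h within one week

    def default_route(self) -> str:
        if self.route is not None:
            return self.route
        return "oral" if self.drug.kind == "phi" else "SC"


def expand_regimen(regimen: Regimen) -> list[DoseEvent]:
    """Expand a repeating regimen into an ordered list of dose events."""
    if regimen.duration_weeks < 0:
        raise ValueError("duration must be non-negative")
    route = regimen.default_route()
    if regimen.drug.kind == "phi" and route != "oral":
        raise ValueError("PHIs are dosed orally")
    if regimen.drug.kind == "esa" and route == "oral":
        raise ValueError("ESAs are dosed SC or IV")

    amount = regimen.dose
    if regimen.per_kg:
        amount = amount * regimen.body_weight_kg

    if regimen.pattern == "custom":
        if regimen.custom_offsets is None:
            raise ValueError("custom pattern requires custom_offsets")
        offsets, block = tuple(regimen.custom_offsets), units.HOURS_PER_WEEK
    elif regimen.pattern in _PATTERNS:
        offsets, block = _PATTERNS[regimen.pattern]
    else:
        raise ValueError(f"unknown dosing pattern {regimen.pattern!r}")

    end = regimen.start + regimen.duration_weeks * units.HOURS_PER_WEEK
    events: list[DoseEvent] = []
    t_block = regimen.start
    while t_block < end - 1e-9:
        for off in offsets:
            t = t_block + off
            if t < end - 1e-9:
                events.append(DoseEvent(time=t, drug=regimen.drug.name,
                                        amount=amount, route=route))
        t_block += block
    events.sort(key=lambda e: e.time)
    return events
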