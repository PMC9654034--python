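"""Battery-autonomy budget for a receiver buoy.

A surface receiver runs from two 12 V / 10 Ah gel batteries (20 Ah total);
the electronics draw ~650 mW on average with a 1 W worst case when
transmitting permanently.  With the solar panel out of the picture the
autonomy is the closed-form energy budget

    hours = V * Ah / W

which gives 240 h in the worst case and 369 h in the average case for the
reference unit.
"""

from __future__ import annotations

from dataclasses import dataclass


class PowerDomainError(ValueError):
    pass


@dataclass(frozen=True)
class PowerBudget:
    """Battery bank voltage (V), total capacity (Ah) and load (W)."""

    battery_voltage: float
    battery_capacity_ah: float
    consumption_w: float

    def __post_init__(self) -> None:
        if self.battery_voltage <= 0:
            raise PowerDomainError("battery voltage must be positive")
        if self.battery_capacity_ah <= 0:
            raise PowerDomainError("battery capacity must be positive")
        if self.consumption_w <= 0:
            raise PowerDomainError("consumption must be positive")


def autonomy_hours(budget: PowerBudget) -> float:
    """Exact autonomy in hours: stored energy (Wh) over draw (W)."""
    return budget.battery_voltage * budget.battery_capacity_ah / budget.consumption_w


def autonomy_hours_rounded(budget: PowerBudget) -> int:
    """Autonomy rounded to integer hours (round-half-to-even)."""
    return round(autonomy_hours(budget))
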