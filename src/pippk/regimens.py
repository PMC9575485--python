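"""Infusion schedules for the compared piperacillin dosing regimens.

Five regimen families are supported, all dosed per kg of body weight with
an absolute cap on the daily piperacillin amount (16 g/day):

* ``IA_q8h`` / ``IA_q6h`` — intermittent administration: the capped daily
  dose split into 3 or 4 short infusions (default 5 min).
* ``EI_q8h`` / ``EI_q6h`` — extended infusion: the same split, but each
  infusion runs for half the dosing interval (4 h or 3 h).
* ``CI`` — continuous infusion at a fixed rate over 24 h, optionally
  preceded by a loading bolus that is *not* subtracted from the daily dose.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DAILY_DOSE_CAP_MG",
    "DEFAULT_BOLUS_DURATION_H",
    "REGIMEN_LABELS",
    "InfusionEvent",
    "Regimen",
    "build_regimen",
    "cap_weight",
    "capped_daily_dose",
    "dosing_interval",
]

DAILY_DOSE_CAP_MG = 16000.0
DEFAULT_BOLUS_DURATION_H = 1.0 / 12.0  # 5 min

#: label -> (dosing interval h, infusion lasts half the interval)
REGIMEN_LABELS: dict[str, tuple[float, bool] | None] = {
    "IA_q8h": (8.0, False),
    "IA_q6h": (6.0, False),
    "EI_q8h": (8.0, True),
    "EI_q6h": (6.0, True),
    "CI": None,
}


@dataclass(frozen=True)
class InfusionEvent:
    start: float     # h
    duration: float  # h; boluses are short infusions
    amount: float    # mg

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("event start must be non-negative")
        if not self.duration > 0:
            raise ValueError("event duration must be strictly positive")
        if self.amount < 0:
            raise ValueError("event amount must be non-negative")

    @property
    def rate(self) -> float:
        """Infusion rate, mg/h."""
        return self.amount / self.duration


@dataclass(frozen=True)
class Regimen:
    label: str
    daily_dose_per_kg: float  # mg/kg/day (nominal, before cap)
    weight: float             # kg
    events: tuple[InfusionEvent, ...]

    @property
    def daily_maintenance_mg(self) -> float:
        """Capped maintenance amount per 24 h."""
        return capped_daily_dose(self.daily_dose_per_kg, self.weight)

    @property
    def interval(self) -> float:
        """Dosing interval in hours (24 for continuous infusion)."""
        spec = REGIMEN_LABELS[self.label]
        return 24.0 if spec is None else spec[0]


def capped_daily_dose(daily_dose_per_kg: float, weight: float) -> float:
    """Daily maintenance amount in mg, capped at 16 000 mg/day."""
    if not daily_dose_per_kg > 0:
        raise ValueError("daily dose must be strictly positive")
    if not weight > 0:
        raise ValueError("weight must be strictly positive")
    return min(daily_dose_per_kg * weight, DAILY_DOSE_CAP_MG)


def cap_weight(daily_dose_per_kg: float) -> float:
    """Body weight (kg) at which per-kg dosing reaches the 16 g/day cap."""
    if not daily_dose_per_kg > 0:
        raise ValueError("daily dose must be strictly positive")
    return DAILY_DOSE_CAP_MG / daily_dose_per_kg


def dosing_interval(label: str) -> float:
    spec = _lookup(label)
    return 24.0 if spec is None else spec[0]


def _lookup(label: str):
    try:
        return REGIMEN_LABELS[label]
    except KeyError:
        raise ValueError(
            f"unknown regimen label {label!r}; expected one of {sorted(REGIMEN_LABELS)}"
        ) from None


def build_regimen(
    label: str,
    daily_dose_per_kg: float,
    weight: float,
    n_days: int = 3,
    loading_mg_per_kg: float | None = None,
    bolus_duration: float = DEFAULT_BOLUS_DURATION_H,
) -> Regimen:
    """Build the infusion schedule for one regimen family.

    For intermittent administration the capped daily dose is split into
    equal short infusions of ``bolus_duration``; for extended infusion each
    infusion lasts half the dosing interval; for continuous infusion an
    optional loading bolus (not subtracted from the daily dose) precedes a
    constant-rate infusion.
    """
    spec = _lookup(label)
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    if not bolus_duration > 0:
        raise ValueError("bolus_duration must be strictly positive")
    daily = capped_daily_dose(daily_dose_per_kg, weight)

    events: list[InfusionEvent] = []
    if spec is None:  # continuous infusion
        t0 = 0.0
        if loading_mg_per_kg:
            events.append(InfusionEvent(0.0, bolus_duration, loading_mg_per_kg * weight))
            t0 = bolus_duration
        events.append(InfusionEvent(t0, 24.0 * n_days, daily * n_days))
    else:
        interval, extended = spec
        per_day = int(round(24.0 / interval))
        amount = daily / per_day
        duration = interval / 2.0 if extended else bolus_duration
        if loading_mg_per_kg:
            events.append(InfusionEvent(0.0, bolus_duration, loading_mg_per_kg * weight))
        for k in range(per_day * n_days):
            events.append(InfusionEvent(k * interval, duration, amount))
    return Regimen(
        label=label,
        daily_dose_per_kg=daily_dose_per_kg,
        weight=weight,
        events=tuple(events),
    )
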