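"""Loading/maintenance dose calculators and the study's named regimens.

The loading dose fills the steady-state volume of distribution to the target
concentration, ``loading = target * Vss / F``; the maintenance rate replaces
elimination, ``rate = target * CL / F``.  Both are computed on the quinidine
base scale and converted to the sulfate-dihydrate scale (factor 1.206) for
prescription, matching how doses are reported clinically.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .structural_pk import (
    DoseEvent,
    PKParameters,
    Regimen,
    secondary_parameters,
    to_salt_dose,
)

__all__ = [
    "TherapeuticWindow",
    "DoseRecommendation",
    "loading_dose",
    "maintenance_dose",
    "dose_table",
    "build_named_regimen",
    "NAMED_REGIMENS",
]


@dataclass(frozen=True)
class TherapeuticWindow:
    """Plasma-concentration window (μg/mL): therapeutic floor, toxicity ceiling.

    The study derived 2.0 μg/mL as the median concentration at conversion to
    sinus rhythm and 3.8 μg/mL as the median concentration at which adverse
    effects appeared.
    """

    lower: float = 2.0
    upper: float = 3.8

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError("window requires 0 < lower < upper")


@dataclass(frozen=True)
class DoseRecommendation:
    """Loading and maintenance doses for one target concentration."""

    target: float
    loading_base: float
    loading_salt: float
    maintenance_rate_base: float
    maintenance_rate_salt: float
    interval: float
    per_interval_base: float
    per_interval_salt: float


def loading_dose(target: float, p: PKParameters) -> float:
    """Loading dose (mg/kg quinidine base) to reach ``target`` μg/mL at once."""
    if target < 0:
        raise ValueError("target concentration must be non-negative")
    vss = secondary_parameters(p)["Vss"]
    return target * vss / p.F


def maintenance_dose(
    target: float, p: PKParameters, interval: float = 2.0
) -> dict[str, float]:
    """Maintenance rate (mg/kg/h base) and per-interval dose holding ``target``."""
    if target < 0:
        raise ValueError("target concentration must be non-negative")
    if interval <= 0:
        raise ValueError("dosing interval must be positive")
    rate = target * p.CL / p.F
    return {"rate": rate, "per_interval": rate * interval, "interval": interval}


def dose_table(
    targets: list[float],
    p: PKParameters,
    interval: float = 2.0,
    salt: str = "sulfate_dihydrate",
) -> list[DoseRecommendation]:
    """Dose recommendations for a list of target concentrations."""
    rows = []
    for target in targets:
        load = loading_dose(target, p)
        maint = maintenance_dose(target, p, interval)
        rows.append(
            DoseRecommendation(
                target=target,
                loading_base=load,
                loading_salt=to_salt_dose(load, salt),
                maintenance_rate_base=maint["rate"],
                maintenance_rate_salt=to_salt_dose(maint["rate"], salt),
                interval=interval,
                per_interval_base=maint["per_interval"],
                per_interval_salt=to_salt_dose(maint["per_interval"], salt),
            )
        )
    return rows


def dose_table_frame(recommendations: list[DoseRecommendation]) -> pd.DataFrame:
    """Dose recommendations as a table in the clinical reporting layout."""
    return pd.DataFrame(
        {
            "target_ug_per_ml": [r.target for r in recommendations],
            "loading_base_mg_per_kg": [r.loading_base for r in recommendations],
            "loading_sulfate_mg_per_kg": [r.loading_salt for r in recommendations],
            "maintenance_base_mg_per_kg_h": [
                r.maintenance_rate_base for r in recommendations
            ],
            "maintenance_sulfate_mg_per_kg_h": [
                r.maintenance_rate_salt for r in recommendations
            ],
        }
    )


def _po(time: float, amount: float) -> DoseEvent:
    return DoseEvent(time=time, amount=amount, route="PO", salt="sulfate_dihydrate")


def _load_maintain(
    loading: float, maintenance: float, interval: float, last_time: float, offset: float = 0.0
) -> list[DoseEvent]:
    events = [_po(offset, loading)]
    t = offset + interval
    while t <= offset + last_time + 1e-9:
        events.append(_po(t, maintenance))
        t += interval
    return events


def _classical_q2h(n_doses: int = 4) -> Regimen:
    return Regimen(
        events=tuple(_po(2.0 * i, 22.0) for i in range(n_doses)),
        label="classical_q2h",
    )


def _classical_q6h() -> Regimen:
    return Regimen(events=(_po(0.0, 22.0), _po(6.0, 22.0)), label="classical_q6h")


def _load30(last_time: float = 22.0) -> Regimen:
    return Regimen(
        events=tuple(_load_maintain(30.0, 6.5, 2.0, last_time)), label="load30_m6.5"
    )


def _load45(last_time: float = 22.0) -> Regimen:
    return Regimen(
        events=tuple(_load_maintain(45.0, 9.0, 2.0, last_time)), label="load45_m9"
    )


def _escalation_3day() -> Regimen:
    """Gradual 3-day escalation: daily loading dose then three q-2-h maintenance doses."""
    events: list[DoseEvent] = []
    for day, (load, maint) in enumerate([(15.0, 3.0), (30.0, 6.5), (40.0, 9.0)]):
        start = 24.0 * day
        events.append(_po(start, load))
        events.extend(_po(start + 2.0 * (i + 1), maint) for i in range(3))
    return Regimen(events=tuple(events), label="escalation_3day")


NAMED_REGIMENS = {
    "classical_q2h": _classical_q2h,
    "classical_q6h": _classical_q6h,
    "load30_m6.5": _load30,
    "load45_m9": _load45,
    "escalation_3day": _escalation_3day,
}


def build_named_regimen(name: str, **kwargs) -> Regimen:
    """One of the study's dosing schedules, all on the sulfate-dihydrate scale.

    ``classical_q2h``: 22 mg/kg q 2 h x 4 (the historically recommended
    regimen; pass ``n_doses`` for the 6-dose variant).
    ``classical_q6h``: 22 mg/kg q 6 h x 2.
    ``load30_m6.5``: 30 mg/kg loading then 6.5 mg/kg q 2 h through 24 h.
    ``load45_m9``: 45 mg/kg loading then 9 mg/kg q 2 h through 24 h.
    ``escalation_3day``: daily loading of 15/30/40 mg/kg followed each day by
    three q-2-h maintenance doses of 3/6.5/9 mg/kg.
    """
    try:
        factory = NAMED_REGIMENS[name]
    except KeyError:
        raise ValueError(
            f"unknown regimen {name!r}; expected one of {sorted(NAMED_REGIMENS)}"
        ) from None
    return factory(**kwargs)
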