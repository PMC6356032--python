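"""GES3/GES4 — amateur (consumer) spray and granule/seed scenarios.

The professional models are adapted for untrained users: no PPE is
available, the treated area is capped at 200 m^2 (0.02 ha) per day, the body
weight is 60 kg, and the 75th-percentile unit-exposure series replaces the
geometric means for spraying.  Consumers are members of the general
population, so RCRs use the general-population DNELs.
"""
from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from .core import ExposureEstimate, Protection, Substance, combine_estimates, make_estimate
from .errors import DomainError
from .params import FORMULATION_ORDER, Registry

SPREAD_KINDS = ("spread_hand", "spread_push", "spread_belly")


class ConsumerScenario(BaseModel):
    """One amateur-use scenario; note there is no protection field."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    kind: Literal["spray_handheld", "spread_hand", "spread_push", "spread_belly"]
    application_rate: float = Field(ge=0, description="kg/ha")
    treated_area: Optional[float] = Field(None, gt=0, description="ha/day")


def _effective_area(scenario: ConsumerScenario, registry: Registry) -> float:
    cap = registry.defaults.consumer_area_cap
    return cap if scenario.treated_area is None else min(scenario.treated_area, cap)


def _check_no_protection(protection: Protection | None) -> None:
    if protection is not None and not protection.is_none:
        raise DomainError("no PPE is available in consumer scenarios")


def consumer_spray_exposure(
    scenario: ConsumerScenario,
    substance: Substance,
    registry: Registry,
    protection: Protection | None = None,
) -> ExposureEstimate:
    """Hand-held spraying by an amateur: loading plus application.

    Uses the 75th-percentile hand-held unit exposures, a 60 kg body weight
    and the capped daily area; the loading formulation with the highest
    total RCR is combined with the application task.
    """
    _check_no_protection(protection)
    if scenario.kind != "spray_handheld":
        raise DomainError(f"{scenario.kind!r} is not the consumer spray scenario")
    area = _effective_area(scenario, registry)
    q_daily = scenario.application_rate * area
    bw = registry.defaults.bw_consumer
    v_breath = registry.defaults.breathing_volume_workday

    def estimate(task: str, formulation: str) -> ExposureEstimate:
        ue_d = registry.ue(task, formulation, "dermal", "p75")
        ue_i = registry.ue(task, formulation, "inhalation", "p75")
        return make_estimate(
            ue_d.value * q_daily / bw, ue_i.value * q_daily / v_breath,
            substance, "general",
            {
                "model": "BBA p75", "task": task, "formulation": formulation,
                "daily_amount_kg": q_daily, "treated_area_ha": area,
            },
        )

    ml_candidates = [estimate("ml_handheld", f) for f in FORMULATION_ORDER]
    worst_ml = max(ml_candidates, key=lambda e: e.rcr_total)
    application = estimate("app_handheld_high", "n/a")
    return combine_estimates([worst_ml, application], label="consumer spray (GES3)")


def consumer_solid_exposure(
    scenario: ConsumerScenario,
    substance: Substance,
    registry: Registry,
    protection: Protection | None = None,
) -> ExposureEstimate:
    """Manual spreading of granules or treated seeds by an amateur."""
    _check_no_protection(protection)
    if scenario.kind not in SPREAD_KINDS:
        raise DomainError(f"{scenario.kind!r} is not a consumer spreading scenario")
    area = _effective_area(scenario, registry)
    q_daily = scenario.application_rate * area
    task = f"soprea_{scenario.kind}"
    ue_d = registry.ue(task, "granule", "dermal", "p75")
    ue_i = registry.ue(task, "granule", "inhalation", "p75")
    dermal = ue_d.value * q_daily / registry.defaults.bw_consumer
    inhalation = ue_i.value * q_daily / registry.defaults.breathing_volume_workday
    return make_estimate(
        dermal, inhalation, substance, "general",
        {
            "model": "residential spreading (SOPREA)", "task": task,
            "daily_amount_kg": q_daily, "treated_area_ha": area,
        },
    )
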