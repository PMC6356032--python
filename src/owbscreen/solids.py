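"""GES2 — professional seed treatment and granular application.

Three contributing scenarios:

* loading (PROC 8a) — seed-treatment loading re-uses the BBA tractor-tank
  transfer task (liquid or WP); granule loading into tractor spreaders uses
  PHED surrogate unit exposures;
* bagging of treated seeds (PROC 8b) — a static full-shift surrogate lookup
  by physical state, dustiness/volatility band and concentration band, with
  optional local exhaust ventilation;
* dispersal (PROC 8a) — PHED surrogates for spreading by hand, belly
  grinder, push rotary spreader or tractor-mounted broadcast spreader.  For
  the hand-held spreaders the loading exposure cannot be separated from the
  dispersal measurement and is implicit in the dispersal unit exposure.

Working clothes (long-sleeve shirt, long pants, shoes plus socks) are
inherent in the PHED values, so no additional coverall credit is applied on
top of them by default.  Seed treatment and dispersal are performed by
different individuals; their RCRs are never combined across the two groups.
"""
from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import (
    ExposureEstimate,
    Protection,
    ScenarioResult,
    ScenarioRow,
    Substance,
    apply_protection,
    make_estimate,
)
from .errors import DomainError
from .params import Registry

PHED_TASKS = (
    "load_granule_tractor",
    "spread_hand",
    "spread_belly",
    "spread_push",
    "spread_tractor",
)
SEEDTREAT_TASKS = ("load_seedtreat_liquid", "load_seedtreat_wp")

#: Correlated task pairs (same workers); never combined across the pairs.
CORRELATED_PAIRS = (
    ("load_seedtreat", "bag_treated_seeds"),
    ("load_granule_tractor", "spread"),
)

_IMPLICIT_LOADING = {"load_spread_hand", "load_spread_belly", "load_spread_push"}


class SolidScenario(BaseModel):
    """One GES2 task: dispersal tasks carry a rate, bagging a concentration."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    task: str
    application_rate: Optional[float] = Field(None, ge=0, description="kg/ha")
    concentration: Optional[float] = Field(None, gt=0, le=1)
    dustiness: Literal["low", "medium", "high", None] = None
    lev: bool = False
    protection: Protection = Protection()

    @model_validator(mode="after")
    def _inputs_for_task(self) -> "SolidScenario":
        if self.task == "bag_treated_seeds" and self.concentration is None:
            raise ValueError("bagging requires a substance concentration in (0, 1]")
        if self.task in PHED_TASKS and self.application_rate is None:
            raise ValueError(f"task {self.task!r} requires an application rate")
        if self.task in SEEDTREAT_TASKS and self.concentration is None:
            raise ValueError(f"task {self.task!r} requires a substance concentration")
        return self


def phed_exposure(
    scenario: SolidScenario, substance: Substance, registry: Registry
) -> ExposureEstimate:
    """PHED surrogate exposure for granule/seed loading and dispersal."""
    if scenario.task in _IMPLICIT_LOADING:
        raise DomainError(
            f"{scenario.task!r}: loading of hand-held spreaders cannot be estimated "
            "separately; it is implicit in the corresponding dispersal task"
        )
    if scenario.task not in PHED_TASKS:
        raise DomainError(f"{scenario.task!r} is not a PHED task (expected one of {PHED_TASKS})")
    area = registry.phed_areas[scenario.task]
    q_daily = scenario.application_rate * area
    ue_d = registry.ue(f"phed_{scenario.task}", "granule", "dermal")
    ue_i = registry.ue(f"phed_{scenario.task}", "granule", "inhalation")
    dermal = ue_d.value * q_daily / registry.defaults.bw_worker
    inhalation = ue_i.value * q_daily / registry.defaults.breathing_volume_workday
    est = make_estimate(
        dermal, inhalation, substance, "worker",
        {
            "model": "PHED", "task": scenario.task, "daily_amount_kg": q_daily,
            "application_rate_kg_ha": scenario.application_rate,
            "working_clothes_inherent": True,
        },
    )
    return apply_protection(est, scenario.protection, registry.protection_factors, substance)


def seedtreat_loading_exposure(
    scenario: SolidScenario, substance: Substance, registry: Registry
) -> ExposureEstimate:
    """Loading of seed-treatment product, as the BBA tractor-tank transfer."""
    if scenario.task not in SEEDTREAT_TASKS:
        raise DomainError(f"{scenario.task!r} is not a seed-treatment loading task")
    formulation = "liquid" if scenario.task.endswith("liquid") else "WP"
    q_daily = scenario.concentration * registry.seed_treatment.product_per_day
    ue_d = registry.ue("ml_boom", formulation, "dermal")
    ue_i = registry.ue("ml_boom", formulation, "inhalation")
    dermal = ue_d.value * q_daily / registry.defaults.bw_worker
    inhalation = ue_i.value * q_daily / registry.defaults.breathing_volume_workday
    est = make_estimate(
        dermal, inhalation, substance, "worker",
        {
            "model": "BBA (tractor-tank analog)", "task": scenario.task,
            "formulation": formulation, "daily_amount_kg": q_daily,
        },
    )
    return apply_protection(est, scenario.protection, registry.protection_factors, substance)


def bagging_exposure(
    scenario: SolidScenario, substance: Substance, registry: Registry
) -> ExposureEstimate:
    """Bagging of treated seeds: full-shift surrogate lookup.

    The surrogate is selected by the physical state of the substance and its
    dustiness band (solids) or vapour-pressure band (liquids), then scaled by
    the concentration-band multiplier.  LEV reduces the inhalation route by
    the registry reduction factor.
    """
    if scenario.task != "bag_treated_seeds":
        raise DomainError(f"{scenario.task!r} is not the bagging task")
    table = registry.bagging
    if substance.physical_state == "solid":
        band = scenario.dustiness or table.default_band
        bands = table.solid
    else:
        vp = substance.vapour_pressure
        band = "low" if vp < 10 else ("medium" if vp <= 500 else "high")
        bands = table.liquid
    if band not in bands:
        raise DomainError(
            f"no bagging surrogate for physical state {substance.physical_state!r}, "
            f"band {band!r}"
        )
    factor = table.concentration_factor(scenario.concentration)
    dermal = bands[band].dermal * factor
    inhalation = bands[band].inhalation * factor
    est = make_estimate(
        dermal, inhalation, substance, "worker",
        {
            "model": "full-shift transfer surrogate", "task": scenario.task,
            "band": band, "concentration": scenario.concentration,
            "concentration_factor": factor,
        },
    )
    protection = scenario.protection
    if scenario.lev and not protection.lev:
        protection = protection.model_copy(update={"lev": True})
    return apply_protection(
        est, protection, registry.protection_factors, substance, supports_lev=True
    )


def ges2_enumerate(
    substance: Substance,
    rate: float,
    concentration: float,
    protection: Protection,
    lev: bool,
    registry: Registry,
) -> dict:
    """All GES2 permutations plus the correlated-task pairing.

    Returns a dict with the three contributing-scenario tables
    (``loading``, ``bagging``, ``dispersal``) and the ``correlated_pairs``
    recording which tasks may be combined — seed-treatment loading with
    bagging, and granule loading with dispersal, never across the groups.
    """
    loading_rows = []
    for task in SEEDTREAT_TASKS:
        est = seedtreat_loading_exposure(
            SolidScenario(task=task, concentration=concentration, protection=protection),
            substance, registry,
        )
        loading_rows.append(
            ScenarioRow(
                equipment=task.replace("_", " "), model="BBA (tractor-tank analog)",
                formulation="liquid" if task.endswith("liquid") else "WP",
                group="seed_treatment", estimate=est,
            )
        )
    est = phed_exposure(
        SolidScenario(task="load_granule_tractor", application_rate=rate, protection=protection),
        substance, registry,
    )
    loading_rows.append(
        ScenarioRow(
            equipment="loading tractor-mounted broadcast spreader", model="PHED",
            formulation="granule", group="dispersal", estimate=est,
        )
    )
    loading = ScenarioResult(
        scenario_id="ges2_proc8a_loading",
        title="PROC 8a: Mixing and loading into seed treatment or delivery equipment",
        rows=loading_rows,
    ).flag_worst_cases()

    bag_est = bagging_exposure(
        SolidScenario(
            task="bag_treated_seeds", concentration=concentration, lev=lev,
            protection=protection,
        ),
        substance, registry,
    )
    bagging = ScenarioResult(
        scenario_id="ges2_proc8b_bagging",
        title="PROC 8b: Transfer of treated seeds from batch treater into bags",
        rows=[
            ScenarioRow(
                equipment="bagging of treated seeds", model="full-shift transfer surrogate",
                formulation="seed", group="seed_treatment", estimate=bag_est,
            )
        ],
    ).flag_worst_cases()

    dispersal_rows = []
    for task in ("spread_hand", "spread_belly", "spread_push", "spread_tractor"):
        est = phed_exposure(
            SolidScenario(task=task, application_rate=rate, protection=protection),
            substance, registry,
        )
        dispersal_rows.append(
            ScenarioRow(
                equipment=task.replace("_", " "), model="PHED", formulation="granule",
                group="dispersal", estimate=est,
            )
        )
    dispersal = ScenarioResult(
        scenario_id="ges2_proc8a_dispersal",
        title="PROC 8a: Delivery and dispersal of granular PPP or treated seeds",
        rows=dispersal_rows,
    ).flag_worst_cases()

    return {
        "loading": loading,
        "bagging": bagging,
        "dispersal": dispersal,
        "correlated_pairs": list(CORRELATED_PAIRS),
    }
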