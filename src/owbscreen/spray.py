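"""GES1 — professional spray applications.

Mixing/loading and spray-application exposure follow the BBA unit-exposure
algebra: with an application rate ``AR`` (kg substance/ha) and a technique
treating ``A`` ha per work day, the daily amount handled is ``Q = AR * A``
(kg/day) and

    dermal      = UE_dermal * Q / bw_worker        (mg/kg bw/day)
    inhalation  = UE_inhalation * Q / V_breath     (mg/m^3)

where the unit exposures ``UE`` are mg of substance reaching the route per
kg handled and ``V_breath`` is the breathing volume over the work day.
Mixing/loading depends on the formulation type; application does not, since
dilution in water occurs before spraying.

For hand-held spraying of high targets indoors (greenhouses), volatile
substances (vapour pressure above 0.1 Pa) receive an additional inhalation
term from the constant rate release model (CRRM): the sprayed amount is
released to the greenhouse air at a constant rate over ``tr`` hours, the
single well-mixed zone is ventilated at ``q`` air changes per hour, and the
concentration is averaged over ``T`` hours of a ``t``-hour working exposure.
"""
from __future__ import annotations

import math
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
from .params import FORMULATION_ORDER, TECHNIQUE_ORDER, Registry

_EQUIPMENT_LABELS = {
    "boom": "tractor-mounted/trailed boom sprayer",
    "airblast": "tractor-mounted/trailed broadcast air-assisted sprayer",
    "handheld": "hand-held sprayer",
}


class GreenhouseParams(BaseModel):
    """Constant-rate-release parameters for the greenhouse vapour term."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    q: float = Field(gt=0, description="air changes per hour, 1/h")
    h: float = Field(gt=0, description="greenhouse height, m")
    tr: float = Field(gt=0, description="release duration, h")
    t: float = Field(gt=0, description="worker exposure time, h")
    T: float = Field(gt=0, description="averaging period, h")
    V: Optional[float] = Field(None, gt=0, description="air volume, m^3 (informational)")

    @model_validator(mode="after")
    def _release_phase(self) -> "GreenhouseParams":
        if self.t > self.tr:
            raise ValueError(
                "worker exposure time t must not exceed the release duration tr "
                "(the model covers the release phase only)"
            )
        return self

    @classmethod
    def from_registry(cls, registry: Registry) -> "GreenhouseParams":
        g = registry.greenhouse
        return cls(q=g.q, h=g.h, tr=g.tr, t=g.t, T=g.T, V=g.V)


class SprayScenario(BaseModel):
    """One spray permutation: technique, formulation, environment, rate, PPE."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    technique: str
    formulation: Literal["liquid", "WP", "WG"] = "liquid"
    environment: Literal["outdoor", "indoor"] = "outdoor"
    application_rate: float = Field(ge=0, description="kg substance per ha")
    protection: Protection = Protection()


def _bba_routes(
    task: str, formulation: str, rate: float, technique_area: float, registry: Registry,
    percentile: str = "geometric_mean",
) -> tuple[float, float, float]:
    """(dermal, inhalation, Q) for a BBA task at the given rate."""
    q_daily = rate * technique_area
    ue_d = registry.ue(task, formulation, "dermal", percentile)
    ue_i = registry.ue(task, formulation, "inhalation", percentile)
    dermal = ue_d.value * q_daily / registry.defaults.bw_worker
    inhalation = ue_i.value * q_daily / registry.defaults.breathing_volume_workday
    return dermal, inhalation, q_daily


def ml_spray_exposure(
    scenario: SprayScenario, substance: Substance, registry: Registry
) -> ExposureEstimate:
    """Mixing/loading exposure for one technique and formulation."""
    spec = registry.technique(scenario.technique)
    if scenario.formulation not in spec.allowed_formulations:
        raise DomainError(
            f"formulation {scenario.formulation!r} not allowed for technique {scenario.technique!r}"
        )
    dermal, inhalation, q_daily = _bba_routes(
        f"ml_{scenario.technique}", scenario.formulation, scenario.application_rate,
        spec.area_per_day, registry,
    )
    est = make_estimate(
        dermal, inhalation, substance, "worker",
        {
            "model": "BBA", "task": f"ml_{scenario.technique}",
            "formulation": scenario.formulation, "daily_amount_kg": q_daily,
            "application_rate_kg_ha": scenario.application_rate,
        },
    )
    return apply_protection(est, scenario.protection, registry.protection_factors, substance)


def crrm_twa(application_rate: float, gp: GreenhouseParams) -> float:
    """T-hour time-weighted average vapour concentration (mg/m^3).

    Closed form of the well-mixed single-zone balance ``dC/dt = S - q*C``
    with constant source ``S = 100 * AR / (h * tr)`` (mg/m^3/h; the factor
    100 converts kg.ha^-1.m^-1 to mg/m^3), integrated over the worker
    exposure time ``t`` and averaged over ``T``:

        TWA = (100 / T) * AR/(q*h*tr) * [ t + (exp(-q*t) - 1)/q ]

    Written with ``expm1`` so the weak-ventilation limit (q -> 0, where the
    bracket collapses to q*t^2/2) stays accurate.
    """
    if application_rate < 0:
        raise DomainError("application rate must be non-negative")
    ar, q, h, tr, t = application_rate, gp.q, gp.h, gp.tr, gp.t
    return (100.0 / gp.T) * ar / (q * h * tr) * (t + math.expm1(-q * t) / q)


def application_spray_exposure(
    scenario: SprayScenario,
    substance: Substance,
    registry: Registry,
    greenhouse: GreenhouseParams | None = None,
) -> ExposureEstimate:
    """Spray-application exposure; indoors adds the CRRM vapour term.

    The aerosol part is formulation-independent.  Indoor use is only defined
    for hand-held spraying of high targets; for substances with vapour
    pressure above the registry threshold the CRRM time-weighted average is
    added to the inhalation route before protection is applied.
    """
    spec = registry.technique(scenario.technique)
    if scenario.environment == "indoor":
        if scenario.technique != "handheld" or "indoor" not in spec.environments:
            raise DomainError("indoor application is only defined for hand-held spraying")
        if greenhouse is None:
            greenhouse = GreenhouseParams.from_registry(registry)
    task = "app_handheld_high" if scenario.technique == "handheld" else f"app_{scenario.technique}"
    dermal, inhalation, q_daily = _bba_routes(
        task, "n/a", scenario.application_rate, spec.area_per_day, registry
    )
    vapour = 0.0
    if scenario.environment == "indoor" and substance.vapour_pressure > registry.defaults.vp_threshold:
        vapour = crrm_twa(scenario.application_rate, greenhouse)
    est = make_estimate(
        dermal, inhalation + vapour, substance, "worker",
        {
            "model": "BBA" if vapour == 0.0 else "BBA+CRRM", "task": task,
            "environment": scenario.environment, "daily_amount_kg": q_daily,
            "application_rate_kg_ha": scenario.application_rate,
            "crrm_vapour_mg_m3": vapour,
        },
    )
    return apply_protection(est, scenario.protection, registry.protection_factors, substance)


def ges1_enumerate(
    substance: Substance,
    rate_tractor: float,
    rate_handheld: float,
    protection: Protection,
    registry: Registry,
    greenhouse: GreenhouseParams | None = None,
) -> tuple[ScenarioResult, ScenarioResult]:
    """All GES1 permutations: mixing/loading and application tables.

    Tractor-mounted and hand-held techniques are grouped and reported
    separately; within each group the permutation with the highest total RCR
    is flagged as the worst case (canonical order, first maximum wins).
    """
    if rate_tractor < 0 or rate_handheld < 0:
        raise DomainError("application rates must be non-negative")

    ml_rows: list[ScenarioRow] = []
    for technique in TECHNIQUE_ORDER:
        spec = registry.technique(technique)
        rate = rate_tractor if spec.group == "tractor" else rate_handheld
        for formulation in FORMULATION_ORDER:
            est = ml_spray_exposure(
                SprayScenario(
                    technique=technique, formulation=formulation,
                    application_rate=rate, protection=protection,
                ),
                substance, registry,
            )
            ml_rows.append(
                ScenarioRow(
                    equipment=f"mixing and loading {_EQUIPMENT_LABELS[technique]}",
                    model="BBA", formulation=formulation, group=spec.group, estimate=est,
                )
            )
    ml_result = ScenarioResult(
        scenario_id="ges1_proc8a",
        title="PROC 8a: Mixing and loading of plant protection products into delivery equipment",
        rows=ml_rows,
    ).flag_worst_cases()

    app_rows: list[ScenarioRow] = []
    for technique in TECHNIQUE_ORDER:
        spec = registry.technique(technique)
        rate = rate_tractor if spec.group == "tractor" else rate_handheld
        for environment in spec.environments:
            est = application_spray_exposure(
                SprayScenario(
                    technique=technique, environment=environment,
                    application_rate=rate, protection=protection,
                ),
                substance, registry, greenhouse,
            )
            label = _EQUIPMENT_LABELS[technique]
            if technique == "handheld":
                label += ", high-level target, " + (
                    "indoors (greenhouses)" if environment == "indoor" else "outdoors"
                )
            app_rows.append(
                ScenarioRow(
                    equipment=label,
                    model="BBA+CRRM" if est.provenance.get("model") == "BBA+CRRM" else "BBA",
                    environment=environment, group=spec.group, estimate=est,
                )
            )
    app_result = ScenarioResult(
        scenario_id="ges1_proc11",
        title="PROC 11: Delivery and dispersion of plant protection products",
        rows=app_rows,
    ).flag_worst_cases()
    return ml_result, app_result
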