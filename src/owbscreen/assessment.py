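"""Orchestration: full assessments, correlated-task combination and use-rate
maximization.

Mixing/loading and application are carried out in sequence by the same
workers, so their exposures are combined per application technique; the
technique with the highest combined RCR — not the cross-technique sum of the
per-scenario worst cases — is the binding combination for a group.  Because
every exposure model in the package is homogeneous of degree one in the
application rate, the maximum use rate for a target RCR has the closed form

    rate_group = target_rcr / max_c slope_c

where the constraints ``c`` are each technique's combined correlated tasks
(worker DNELs), worker re-entry (worker dermal DNEL) and bystander drift
(general-population DNELs), and ``slope_c`` is the RCR accrued per kg/ha.
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
    combine_estimates,
)
from .errors import DomainError
from .offtarget import bystander_exposure, reentry_exposure
from .params import TECHNIQUE_ORDER, Registry, load_registry
from .solids import ges2_enumerate
from .spray import GreenhouseParams, ges1_enumerate

GROUPS = ("tractor", "hand_held")


class AssessmentRequest(BaseModel):
    """Inputs for one assessment run.

    ``fixed_rate`` mode evaluates the scenarios at the given per-group
    application rates; ``maximize`` mode solves for the largest rate per
    technique group such that no constraint exceeds ``target_rcr``.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    substance: Substance
    mode: Literal["fixed_rate", "maximize"]
    rate_tractor: Optional[float] = Field(None, ge=0, description="kg/ha")
    rate_handheld: Optional[float] = Field(None, ge=0, description="kg/ha")
    target_rcr: Optional[float] = Field(None, gt=0, le=1)
    protection: Protection = Protection()
    ges: tuple[Literal["ges1", "ges2", "ges3", "ges4"], ...] = ("ges1",)
    concentration: float = Field(0.01, gt=0, le=1, description="seed-treatment concentration")
    lev: bool = False
    single_rate: bool = False

    @model_validator(mode="after")
    def _mode_inputs(self) -> "AssessmentRequest":
        if self.mode == "maximize" and self.target_rcr is None:
            raise ValueError("maximize mode requires target_rcr")
        if self.mode == "fixed_rate" and (self.rate_tractor is None or self.rate_handheld is None):
            raise ValueError("fixed_rate mode requires rate_tractor and rate_handheld")
        return self


class MaxRateResult(BaseModel):
    """Maximized rate for one technique group, with the constraint ledger."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    group: str
    rate: Optional[float] = None
    unbounded: bool = False
    binding_constraint: Optional[str] = None
    slopes: dict[str, float] = Field(default_factory=dict, description="RCR per kg/ha")


class AssessmentResult(BaseModel):
    """All scenario tables, combined estimates, rates and provenance."""

    model_config = ConfigDict(extra="forbid")

    request: AssessmentRequest
    rates_used: dict[str, float]
    daily_amounts: dict[str, float]
    ges1_ml: Optional[ScenarioResult] = None
    ges1_app: Optional[ScenarioResult] = None
    combined: dict[str, ExposureEstimate] = Field(default_factory=dict)
    worst_combined: dict[str, str] = Field(default_factory=dict)
    max_use_rates: dict[str, MaxRateResult] = Field(default_factory=dict)
    ges2: Optional[dict] = None
    ges3: Optional[ScenarioResult] = None
    ges4: Optional[ScenarioResult] = None


def _technique_of(row: ScenarioRow) -> str | None:
    """Technique id behind a table row, or None for indirect-exposure rows."""
    task = row.estimate.provenance.get("task", "")
    for technique in TECHNIQUE_ORDER:
        if task.startswith(f"ml_{technique}") or task.startswith(f"app_{technique}"):
            return technique
    return None


def combined_correlated(
    ges1_ml: ScenarioResult, ges1_app: ScenarioResult, technique_group: str
) -> tuple[dict[str, ExposureEstimate], str]:
    """Combined mixing/loading + application exposure per technique.

    For each technique in the group, the worst formulation for that
    technique's loading task is added to that technique's worst application
    variant; ties between indoor and outdoor application go to the indoor
    (greenhouse) variant, which dominates whenever the vapour term is
    non-zero.  Returns the per-technique combinations and the worst
    technique of the group.
    """
    techniques = [
        t for t in TECHNIQUE_ORDER
        if any(_technique_of(r) == t and r.group == technique_group for r in ges1_ml.rows)
    ]
    if not techniques:
        raise DomainError(f"no techniques found for group {technique_group!r}")
    combos: dict[str, ExposureEstimate] = {}
    for technique in techniques:
        ml_rows = [r for r in ges1_ml.rows if _technique_of(r) == technique]
        app_rows = [r for r in ges1_app.rows if _technique_of(r) == technique]
        worst_ml = max(ml_rows, key=lambda r: r.estimate.rcr_total)
        worst_app = max(
            app_rows, key=lambda r: (r.estimate.rcr_total, r.environment == "indoor")
        )
        combos[technique] = combine_estimates(
            [worst_ml.estimate, worst_app.estimate], label=f"PROC 8a+11 ({technique})"
        )
    worst = max(techniques, key=lambda t: combos[t].rcr_total)
    return combos, worst


def _group_constraint_slopes(
    substance: Substance,
    protection: Protection,
    registry: Registry,
    group: str,
    greenhouse: GreenhouseParams | None = None,
) -> dict[str, float]:
    """RCR per kg/ha for every constraint of a technique group.

    Evaluated at a probe rate of 1 kg/ha; exactness relies on every model
    being homogeneous of degree one in the rate.
    """
    probe = 1.0
    ml_res, app_res = ges1_enumerate(substance, probe, probe, protection, registry, greenhouse)
    combos, _ = combined_correlated(ml_res, app_res, group)
    slopes = {f"combined_{t}": combos[t].rcr_total / probe for t in combos}
    slopes["reentry"] = reentry_exposure(probe, substance, registry).rcr_total / probe
    slopes["bystander"] = bystander_exposure(probe, substance, registry).rcr_total / probe
    return slopes


def maximize_use_rate(
    request: AssessmentRequest,
    registry: Registry | None = None,
    greenhouse: GreenhouseParams | None = None,
) -> dict[str, MaxRateResult]:
    """Largest application rate per technique group for the target RCR.

    The binding constraint is the one with the largest RCR slope (first in
    canonical order on ties); if no pathway produces exposure the rate is
    unbounded and flagged as such rather than returned as a number.
    """
    if request.target_rcr is None:
        raise DomainError("maximize_use_rate requires a target RCR")
    if registry is None:
        registry = load_registry()
    results: dict[str, MaxRateResult] = {}
    for group in GROUPS:
        slopes = _group_constraint_slopes(
            request.substance, request.protection, registry, group, greenhouse
        )
        max_slope = max(slopes.values())
        if max_slope <= 0.0:
            results[group] = MaxRateResult(group=group, unbounded=True, slopes=slopes)
            continue
        binding = next(name for name, s in slopes.items() if s == max_slope)
        results[group] = MaxRateResult(
            group=group,
            rate=request.target_rcr / max_slope,
            binding_constraint=binding,
            slopes=slopes,
        )
    return results


def run_full_assessment(
    request: AssessmentRequest,
    registry: Registry | None = None,
    greenhouse: GreenhouseParams | None = None,
) -> AssessmentResult:
    """Run the selected generic exposure scenarios end to end.

    Deterministic: identical requests produce identical results.  In
    maximize mode the per-group rates come from :func:`maximize_use_rate`
    (optionally collapsed to the global minimum with ``single_rate``); the
    scenario tables, combined estimates and indirect-exposure rows are then
    evaluated at those rates.
    """
    if registry is None:
        registry = load_registry()
    substance = request.substance

    max_rates: dict[str, MaxRateResult] = {}
    if request.mode == "maximize":
        max_rates = maximize_use_rate(request, registry, greenhouse)
        rates = {
            group: (0.0 if res.unbounded else res.rate) for group, res in max_rates.items()
        }
        if request.single_rate:
            bounded = [r for r in rates.values() if r > 0]
            if bounded:
                rates = {group: min(bounded) for group in rates}
    else:
        rates = {"tractor": request.rate_tractor, "hand_held": request.rate_handheld}

    result = AssessmentResult(
        request=request, rates_used=dict(rates), daily_amounts={}, max_use_rates=max_rates
    )

    if "ges1" in request.ges:
        ml_res, app_res = ges1_enumerate(
            substance, rates["tractor"], rates["hand_held"], request.protection,
            registry, greenhouse,
        )
        for technique in TECHNIQUE_ORDER:
            spec = registry.technique(technique)
            rate = rates[spec.group]
            result.daily_amounts[technique] = rate * spec.area_per_day
        # indirect exposure rows, evaluated at each group's own rate
        for group in GROUPS:
            rate = rates[group]
            app_res.rows.append(
                ScenarioRow(
                    equipment="worker re-entry (indirect exposure)",
                    model="re-entry DFR/TC", group=group,
                    estimate=reentry_exposure(rate, substance, registry),
                )
            )
            app_res.rows.append(
                ScenarioRow(
                    equipment="indirect exposure of bystanders",
                    model="bystander drift", group=group,
                    estimate=bystander_exposure(rate, substance, registry),
                )
            )
        app_res.flag_worst_cases()
        result.ges1_ml, result.ges1_app = ml_res, app_res
        for group in GROUPS:
            combos, worst = combined_correlated(ml_res, app_res, group)
            result.combined.update(combos)
            result.worst_combined[group] = worst

    if "ges2" in request.ges:
        result.ges2 = ges2_enumerate(
            substance, rates["tractor"], request.concentration, request.protection,
            request.lev, registry,
        )

    if "ges3" in request.ges or "ges4" in request.ges:
        from .consumer import ConsumerScenario, consumer_solid_exposure, consumer_spray_exposure

        if "ges3" in request.ges:
            est = consumer_spray_exposure(
                ConsumerScenario(kind="spray_handheld", application_rate=rates["hand_held"]),
                substance, registry,
            )
            result.ges3 = ScenarioResult(
                scenario_id="ges3_pc27_spray",
                title="PC 27: Spray application by consumers",
                rows=[
                    ScenarioRow(
                        equipment="hand-held sprayer (amateur)", model="BBA p75",
                        group="consumer", estimate=est,
                    )
                ],
            ).flag_worst_cases()
        if "ges4" in request.ges:
            rows = []
            for kind in ("spread_hand", "spread_push", "spread_belly"):
                est = consumer_solid_exposure(
                    ConsumerScenario(kind=kind, application_rate=rates["hand_held"]),
                    substance, registry,
                )
                rows.append(
                    ScenarioRow(
                        equipment=kind.replace("_", " ") + " (amateur)",
                        model="residential spreading (SOPREA)", group="consumer",
                        estimate=est,
                    )
                )
            result.ges4 = ScenarioResult(
                scenario_id="ges4_pc27_spread",
                title="PC 27: Manual spreading of granular PPP or treated seeds by consumers",
                rows=rows,
            ).flag_worst_cases()

    return result
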