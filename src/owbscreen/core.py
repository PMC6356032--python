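"""Substances, protection, exposure estimates and RCR arithmetic.

The risk characterization ratio (RCR) is exposure divided by the DNEL for the
route and population, summed over routes.  All scenario models in this
package produce :class:`ExposureEstimate` objects through the helpers here,
so RCR handling, protection mitigation and combination of correlated tasks
are uniform across models.
"""
from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Any, Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import DomainError
from .params import ProtectionFactors

Population = Literal["worker", "general"]


class Substance(BaseModel):
    """A co-formulant: physical state, volatility and its four DNELs.

    DNELs are external doses — dermal in mg/kg bw/day, inhalation in mg/m^3 —
    for the worker and general populations.  An optional area-based dermal
    DNEL (mg/cm^2/day) is accepted but only used by the dermal-load path.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str = "substance"
    physical_state: Literal["solid", "liquid"] = "liquid"
    vapour_pressure: float = Field(ge=0, description="Pa")
    dnel_worker_dermal: float = Field(gt=0, description="mg/kg bw/day")
    dnel_worker_inhalation: float = Field(gt=0, description="mg/m^3")
    dnel_general_dermal: float = Field(gt=0, description="mg/kg bw/day")
    dnel_general_inhalation: float = Field(gt=0, description="mg/m^3")
    dnel_dermal_area: Optional[float] = Field(None, gt=0, description="mg/cm^2/day")

    def dnels(self, population: Population) -> tuple[float, float]:
        """(dermal, inhalation) DNELs for a population."""
        if population == "worker":
            return self.dnel_worker_dermal, self.dnel_worker_inhalation
        if population == "general":
            return self.dnel_general_dermal, self.dnel_general_inhalation
        raise DomainError(f"unknown population {population!r}")


class Protection(BaseModel):
    """PPE/RPE selection for one contributing scenario."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    gloves: bool = False
    coverall: bool = False
    rpe: Literal["none", "pf10", "pf20"] = "none"
    lev: bool = False

    @property
    def is_none(self) -> bool:
        return not (self.gloves or self.coverall or self.lev) and self.rpe == "none"

    def label(self) -> tuple[str, str]:
        """(PPE, RPE) column labels as used in the result tables."""
        ppe = "+".join(
            name for flag, name in ((self.gloves, "gloves"), (self.coverall, "coverall")) if flag
        )
        rpe = {"none": "No RPE", "pf10": "RPE PF10", "pf20": "RPE PF20"}[self.rpe]
        return (ppe or "No PPE", rpe)


class ExposureEstimate(BaseModel):
    """Paired dermal/inhalation prediction with its RCRs and provenance."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    dermal: float = Field(ge=0, description="mg/kg bw/day")
    inhalation: float = Field(ge=0, description="mg/m^3")
    rcr_dermal: float = Field(ge=0)
    rcr_inhalation: float = Field(ge=0)
    rcr_total: float = Field(ge=0)
    population: Population
    provenance: dict[str, Any] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _additive(self) -> "ExposureEstimate":
        if not math.isclose(
            self.rcr_total, self.rcr_dermal + self.rcr_inhalation, rel_tol=1e-12, abs_tol=1e-15
        ):
            raise ValueError("rcr_total must equal rcr_dermal + rcr_inhalation")
        return self

    @property
    def protected(self) -> bool:
        return self.provenance.get("protection") is not None


def compute_rcr(
    dermal: float, inhalation: float, substance: Substance, population: Population
) -> tuple[float, float, float]:
    """Per-route and total RCR of a (dermal, inhalation) exposure pair."""
    dnel_d, dnel_i = substance.dnels(population)
    rcr_d = dermal / dnel_d
    rcr_i = inhalation / dnel_i
    return rcr_d, rcr_i, rcr_d + rcr_i


def make_estimate(
    dermal: float,
    inhalation: float,
    substance: Substance,
    population: Population,
    provenance: dict[str, Any] | None = None,
) -> ExposureEstimate:
    """Build an (unprotected) estimate with its RCRs filled in."""
    prov = dict(provenance or {})
    prov.setdefault("protection", None)
    rcr_d, rcr_i, rcr_t = compute_rcr(dermal, inhalation, substance, population)
    return ExposureEstimate(
        dermal=dermal,
        inhalation=inhalation,
        rcr_dermal=rcr_d,
        rcr_inhalation=rcr_i,
        rcr_total=rcr_t,
        population=population,
        provenance=prov,
    )


def apply_protection(
    estimate: ExposureEstimate,
    protection: Protection,
    factors: ProtectionFactors,
    substance: Substance,
    *,
    supports_lev: bool = False,
) -> ExposureEstimate:
    """Mitigate an unprotected estimate by the selected PPE/RPE/LEV.

    The dermal route is divided by the product of the active dermal
    protection factors (gloves, coverall) — the screening simplification of
    applying one factor to the whole-body estimate.  The inhalation route is
    divided by the RPE protection factor and, where the scenario supports
    local exhaust ventilation, multiplied by ``1 - lev_inhalation_reduction``.
    """
    if estimate.protected:
        raise DomainError("protection has already been applied to this estimate")
    dermal_pf = 1.0
    if protection.gloves:
        dermal_pf *= factors.gloves_dermal_pf
    if protection.coverall:
        dermal_pf *= factors.coverall_dermal_pf
    inhalation = estimate.inhalation / factors.rpe_pfs[protection.rpe]
    if protection.lev and supports_lev:
        inhalation *= 1.0 - factors.lev_inhalation_reduction
    prov = dict(estimate.provenance)
    prov["protection"] = protection.model_dump()
    return make_estimate(
        estimate.dermal / dermal_pf, inhalation, substance, estimate.population, prov
    ).model_copy()


def combine_estimates(
    parts: Sequence[ExposureEstimate], label: str = "combined"
) -> ExposureEstimate:
    """Sum correlated-task estimates (same workers, same population).

    Exposures and RCRs add; provenance records the contributing parts.
    """
    if not parts:
        raise DomainError("cannot combine an empty list of estimates")
    populations = {p.population for p in parts}
    if len(populations) > 1:
        raise DomainError(f"cannot combine estimates across populations {sorted(populations)}")
    if len(parts) == 1:
        return parts[0]
    return ExposureEstimate(
        dermal=sum(p.dermal for p in parts),
        inhalation=sum(p.inhalation for p in parts),
        rcr_dermal=sum(p.rcr_dermal for p in parts),
        rcr_inhalation=sum(p.rcr_inhalation for p in parts),
        rcr_total=sum(p.rcr_total for p in parts),
        population=parts[0].population,
        provenance={
            "model": label,
            "protection": "combined",
            "parts": [p.provenance for p in parts],
        },
    )


def dermal_load_rcr(
    estimate: ExposureEstimate, substance: Substance, exposed_skin_area: float, bw: float
) -> float:
    """RCR for an area-based dermal DNEL (mg/cm^2/day).

    The systemic dermal dose (mg/kg bw/day) is converted to a skin load over
    the exposed area, ``load = dermal * bw / area``, and divided by the
    area-based DNEL.  Only available when the substance declares one.
    """
    if substance.dnel_dermal_area is None:
        raise DomainError(f"substance {substance.name!r} has no area-based dermal DNEL")
    if exposed_skin_area <= 0 or bw <= 0:
        raise DomainError("exposed skin area and body weight must be positive")
    return estimate.dermal * bw / exposed_skin_area / substance.dnel_dermal_area


def round_display(x: float, decimals: int) -> float:
    """Round half away from zero, as in the published result tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class ScenarioRow(BaseModel):
    """One permutation row of a contributing-scenario result table."""

    model_config = ConfigDict(extra="forbid")

    equipment: str
    model: str
    formulation: str = "-"
    environment: str = "-"
    group: str = "-"
    estimate: ExposureEstimate
    worst_case: bool = False


class ScenarioResult(BaseModel):
    """Permutation table for one contributing scenario, with worst cases.

    Rows are listed in canonical enumeration order; per reporting group the
    first row attaining the maximal total RCR is flagged as the worst case
    (stable tie-break).
    """

    model_config = ConfigDict(extra="forbid")

    scenario_id: str
    title: str
    rows: list[ScenarioRow]

    def flag_worst_cases(self) -> "ScenarioResult":
        for group in dict.fromkeys(row.group for row in self.rows):
            members = [row for row in self.rows if row.group == group]
            best = max(members, key=lambda row: row.estimate.rcr_total)
            for row in members:
                row.worst_case = row is best
        return self

    def worst(self, group: str | None = None) -> ScenarioRow:
        rows = self.rows if group is None else [r for r in self.rows if r.group == group]
        if not rows:
            raise DomainError(f"no rows for group {group!r} in scenario {self.scenario_id}")
        return max(rows, key=lambda row: row.estimate.rcr_total)

    def to_frame(self):
        """Tabular view with the published column set plus a worst_case flag."""
        import pandas as pd

        records = []
        for row in self.rows:
            est = row.estimate
            ppe, rpe = ("-", "-")
            prot = est.provenance.get("protection")
            if isinstance(prot, dict):
                ppe, rpe = Protection(**prot).label()
            records.append(
                {
                    "equipment": row.equipment,
                    "model": row.model,
                    "formulation": row.formulation,
                    "environment": row.environment,
                    "group": row.group,
                    "ppe": ppe,
                    "rpe": rpe,
                    "population": est.population,
                    "dermal_mg_per_kg_bw_day": est.dermal,
                    "inhalation_mg_per_m3": est.inhalation,
                    "rcr_dermal": est.rcr_dermal,
                    "rcr_inhalation": est.rcr_inhalation,
                    "rcr_total": est.rcr_total,
                    "worst_case": row.worst_case,
                }
            )
        return pd.DataFrame.from_records(
            records,
            columns=[
                "equipment", "model", "formulation", "environment", "group",
                "ppe", "rpe", "population", "dermal_mg_per_kg_bw_day",
                "inhalation_mg_per_m3", "rcr_dermal", "rcr_inhalation",
                "rcr_total", "worst_case",
            ],
        )
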