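"""GES1 indirect exposure: worker re-entry and bystanders.

Re-entry dermal exposure follows the dislodgeable-foliar-residue (DFR)
transfer model:

    dermal = DFR0 * n_app * AR * TC * duration / (bw * 1000)   (mg/kg bw/day)

with DFR0 in ug/cm^2 per kg/ha per application, the transfer coefficient TC
in cm^2/h and AR the application rate in kg/ha.  For volatile co-formulants
(vapour pressure >= 0.1 Pa) the residue is assumed to have evaporated within
a day of application and re-entry exposure is zero.

Bystander dermal exposure uses the areal spray deposit (1 kg/ha is the
dimensional identity 0.01 mg/cm^2) scaled by the drift fraction, exposed
body area and body weight; inhalation uses a unit exposure per kg of
substance handled during the application day divided by the inhaled air
volume, plus a vapour add-on above the volatility threshold.  Bystanders are
members of the general population, so their RCRs always use the
general-population DNELs even though the scenario is triggered by a
professional use.
"""
from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

from .core import ExposureEstimate, Substance, make_estimate
from .errors import DomainError
from .params import Registry

#: kg/ha expressed as an areal deposit in mg/cm^2 (dimensional identity).
KG_PER_HA_TO_MG_PER_CM2 = 0.01


class ReentryParams(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    dfr0: float = Field(gt=0, description="ug/cm^2 per kg/ha per application")
    n_applications: int = Field(ge=1)
    tc: float = Field(gt=0, description="cm^2/h")
    duration: float = Field(gt=0, description="h")
    bw: float = Field(gt=0, description="kg")

    @classmethod
    def from_registry(cls, registry: Registry) -> "ReentryParams":
        r = registry.reentry
        return cls(
            dfr0=r.dfr0, n_applications=registry.defaults.n_applications_reentry,
            tc=r.tc, duration=r.duration, bw=r.bw,
        )


class BystanderParams(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    drift_fraction: float = Field(gt=0, lt=1)
    exposed_area: float = Field(gt=0, description="cm^2")
    bw: float = Field(gt=0, description="kg")
    inhalation_unit_exposure: float = Field(ge=0, description="mg per kg handled")
    breathing_rate: float = Field(gt=0, description="m^3/h")
    duration: float = Field(gt=0, description="h")
    vapour_unit: float = Field(ge=0, description="mg/m^3 per kg/ha")

    @classmethod
    def from_registry(cls, registry: Registry) -> "BystanderParams":
        b = registry.bystander
        return cls(
            drift_fraction=b.drift_fraction, exposed_area=b.exposed_area, bw=b.bw,
            inhalation_unit_exposure=b.inhalation_unit_exposure,
            breathing_rate=b.breathing_rate, duration=b.duration,
            vapour_unit=b.vapour_unit,
        )


def reentry_exposure(
    application_rate: float,
    substance: Substance,
    registry: Registry,
    rp: ReentryParams | None = None,
) -> ExposureEstimate:
    """Dermal-only worker exposure from re-entry into a treated crop."""
    if application_rate < 0:
        raise DomainError("application rate must be non-negative")
    if rp is None:
        rp = ReentryParams.from_registry(registry)
    volatile = substance.vapour_pressure >= registry.defaults.vp_threshold
    if volatile:
        dermal = 0.0
    else:
        dermal = (
            rp.dfr0 * rp.n_applications * application_rate * rp.tc * rp.duration
            / (rp.bw * 1000.0)
        )
    return make_estimate(
        dermal, 0.0, substance, "worker",
        {
            "model": "re-entry DFR/TC", "task": "reentry",
            "application_rate_kg_ha": application_rate,
            "volatile_negligible_dfr": volatile,
        },
    )


def bystander_exposure(
    application_rate: float,
    substance: Substance,
    registry: Registry,
    bp: BystanderParams | None = None,
) -> ExposureEstimate:
    """General-population exposure to spray drift near a treated field."""
    if application_rate < 0:
        raise DomainError("application rate must be non-negative")
    if bp is None:
        bp = BystanderParams.from_registry(registry)
    deposit = application_rate * KG_PER_HA_TO_MG_PER_CM2 * bp.drift_fraction
    dermal = deposit * bp.exposed_area / bp.bw
    # amount handled during the application day: the tractor reference task
    daily_amount = application_rate * registry.technique("boom").area_per_day
    inhaled_volume = bp.breathing_rate * bp.duration
    inhalation = bp.inhalation_unit_exposure * daily_amount / inhaled_volume
    if substance.vapour_pressure > registry.defaults.vp_threshold:
        inhalation += bp.vapour_unit * application_rate
    return make_estimate(
        dermal, inhalation, substance, "general",
        {
            "model": "bystander drift", "task": "bystander",
            "application_rate_kg_ha": application_rate,
            "daily_amount_kg": daily_amount,
        },
    )
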