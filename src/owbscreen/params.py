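"""Central parameter registry for the OWB screening model.

Every constant used by the exposure models lives here: BBA and PHED unit
exposures, technique work areas, body weights, protection factors, and the
parameter blocks for the greenhouse, re-entry, bystander, seed-treatment and
bagging models.  A registry is immutable for the duration of a run and every
constant carries a provenance tag.

The module also provides :func:`calibrate_unit_exposure`, the back-derivation
of a unit exposure (mg per kg of substance handled) from a published
route-specific exposure at a known daily amount handled — the calibration
route through which the built-in BBA unit exposures were obtained.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Literal, Mapping, Optional

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    PrivateAttr,
    ValidationError,
    field_validator,
    model_validator,
)

from .errors import DomainError, RegistryError

Formulation = Literal["liquid", "WP", "WG", "granule", "seed", "n/a"]
Route = Literal["dermal", "inhalation"]
Percentile = Literal["geometric_mean", "p75"]

#: Canonical enumeration orders used for deterministic worst-case tie-breaks.
TECHNIQUE_ORDER = ("boom", "airblast", "handheld")
FORMULATION_ORDER = ("liquid", "WP", "WG")

#: Hand-held spray tasks also used by the consumer scenarios, which require a
#: 75th-percentile series next to the geometric means.
_CONSUMER_SPRAY_TASKS = frozenset({"ml_handheld", "app_handheld_high"})


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class UnitExposure(_Frozen):
    """Exposure per kg of substance handled, for one task/formulation/route."""

    task_id: str
    formulation: Formulation
    route: Route
    value: float = Field(ge=0, description="mg per kg substance handled")
    percentile: Percentile = "geometric_mean"
    source: str = "unspecified"

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.task_id, self.formulation, self.route, self.percentile)


class TechniqueSpec(_Frozen):
    """An application technique: group, daily work area, environments."""

    technique_id: str
    group: Literal["tractor", "hand_held"]
    area_per_day: float = Field(gt=0, description="ha treated per work day")
    environments: tuple[Literal["outdoor", "indoor"], ...] = ("outdoor",)
    allowed_formulations: tuple[Formulation, ...] = ("liquid", "WP", "WG")


class Defaults(_Frozen):
    bw_worker: float = Field(70.0, gt=0, description="kg")
    bw_consumer: float = Field(60.0, gt=0, description="kg")
    bw_bystander: float = Field(60.0, gt=0, description="kg")
    breathing_volume_workday: float = Field(10.0, gt=0, description="m^3 per work day")
    vp_threshold: float = Field(0.1, description="Pa; volatility cut-off")
    consumer_area_cap: float = Field(0.02, gt=0, description="ha/day")
    n_applications_reentry: int = Field(2, ge=1)
    exposed_skin_area: float = Field(17500.0, gt=0, description="cm^2; dermal-load reference")

    @field_validator("vp_threshold")
    @classmethod
    def _vp_fixed(cls, v: float) -> float:
        if v != 0.1:
            raise ValueError("vp_threshold must be 0.1 Pa exactly")
        return v


class ProtectionFactors(_Frozen):
    gloves_dermal_pf: float = Field(10.0, ge=1)
    coverall_dermal_pf: float = Field(5.0, ge=1)
    rpe_pfs: dict[str, float] = Field(
        default_factory=lambda: {"none": 1.0, "pf10": 10.0, "pf20": 20.0}
    )
    lev_inhalation_reduction: float = Field(0.9, ge=0, lt=1)

    @field_validator("rpe_pfs")
    @classmethod
    def _rpe_allowed(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != {"none", "pf10", "pf20"} or any(
            pf not in (1.0, 10.0, 20.0) for pf in v.values()
        ):
            raise ValueError("RPE protection factors must map none/pf10/pf20 to {1, 10, 20}")
        return v


class GreenhouseDefaults(_Frozen):
    """Default constant-rate-release parameters for greenhouse spraying."""

    q: float = Field(gt=0, description="air changes per hour")
    h: float = Field(gt=0, description="greenhouse height, m")
    tr: float = Field(gt=0, description="release duration, h")
    t: float = Field(gt=0, description="worker exposure time, h")
    T: float = Field(gt=0, description="averaging period, h")
    V: float = Field(gt=0, description="greenhouse air volume, m^3 (informational)")

    @model_validator(mode="after")
    def _release_phase(self) -> "GreenhouseDefaults":
        if self.t > self.tr:
            raise ValueError("worker exposure time t must not exceed release duration tr")
        return self


class ReentryDefaults(_Frozen):
    dfr0: float = Field(gt=0, description="ug/cm^2 per kg/ha per application")
    tc: float = Field(gt=0, description="transfer coefficient, cm^2/h")
    duration: float = Field(gt=0, description="h")
    bw: float = Field(gt=0, description="kg")


class BystanderDefaults(_Frozen):
    drift_fraction: float = Field(gt=0, lt=1)
    exposed_area: float = Field(gt=0, description="cm^2")
    bw: float = Field(gt=0, description="kg")
    inhalation_unit_exposure: float = Field(ge=0, description="mg per kg handled")
    breathing_rate: float = Field(gt=0, description="m^3/h")
    duration: float = Field(gt=0, description="h")
    vapour_unit: float = Field(ge=0, description="mg/m^3 per kg/ha vapour add-on")


class SeedTreatmentDefaults(_Frozen):
    product_per_day: float = Field(gt=0, description="kg product loaded per day")


class _BandValues(_Frozen):
    dermal: float = Field(ge=0)
    inhalation: float = Field(ge=0)


class _ConcentrationBand(_Frozen):
    upper: float = Field(gt=0, le=1)
    factor: float = Field(gt=0, le=1)


class BaggingTable(_Frozen):
    """Static full-shift surrogate lookup for bagging of treated seeds."""

    solid: dict[str, _BandValues]
    liquid: dict[str, _BandValues]
    units: dict[str, str] = Field(default_factory=dict)
    source: str = "unspecified"
    default_band: str = "medium"
    concentration_bands: tuple[_ConcentrationBand, ...]

    @model_validator(mode="after")
    def _monotone_bands(self) -> "BaggingTable":
        uppers = [b.upper for b in self.concentration_bands]
        factors = [b.factor for b in self.concentration_bands]
        if uppers != sorted(uppers) or factors != sorted(factors):
            raise ValueError("concentration bands must be sorted with non-decreasing factors")
        if uppers[-1] != 1.0:
            raise ValueError("concentration bands must cover up to 1.0")
        return self

    def concentration_factor(self, concentration: float) -> float:
        if not 0 < concentration <= 1:
            raise DomainError("bagging concentration must be in (0, 1]")
        for band in self.concentration_bands:
            if concentration <= band.upper:
                return band.factor
        return self.concentration_bands[-1].factor


class Registry(_Frozen):
    """Immutable bundle of every model constant, with provenance."""

    defaults: Defaults
    protection_factors: ProtectionFactors
    techniques: dict[str, TechniqueSpec]
    greenhouse: GreenhouseDefaults
    reentry: ReentryDefaults
    bystander: BystanderDefaults
    seed_treatment: SeedTreatmentDefaults
    bagging: BaggingTable
    phed_areas: dict[str, float]
    unit_exposures: tuple[UnitExposure, ...]
    provenance: dict[str, dict[str, str]] = Field(default_factory=dict)

    _ue_index: Optional[dict[tuple, UnitExposure]] = PrivateAttr(default=None)

    @model_validator(mode="after")
    def _invariants(self) -> "Registry":
        seen: set[tuple] = set()
        for ue in self.unit_exposures:
            if ue.key in seen:
                raise ValueError(f"duplicate unit exposure entry {ue.key}")
            seen.add(ue.key)
        # p75 coverage for the tasks used by consumer spray scenarios
        for ue in self.unit_exposures:
            if ue.task_id in _CONSUMER_SPRAY_TASKS and ue.percentile == "geometric_mean":
                p75_key = (ue.task_id, ue.formulation, ue.route, "p75")
                if p75_key not in seen:
                    raise ValueError(f"missing p75 unit exposure for consumer task {p75_key}")
        tractor_areas = [t.area_per_day for t in self.techniques.values() if t.group == "tractor"]
        for t in self.techniques.values():
            if t.group == "hand_held" and tractor_areas and t.area_per_day > min(tractor_areas):
                raise ValueError(
                    f"hand-held technique {t.technique_id} treats more area per day than a tractor technique"
                )
        return self

    # -- lookups ---------------------------------------------------------
    def ue(
        self,
        task_id: str,
        formulation: str,
        route: str,
        percentile: str = "geometric_mean",
    ) -> UnitExposure:
        """Return the unit exposure for a task key, or raise naming the key."""
        if self._ue_index is None:
            object.__setattr__(
                self, "_ue_index", {u.key: u for u in self.unit_exposures}
            )
        key = (task_id, formulation, route, percentile)
        try:
            return self._ue_index[key]  # type: ignore[index]
        except KeyError:
            raise RegistryError(f"no unit exposure registered for {key}") from None

    def technique(self, technique_id: str) -> TechniqueSpec:
        try:
            return self.techniques[technique_id]
        except KeyError:
            raise RegistryError(f"unknown technique {technique_id!r}") from None

    def source_of(self, dotted_key: str) -> str:
        """Provenance tag of a scalar constant, e.g. ``defaults.bw_worker``."""
        try:
            return self.provenance[dotted_key]["source"]
        except KeyError:
            raise RegistryError(f"no provenance recorded for {dotted_key!r}") from None


def _strip_constants(node: Any, path: str, provenance: dict[str, dict[str, str]]) -> Any:
    """Replace ``{value, units, source}`` leaves by their value, recording provenance."""
    if isinstance(node, Mapping):
        if "value" in node and set(node) <= {"value", "units", "source"}:
            provenance[path] = {
                "units": str(node.get("units", "")),
                "source": str(node.get("source", "unspecified")),
            }
            return node["value"]
        return {
            key: _strip_constants(sub, f"{path}.{key}" if path else str(key), provenance)
            for key, sub in node.items()
        }
    if isinstance(node, list):
        return [_strip_constants(item, f"{path}[{i}]", provenance) for i, item in enumerate(node)]
    return node


def _techniques_with_ids(raw: dict[str, Any]) -> dict[str, Any]:
    return {tid: {"technique_id": tid, **spec} for tid, spec in raw.items()}


def load_registry(source: str | Path | Mapping[str, Any] | None = None) -> Registry:
    """Load and validate a parameter registry.

    Parameters
    ----------
    source
        ``None`` for the built-in defaults, a path to a YAML document, or an
        already-parsed mapping.  The document layout mirrors the built-in
        ``data/default_registry.yaml``: each scalar constant is a
        ``{value, units, source}`` entry.
    """
    if source is None:
        text = resources.files("owbscreen.data").joinpath("default_registry.yaml").read_text()
        raw = yaml.safe_load(text)
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise RegistryError(f"registry document not found: {path}")
        raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise RegistryError("registry document must be a mapping")

    provenance: dict[str, dict[str, str]] = {}
    stripped = _strip_constants(dict(raw), "", provenance)
    if "techniques" in stripped:
        stripped["techniques"] = _techniques_with_ids(stripped["techniques"])
    stripped["provenance"] = provenance
    try:
        return Registry(**stripped)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise RegistryError(f"invalid registry: {details}") from exc
    except TypeError as exc:
        raise RegistryError(f"invalid registry: {exc}") from exc


def dump_registry(registry: Registry) -> str:
    """Serialize a registry (values plus the provenance map) as YAML."""
    payload = registry.model_dump(mode="json")
    return yaml.safe_dump(payload, sort_keys=True)


def calibrate_unit_exposure(
    printed_exposure: float, daily_amount: float, reference: float
) -> float:
    """Back-derive a unit exposure from a published route exposure.

    The forward prediction is ``exposure = UE * Q / reference`` where ``Q`` is
    the daily amount of substance handled (kg/day) and ``reference`` is the
    body weight (kg, dermal route) or the breathing volume per work day
    (m^3, inhalation route).  Inverting gives
    ``UE = exposure * reference / Q`` in mg per kg handled.
    """
    if daily_amount <= 0 or reference <= 0:
        raise DomainError("daily_amount and reference must be strictly positive")
    if printed_exposure < 0:
        raise DomainError("exposure must be non-negative")
    return printed_exposure * reference / daily_amount
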