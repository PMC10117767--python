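"""Land-application geometry and cost, wastewater-treatment cost, and manure
comparators.

Spent media is assumed applied at an agronomic nitrogen rate to the corn
cropland surrounding the facility. Because only a fraction of land grows
corn, the serviced area dilates, and the facility's service territory is
modelled as a circle. Application is spread uniformly over that circle, so
the volume hauled beyond a threshold radius (and billed a surcharge) is
proportional to the area beyond the threshold circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from . import units
from .params import AnimalSpec, EconCosts
from .growth import feed_and_protein
from .nbalance import ProductionScenario

__all__ = [
    "ApplicationPlan",
    "WwtCost",
    "application_area",
    "fraction_beyond_threshold",
    "application_cost",
    "application_plan",
    "wwt_cost",
    "manure_application_cost",
]


@dataclass(frozen=True)
class ApplicationPlan:
    required_area_ha: float        # at the N application rate
    adjusted_area_ha: float        # after corn-land dilution
    service_radius_km: float
    fraction_beyond_threshold: float
    annual_volume_m3: float
    total_cost: float              # $ per year
    specific_cost: float           # $ per kg CM

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class WwtCost:
    n_cost: float                  # $ per year
    cod_cost: float                # $ per year
    specific_n_cost: float         # $ per kg CM
    specific_cod_cost: float       # $ per kg CM

    @property
    def total_cost(self) -> float:
        return self.n_cost + self.cod_cost

    @property
    def specific_total_cost(self) -> float:
        return self.specific_n_cost + self.specific_cod_cost

    def as_dict(self) -> dict:
        d = asdict(self)
        d["total_cost"] = self.total_cost
        d["specific_total_cost"] = self.specific_total_cost
        return d


def application_area(
    annual_n: float, rate: float, corn_fraction: float
) -> tuple[float, float, float]:
    """(required ha, corn-adjusted ha, service radius km) for an annual N load."""
    if rate <= 0:
        raise ValueError("application rate must be positive")
    if not 0 < corn_fraction <= 1:
        raise ValueError("corn_fraction must be in (0, 1]")
    required = annual_n / rate
    adjusted = required / corn_fraction
    radius_km = math.sqrt(adjusted * units.M2_PER_HA / math.pi) / 1000.0
    return required, adjusted, radius_km


def fraction_beyond_threshold(adjusted_area_ha: float, threshold_miles: float) -> float:
    """Area fraction of the service circle lying beyond the threshold radius."""
    if adjusted_area_ha <= 0:
        return 0.0
    r_t = threshold_miles * units.METERS_PER_MILE
    inner = math.pi * r_t**2 / units.M2_PER_HA
    return max(0.0, (adjusted_area_ha - inner) / adjusted_area_ha)


def application_cost(
    volume_m3: float, adjusted_area_ha: float, econ: EconCosts
) -> float:
    """Annual land-application cost, $: base rate on all volume plus a flat
    surcharge on the volume destined beyond the threshold radius."""
    if volume_m3 < 0:
        raise ValueError("volume must be >= 0")
    gallons = volume_m3 * units.US_GALLONS_PER_M3
    beyond = fraction_beyond_threshold(adjusted_area_ha, econ.distance_threshold_miles)
    return gallons * econ.application_base_cost + gallons * beyond * econ.application_distance_surcharge


def application_plan(scenario: ProductionScenario, econ: EconCosts) -> ApplicationPlan:
    """Geometry and cost of land-applying a scenario's annual spent media."""
    required, adjusted, radius_km = application_area(
        scenario.annual_nitrogen, econ.n_application_rate, econ.corn_land_fraction
    )
    beyond = fraction_beyond_threshold(adjusted, econ.distance_threshold_miles)
    total = application_cost(scenario.annual_wastewater, adjusted, econ)
    if scenario.annual_mass <= 0:
        raise ValueError("annual mass must be positive")
    return ApplicationPlan(
        required_area_ha=required,
        adjusted_area_ha=adjusted,
        service_radius_km=radius_km,
        fraction_beyond_threshold=beyond,
        annual_volume_m3=scenario.annual_wastewater,
        total_cost=total,
        specific_cost=total / scenario.annual_mass,
    )


def wwt_cost(
    annual_n: float, annual_cod: float, econ: EconCosts, annual_mass: float
) -> WwtCost:
    """Annual wastewater-treatment cost for nitrogen (TKN) and COD."""
    if annual_mass <= 0:
        raise ValueError("annual mass must be positive")
    n_cost = annual_n * econ.n_treatment_cost
    cod_cost = annual_cod * econ.cod_treatment_cost
    return WwtCost(
        n_cost=n_cost,
        cod_cost=cod_cost,
        specific_n_cost=n_cost / annual_mass,
        specific_cod_cost=cod_cost / annual_mass,
    )


def manure_application_cost(animal: AnimalSpec, econ: EconCosts) -> float:
    """Lifetime manure application cost per kg of edible meat, $ kg-1."""
    meat_output = feed_and_protein(animal).meat_output
    if meat_output <= 0:
        raise ValueError("meat output must be positive")
    gallons = units.convert(animal.lifetime_manure_volume, "L", "us_gal")
    return gallons * econ.application_base_cost / meat_output
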