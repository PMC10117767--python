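"""Spent-media mass balances per batch, and scaling to annual production.

The protein ledger closes exactly: fed = retained + waste, with waste
nitrogen at 16% of waste protein. The glucose ledger closes exactly as well:
fed = retained (caloric conversion efficiency) + respired + waste, with
respiration driven by the cellular oxygen uptake rate through the
stoichiometry of complete aerobic oxidation (180 g glucose per 192 g O2).
Waste glucose is expressed as chemical oxygen demand (COD) via its carbon
content. Annual loads follow from a revenue-driven batch count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Literal

from . import areal, units
from .params import CMBatchSpec

__all__ = [
    "BatchBalance",
    "ProductionScenario",
    "batch_protein_nitrogen",
    "batch_water",
    "nitrogen_concentration",
    "oxygen_uptake",
    "glucose_respired",
    "glucose_cod",
    "batch_balance",
    "scale_scenario",
]


@dataclass(frozen=True)
class BatchBalance:
    """Closed protein, glucose, water, and oxygen ledgers for one batch."""

    protein_fed: float          # kg
    protein_retained: float     # kg
    protein_waste: float        # kg
    nitrogen_waste: float       # kg N
    glucose_fed: float          # kg
    glucose_retained: float     # kg
    glucose_respired: float     # kg
    glucose_waste: float        # kg
    oxygen_uptake: float        # kg O2
    cod_waste: float            # kg COD
    wastewater_volume: float    # m3
    nitrogen_concentration: float  # kg N per m3

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ProductionScenario:
    """Annual scale implied by a meat price and revenue target."""

    meat_price: float               # $ per kg
    revenue_target: float           # $ per year
    annual_mass: float              # kg CM per year
    batches_per_year: int
    batch_days: float
    batches_per_reactor_year: int
    reactors: int
    annual_nitrogen: float          # kg N per year
    annual_cod: float               # kg COD per year
    annual_wastewater: float        # m3 per year

    def as_dict(self) -> dict:
        return asdict(self)


def batch_protein_nitrogen(spec: CMBatchSpec) -> tuple[float, float, float, float]:
    """Protein ledger for one batch: (fed, retained, waste, waste N) in kg."""
    pce = spec.protein_conversion_efficiency
    if pce <= 0:
        raise ZeroDivisionError("protein_conversion_efficiency is zero")
    retained = spec.batch_meat_mass * spec.meat_protein_fraction
    fed = retained / pce
    waste = fed - retained
    return fed, retained, waste, units.NITROGEN_PER_PROTEIN * waste


def batch_water(spec: CMBatchSpec, include_cleaning: bool = False) -> float:
    """Wastewater volume per batch, m3: media water minus water in the meat.

    Cleaning water is handled as a separate stream by default; pass
    ``include_cleaning=True`` for what-if runs that merge the streams.
    """
    meat_water = spec.batch_meat_mass * spec.water_balance_moisture / units.LITERS_PER_M3
    wastewater = spec.water_per_batch - meat_water
    if include_cleaning:
        wastewater += spec.cleaning_water_per_batch
    if wastewater < 0:
        raise ValueError("negative wastewater volume; check water inputs")
    return wastewater


def nitrogen_concentration(nitrogen_kg: float, volume_m3: float) -> float:
    """kg N per m3 of spent media; scale-invariant for fixed batch parameters."""
    if volume_m3 <= 0:
        raise ValueError("volume must be positive")
    return nitrogen_kg / volume_m3


def oxygen_uptake(
    spec: CMBatchSpec,
    proliferation_mean_rule: Literal["arithmetic", "geometric"] = "arithmetic",
) -> float:
    """Oxygen consumed per batch, kg O2.

    The cell inventory during proliferation is represented by a single
    midpoint count (arithmetic mean of initial and final totals by default,
    geometric mean under the alternate rule) held for the proliferation
    phase; the final count is held for the whole maturation phase.
    """
    volume_ml = spec.reactor_volume * 1e6
    n0 = spec.initial_cell_density * volume_ml
    nf = spec.final_cell_density * volume_ml
    if proliferation_mean_rule == "arithmetic":
        n_mid = 0.5 * (n0 + nf)
    elif proliferation_mean_rule == "geometric":
        n_mid = math.sqrt(n0 * nf)
    else:
        raise ValueError(f"unknown mean rule {proliferation_mean_rule!r}")
    # OUR is nmol O2 per hour per 1e6 cells -> mol per cell-hour:
    mol_per_cell_hour = spec.oxygen_uptake_rate * 1e-9 / 1e6
    cell_hours = n_mid * spec.proliferation_duration + nf * spec.maturation_duration
    return cell_hours * mol_per_cell_hour * units.O2_G_PER_MOL / 1000.0


def glucose_respired(oxygen_kg: float) -> float:
    """kg glucose oxidised per kg O2 consumed (180:192 mass ratio)."""
    if oxygen_kg < 0:
        raise ValueError("oxygen mass must be >= 0")
    return oxygen_kg * units.GLUCOSE_PER_O2


def glucose_cod(
    spec: CMBatchSpec, glucose_fed: float, respired: float
) -> tuple[float, float]:
    """(waste glucose kg, COD kg) for one batch.

    Retained glucose is the caloric conversion efficiency times the feed;
    the remainder after respiration is waste, converted to COD through the
    carbon content of glucose.
    """
    retained = spec.calorie_conversion_efficiency * glucose_fed
    waste = glucose_fed - retained - respired
    if waste < 0:
        raise ValueError("glucose ledger does not close: retained + respired > fed")
    cod = waste * units.CARBON_PER_GLUCOSE * units.COD_PER_CARBON
    return waste, cod


def batch_balance(
    spec: CMBatchSpec,
    include_cleaning_water: bool = False,
    proliferation_mean_rule: Literal["arithmetic", "geometric"] = "arithmetic",
) -> BatchBalance:
    """Assemble the complete per-batch spent-media balance."""
    fed, retained, waste, n_waste = batch_protein_nitrogen(spec)
    glucose_fed = areal.glucose_feed_per_kg(
        spec.meat_energy_density * 1000.0,
        spec.calorie_conversion_efficiency,
        spec.glucose_energy_density,
    ) * spec.batch_meat_mass
    o2 = oxygen_uptake(spec, proliferation_mean_rule)
    respired = glucose_respired(o2)
    g_waste, cod = glucose_cod(spec, glucose_fed, respired)
    wastewater = batch_water(spec, include_cleaning=include_cleaning_water)
    return BatchBalance(
        protein_fed=fed,
        protein_retained=retained,
        protein_waste=waste,
        nitrogen_waste=n_waste,
        glucose_fed=glucose_fed,
        glucose_retained=spec.calorie_conversion_efficiency * glucose_fed,
        glucose_respired=respired,
        glucose_waste=g_waste,
        oxygen_uptake=o2,
        cod_waste=cod,
        wastewater_volume=wastewater,
        nitrogen_concentration=nitrogen_concentration(n_waste, wastewater),
    )


def scale_scenario(
    spec: CMBatchSpec,
    meat_price: float,
    revenue_target: float,
    batch: BatchBalance,
) -> ProductionScenario:
    """Scale the per-batch balance to a revenue-driven annual facility.

    Batch counts round up (partial batches are impossible). The reactor
    count divides the exact annual batch requirement by the exact batches a
    reactor can run per year (365 / batch_days) before rounding up, which
    reproduces the published fleet sizes; the integer
    ``batches_per_reactor_year`` (floor) is reported alongside.
    """
    if meat_price <= 0:
        raise ValueError("meat price must be positive")
    annual_mass = revenue_target / meat_price
    exact_batches = annual_mass / spec.batch_meat_mass
    batches = math.ceil(exact_batches)
    per_reactor_exact = units.DAYS_PER_YEAR / spec.batch_days
    reactors = math.ceil(exact_batches / per_reactor_exact) if batches else 0
    return ProductionScenario(
        meat_price=meat_price,
        revenue_target=revenue_target,
        annual_mass=annual_mass,
        batches_per_year=batches,
        batch_days=spec.batch_days,
        batches_per_reactor_year=math.floor(per_reactor_exact),
        reactors=reactors,
        annual_nitrogen=batch.nitrogen_waste * batches,
        annual_cod=batch.cod_waste * batches,
        annual_wastewater=batch.wastewater_volume * batches,
    )
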