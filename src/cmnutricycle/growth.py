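"""Growth and feed-use metrics for conventional species and cultured meat.

The endpoint arithmetic is deliberately simple: specific growth rate from an
exponential fit between two masses, average daily gain as a difference
quotient, and feed/protein ledgers from slaughter weight, feed conversion
ratio (FCR), and diet composition. Protein conversion efficiency (PCE) is
edible protein out over protein fed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Literal

import pandas as pd

from .params import AnimalSpec, CMBatchSpec, inoculum_mass
from . import areal

__all__ = [
    "GrowthMetrics",
    "specific_growth_rate",
    "average_daily_gain",
    "feed_and_protein",
    "cm_growth_metrics",
    "growth_table",
]


@dataclass(frozen=True)
class GrowthMetrics:
    """One species' column of the growth/feed comparison."""

    species: str
    initial_mass: float              # kg (birth weight / inoculum)
    final_mass: float                # kg (live weight / batch meat mass)
    growth_time: float               # days
    specific_growth_rate: float      # day-1
    average_daily_gain: float        # kg day-1
    meat_output: float               # kg wet edible
    meat_protein_fraction: float
    meat_moisture_fraction: float
    feed_conversion_ratio: float     # kg feed per kg live weight (or per kg CM)
    total_feed: float                # kg
    diet_protein_fraction: float
    protein_fed: float               # kg
    protein_output: float            # kg
    protein_conversion_efficiency: float

    def as_dict(self) -> dict:
        return asdict(self)


def specific_growth_rate(initial_mass: float, final_mass: float, duration_days: float) -> float:
    """Exponential growth constant mu = ln(m_f / m_i) / t, in day-1.

    Works on any consistent basis (kg or cell counts); the ratio is what
    matters. Antisymmetric under swapping the two masses.
    """
    if initial_mass <= 0 or final_mass <= 0:
        raise ValueError("masses must be positive")
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    return math.log(final_mass / initial_mass) / duration_days


def average_daily_gain(birth: float, live: float, duration_days: float) -> float:
    """(live - birth) / growth time, kg per day."""
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    return (live - birth) / duration_days


def feed_and_protein(
    spec: AnimalSpec,
    mu_basis: Literal["live", "edible_output"] = "live",
) -> GrowthMetrics:
    """Full growth/feed metrics for a conventional species.

    ``mu_basis`` selects the masses entering the growth-rate fit: ``"live"``
    (birth -> live weight, the basis that reproduces the published rates) or
    ``"edible_output"`` (birth weight -> edible meat output, the literal
    edible-mass reading). Both are kept because the source text and its
    arithmetic disagree on this point.
    """
    total_feed = spec.live_weight * spec.feed_conversion_ratio
    protein_fed = total_feed * spec.diet_protein_fraction
    meat_output = spec.live_weight * spec.edible_fraction
    protein_output = meat_output * spec.meat_protein_fraction
    if protein_fed <= 0:
        raise ZeroDivisionError("protein_fed is zero; PCE undefined")
    final_for_mu = spec.live_weight if mu_basis == "live" else meat_output
    return GrowthMetrics(
        species=spec.species,
        initial_mass=spec.birth_weight,
        final_mass=spec.live_weight,
        growth_time=spec.growth_time,
        specific_growth_rate=specific_growth_rate(spec.birth_weight, final_for_mu, spec.growth_time),
        average_daily_gain=average_daily_gain(spec.birth_weight, spec.live_weight, spec.growth_time),
        meat_output=meat_output,
        meat_protein_fraction=spec.meat_protein_fraction,
        meat_moisture_fraction=spec.meat_moisture_fraction,
        feed_conversion_ratio=spec.feed_conversion_ratio,
        total_feed=total_feed,
        diet_protein_fraction=spec.diet_protein_fraction,
        protein_fed=protein_fed,
        protein_output=protein_output,
        protein_conversion_efficiency=protein_output / protein_fed,
    )


def cm_growth_metrics(
    spec: CMBatchSpec,
    total_feed: float | None = None,
    mu_basis: Literal["cells", "mass"] = "cells",
) -> GrowthMetrics:
    """Growth/feed metrics for one CM batch.

    ``total_feed`` is protein feed + glucose feed for the batch; when omitted
    it is computed from the batch spec (protein need from PCE, glucose need
    from the caloric balance). ``mu_basis="cells"`` fits the growth rate on
    proliferation-phase cell densities over the proliferation time, the basis
    consistent with exponential cell growth; ``"mass"`` uses inoculum ->
    harvest mass over the whole batch.
    """
    protein_output = spec.batch_meat_mass * spec.meat_protein_fraction
    pce = spec.protein_conversion_efficiency
    if pce <= 0:
        raise ZeroDivisionError("protein_conversion_efficiency is zero")
    protein_fed = protein_output / pce
    if total_feed is None:
        glucose = areal.glucose_feed_per_kg(
            spec.meat_energy_density * 1000.0,
            spec.calorie_conversion_efficiency,
            spec.glucose_energy_density,
        ) * spec.batch_meat_mass
        total_feed = protein_fed + glucose

    inoc = inoculum_mass(spec)
    growth_days = (spec.proliferation_duration + spec.maturation_duration) / 24.0
    if mu_basis == "cells":
        mu = specific_growth_rate(
            spec.initial_cell_density,
            spec.final_cell_density,
            spec.proliferation_duration / 24.0,
        )
    else:
        mu = specific_growth_rate(inoc, spec.batch_meat_mass, growth_days)
    return GrowthMetrics(
        species=spec.label,
        initial_mass=inoc,
        final_mass=spec.batch_meat_mass,
        growth_time=growth_days,
        specific_growth_rate=mu,
        average_daily_gain=average_daily_gain(inoc, spec.batch_meat_mass, growth_days),
        meat_output=spec.batch_meat_mass,        # 100% edible
        meat_protein_fraction=spec.meat_protein_fraction,
        meat_moisture_fraction=spec.meat_moisture_fraction,
        feed_conversion_ratio=total_feed / spec.batch_meat_mass,
        total_feed=total_feed,
        diet_protein_fraction=protein_fed / total_feed,
        protein_fed=protein_fed,
        protein_output=protein_output,
        protein_conversion_efficiency=pce,
    )


_ROW_ORDER = [
    ("Birth weight (kg)", "initial_mass"),
    ("Live weight (kg)", "final_mass"),
    ("Edible meat fraction", None),
    ("Meat output wb (kg)", "meat_output"),
    ("Meat protein content (kg/kg)", "meat_protein_fraction"),
    ("Meat moisture content", "meat_moisture_fraction"),
    ("Growth time (day)", "growth_time"),
    ("Average weight gain (kg/day)", "average_daily_gain"),
    ("Specific growth rate (day-1)", "specific_growth_rate"),
    ("Feed conversion ratio", "feed_conversion_ratio"),
    ("Total feed mass (kg)", "total_feed"),
    ("Protein in diet", "diet_protein_fraction"),
    ("Protein fed (kg)", "protein_fed"),
    ("Protein conversion efficiency", "protein_conversion_efficiency"),
]


def growth_table(
    animals: dict[str, AnimalSpec],
    cm_spec: CMBatchSpec,
    mu_basis: Literal["live", "edible_output"] = "live",
) -> pd.DataFrame:
    """Growth/feed comparison table, one column per production system."""
    columns: dict[str, GrowthMetrics] = {
        name: feed_and_protein(spec, mu_basis=mu_basis) for name, spec in animals.items()
    }
    columns[cm_spec.label] = cm_growth_metrics(cm_spec)
    edible = {name: spec.edible_fraction for name, spec in animals.items()}
    edible[cm_spec.label] = 1.0

    data = {}
    for name, gm in columns.items():
        col = {}
        for row_label, attr in _ROW_ORDER:
            col[row_label] = edible[name] if attr is None else getattr(gm, attr)
        data[name] = col
    df = pd.DataFrame(data)
    df.index.name = "quantity"
    return df
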