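"""Feed requirements, land use with price-based co-product allocation, and
areal protein/energy productivities.

Land use per kg of cultured meat is assembled from two crop chains: soybean
hydrolysate supplies protein (scaled by the protein conversion efficiency)
and corn starch supplies glucose (scaled by the caloric conversion
efficiency). Each crop's land footprint is split among its co-products in
proportion to market value, and only the share of the media ingredient is
charged to the meat. Productivity is the reciprocal view: nutrient content
divided by land use, in g protein or MJ per m2 per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import units
from .params import CMBatchSpec, FeedstockChain, LandUseEntry

__all__ = [
    "LandUseResult",
    "ArealProductivity",
    "protein_feed_per_kg",
    "glucose_feed_per_kg",
    "crop_land_per_kg",
    "price_allocation",
    "feedstock_land_per_kg_cm",
    "soy_land_per_kg_cm",
    "corn_land_per_kg_cm",
    "cm_land_use",
    "landuse_to_productivity",
    "productivity_table",
]


@dataclass(frozen=True)
class LandUseResult:
    """Land footprint of one kg of CM, split by nutrient source."""

    protein_land: float          # m2 per kg CM
    energy_land: float           # m2 per kg CM
    ledger: dict = field(default_factory=dict)

    @property
    def total_land(self) -> float:
        return self.protein_land + self.energy_land


@dataclass(frozen=True)
class ArealProductivity:
    label: str
    land_use: float                       # m2 per kg per year (midpoint if ranged)
    protein_productivity: float           # g protein m-2 yr-1
    energy_productivity: float            # MJ m-2 yr-1
    land_low: float | None = None
    land_high: float | None = None


def protein_feed_per_kg(meat_protein_fraction: float, pce: float) -> float:
    """kg of feed protein (hydrolysate) required per kg of CM."""
    if not 0 < pce <= 1:
        raise ValueError("pce must be in (0, 1]")
    return meat_protein_fraction / pce


def glucose_feed_per_kg(
    meat_energy_kcal_per_kg: float,
    calorie_efficiency: float,
    glucose_energy_kcal_per_kg: float,
) -> float:
    """kg glucose required per kg of CM from the caloric balance."""
    if not 0 < calorie_efficiency <= 1:
        raise ValueError("calorie_efficiency must be in (0, 1]")
    if glucose_energy_kcal_per_kg <= 0:
        raise ValueError("glucose energy density must be positive")
    return meat_energy_kcal_per_kg / calorie_efficiency / glucose_energy_kcal_per_kg


def crop_land_per_kg(yield_mg_per_ha: float) -> float:
    """m2 of cropland per kg of harvested crop at a given annual yield."""
    if yield_mg_per_ha <= 0:
        raise ValueError("yield must be positive")
    return units.M2_PER_HA / (yield_mg_per_ha * 1000.0)


def price_allocation(
    mass_fractions: Mapping[str, float], prices: Mapping[str, float]
) -> dict[str, float]:
    """Value shares share_i = m_i p_i / sum_j m_j p_j; shares sum to 1."""
    if not mass_fractions:
        raise ValueError("at least one component required")
    values = {k: mass_fractions[k] * prices[k] for k in mass_fractions}
    total = sum(values.values())
    if total <= 0:
        raise ValueError("total component value is zero; allocation undefined")
    return {k: v / total for k, v in values.items()}


def _allocation_share(chain: FeedstockChain) -> float:
    if chain.allocation_mode == "none":
        return 1.0
    if chain.printed_allocation_share is not None and chain.chain_mode == "as_printed":
        return chain.printed_allocation_share
    if any(p > 0 for p in chain.component_prices.values()):
        return price_allocation(chain.component_fractions, chain.component_prices)[
            chain.target_component
        ]
    if chain.printed_allocation_share is not None:
        return chain.printed_allocation_share
    raise ValueError(f"no allocation share available for chain {chain.crop!r}")


def feedstock_land_per_kg_cm(chain: FeedstockChain, nutrient_need: float) -> float:
    """Allocated cropland (m2) per kg CM for one nutrient chain.

    ``as_printed`` divides the nutrient need by the target component's
    nutrient content alone (the component-fraction and recovery factors
    cancel, as in the published arithmetic) and uses the printed allocation
    share; ``stated_chain`` applies the full chain
    need / (component_fraction x nutrient_fraction x recovery) with exact
    price-based shares where prices are available.
    """
    if nutrient_need < 0:
        raise ValueError("nutrient need must be >= 0")
    if chain.chain_mode == "as_printed":
        denom = chain.nutrient_fraction
    else:
        denom = (
            chain.component_fractions[chain.target_component]
            * chain.nutrient_fraction
            * chain.recovery_fraction
        )
    if denom <= 0:
        raise ValueError("chain nutrient denominator is zero")
    crop_kg = nutrient_need / denom
    return crop_kg * crop_land_per_kg(chain.yield_mg_per_ha) * _allocation_share(chain)


def soy_land_per_kg_cm(chain: FeedstockChain, protein_need: float) -> float:
    """Allocated soybean land (m2) per kg CM for the protein requirement."""
    return feedstock_land_per_kg_cm(chain, protein_need)


def corn_land_per_kg_cm(chain: FeedstockChain, glucose_need: float) -> float:
    """Allocated corn land (m2) per kg CM for the glucose requirement.

    The corn chain always divides by the starch fraction of the grain (wet
    milling), so the chain is evaluated in ``stated_chain`` form; the starch
    allocation share (0.74) is a literature figure, not price-derived here.
    """
    if chain.component_fractions[chain.target_component] <= 0:
        raise ValueError("starch fraction must be positive")
    working = chain if chain.chain_mode == "stated_chain" else chain.model_copy(
        update={"chain_mode": "stated_chain"}
    )
    return feedstock_land_per_kg_cm(working, glucose_need)


def cm_land_use(
    spec: CMBatchSpec, soy: FeedstockChain, corn: FeedstockChain
) -> LandUseResult:
    """Full land footprint of 1 kg CM with an intermediate ledger."""
    protein_need = protein_feed_per_kg(spec.meat_protein_fraction, spec.protein_conversion_efficiency)
    glucose_need = glucose_feed_per_kg(
        spec.meat_energy_density * 1000.0,
        spec.calorie_conversion_efficiency,
        spec.glucose_energy_density,
    )
    protein_land = soy_land_per_kg_cm(soy, protein_need)
    energy_land = corn_land_per_kg_cm(corn, glucose_need)
    ledger = {
        "protein_need_kg_per_kg": protein_need,
        "glucose_need_kg_per_kg": glucose_need,
        "soy_allocation_share": _allocation_share(soy),
        "corn_allocation_share": _allocation_share(
            corn if corn.chain_mode == "stated_chain" else corn.model_copy(update={"chain_mode": "stated_chain"})
        ),
        "soy_crop_land_m2_per_kg": crop_land_per_kg(soy.yield_mg_per_ha),
        "corn_crop_land_m2_per_kg": crop_land_per_kg(corn.yield_mg_per_ha),
        "soy_printed_land_reference": soy.printed_land_reference,
        "corn_printed_land_reference": corn.printed_land_reference,
    }
    return LandUseResult(protein_land=protein_land, energy_land=energy_land, ledger=ledger)


def landuse_to_productivity(
    land_use: float,
    protein_fraction: float,
    energy_kcal_per_kg: float,
    label: str = "",
    land_low: float | None = None,
    land_high: float | None = None,
) -> ArealProductivity:
    """Invert a land-use figure (m2 kg-1 yr-1) into areal productivities."""
    if land_use <= 0:
        raise ValueError("land_use must be positive")
    return ArealProductivity(
        label=label,
        land_use=land_use,
        protein_productivity=1000.0 * protein_fraction / land_use,
        energy_productivity=energy_kcal_per_kg * units.KJ_PER_KCAL / 1000.0 / land_use,
        land_low=land_low,
        land_high=land_high,
    )


def productivity_table(
    cm_spec: CMBatchSpec,
    soy: FeedstockChain,
    corn: FeedstockChain,
    livestock: Mapping[str, LandUseEntry],
) -> pd.DataFrame:
    """One row per production system: land use and areal productivities.

    Livestock rows use midpoint land use with the published range carried in
    ``land_low``/``land_high``; the CM row uses the computed chain.
    """
    rows = []
    for name, entry in livestock.items():
        prod = landuse_to_productivity(
            entry.land_mid, entry.protein_fraction, entry.energy_kcal_per_kg,
            label=name, land_low=entry.land_low, land_high=entry.land_high,
        )
        rows.append(prod)
    lu = cm_land_use(cm_spec, soy, corn)
    rows.append(
        landuse_to_productivity(
            lu.total_land,
            cm_spec.meat_protein_fraction,
            cm_spec.meat_energy_density * 1000.0,
            label=cm_spec.label,
        )
    )
    df = pd.DataFrame(
        {
            "system": [r.label for r in rows],
            "land_use_m2_per_kg_yr": [r.land_use for r in rows],
            "land_low": [r.land_low for r in rows],
            "land_high": [r.land_high for r in rows],
            "protein_productivity_g_per_m2_yr": [r.protein_productivity for r in rows],
            "energy_productivity_MJ_per_m2_yr": [r.energy_productivity for r in rows],
        }
    ).set_index("system")
    return df
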