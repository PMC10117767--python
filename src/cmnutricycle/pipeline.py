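"""End-to-end evaluation of one parameter set through every stage.

This is the single path the sampler, the report builder, and downstream
scripts all call, so ensemble draws and the headline tables are guaranteed
to run identical arithmetic.
"""

from __future__ import annotations

from typing import Literal

from . import areal, costs, nbalance, nue
from .params import CMBatchSpec, EconCosts, FeedstockChain, Scenario

__all__ = ["run_scenario", "scenario_record"]


def run_scenario(
    cm: CMBatchSpec,
    econ: EconCosts,
    soy: FeedstockChain,
    corn: FeedstockChain,
    meat_price: float,
    revenue_target: float,
    include_cleaning_water: bool = False,
    proliferation_mean_rule: Literal["arithmetic", "geometric"] = "arithmetic",
) -> dict:
    """Run land use -> batch balance -> annual scale -> costs -> NUE.

    Returns a flat record of the headline outputs plus the nested result
    objects under ``objects``.
    """
    land = areal.cm_land_use(cm, soy, corn)
    batch = nbalance.batch_balance(
        cm,
        include_cleaning_water=include_cleaning_water,
        proliferation_mean_rule=proliferation_mean_rule,
    )
    scen = nbalance.scale_scenario(cm, meat_price, revenue_target, batch)
    plan = costs.application_plan(scen, econ)
    wwt = costs.wwt_cost(scen.annual_nitrogen, scen.annual_cod, econ, scen.annual_mass)
    partition = nue.cm_partition(cm.protein_conversion_efficiency)
    return {
        "meat_price": meat_price,
        "annual_mass_kg": scen.annual_mass,
        "batches_per_year": scen.batches_per_year,
        "reactors": scen.reactors,
        "protein_land_m2_per_kg": land.protein_land,
        "energy_land_m2_per_kg": land.energy_land,
        "total_land_m2_per_kg": land.total_land,
        "batch_nitrogen_kg": batch.nitrogen_waste,
        "batch_cod_kg": batch.cod_waste,
        "nitrogen_concentration_kg_m3": batch.nitrogen_concentration,
        "annual_nitrogen_kg": scen.annual_nitrogen,
        "annual_cod_kg": scen.annual_cod,
        "annual_wastewater_m3": scen.annual_wastewater,
        "application_cost_per_year": plan.total_cost,
        "specific_application_cost": plan.specific_cost,
        "wwt_cost_per_year": wwt.total_cost,
        "specific_wwt_cost": wwt.specific_total_cost,
        "cm_lost_n_fraction": partition.lost_fraction,
        "person_equivalents": nue.person_equivalents(scen.annual_nitrogen),
        "objects": {
            "land": land,
            "batch": batch,
            "scenario": scen,
            "application": plan,
            "wwt": wwt,
            "partition": partition,
        },
    }


def scenario_record(scenario: Scenario, meat_price: float) -> dict:
    """Convenience wrapper taking a resolved :class:`Scenario`."""
    return run_scenario(
        scenario.cm_batch,
        scenario.economics,
        scenario.feedstocks["soy"],
        scenario.feedstocks["corn"],
        meat_price,
        scenario.revenue_target,
    )
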