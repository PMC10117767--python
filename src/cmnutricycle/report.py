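"""Report bundle: regenerate every headline table as a DataFrame and write
them to disk as CSV or a single JSON document.

Tables carry full-precision values plus companion ``*_printed`` columns
rounded to the precision at which the corresponding published figures are
reported, so like can be compared with like.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, areal, costs, growth, nue
from .params import Scenario, default_scenario, livestock_land_use
from .pipeline import scenario_record

__all__ = ["ReportBundle", "build_report", "write_tables", "round_sig"]


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    metadata: dict = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _scenario_table(scenario: Scenario) -> pd.DataFrame:
    rows = {}
    for price in scenario.meat_prices:
        rec = scenario_record(scenario, price)
        plan = rec["objects"]["application"]
        wwt = rec["objects"]["wwt"]
        rows[f"${price:g}/kg"] = {
            "meat_price_per_kg": price,
            "annual_cm_production_kg": rec["annual_mass_kg"],
            "batches_per_year": rec["batches_per_year"],
            "reactors": rec["reactors"],
            "waste_nitrogen_kg_per_yr": rec["annual_nitrogen_kg"],
            "waste_cod_kg_per_yr": rec["annual_cod_kg"],
            "wastewater_m3_per_yr": rec["annual_wastewater_m3"],
            "wwt_cost_per_yr": wwt.total_cost,
            "application_cost_per_yr": plan.total_cost,
            "specific_wwt_cost_per_kg": wwt.specific_total_cost,
            "specific_application_cost_per_kg": plan.specific_cost,
            "required_area_ha": plan.required_area_ha,
            "adjusted_area_ha": plan.adjusted_area_ha,
            "service_radius_km": plan.service_radius_km,
            "fraction_beyond_threshold": plan.fraction_beyond_threshold,
            "nitrogen_concentration_kg_m3": rec["nitrogen_concentration_kg_m3"],
            "person_equivalents": rec["person_equivalents"],
        }
    df = pd.DataFrame(rows)
    # companion rows at published rounding (3 significant figures)
    printed = df.map(lambda v: round_sig(v, 3))
    printed.index = [f"{i}_printed" for i in df.index]
    df = pd.concat([df, printed])
    df.index.name = "quantity"
    return df


def _cost_comparison(scenario: Scenario) -> pd.DataFrame:
    rows = []
    for name, animal in scenario.animals.items():
        rows.append({
            "system": name,
            "strategy": "manure land application",
            "cost_per_kg_meat": costs.manure_application_cost(animal, scenario.economics),
        })
    for price in scenario.meat_prices:
        rec = scenario_record(scenario, price)
        rows.append({
            "system": f"cm ${price:g}/kg",
            "strategy": "spent media land application",
            "cost_per_kg_meat": rec["specific_application_cost"],
        })
        rows.append({
            "system": f"cm ${price:g}/kg",
            "strategy": "wastewater treatment",
            "cost_per_kg_meat": rec["specific_wwt_cost"],
        })
    return pd.DataFrame(rows).set_index(["system", "strategy"])


def _nue_table(scenario: Scenario) -> pd.DataFrame:
    parts = [nue.partition_from_animal(a) for a in scenario.animals.values()]
    cm_part = nue.cm_partition(scenario.cm_batch.protein_conversion_efficiency)
    parts.append(cm_part)
    df = pd.DataFrame([p.as_dict() for p in parts]).set_index("label")
    parity = []
    for p in parts[:-1]:
        if p.lost_fraction >= cm_part.lost_fraction:
            # systems losing more N than CM are already matched with no recovery
            fed, waste = 0.0, 0.0
        else:
            fed, waste = nue.recovery_to_match(cm_part.lost_fraction, p.lost_fraction)
        parity.append({"match_target": p.label,
                       "recovery_of_fed_n": fed,
                       "recovery_of_waste_stream": waste})
    df2 = pd.DataFrame(parity).set_index("match_target")
    return df.join(df2, how="left")


def build_report(scenario: Scenario | None = None) -> ReportBundle:
    """Run every module pipeline and collect the output tables.

    Stage errors are captured per table; the bundle is returned partial with
    the failure recorded rather than raising.
    """
    scenario = scenario or default_scenario()
    tables: dict[str, pd.DataFrame] = {}
    failures: dict[str, str] = {}
    stages = {
        "growth": lambda: growth.growth_table(scenario.animals, scenario.cm_batch),
        "scenario": lambda: _scenario_table(scenario),
        "areal": lambda: areal.productivity_table(
            scenario.cm_batch, scenario.feedstocks["soy"],
            scenario.feedstocks["corn"], livestock_land_use(),
        ),
        "cost_comparison": lambda: _cost_comparison(scenario),
        "nue": lambda: _nue_table(scenario),
    }
    for name, fn in stages.items():
        try:
            tables[name] = fn()
        except Exception as exc:  # stage-tagged failure, bundle stays partial
            failures[name] = f"{type(exc).__name__}: {exc}"
    presets_hash = hashlib.sha256(
        scenario.model_dump_json().encode()
    ).hexdigest()[:16]
    metadata = {
        "version": __version__,
        "presets_hash": presets_hash,
        "meat_prices": list(scenario.meat_prices),
        "revenue_target": scenario.revenue_target,
        "tables": sorted(tables),
        "failures": failures,
    }
    return ReportBundle(tables=tables, metadata=metadata, failures=failures)


def write_tables(
    bundle: ReportBundle, outdir: str | Path, fmt: str = "csv"
) -> list[Path]:
    """Write one file per table plus metadata; returns the paths written."""
    if not bundle.tables:
        raise ValueError("empty bundle; nothing to write")
    if fmt not in {"csv", "json"}:
        raise ValueError(f"unknown format {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    if fmt == "csv":
        for name, df in bundle.tables.items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, float_format="%.10g")
            paths.append(p)
        meta = outdir / "metadata.json"
        meta.write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True))
        paths.append(meta)
    else:
        doc = {
            "metadata": bundle.metadata,
            "tables": {
                name: json.loads(df.reset_index().to_json(orient="records"))
                for name, df in bundle.tables.items()
            },
        }
        p = outdir / "report.json"
        p.write_text(json.dumps(doc, indent=2, sort_keys=True))
        paths.append(p)
    return paths
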