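"""Seeded scenario ensembles over published parameter ranges.

The analysis itself is deterministic; uncertainty enters only through the
spread of published bioreactor and economic parameters. This module draws
parameter sets from those ranges (uniform by default; log-uniform for cell
densities, whose published spread exceeds an order of magnitude), pushes
each draw through the full pipeline, and summarises the output spread. A
one-at-a-time tornado ranks parameters by their swing on a chosen metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import nbalance
from .params import (
    CMBatchSpec,
    EconCosts,
    FeedstockChain,
    corn_chain,
    default_costs,
    mattick_batch,
    soy_chain,
)
from .pipeline import run_scenario

__all__ = [
    "ParameterRange",
    "EnsembleResult",
    "default_ranges",
    "sample_scenarios",
    "run_ensemble",
    "tornado",
    "METRICS",
]


class ParameterRange(BaseModel):
    """A sampling range for one scalar parameter."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    low: float
    high: float
    distribution: Literal["uniform", "loguniform", "triangular"] = "uniform"
    mode: float | None = None
    units: str = ""

    @model_validator(mode="after")
    def _check(self) -> "ParameterRange":
        if self.low > self.high:
            raise ValueError(f"{self.name}: low must be <= high")
        if self.distribution == "loguniform" and self.low <= 0:
            raise ValueError(f"{self.name}: log-uniform requires low > 0")
        if self.distribution == "triangular":
            m = self.mode if self.mode is not None else 0.5 * (self.low + self.high)
            if not self.low <= m <= self.high:
                raise ValueError(f"{self.name}: triangular mode outside [low, high]")
        return self


#: Fields sampled on the batch spec vs the cost model vs the scenario level.
_CM_FIELDS = {
    "initial_cell_density", "final_cell_density", "proliferation_duration",
    "maturation_duration", "cell_wet_mass", "reactor_volume",
    "protein_conversion_efficiency", "calorie_conversion_efficiency",
    "batch_meat_mass", "water_per_batch", "oxygen_uptake_rate",
}
_ECON_FIELDS = {
    "application_base_cost", "application_distance_surcharge",
    "n_treatment_cost", "cod_treatment_cost", "n_application_rate",
    "corn_land_fraction",
}
_SCENARIO_FIELDS = {"meat_price"}


def default_ranges() -> list[ParameterRange]:
    """Published parameter spreads used as ensemble defaults.

    Cell densities and phase lengths span the range of published bioreactor
    models; conversion efficiencies span the published possible range; the
    meat price spans the two price scenarios.
    """
    return [
        ParameterRange(name="initial_cell_density", low=1e5, high=2e6,
                       distribution="loguniform", units="cells/ml"),
        ParameterRange(name="final_cell_density", low=4e6, high=4e7,
                       distribution="loguniform", units="cells/ml"),
        ParameterRange(name="proliferation_duration", low=53, high=240, units="h"),
        ParameterRange(name="maturation_duration", low=24, high=240, units="h"),
        ParameterRange(name="protein_conversion_efficiency", low=0.17, high=0.33),
        ParameterRange(name="calorie_conversion_efficiency", low=0.17, high=0.33),
        ParameterRange(name="meat_price", low=10.0, high=25.0, units="$/kg"),
    ]


def _draw(rng: np.random.Generator, r: ParameterRange) -> float:
    if r.low == r.high:
        return r.low
    if r.distribution == "uniform":
        return rng.uniform(r.low, r.high)
    if r.distribution == "loguniform":
        return math.exp(rng.uniform(math.log(r.low), math.log(r.high)))
    mode = r.mode if r.mode is not None else 0.5 * (r.low + r.high)
    return rng.triangular(r.low, mode, r.high)


@dataclass(frozen=True)
class Draw:
    """One sampled parameter set, already validated into spec objects."""

    params: dict
    cm: CMBatchSpec
    econ: EconCosts
    meat_price: float


def sample_scenarios(
    ranges: Sequence[ParameterRange],
    n: int,
    seed: int,
    base_cm: CMBatchSpec | None = None,
    base_econ: EconCosts | None = None,
    base_meat_price: float = 25.0,
    max_retries: int = 100,
) -> list[Draw]:
    """Draw ``n`` validated parameter sets; bit-reproducible for fixed seed.

    Draws violating joint invariants (e.g. final density below initial) are
    resampled up to ``max_retries`` times; exhausting the cap raises.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for r in ranges:
        unknown = r.name not in (_CM_FIELDS | _ECON_FIELDS | _SCENARIO_FIELDS)
        if unknown:
            raise ValueError(f"unknown parameter {r.name!r}")
    rng = np.random.default_rng(seed)
    base_cm = base_cm or mattick_batch()
    base_econ = base_econ or default_costs()
    draws: list[Draw] = []
    rejections = 0
    import warnings as _warnings
    for _ in range(n):
        for attempt in range(max_retries):
            params = {r.name: _draw(rng, r) for r in ranges}
            cm_over = {k: v for k, v in params.items() if k in _CM_FIELDS}
            econ_over = {k: v for k, v in params.items() if k in _ECON_FIELDS}
            price = params.get("meat_price", base_meat_price)
            try:
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    cm = base_cm.model_copy(update=cm_over)
                    cm = CMBatchSpec.model_validate(cm.model_dump())
                    econ = base_econ.model_copy(update=econ_over)
                    econ = EconCosts.model_validate(econ.model_dump())
                # joint-consistency check: the sampled caloric efficiency and
                # oxygen demand must admit a closing glucose ledger
                nbalance.batch_balance(cm)
            except (ValueError, ZeroDivisionError):
                rejections += 1
                continue
            draws.append(Draw(params=params, cm=cm, econ=econ, meat_price=price))
            break
        else:
            raise RuntimeError(f"could not draw a valid parameter set in {max_retries} tries")
    if rejections:
        logging.getLogger(__name__).info(
            "resampled %d infeasible draw(s) for %d accepted", rejections, n
        )
    return draws


_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)

#: Registered output metrics: record key -> description.
METRICS: dict[str, str] = {
    "total_land_m2_per_kg": "total cropland per kg CM (m2)",
    "annual_nitrogen_kg": "annual spent-media nitrogen (kg N/yr)",
    "annual_cod_kg": "annual spent-media COD (kg/yr)",
    "nitrogen_concentration_kg_m3": "spent-media N concentration (kg/m3)",
    "specific_application_cost": "land application cost ($/kg CM)",
    "specific_wwt_cost": "wastewater treatment cost ($/kg CM)",
    "cm_lost_n_fraction": "fed N lost without recovery (fraction)",
    "person_equivalents": "waste N person-equivalents",
}


@dataclass
class EnsembleResult:
    seed: int
    n_draws: int
    records: pd.DataFrame = field(repr=False)
    failures: list[tuple[int, str]] = field(default_factory=list)

    def quantiles(self) -> pd.DataFrame:
        return self.records[list(METRICS)].quantile(list(_QUANTILES))


def run_ensemble(
    draws: Sequence[Draw],
    revenue_target: float = 1e7,
    soy: FeedstockChain | None = None,
    corn: FeedstockChain | None = None,
    seed: int = 0,
) -> EnsembleResult:
    """Evaluate the full pipeline on every draw.

    Per-draw failures are recorded and skipped rather than aborting; if
    every draw fails the first cause is raised.
    """
    if not draws:
        raise ValueError("ensemble is empty")
    soy = soy or soy_chain()
    corn = corn or corn_chain()
    rows, failures = [], []
    for i, d in enumerate(draws):
        try:
            rec = run_scenario(d.cm, d.econ, soy, corn, d.meat_price, revenue_target)
        except (ValueError, ZeroDivisionError) as exc:
            failures.append((i, str(exc)))
            continue
        rec = {k: v for k, v in rec.items() if k != "objects"}
        rec.update({f"param:{k}": v for k, v in d.params.items()})
        rec["draw"] = i
        rows.append(rec)
    if not rows:
        raise RuntimeError(f"all {len(draws)} draws failed; first cause: {failures[0][1]}")
    return EnsembleResult(
        seed=seed, n_draws=len(draws),
        records=pd.DataFrame(rows).set_index("draw"),
        failures=failures,
    )


def tornado(
    ranges: Sequence[ParameterRange],
    metric: str,
    base_cm: CMBatchSpec | None = None,
    base_econ: EconCosts | None = None,
    base_meat_price: float = 25.0,
    revenue_target: float = 1e7,
    soy: FeedstockChain | None = None,
    corn: FeedstockChain | None = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity: metric at each range's endpoints with all
    other parameters at baseline, ranked by absolute swing."""
    if metric not in METRICS:
        raise ValueError(f"unregistered metric {metric!r}; choose from {sorted(METRICS)}")
    base_cm = base_cm or mattick_batch()
    base_econ = base_econ or default_costs()
    soy = soy or soy_chain()
    corn = corn or corn_chain()

    import warnings as _warnings

    def evaluate(overrides: dict) -> float:
        cm_over = {k: v for k, v in overrides.items() if k in _CM_FIELDS}
        econ_over = {k: v for k, v in overrides.items() if k in _ECON_FIELDS}
        price = overrides.get("meat_price", base_meat_price)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            cm = CMBatchSpec.model_validate({**base_cm.model_dump(), **cm_over})
            econ = EconCosts.model_validate({**base_econ.model_dump(), **econ_over})
        try:
            return run_scenario(cm, econ, soy, corn, price, revenue_target)[metric]
        except (ValueError, ZeroDivisionError):
            # endpoint infeasible under the joint model (e.g. respiration
            # demand exceeding the caloric-balance feed): recorded as NaN
            return float("nan")

    rows = []
    for r in ranges:
        lo = evaluate({r.name: r.low})
        hi = evaluate({r.name: r.high})
        rows.append({
            "parameter": r.name,
            "low": r.low,
            "high": r.high,
            "metric_at_low": lo,
            "metric_at_high": hi,
            "swing": hi - lo,
        })
    df = pd.DataFrame(rows)
    return df.reindex(df["swing"].abs().sort_values(ascending=False).index).reset_index(drop=True)
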