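"""Nitrogen-use-efficiency partitions and recovery-parity targets.

Fed nitrogen splits three ways: retained in the meat (numerically equal to
the protein conversion efficiency, since protein and nitrogen are
proportional on both sides), recoverable (manure nitrogen that survives
volatilization during application and leaching in the field, available to
fertilise crops), and lost. The three fractions sum to one by construction.
Cultured meat without recovery retains only its PCE; the rest of the fed
nitrogen leaves in the spent media.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from . import units
from .params import AnimalSpec
from .growth import feed_and_protein

__all__ = [
    "NuePartition",
    "animal_partition",
    "partition_from_animal",
    "cm_partition",
    "recovery_to_match",
    "person_equivalents",
]

#: Fraction of applied manure N surviving ammonia volatilization when the
#: manure is directly injected.
VOLATILIZATION_RETENTION = 0.98
#: Fraction of post-volatilization N lost to leaching in the field.
LEACHING_LOSS = 0.20


@dataclass(frozen=True)
class NuePartition:
    """Retained / recoverable / lost split of fed nitrogen."""

    label: str
    retained_fraction: float
    recoverable_fraction: float
    lost_fraction: float

    def __post_init__(self) -> None:
        for f in (self.retained_fraction, self.recoverable_fraction, self.lost_fraction):
            if f < -1e-12:
                raise ValueError("partition fractions must be >= 0")
        if abs(self.retained_fraction + self.recoverable_fraction + self.lost_fraction - 1.0) > 1e-9:
            raise ValueError("partition fractions must sum to 1")

    def as_dict(self) -> dict:
        return asdict(self)


def animal_partition(
    pce: float,
    available_n_fraction: float,
    volatilization_retention: float = VOLATILIZATION_RETENTION,
    leaching_loss: float = LEACHING_LOSS,
    label: str = "",
) -> NuePartition:
    """Partition for a manure system from the available-N fraction of fed N.

    recoverable = available x volatilization retention x (1 - leaching);
    lost is the remainder after retention (PCE) and recovery.
    """
    for name, v in [("pce", pce), ("available_n_fraction", available_n_fraction),
                    ("volatilization_retention", volatilization_retention),
                    ("leaching_loss", leaching_loss)]:
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    recoverable = available_n_fraction * volatilization_retention * (1.0 - leaching_loss)
    lost = 1.0 - pce - recoverable
    if lost < -1e-12:
        raise ValueError("pce + recoverable exceed 1; partition invalid")
    return NuePartition(
        label=label,
        retained_fraction=pce,
        recoverable_fraction=recoverable,
        lost_fraction=max(lost, 0.0),
    )


def partition_from_animal(spec: AnimalSpec) -> NuePartition:
    """Partition for a preset species using its stored recoverable fraction.

    Preset recoverable fractions are net of volatilization and leaching (the
    manure available-N source data are not part of the presets), so no loss
    chain is applied here; use :func:`animal_partition` with user-supplied
    manure data for the full chain.
    """
    pce = feed_and_protein(spec).protein_conversion_efficiency
    recoverable = spec.manure_recoverable_n_fraction
    lost = 1.0 - pce - recoverable
    if lost < -1e-12:
        raise ValueError("pce + recoverable exceed 1; partition invalid")
    return NuePartition(
        label=spec.species,
        retained_fraction=pce,
        recoverable_fraction=recoverable,
        lost_fraction=max(lost, 0.0),
    )


def cm_partition(
    pce: float, recovery_fraction_of_fed: float = 0.0, label: str = "cm"
) -> NuePartition:
    """Partition for cultured meat with an optional spent-media N recovery."""
    if not 0 <= pce <= 1 or not 0 <= recovery_fraction_of_fed <= 1:
        raise ValueError("fractions must be in [0, 1]")
    lost = 1.0 - pce - recovery_fraction_of_fed
    if lost < -1e-12:
        raise ValueError("pce + recovery exceed 1; partition invalid")
    return NuePartition(
        label=label,
        retained_fraction=pce,
        recoverable_fraction=recovery_fraction_of_fed,
        lost_fraction=max(lost, 0.0),
    )


def recovery_to_match(
    cm_lost_no_recovery: float, target_lost: float
) -> tuple[float, float]:
    """Recovery rate needed for CM to match a target lost fraction.

    Returns (fraction of fed N, fraction of the waste stream).
    """
    if not 0 <= target_lost <= cm_lost_no_recovery <= 1:
        raise ValueError("need 0 <= target_lost <= cm_lost_no_recovery <= 1")
    if cm_lost_no_recovery == 0:
        return 0.0, 0.0
    fed_basis = cm_lost_no_recovery - target_lost
    return fed_basis, fed_basis / cm_lost_no_recovery


def person_equivalents(
    annual_n_kg: float, excretion_g_per_day: float = units.PERSON_N_G_PER_DAY
) -> float:
    """Number of people excreting the same nitrogen mass per year."""
    if excretion_g_per_day <= 0:
        raise ValueError("excretion rate must be positive")
    return annual_n_kg / (excretion_g_per_day * units.DAYS_PER_YEAR / 1000.0)
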