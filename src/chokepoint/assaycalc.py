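"""Quantification arithmetic for cofactor and quinone assays.

Beer–Lambert concentrations, flavin occupancy per protein monomer, NADH
oxidation rates and turnover, and single-point internal-standard recovery
correction (a known amount of Q4 spiked before lipid extraction calibrates
losses of the Q6 analyte).  Units are enforced at the boundary: molar
concentrations, cm path lengths, per-minute slopes.  All operations are
homogeneous of degree 1 in their amount/absorbance arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = [
    "EPSILON_FAD_450",
    "EPSILON_NADH_340",
    "AssayReading",
    "ExtinctionConstant",
    "cofactor_occupancy",
    "concentration_from_absorbance",
    "internal_standard_correction",
    "nadh_oxidation_rate",
]


@dataclass(frozen=True)
class ExtinctionConstant:
    """Molar extinction coefficient at one wavelength, in M⁻¹·cm⁻¹."""

    wavelength_nm: float
    epsilon: float
    species: str

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("extinction coefficient must be positive")


# Free FAD at 450 nm: 11300 M^-1 cm^-1 (= 11.3 mM^-1 cm^-1, the standard
# literature value); NADH at 340 nm: 6220 M^-1 cm^-1.
EPSILON_FAD_450 = ExtinctionConstant(450.0, 11300.0, "FAD")
EPSILON_NADH_340 = ExtinctionConstant(340.0, 6220.0, "NADH")


@dataclass(frozen=True)
class AssayReading:
    absorbance: float
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise ValueError("absorbance must be >= 0")
        if self.path_length_cm <= 0:
            raise ValueError("path length must be positive")


def concentration_from_absorbance(reading: AssayReading, k: ExtinctionConstant) -> float:
    """Molar concentration from Beer–Lambert: c = A / (ε·l)."""
    return reading.absorbance / (k.epsilon * reading.path_length_cm)


def cofactor_occupancy(cofactor_conc: float, protein_conc: float) -> float:
    """Cofactor-to-protein molar ratio; > 1 is allowed but flagged as
    over-stoichiometric (usually a concentration-determination problem)."""
    if protein_conc <= 0:
        raise ValueError("protein concentration must be positive")
    if cofactor_conc < 0:
        raise ValueError("cofactor concentration must be >= 0")
    occ = cofactor_conc / protein_conc
    if occ > 1.0:
        logger.warning("occupancy %.3f > 1: over-stoichiometric cofactor reading", occ)
    return occ


def nadh_oxidation_rate(
    slope_per_min: float,
    k: ExtinctionConstant = EPSILON_NADH_340,
    path_length_cm: float = 1.0,
    enzyme_conc: float | None = None,
) -> tuple[float, float | None]:
    """Consumption rate from an A340 time course.

    *slope_per_min* is dA/dt in min⁻¹; consumption gives a negative slope and
    the magnitude is used.  Returns ``(rate in M·min⁻¹, turnover in min⁻¹)``,
    turnover ``None`` when no enzyme concentration is given.
    """
    if slope_per_min > 0:
        logger.warning(
            "positive A340 slope (%.3g/min): expected a decrease for NADH "
            "consumption; using its magnitude", slope_per_min,
        )
    rate = abs(slope_per_min) / (k.epsilon * path_length_cm)
    if enzyme_conc is None:
        return rate, None
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")
    return rate, rate / enzyme_conc


def internal_standard_correction(
    measured_analyte: float,
    standard_added: float,
    standard_recovered: float,
) -> tuple[float, float]:
    """Correct an analyte amount for extraction losses.

    recovery = recovered/added; corrected = measured/recovery.  Exactly
    inverts a proportional loss: if a fraction f of both analyte and standard
    survives extraction, the corrected amount equals the true amount for any
    f in (0, 1].
    """
    if standard_added <= 0:
        raise ValueError("standard_added must be positive")
    if standard_recovered < 0:
        raise ValueError("standard_recovered must be >= 0")
    recovery = standard_recovered / standard_added
    if recovery == 0:
        raise ValueError("standard recovery is zero: correction undefined")
    return measured_analyte / recovery, recovery
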