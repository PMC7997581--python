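"""Shielding-to-shift pipeline: Boltzmann averaging and calibration.

Quantum-chemistry codes emit one isotropic shielding tensor trace per
atom per conformer, plus conformer energies.  Turning these into a
single chemical-shift set per isomer takes three steps:

1. discard conformers above an energy window (default 3.0 kcal/mol,
   i.e. 12.5 kJ/mol, above the global minimum),
2. Boltzmann-average the shieldings with weights
   ``w_i = exp(-dE_i / RT) / sum_j exp(-dE_j / RT)``,
3. calibrate shieldings to shifts against reference compounds computed
   at the same level of theory — the multistandard scheme uses TMS for
   sp3 carbons and benzene for non-carbonyl sp2 carbons, because a
   chemically similar reference cancels more of the method error than a
   single universal standard.

Calibration is affine (``delta = sigma_ref - sigma + delta_ref``), so
averaging shieldings then calibrating equals calibrating per conformer
then averaging; the pipeline does the former.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import constants

from .containers import (
    AtomRecord,
    Conformer,
    ConformerEnsemble,
    Hybridization,
    Origin,
    ShiftSet,
)

DEFAULT_TEMPERATURE_K = 298.15
DEFAULT_ENERGY_WINDOW_KCAL = 3.0  # = 12.5 kJ/mol


class EnergyUnit(enum.Enum):
    KCAL_MOL = "kcal_mol"
    KJ_MOL = "kj_mol"
    HARTREE = "hartree"


# Gas constant expressed in each supported energy unit per kelvin.
_R_BY_UNIT = {
    EnergyUnit.KCAL_MOL: constants.R / constants.calorie / 1e3,
    EnergyUnit.KJ_MOL: constants.R / 1e3,
    EnergyUnit.HARTREE: constants.k / constants.physical_constants["Hartree energy"][0],
}


@dataclass(frozen=True)
class CalibrationStandards:
    """Reference shieldings/shifts for the multistandard calibration.

    ``tms_sigma`` and ``benzene_sigma`` are the isotropic shieldings of
    the reference carbons computed at the *same* level of theory as the
    compound; ``benzene_delta_exp`` is benzene's experimental 13C shift
    (128.5 ppm on the TMS scale) and ``tms_delta_exp`` is 0 by
    definition of the delta scale.
    """

    tms_sigma: float
    benzene_sigma: float
    benzene_delta_exp: float = 128.5
    tms_delta_exp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tms_sigma", "benzene_sigma", "benzene_delta_exp"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.tms_delta_exp != 0.0:
            raise ValueError("tms_delta_exp is 0 by definition of the TMS scale")


@dataclass
class BoltzmannWeights:
    """Normalized conformer populations."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights sum to {total}, expected 1")
        if any(w < 0 or w > 1 for w in self.weights.values()):
            raise ValueError("weights must lie in [0, 1]")


def energy_window_filter(
    ensemble: ConformerEnsemble, window: float = DEFAULT_ENERGY_WINDOW_KCAL
) -> ConformerEnsemble:
    """Drop conformers more than ``window`` above the minimum energy.

    ``window`` is in the same unit as the ensemble's energies.  The
    minimum-energy conformer always survives (its relative energy is 0).
    """
    if window <= 0:
        raise ValueError("energy window must be positive")
    kept = [c for c in ensemble.conformers if c.rel_energy <= window]
    return ConformerEnsemble(
        ensemble.isomer_id,
        [Conformer(c.conformer_id, c.rel_energy, dict(c.shieldings)) for c in kept],
    )


def boltzmann_weights(
    ensemble: ConformerEnsemble,
    temperature: float = DEFAULT_TEMPERATURE_K,
    energy_unit: EnergyUnit | str = EnergyUnit.KCAL_MOL,
) -> BoltzmannWeights:
    """Boltzmann populations from relative energies.

    ``w_i = exp(-dE_i/RT) / sum_j exp(-dE_j/RT)`` with R in the stated
    energy unit.  Weights depend only on energy differences, so any
    constant offset in the energies cancels.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if isinstance(energy_unit, str):
        energy_unit = EnergyUnit(energy_unit)
    rt = _R_BY_UNIT[energy_unit] * temperature
    energies = np.array([c.rel_energy for c in ensemble.conformers])
    # shift by the minimum for numerical safety (no-op after re-zeroing)
    factors = np.exp(-(energies - energies.min()) / rt)
    probs = factors / factors.sum()
    return BoltzmannWeights(
        {c.conformer_id: float(p) for c, p in zip(ensemble.conformers, probs)}
    )


def average_shieldings(
    ensemble: ConformerEnsemble, weights: BoltzmannWeights
) -> dict[str, float]:
    """Population-weighted mean isotropic shielding per atom."""
    if set(weights.weights) != {c.conformer_id for c in ensemble.conformers}:
        raise ValueError("weights do not cover exactly the ensemble's conformers")
    out: dict[str, float] = {}
    for label in ensemble.labels:
        out[label] = sum(
            weights.weights[c.conformer_id] * c.shieldings[label]
            for c in ensemble.conformers
        )
    return out


def calibrate_multistandard(
    shieldings: dict[str, float],
    atom_index: list[AtomRecord],
    standards: CalibrationStandards,
    carbonyl_policy: str = "tms",
    *,
    set_id: str = "calc",
) -> ShiftSet:
    """Convert shieldings to shifts with per-hybridization references.

    sp3 carbons: ``delta = tms_sigma - sigma`` (TMS reference);
    sp2 non-carbonyl carbons: ``delta = benzene_sigma - sigma + 128.5``;
    carbonyl carbons follow ``carbonyl_policy`` ("tms" or "benzene").
    """
    if carbonyl_policy not in ("tms", "benzene"):
        raise ValueError("carbonyl_policy must be 'tms' or 'benzene'")
    hyb = {rec.label: rec.hybridization for rec in atom_index}
    shifts: dict[str, float] = {}
    for label, sigma in shieldings.items():
        if label not in hyb:
            raise ValueError(f"atom {label!r} absent from the atom index")
        kind = hyb[label]
        if kind is Hybridization.CARBONYL:
            use_benzene = carbonyl_policy == "benzene"
        else:
            use_benzene = kind is Hybridization.SP2
        if use_benzene:
            shifts[label] = standards.benzene_sigma - sigma + standards.benzene_delta_exp
        else:
            shifts[label] = standards.tms_sigma - sigma + standards.tms_delta_exp
    return ShiftSet(set_id, Origin.CALCULATED, shifts)


def ensemble_to_shift_set(
    ensemble: ConformerEnsemble,
    atom_index: list[AtomRecord],
    standards: CalibrationStandards,
    *,
    temperature: float = DEFAULT_TEMPERATURE_K,
    energy_unit: EnergyUnit | str = EnergyUnit.KCAL_MOL,
    energy_window: float | None = DEFAULT_ENERGY_WINDOW_KCAL,
    carbonyl_policy: str = "tms",
    set_id: str | None = None,
) -> ShiftSet:
    """Full pipeline: window filter, Boltzmann average, calibrate."""
    if energy_window is not None:
        ensemble = energy_window_filter(ensemble, energy_window)
    weights = boltzmann_weights(ensemble, temperature, energy_unit)
    sigma = average_shieldings(ensemble, weights)
    return calibrate_multistandard(
        sigma,
        atom_index,
        standards,
        carbonyl_policy,
        set_id=set_id or f"calc_{ensemble.isomer_id}",
    )
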