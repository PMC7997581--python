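"""Core data containers shared across the package.

Everything downstream (Boltzmann averaging, calibration, per-set error
statistics, alignment ranking) operates on these containers:

* :class:`AtomRecord` — one carbon of the shared atom index, with a
  hybridization tag that decides which calibration standard applies.
* :class:`ShiftSet` — one isomer's labelled chemical shifts (ppm).
* :class:`ConformerEnsemble` — relative conformer energies plus per-atom
  isotropic shieldings for one isomer, the input of the averaging pipeline.
* :class:`StudyBundle` — the full study: an atom index, n calculated and
  n experimental shift sets in a fixed order.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field


class Hybridization(enum.Enum):
    """Carbon hybridization class used to pick the calibration standard."""

    SP3 = "sp3"
    SP2 = "sp2"
    CARBONYL = "carbonyl"

    @classmethod
    def parse(cls, token: str) -> "Hybridization":
        t = token.strip().lower()
        for member in cls:
            if member.value == t:
                return member
        raise ValueError(
            f"unknown hybridization token {token!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


class Origin(enum.Enum):
    """Provenance of a shift set."""

    CALCULATED = "calculated"
    EXPERIMENTAL = "experimental"


# Shifts outside this window are legal but almost certainly a data error
# for 13C, so we warn rather than fail.
PLAUSIBLE_SHIFT_RANGE = (-20.0, 250.0)


@dataclass(frozen=True)
class AtomRecord:
    """One carbon of the shared atom index."""

    label: str
    hybridization: Hybridization

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("atom label must be non-empty")


@dataclass
class ShiftSet:
    """Labelled 13C chemical shifts (ppm) for one isomer.

    Parameters
    ----------
    set_id : str
        Identifier, e.g. ``"calc_1a"`` or ``"exp_1b"``.
    origin : Origin
        Whether the values are calculated or experimental.
    shifts : dict[str, float]
        Mapping atom label -> shift in ppm.  Atoms absent from the
        mapping are treated as missing, never as zero.
    """

    set_id: str
    origin: Origin
    shifts: dict[str, float]

    def __post_init__(self) -> None:
        lo, hi = PLAUSIBLE_SHIFT_RANGE
        for label, value in self.shifts.items():
            if not math.isfinite(value):
                raise ValueError(
                    f"non-finite shift for atom {label!r} in set {self.set_id!r}"
                )
            if not lo <= value <= hi:
                warnings.warn(
                    f"shift {value:.3f} ppm for atom {label!r} in set "
                    f"{self.set_id!r} is outside the plausible 13C range "
                    f"[{lo}, {hi}] ppm",
                    stacklevel=2,
                )

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self.shifts)

    def restricted_to(self, labels) -> "ShiftSet":
        """Return a copy containing only the given labels (order-preserving)."""
        keep = set(labels)
        return ShiftSet(
            self.set_id,
            self.origin,
            {k: v for k, v in self.shifts.items() if k in keep},
        )


@dataclass
class Conformer:
    """One conformer: relative energy plus per-atom isotropic shieldings."""

    conformer_id: str
    rel_energy: float
    shieldings: dict[str, float]

    def __post_init__(self) -> None:
        if not math.isfinite(self.rel_energy):
            raise ValueError(
                f"non-finite energy for conformer {self.conformer_id!r}"
            )
        for label, sigma in self.shieldings.items():
            if not math.isfinite(sigma):
                raise ValueError(
                    f"non-finite shielding for atom {label!r} in conformer "
                    f"{self.conformer_id!r}"
                )


@dataclass
class ConformerEnsemble:
    """Conformers of one isomer, energies re-zeroed to the minimum.

    Energies are stored relative to the most stable conformer (min == 0);
    the constructor enforces this by re-zeroing, so Boltzmann weights are
    invariant to any constant offset the user's quantum-chemistry export
    carried.
    """

    isomer_id: str
    conformers: list[Conformer] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError(f"ensemble {self.isomer_id!r} has no conformers")
        ids = [c.conformer_id for c in self.conformers]
        if len(set(ids)) != len(ids):
            raise ValueError(
                f"duplicate conformer ids in ensemble {self.isomer_id!r}"
            )
        reference = set(self.conformers[0].shieldings)
        for conf in self.conformers[1:]:
            if set(conf.shieldings) != reference:
                raise ValueError(
                    f"conformer {conf.conformer_id!r} covers a different atom "
                    f"index than {self.conformers[0].conformer_id!r}"
                )
        e_min = min(c.rel_energy for c in self.conformers)
        if e_min != 0.0:
            for conf in self.conformers:
                conf.rel_energy -= e_min

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self.conformers[0].shieldings)

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass
class StudyBundle:
    """n calculated and n experimental shift sets over a shared atom index.

    The order of ``calc_sets`` is the fixed reference sequence for
    alignment ranking; the order of ``exp_sets`` defines the identity
    permutation.  All comparisons run on :attr:`common_labels`, the label
    intersection across every set — an atom missing from any set is
    dropped everywhere (with a warning at construction) so each pairwise
    difference set contributes the same atom count.
    """

    atom_index: list[AtomRecord]
    calc_sets: list[ShiftSet]
    exp_sets: list[ShiftSet]

    def __post_init__(self) -> None:
        if len(self.calc_sets) != len(self.exp_sets):
            raise ValueError(
                f"{len(self.calc_sets)} calculated vs {len(self.exp_sets)} "
                "experimental sets; counts must match"
            )
        if len(self.calc_sets) < 2:
            raise ValueError("a study bundle needs at least 2 isomers")
        labels = [rec.label for rec in self.atom_index]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in atom index")
        common = set(labels)
        for s in self.calc_sets + self.exp_sets:
            common &= s.labels
        if not common:
            raise ValueError("shift sets share no common atom labels")
        dropped = set(labels) - common
        if dropped:
            warnings.warn(
                f"atoms {sorted(dropped)} are missing from at least one set "
                "and are excluded from all comparisons",
                stacklevel=2,
            )
        # preserve atom-index order for the common labels
        self._common_labels = tuple(l for l in labels if l in common)

    @property
    def n(self) -> int:
        """Number of isomers (= number of sets per origin)."""
        return len(self.calc_sets)

    @property
    def common_labels(self) -> tuple[str, ...]:
        """Atom labels present in every set, in atom-index order."""
        return self._common_labels

    @property
    def hybridizations(self) -> dict[str, Hybridization]:
        return {rec.label: rec.hybridization for rec in self.atom_index}
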