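"""Seeded synthetic study bundles with a known ground-truth assignment.

Real inputs for this problem are tables of per-isomer 13C shifts from
reference syntheses plus DFT shielding outputs; neither is required for
testing the comparison machinery, because the machinery only sees
labelled numbers.  The generator emulates the structure of such data:

* a base "molecule" of 18 carbons with sp3 shifts in 10–80 ppm and sp2
  shifts in 100–170 ppm,
* per-isomer perturbations (sd ``contrast_sd``, default 2 ppm) standing
  in for the configuration-dependent shift differences between
  diastereomers — pairwise set RMSDs of a few ppm at this contrast
  match what closely related stereoisomer tetrads show,
* experimental sets that are the true shifts reordered by a known
  permutation plus measurement noise (sd ``noise_sd``, default 0.3 ppm),
* an optional constant offset on every calculated set, mimicking a
  systematic calibration error.

Perturbations are independent across atoms and isomers; real
stereochemical shift correlations are deliberately not modelled — the
fixtures exercise the formulas, not shift-prediction physics.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .containers import (
    AtomRecord,
    Conformer,
    ConformerEnsemble,
    Hybridization,
    Origin,
    ShiftSet,
    StudyBundle,
)

SP3_RANGE = (10.0, 80.0)
SP2_RANGE = (100.0, 170.0)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study bundle."""

    n_isomers: int = 4
    n_atoms: int = 18
    sp2_fraction: float = 0.3
    contrast_sd: float = 2.0
    noise_sd: float = 0.3
    systematic_offset: float = 0.0
    true_permutation: tuple[int, ...] | str = "random"
    seed: int = 0
    base_range_sp3: tuple[float, float] = SP3_RANGE
    base_range_sp2: tuple[float, float] = SP2_RANGE

    def __post_init__(self) -> None:
        if self.n_isomers < 2:
            raise ValueError("need at least 2 isomers")
        if self.n_atoms < 2:
            raise ValueError("need at least 2 atoms")
        if not 0.0 <= self.sp2_fraction <= 1.0:
            raise ValueError("sp2_fraction must be in [0, 1]")
        if self.contrast_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not isinstance(self.true_permutation, str):
            perm = tuple(self.true_permutation)
            if sorted(perm) != list(range(self.n_isomers)):
                raise ValueError(
                    f"true_permutation {perm} is not a permutation of "
                    f"0..{self.n_isomers - 1}"
                )
            self.true_permutation = perm


def _isomer_suffix(i: int) -> str:
    # a, b, ..., z, aa, ab, ... — mirrors the 1a–1d style naming
    letters = string.ascii_lowercase
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = letters[r] + out
    return out


def generate_bundle(spec: FixtureSpec) -> tuple[StudyBundle, tuple[int, ...]]:
    """Generate a seeded bundle; returns it with the true permutation.

    ``true_permutation[k]`` is the index of the experimental set that
    genuinely corresponds to the k-th calculated set, i.e. the alignment
    scheme a perfect ranking should place first.  Deterministic for a
    given spec (NumPy PCG64 generator seeded with ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_isomers, spec.n_atoms

    n_sp2 = round(spec.sp2_fraction * m)
    atom_index = []
    base = np.empty(m)
    for a in range(m):
        if a < n_sp2:
            hyb, (lo, hi) = Hybridization.SP2, spec.base_range_sp2
        else:
            hyb, (lo, hi) = Hybridization.SP3, spec.base_range_sp3
        atom_index.append(AtomRecord(f"C{a + 1}", hyb))
        base[a] = rng.uniform(lo, hi)

    # true per-isomer shifts: base molecule + configuration contrast
    true_shifts = base + rng.normal(0.0, spec.contrast_sd, size=(n, m))

    if spec.true_permutation == "random":
        perm = tuple(int(x) for x in rng.permutation(n))
    else:
        perm = tuple(spec.true_permutation)

    calc_vals = true_shifts + spec.systematic_offset
    exp_vals = np.empty_like(true_shifts)
    # calc set k corresponds to exp set perm[k]
    for k in range(n):
        exp_vals[perm[k]] = true_shifts[k] + rng.normal(
            0.0, spec.noise_sd, size=m
        )

    labels = [rec.label for rec in atom_index]
    calc_sets = [
        ShiftSet(
            f"calc_{_isomer_suffix(k)}",
            Origin.CALCULATED,
            dict(zip(labels, map(float, calc_vals[k]))),
        )
        for k in range(n)
    ]
    exp_sets = [
        ShiftSet(
            f"exp_{_isomer_suffix(j)}",
            Origin.EXPERIMENTAL,
            dict(zip(labels, map(float, exp_vals[j]))),
        )
        for j in range(n)
    ]
    return StudyBundle(atom_index, calc_sets, exp_sets), perm


def generate_ambiguous_bundle(
    seed: int = 0, n_atoms: int = 18, closeness: float = 0.7
) -> tuple[StudyBundle, tuple[int, ...]]:
    """Bundle where per-set MAE is misleading but the alignment is not.

    The first experimental set is displaced toward the *second*
    calculated isomer by a systematic fraction ``closeness`` of the
    inter-isomer difference, so under classic per-set MAE both exp sets
    0 and 1 fit calculated set 1 best.  The identity alignment is still
    the truth, and comparing shift differences (which cancels the shared
    displacement pattern asymmetrically) recovers it.
    """
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(
        n_isomers=4,
        n_atoms=n_atoms,
        contrast_sd=2.0,
        noise_sd=0.0,
        true_permutation=tuple(range(4)),
        seed=int(rng.integers(2**31)),
    )
    bundle, perm = generate_bundle(spec)
    labels = bundle.common_labels
    c0 = bundle.calc_sets[0].shifts
    c1 = bundle.calc_sets[1].shifts
    # pull exp 0 most of the way toward calc 1
    e0 = bundle.exp_sets[0]
    e0.shifts = {
        lab: c0[lab] + closeness * (c1[lab] - c0[lab]) for lab in labels
    }
    return bundle, perm


def generate_conformer_ensemble(
    n_conformers: int,
    n_atoms: int,
    energy_scale: float = 1.0,
    seed: int = 0,
    isomer_id: str = "synthetic",
) -> ConformerEnsemble:
    """Seeded ensemble with exponential energy spread (kcal/mol).

    Shieldings vary smoothly around a per-atom base value; energies are
    exponentially distributed with mean ``energy_scale`` and re-zeroed
    to the minimum.
    """
    if n_conformers < 1 or n_atoms < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    labels = [f"C{a + 1}" for a in range(n_atoms)]
    base = rng.uniform(20.0, 180.0, size=n_atoms)
    energies = rng.exponential(energy_scale, size=n_conformers)
    energies -= energies.min()
    conformers = []
    for c in range(n_conformers):
        sigma = base + rng.normal(0.0, 2.0, size=n_atoms)
        conformers.append(
            Conformer(
                f"conf_{c:03d}",
                float(energies[c]),
                dict(zip(labels, map(float, sigma))),
            )
        )
    return ConformerEnsemble(isomer_id, conformers)
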