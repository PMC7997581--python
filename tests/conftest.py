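import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from shiftalign.containers import (
    AtomRecord,
    Hybridization,
    Origin,
    ShiftSet,
    StudyBundle,
)


def make_random_bundle(rng, n=4, n_atoms=10, spread=2.0, noise=0.3):
    """Random bundle built directly from ShiftSets (bypasses the generator)."""
    labels = [f"C{i + 1}" for i in range(n_atoms)]
    atom_index = [AtomRecord(lab, Hybridization.SP3) for lab in labels]
    base = rng.uniform(10.0, 170.0, size=n_atoms)
    calc = base + rng.normal(0.0, spread, size=(n, n_atoms))
    exp = calc + rng.normal(0.0, noise, size=(n, n_atoms))
    calc_sets = [
        ShiftSet(f"calc_{k}", Origin.CALCULATED, dict(zip(labels, map(float, calc[k]))))
        for k in range(n)
    ]
    exp_sets = [
        ShiftSet(f"exp_{k}", Origin.EXPERIMENTAL, dict(zip(labels, map(float, exp[k]))))
        for k in range(n)
    ]
    return StudyBundle(atom_index, calc_sets, exp_sets)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_bundle(rng):
    return make_random_bundle(rng, n=3, n_atoms=5)


@pytest.fixture
def bundle4(rng):
    return make_random_bundle(rng, n=4, n_atoms=10)
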