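"""Classic one-experimental-set-versus-all-calculated statistics.

These are the per-set diagnostics practitioners compute first: the
signed per-atom error Δδ = δ_calc − δ_exp, its mean absolute value
(MAE), the RMSD between two shift sets as a set-similarity measure, and
a DP4-style normalized t-density probability over candidate
stereoisomers.  On closely related diastereomers these per-set rankings
can be ambiguous — two experimental sets pointing at the same
calculated isomer — which is exactly what the alignment engine in
:mod:`shiftalign.alignment` resolves.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ShiftSet, StudyBundle

TIE_TOL = 1e-9


@dataclass
class DeltaSet:
    """Signed per-atom shift differences for one ordered pair of sets."""

    pair: tuple[str, str]
    deltas: dict[str, float]


@dataclass(frozen=True)
class ProbabilityBackendParams:
    """Location-scale t-distribution parameters for the DP4-style backend.

    The degrees of freedom, location and scale of the error distribution
    must be supplied by the user from a published parametrization; none
    ship with this package.
    """

    degrees_of_freedom: float
    location: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.degrees_of_freedom <= 0:
            raise ValueError("degrees_of_freedom must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def _common_labels(a: ShiftSet, b: ShiftSet) -> list[str]:
    common = [lab for lab in a.shifts if lab in b.shifts]
    if not common:
        raise ValueError(
            f"sets {a.set_id!r} and {b.set_id!r} share no atom labels"
        )
    return common


def delta_shift(calc: ShiftSet, exp: ShiftSet) -> DeltaSet:
    """Signed per-atom error δ_calc − δ_exp over the label intersection."""
    labels = _common_labels(calc, exp)
    return DeltaSet(
        (calc.set_id, exp.set_id),
        {lab: calc.shifts[lab] - exp.shifts[lab] for lab in labels},
    )


def mae(calc: ShiftSet, exp: ShiftSet) -> float:
    """Mean absolute error Σ|Δδ|/n over the label intersection."""
    deltas = delta_shift(calc, exp).deltas
    return float(np.mean(np.abs(list(deltas.values()))))


def rmsd_between_sets(a: ShiftSet, b: ShiftSet) -> float:
    """Root-mean-square deviation sqrt(ΣΔδ²/n) between two shift sets."""
    deltas = delta_shift(a, b).deltas
    return float(np.sqrt(np.mean(np.square(list(deltas.values())))))


def rmsd_summary(sets: list[ShiftSet]) -> dict[str, float]:
    """Mean/min/max pairwise RMSD over all unordered pairs of sets.

    Quantifies how similar a group of shift sets is to itself — low
    values flag a hard assignment problem where the isomers' spectra
    barely differ.
    """
    if len(sets) < 2:
        raise ValueError("rmsd_summary needs at least 2 sets")
    values = [
        rmsd_between_sets(a, b) for a, b in itertools.combinations(sets, 2)
    ]
    return {
        "average": float(np.mean(values)),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


@dataclass
class ClassicRanking:
    """n×n score matrix plus the per-experimental-set best candidates.

    ``matrix`` has experimental set ids as rows and calculated set ids
    as columns.  ``best`` maps each experimental id to *all* calculated
    ids within the tie tolerance of its optimum — ties are reported,
    never silently broken.
    """

    metric: str
    matrix: pd.DataFrame
    best: dict[str, list[str]]

    @property
    def ambiguous(self) -> bool:
        """True if any calculated set is the best fit of ≥2 experimental sets."""
        flat = [c for cands in self.best.values() for c in cands]
        return len(flat) != len(set(flat)) or any(
            len(c) > 1 for c in self.best.values()
        )


def classic_ranking(
    bundle: StudyBundle,
    metric: str = "mae",
    params: ProbabilityBackendParams | None = None,
) -> ClassicRanking:
    """Score every experimental set against every calculated set.

    ``metric`` is ``"mae"``, ``"rmsd"`` (lower is better) or
    ``"probability"`` (DP4-style, higher is better, requires ``params``).
    """
    calc = [s.restricted_to(bundle.common_labels) for s in bundle.calc_sets]
    exp = [s.restricted_to(bundle.common_labels) for s in bundle.exp_sets]
    exp_ids = [s.set_id for s in exp]
    calc_ids = [s.set_id for s in calc]

    if metric in ("mae", "rmsd"):
        score = mae if metric == "mae" else rmsd_between_sets
        rows = [[score(c, e) for c in calc] for e in exp]
        better_is_lower = True
    elif metric == "probability":
        if params is None:
            raise ValueError(
                "metric='probability' needs ProbabilityBackendParams with "
                "published distribution parameters"
            )
        rows = []
        for e in exp:
            probs = dp4_style_probability(
                [delta_shift(c, e) for c in calc], params
            )
            rows.append([probs[c.set_id] for c in calc])
        better_is_lower = False
    else:
        raise ValueError(f"unknown metric {metric!r}")

    matrix = pd.DataFrame(rows, index=exp_ids, columns=calc_ids)
    best: dict[str, list[str]] = {}
    for eid in exp_ids:
        row = matrix.loc[eid]
        opt = row.min() if better_is_lower else row.max()
        best[eid] = [cid for cid in calc_ids if abs(row[cid] - opt) <= TIE_TOL]
    return ClassicRanking(metric, matrix, best)


def dp4_style_probability(
    deltas_by_candidate: list[DeltaSet], params: ProbabilityBackendParams
) -> dict[str, float]:
    """Normalized t-density likelihood per candidate stereoisomer.

    Each candidate's errors are scored under a single location-scale
    Student-t density; the per-candidate products are normalized to sum
    to 1 across candidates.  This is a generic DP4-style backend, not a
    reimplementation of any published parametrization.
    """
    if len(deltas_by_candidate) < 2:
        raise ValueError("need at least 2 candidates to rank")
    ids = [d.pair[0] for d in deltas_by_candidate]
    log_liks = []
    for d in deltas_by_candidate:
        errs = np.array(list(d.deltas.values()))
        log_liks.append(
            sps.t.logpdf(
                errs, df=params.degrees_of_freedom,
                loc=params.location, scale=params.scale,
            ).sum()
        )
    log_liks = np.array(log_liks)
    w = np.exp(log_liks - log_liks.max())
    probs = w / w.sum()
    return {cid: float(p) for cid, p in zip(ids, probs)}


def mean_signed_error(calc: ShiftSet, exp: ShiftSet) -> float:
    """Mean signed Δδ; |value| is a lower bound on the RMSD."""
    deltas = delta_shift(calc, exp).deltas
    return float(np.mean(list(deltas.values())))


def is_tied(a: float, b: float, tol: float = TIE_TOL) -> bool:
    return math.isclose(a, b, rel_tol=0.0, abs_tol=tol)
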