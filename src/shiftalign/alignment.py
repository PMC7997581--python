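"""Exhaustive alignment ranking of calculated vs experimental shift sets.

The assignment question: given n calculated shift sets (stereochemistry
known a priori, fixed order) and n experimental sets (stereochemistry to
be determined), which experimental set belongs to which isomer?  Rather
than scoring each experimental set against each calculated set in
isolation, every one of the n! candidate correspondences is scored as a
whole:

* for every unordered pair of calculated sets, the per-atom shift
  difference Δδ_calc = δ_calcA − δ_calcB is computed; likewise
  Δδ_exp for the experimental pair the alignment puts in
  correspondence;
* the per-atom discrepancy ΔΔδ = |Δδ_calc − Δδ_exp| compares
  differences rather than raw shifts, so any constant (calibration /
  referencing) error common to a group of sets cancels;
* the alignment's score, MAE_ΔΔδ, is the mean of all ΔΔδ values over
  the n(n−1)/2 pairs and all shared atoms; the lowest score across the
  n! alignments proposes the assignment.

Enumeration is exhaustive — n! is desk-scale for realistic n (a ceiling
of 8 sets, 40320 alignments, is enforced and configurable).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .containers import Origin, ShiftSet, StudyBundle
from .stats import mae

DEFAULT_TIE_TOL = 1e-9
DEFAULT_MAX_SETS = 8


@dataclass(frozen=True)
class AlignmentScheme:
    """One candidate correspondence between calculated and experimental sets.

    ``permutation[k]`` is the index of the experimental set aligned to
    the k-th calculated set.  The identity permutation aligns the sets
    in file order.
    """

    permutation: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.permutation) != list(range(len(self.permutation))):
            raise ValueError(
                f"{self.permutation} is not a permutation of 0..n-1"
            )

    @property
    def n(self) -> int:
        return len(self.permutation)

    def compose(self, other: "AlignmentScheme") -> "AlignmentScheme":
        """Return self ∘ other: ``(self∘other)[k] = self[other[k]]``."""
        return AlignmentScheme(
            tuple(self.permutation[j] for j in other.permutation)
        )


@dataclass
class PairDifferenceSet:
    """Per-atom signed shift differences for one ordered pair of sets."""

    pair: tuple[int, int]
    origin: Origin
    deltas: dict[str, float]

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValueError("pair indices must be distinct")


@dataclass
class AlignmentScore:
    scheme: AlignmentScheme
    mae_dddelta: float
    n_terms: int
    avg_mae: float | None = None


@dataclass
class AlignmentRanking:
    """All n! alignments with their scores, sorted ascending.

    ``best`` is the top-ranked scheme; ``ties`` lists every scheme whose
    score is within ``tie_tol`` of the best (including the best itself)
    whenever more than one qualifies.  ``gap_to_second`` is the score
    margin separating the best alignment from the runner-up; it is a
    confidence diagnostic only — no significance threshold is attached
    to it.
    """

    scores: list[AlignmentScore]
    calc_ids: tuple[str, ...]
    exp_ids: tuple[str, ...]
    labels: tuple[str, ...]
    tie_tol: float = DEFAULT_TIE_TOL
    ties: list[AlignmentScheme] = field(init=False)

    def __post_init__(self) -> None:
        values = [s.mae_dddelta for s in self.scores]
        if any(b < a for a, b in zip(values, values[1:])):
            raise ValueError("scores must be sorted ascending")
        top = values[0]
        tied = [s.scheme for s in self.scores if s.mae_dddelta - top <= self.tie_tol]
        self.ties = tied if len(tied) > 1 else []

    @property
    def n(self) -> int:
        return len(self.calc_ids)

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def best(self) -> AlignmentScheme:
        return self.scores[0].scheme

    @property
    def gap_to_second(self) -> float | None:
        if len(self.scores) < 2:
            return None
        return self.scores[1].mae_dddelta - self.scores[0].mae_dddelta

    def exp_ids_for(self, scheme: AlignmentScheme) -> tuple[str, ...]:
        """Experimental set ids in calculated order under ``scheme``."""
        return tuple(self.exp_ids[j] for j in scheme.permutation)

    @property
    def assignment(self) -> dict[str, str]:
        """Best calc_id -> exp_id correspondence."""
        return dict(zip(self.calc_ids, self.exp_ids_for(self.best)))


def count_alignments(n: int) -> int:
    """Number of candidate correspondences for n sets: n!."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.factorial(n)


def count_pairs(n: int) -> int:
    """Number of difference sets per alignment: n(n-1)/2."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return n * (n - 1) // 2


def enumerate_alignments(n: int) -> list[AlignmentScheme]:
    """All n! schemes in lexicographic order; the identity comes first."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return [
        AlignmentScheme(perm) for perm in itertools.permutations(range(n))
    ]


def _shift_matrix(sets: list[ShiftSet], labels: tuple[str, ...]) -> np.ndarray:
    """(n_sets, n_labels) array of shifts; raises if any label is missing."""
    try:
        return np.array([[s.shifts[lab] for lab in labels] for s in sets])
    except KeyError as exc:
        raise ValueError(f"atom label {exc} missing from a shift set") from None


def _common_labels(sets: list[ShiftSet]) -> tuple[str, ...]:
    common = set(sets[0].shifts)
    for s in sets[1:]:
        common &= s.labels
    if not common:
        raise ValueError("sets share no common atom labels")
    # deterministic order: first set's insertion order
    return tuple(lab for lab in sets[0].shifts if lab in common)


def pair_difference_sets(sets: list[ShiftSet]) -> list[PairDifferenceSet]:
    """One difference set per unordered pair (i<j): δ_i − δ_j per atom.

    Orientation within a pair is irrelevant downstream because the
    ΔΔδ comparison takes absolute values; unordered pairs are used once
    each.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    labels = _common_labels(sets)
    origin = sets[0].origin
    out = []
    for i, j in itertools.combinations(range(len(sets)), 2):
        deltas = {
            lab: sets[i].shifts[lab] - sets[j].shifts[lab] for lab in labels
        }
        out.append(PairDifferenceSet((i, j), origin, deltas))
    return out


def dd_delta(
    calc_pair: PairDifferenceSet, exp_pair: PairDifferenceSet
) -> dict[str, float]:
    """Per-atom ΔΔδ = |Δδ_calc − Δδ_exp|."""
    if set(calc_pair.deltas) != set(exp_pair.deltas):
        raise ValueError("difference sets cover different atom labels")
    return {
        lab: abs(calc_pair.deltas[lab] - exp_pair.deltas[lab])
        for lab in calc_pair.deltas
    }


def mae_dddelta(
    calc_sets: list[ShiftSet],
    exp_sets: list[ShiftSet],
    scheme: AlignmentScheme,
    *,
    with_avg_mae: bool = False,
) -> AlignmentScore:
    """Score one alignment: mean ΔΔδ over all set pairs and shared atoms.

    The experimental sets are reordered by ``scheme``; for every
    unordered pair (i<j) the calculated and experimental difference sets
    are compared atom by atom, and all |Δδ_calc − Δδ_exp| values are
    averaged over the n(n−1)/2 × n_atoms terms.
    """
    n = len(calc_sets)
    if len(exp_sets) != n:
        raise ValueError("calculated and experimental set counts differ")
    if scheme.n != n:
        raise ValueError("scheme size does not match the set count")
    labels = _common_labels(list(calc_sets) + list(exp_sets))
    calc = _shift_matrix(calc_sets, labels)
    exp = _shift_matrix(exp_sets, labels)[list(scheme.permutation)]
    iu, ju = np.triu_indices(n, k=1)
    dd = np.abs((calc[iu] - calc[ju]) - (exp[iu] - exp[ju]))
    score = AlignmentScore(
        scheme=scheme,
        mae_dddelta=float(dd.mean()),
        n_terms=int(dd.size),
    )
    if with_avg_mae:
        score.avg_mae = avg_mae_per_alignment(calc_sets, exp_sets, scheme)
    return score


def avg_mae_per_alignment(
    calc_sets: list[ShiftSet],
    exp_sets: list[ShiftSet],
    scheme: AlignmentScheme,
) -> float:
    """Mean of the n per-set MAEs under one alignment.

    An alternative whole-alignment metric: average the classic
    calc-vs-exp MAE over the n matched set pairs.  Unlike MAE_ΔΔδ it
    does not cancel systematic calibration offsets.
    """
    if len(exp_sets) != len(calc_sets) or scheme.n != len(calc_sets):
        raise ValueError("set counts and scheme size must match")
    return float(
        np.mean(
            [
                mae(c, exp_sets[j])
                for c, j in zip(calc_sets, scheme.permutation)
            ]
        )
    )


def rank_alignments(
    bundle: StudyBundle,
    metrics: tuple[str, ...] = ("mae_dddelta",),
    *,
    tie_tol: float = DEFAULT_TIE_TOL,
    max_sets: int = DEFAULT_MAX_SETS,
) -> AlignmentRanking:
    """Score and sort every alignment of a study bundle.

    ``metrics`` always includes the primary ``"mae_dddelta"`` score (the
    sort key); add ``"avg_mae"`` to also record the per-alignment mean
    of classic MAEs.  Raises when n exceeds ``max_sets`` — pass a larger
    ceiling explicitly for bigger (slower) problems.
    """
    unknown = set(metrics) - {"mae_dddelta", "avg_mae"}
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    n = bundle.n
    if n > max_sets:
        raise ValueError(
            f"{n} sets means {math.factorial(n)} alignments, above the "
            f"ceiling of {max_sets}; raise max_sets to proceed"
        )
    labels = bundle.common_labels
    calc_sets = [s.restricted_to(labels) for s in bundle.calc_sets]
    exp_sets = [s.restricted_to(labels) for s in bundle.exp_sets]
    calc = _shift_matrix(calc_sets, labels)
    exp = _shift_matrix(exp_sets, labels)
    iu, ju = np.triu_indices(n, k=1)
    d_calc = calc[iu] - calc[ju]  # (n_pairs, n_labels)

    want_avg = "avg_mae" in metrics
    schemes = enumerate_alignments(n)
    scores = []
    for scheme in schemes:
        e = exp[list(scheme.permutation)]
        dd = np.abs(d_calc - (e[iu] - e[ju]))
        score = AlignmentScore(scheme, float(dd.mean()), int(dd.size))
        if want_avg:
            perm = list(scheme.permutation)
            score.avg_mae = float(np.mean(np.abs(calc - exp[perm])))
        scores.append(score)
    # stable sort keeps lexicographic (identity-first) order among ties
    scores.sort(key=lambda s: s.mae_dddelta)
    return AlignmentRanking(
        scores=scores,
        calc_ids=tuple(s.set_id for s in bundle.calc_sets),
        exp_ids=tuple(s.set_id for s in bundle.exp_sets),
        labels=labels,
        tie_tol=tie_tol,
    )
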