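"""Model/results facade over the alignment engine.

:class:`StereoAssignment` is constructed from data (a
:class:`~shiftalign.containers.StudyBundle`, a pair of data frames, or a
pair of CSV files); :meth:`StereoAssignment.fit` exhaustively scores
every alignment and returns a :class:`StereoAssignmentResults` carrying
the ranking, the proposed correspondence, tie/gap diagnostics and the
classic per-set statistics, with a ``summary()`` table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment, stats
from .containers import AtomRecord, Hybridization, Origin, ShiftSet, StudyBundle
from .io import read_bundle, write_report


class StereoAssignment:
    """Assign n experimental shift sets to n calculated stereoisomer sets.

    Parameters
    ----------
    bundle : StudyBundle
        The calculated and experimental shift sets.  The calculated
        order is the fixed reference sequence; the experimental order
        defines the identity permutation.
    tie_tol : float
        Score difference below which two alignments count as tied.
    max_sets : int
        Ceiling on n (the engine enumerates all n! alignments).

    Examples
    --------
    >>> from shiftalign.synthetic import FixtureSpec, generate_bundle
    >>> bundle, truth = generate_bundle(FixtureSpec(seed=7))
    >>> res = StereoAssignment(bundle).fit()
    >>> res.best_permutation == truth
    True
    """

    def __init__(
        self,
        bundle: StudyBundle,
        *,
        tie_tol: float = alignment.DEFAULT_TIE_TOL,
        max_sets: int = alignment.DEFAULT_MAX_SETS,
    ) -> None:
        self.bundle = bundle
        self.tie_tol = tie_tol
        self.max_sets = max_sets

    @classmethod
    def from_files(cls, calc_path, exp_path, **kwargs) -> "StereoAssignment":
        """Build from a calculated and an experimental shift table."""
        return cls(read_bundle(calc_path, exp_path), **kwargs)

    @classmethod
    def from_dataframes(
        cls, calc: pd.DataFrame, exp: pd.DataFrame, **kwargs
    ) -> "StereoAssignment":
        """Build from data frames shaped like the shift tables.

        Both frames need ``label`` and ``hybridization`` columns plus
        one column per shift set; NaN cells mean missing.
        """
        atom_index = [
            AtomRecord(str(row.label), Hybridization.parse(str(row.hybridization)))
            for row in calc.itertuples(index=False)
        ]

        def to_sets(df: pd.DataFrame, origin: Origin) -> list[ShiftSet]:
            value_cols = [
                c for c in df.columns if c not in ("label", "hybridization")
            ]
            sets = []
            for col in value_cols:
                shifts = {
                    str(lab): float(v)
                    for lab, v in zip(df["label"], df[col])
                    if pd.notna(v)
                }
                sets.append(ShiftSet(str(col), origin, shifts))
            return sets

        return cls(
            StudyBundle(
                atom_index,
                to_sets(calc, Origin.CALCULATED),
                to_sets(exp, Origin.EXPERIMENTAL),
            ),
            **kwargs,
        )

    def fit(
        self, metrics: tuple[str, ...] = ("mae_dddelta", "avg_mae")
    ) -> "StereoAssignmentResults":
        """Enumerate and rank all alignments; compute classic diagnostics."""
        ranking = alignment.rank_alignments(
            self.bundle,
            metrics=metrics,
            tie_tol=self.tie_tol,
            max_sets=self.max_sets,
        )
        classic = stats.classic_ranking(self.bundle, metric="mae")
        return StereoAssignmentResults(self, ranking, classic)


class StereoAssignmentResults:
    """Ranking, assignment and diagnostics from a fitted model."""

    def __init__(
        self,
        model: StereoAssignment,
        ranking: alignment.AlignmentRanking,
        classic: stats.ClassicRanking,
    ) -> None:
        self.model = model
        self.ranking = ranking
        self.classic = classic

    # -- primary outcome ------------------------------------------------
    @property
    def best_permutation(self) -> tuple[int, ...]:
        return self.ranking.best.permutation

    @property
    def assignment(self) -> dict[str, str]:
        """Proposed calc_id -> exp_id correspondence."""
        return self.ranking.assignment

    @property
    def score(self) -> float:
        """MAE_ΔΔδ of the best alignment (ppm)."""
        return self.ranking.scores[0].mae_dddelta

    @property
    def gap_to_second(self) -> float | None:
        return self.ranking.gap_to_second

    @property
    def has_ties(self) -> bool:
        return bool(self.ranking.ties)

    # -- tabular views ---------------------------------------------------
    def ranking_frame(self) -> pd.DataFrame:
        """Full ranking as a data frame, one row per alignment."""
        rows = []
        for rank, s in enumerate(self.ranking.scores, start=1):
            rows.append(
                {
                    "rank": rank,
                    "exp_order": " ".join(self.ranking.exp_ids_for(s.scheme)),
                    "mae_dddelta": s.mae_dddelta,
                    "avg_mae": s.avg_mae if s.avg_mae is not None else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def classic_matrix(self) -> pd.DataFrame:
        """Per-set MAE matrix (experimental rows, calculated columns)."""
        return self.classic.matrix

    def rmsd_diagnostics(self) -> dict[str, dict[str, float]]:
        """Within-group pairwise RMSD summaries (set-similarity check)."""
        return {
            "calculated": stats.rmsd_summary(self.model.bundle.calc_sets),
            "experimental": stats.rmsd_summary(self.model.bundle.exp_sets),
        }

    def save_report(self, path, *, metadata: dict | None = None) -> None:
        write_report(self.ranking, path, metadata=metadata)

    # -- presentation ----------------------------------------------------
    def summary(self, top: int = 10) -> str:
        """Human-readable summary of the fit."""
        b = self.model.bundle
        rk = self.ranking
        lines = [
            "Stereoisomer assignment by exhaustive alignment ranking",
            "=" * 56,
            f"sets per group:    {b.n}",
            f"alignments scored: {len(rk.scores)}",
            f"atoms compared:    {rk.n_labels}",
            f"difference pairs:  {alignment.count_pairs(b.n)} per alignment",
            "",
            "Proposed correspondence (best alignment):",
        ]
        for cid, eid in self.assignment.items():
            lines.append(f"  {cid}  <->  {eid}")
        lines.append("")
        lines.append(f"best MAE_dd (ppm):     {self.score:.4f}")
        if self.gap_to_second is not None:
            lines.append(f"gap to 2nd (ppm):      {self.gap_to_second:.4f}")
        if self.has_ties:
            lines.append(f"TIED alignments:       {len(rk.ties)}")
        if self.classic.ambiguous:
            lines.append(
                "note: classic per-set MAE is ambiguous on these data "
                "(some calculated set is the best fit of several "
                "experimental sets)"
            )
        lines.append("")
        lines.append(f"Top {min(top, len(rk.scores))} alignments:")
        frame = self.ranking_frame().head(top)
        lines.append(frame.to_string(index=False))
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<StereoAssignmentResults n={self.model.bundle.n} "
            f"best={self.best_permutation} score={self.score:.4f}>"
        )
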