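"""Reading and writing the tabular exchange formats.

Shift tables and conformer tables are plain CSV/TSV (dialect chosen by
file extension, decimal points only).  A shift table holds one compound's
atom index plus one column per shift set::

    label,hybridization,calc_1a,calc_1b
    C1,sp3,24.1,25.0
    C2,sp2,128.4,127.9

Empty cells mean *missing*, never zero.  A conformer table holds one row
per conformer::

    conformer_id,rel_energy,C1,C2
    conf_00,0.0,170.1,60.2

Writers emit full ``repr`` precision so a write -> read round trip is
bit-identical.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Iterable

import yaml

from .containers import (
    AtomRecord,
    Conformer,
    ConformerEnsemble,
    Hybridization,
    Origin,
    ShiftSet,
    StudyBundle,
)

_RESERVED = ("label", "hybridization")


def _dialect_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _read_rows(path: Path) -> list[list[str]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=_dialect_delimiter(path))
        rows = [row for row in reader if row and any(c.strip() for c in row)]
    if not rows:
        raise ValueError(f"{path}: empty table")
    return rows


def _parse_float(cell: str, *, row: str, column: str, path: Path) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ValueError(
            f"{path}: non-numeric value {cell!r} at row {row!r}, "
            f"column {column!r}"
        ) from None


def read_shift_table(
    path: str | Path, origin: Origin | str
) -> tuple[list[AtomRecord], list[ShiftSet]]:
    """Read a shift table.

    Returns the atom index (label + hybridization per row) and one
    :class:`ShiftSet` per set-id column, in header order.
    """
    path = Path(path)
    if isinstance(origin, str):
        origin = Origin(origin)
    rows = _read_rows(path)
    header = [c.strip() for c in rows[0]]
    if len(header) < 3 or tuple(header[:2]) != _RESERVED:
        raise ValueError(
            f"{path}: header must start with 'label, hybridization' followed "
            f"by at least one set-id column, got {header!r}"
        )
    set_ids = header[2:]
    if len(set(set_ids)) != len(set_ids):
        raise ValueError(f"{path}: duplicate set-id columns in header")

    atom_index: list[AtomRecord] = []
    seen: set[str] = set()
    shifts: dict[str, dict[str, float]] = {sid: {} for sid in set_ids}
    for row in rows[1:]:
        row = [c.strip() for c in row]
        if len(row) != len(header):
            raise ValueError(
                f"{path}: row {row[0]!r} has {len(row)} cells, expected "
                f"{len(header)}"
            )
        label = row[0]
        if label in seen:
            raise ValueError(f"{path}: duplicate atom label {label!r}")
        seen.add(label)
        atom_index.append(AtomRecord(label, Hybridization.parse(row[1])))
        for sid, cell in zip(set_ids, row[2:]):
            if cell == "":
                continue  # missing, not zero
            shifts[sid][label] = _parse_float(
                cell, row=label, column=sid, path=path
            )
    sets = [ShiftSet(sid, origin, shifts[sid]) for sid in set_ids]
    return atom_index, sets


def write_shift_table(
    path: str | Path, atom_index: list[AtomRecord], sets: Iterable[ShiftSet]
) -> None:
    """Write a shift table (full float precision, round-trip safe)."""
    path = Path(path)
    sets = list(sets)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=_dialect_delimiter(path))
        writer.writerow(list(_RESERVED) + [s.set_id for s in sets])
        for rec in atom_index:
            row = [rec.label, rec.hybridization.value]
            for s in sets:
                v = s.shifts.get(rec.label)
                row.append("" if v is None else repr(v))
            writer.writerow(row)


def read_conformer_table(
    path: str | Path, isomer_id: str | None = None
) -> ConformerEnsemble:
    """Read a conformer table; energies are re-zeroed to the minimum."""
    path = Path(path)
    rows = _read_rows(path)
    header = [c.strip() for c in rows[0]]
    if len(header) < 3 or header[0] != "conformer_id" or header[1] != "rel_energy":
        raise ValueError(
            f"{path}: header must be 'conformer_id, rel_energy, <labels...>', "
            f"got {header!r}"
        )
    labels = header[2:]
    conformers = []
    for row in rows[1:]:
        row = [c.strip() for c in row]
        if len(row) != len(header):
            raise ValueError(
                f"{path}: conformer {row[0]!r} has {len(row)} cells, "
                f"expected {len(header)} (atom columns must be consistent)"
            )
        cid = row[0]
        energy = _parse_float(row[1], row=cid, column="rel_energy", path=path)
        shieldings = {
            lab: _parse_float(cell, row=cid, column=lab, path=path)
            for lab, cell in zip(labels, row[2:])
        }
        conformers.append(Conformer(cid, energy, shieldings))
    return ConformerEnsemble(isomer_id or path.stem, conformers)


def write_conformer_table(path: str | Path, ensemble: ConformerEnsemble) -> None:
    path = Path(path)
    labels = sorted(ensemble.labels)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=_dialect_delimiter(path))
        writer.writerow(["conformer_id", "rel_energy"] + labels)
        for conf in ensemble.conformers:
            writer.writerow(
                [conf.conformer_id, repr(conf.rel_energy)]
                + [repr(conf.shieldings[lab]) for lab in labels]
            )


def read_bundle(calc_path: str | Path, exp_path: str | Path) -> StudyBundle:
    """Read calculated + experimental shift tables into one bundle.

    The two tables must describe the same atom index; the calculated
    file's column order fixes the reference sequence and the experimental
    file's column order defines the identity permutation.
    """
    atom_index, calc_sets = read_shift_table(calc_path, Origin.CALCULATED)
    exp_index, exp_sets = read_shift_table(exp_path, Origin.EXPERIMENTAL)
    exp_hyb = {r.label: r.hybridization for r in exp_index}
    for rec in atom_index:
        if rec.label in exp_hyb and exp_hyb[rec.label] != rec.hybridization:
            raise ValueError(
                f"atom {rec.label!r} tagged {rec.hybridization.value} in "
                f"{calc_path} but {exp_hyb[rec.label].value} in {exp_path}"
            )
    return StudyBundle(atom_index, calc_sets, exp_sets)


def load_config(path: str | Path) -> dict:
    """Load the YAML run configuration (temperature, standards, ...)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping, for report metadata."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(ranking, path: str | Path, *, metadata: dict | None = None) -> None:
    """Write an alignment ranking as JSON plus a TSV mirror.

    Each entry records the rank, the experimental-set ids in calculated
    order, the alignment score, and the optional per-set average MAE.
    The TSV mirror lives next to the JSON file with a ``.tsv`` suffix.
    """
    path = Path(path)
    if not ranking.scores:
        raise ValueError("cannot write an empty ranking")
    entries = []
    for rank, score in enumerate(ranking.scores, start=1):
        entries.append(
            {
                "rank": rank,
                "exp_order": list(ranking.exp_ids_for(score.scheme)),
                "permutation": list(score.scheme.permutation),
                "mae_dddelta": score.mae_dddelta,
                "avg_mae": score.avg_mae,
                "n_terms": score.n_terms,
            }
        )
    doc = {
        "metadata": {
            "n_sets": ranking.n,
            "n_atoms": ranking.n_labels,
            "calc_order": list(ranking.calc_ids),
            "best_exp_order": list(ranking.exp_ids_for(ranking.best)),
            "gap_to_second": ranking.gap_to_second,
            "ties": [list(t.permutation) for t in ranking.ties],
            **(metadata or {}),
        },
        "ranking": entries,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
    tsv_path = path.with_suffix(".tsv")
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["rank", "exp_order", "mae_dddelta", "avg_mae"])
        for e in entries:
            writer.writerow(
                [
                    e["rank"],
                    " ".join(e["exp_order"]),
                    repr(e["mae_dddelta"]),
                    "" if e["avg_mae"] is None else repr(e["avg_mae"]),
                ]
            )
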