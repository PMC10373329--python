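"""Compound tables: reading, writing, split decoding and summaries.

A dataset is an ordered collection of compounds, each with an identifier, a
SMILES string, an observed pIC50 (may be missing for prediction-only rows)
and, per split, a role in one of the four modelling sets:

* ``TRN``  — training: fits the correlation weights,
* ``ITRN`` — invisible training: steadies the target function,
* ``CAL``  — calibration: detects overtraining, carries the IIC,
* ``VAL``  — validation: untouched until the final assessment.

Role cells may hold the words above or the compact markers ``+ - # *``
(training, invisible training, calibration, validation respectively).

The package ships the study table of 80 flavonols assayed against the PC-3
prostate-cancer cell line as ``mcqsar.dataset.load_flavonols()``, including
the published per-split descriptor values and predictions as reference
columns.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

ROLES = ("TRN", "ITRN", "CAL", "VAL")
_MARKERS = {"+": "TRN", "-": "ITRN", "−": "ITRN", "#": "CAL", "*": "VAL"}


class DatasetError(ValueError):
    """Malformed compound table."""


@dataclass
class CompoundRecord:
    id: str
    smiles: str
    activity: float | None
    roles: dict[str, str] = field(default_factory=dict)
    extra: dict[str, float] = field(default_factory=dict)

    def role(self, split: str) -> str | None:
        return self.roles.get(split)


@dataclass
class Dataset:
    records: list[CompoundRecord]
    splits: list[str]

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.id in seen:
                raise DatasetError(f"duplicate compound id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self, cid: str) -> CompoundRecord:
        for rec in self.records:
            if rec.id == cid:
                return rec
        raise KeyError(cid)

    def subset(self, split: str, role: str) -> list[CompoundRecord]:
        if role not in ROLES:
            raise DatasetError(f"unknown role {role!r}")
        return [r for r in self.records if r.roles.get(split) == role]

    def set_sizes(self, split: str) -> dict[str, int]:
        return {role: len(self.subset(split, role)) for role in ROLES}


def decode_role(cell: str, row_id: str) -> str:
    cell = cell.strip()
    if cell.upper() in ROLES:
        return cell.upper()
    if cell in _MARKERS:
        return _MARKERS[cell]
    raise DatasetError(f"unknown role symbol {cell!r} in row {row_id!r}")


def parse_dataset(path: str | Path, split_columns: list[str] | None = None,
                  delimiter: str = ",") -> Dataset:
    """Read a delimited compound table.

    The header must contain ``id``, ``smiles`` and ``pic50`` columns; split
    columns default to every column whose name starts with ``split``.  Rows
    with an empty activity cell are kept as prediction-only compounds; any
    other numeric columns are carried along in ``record.extra``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise DatasetError(f"{path}: empty file")
        header = [h.strip() for h in reader.fieldnames]
        for required in ("id", "smiles", "pic50"):
            if required not in header:
                raise DatasetError(f"{path}: missing column {required!r}")
        if split_columns is None:
            split_columns = [h for h in header if h.lower().startswith("split")]
        else:
            for col in split_columns:
                if col not in header:
                    raise DatasetError(f"{path}: missing split column {col!r}")
        extra_cols = [h for h in header
                      if h not in ("id", "smiles", "pic50") and h not in split_columns]
        records = []
        for row in reader:
            cid = row["id"].strip()
            smiles = row["smiles"].strip()
            if not smiles:
                raise DatasetError(f"{path}: empty SMILES in row {cid!r}")
            cell = row["pic50"].strip()
            activity = float(cell) if cell else None
            if activity is not None and not math.isfinite(activity):
                raise DatasetError(f"{path}: non-finite activity in row {cid!r}")
            roles = {}
            for col in split_columns:
                cell = (row.get(col) or "").strip()
                if cell:
                    roles[col] = decode_role(cell, cid)
            extra = {}
            for col in extra_cols:
                cell = (row.get(col) or "").strip()
                if cell:
                    extra[col] = float(cell)
            records.append(CompoundRecord(cid, smiles, activity, roles, extra))
    if not records:
        raise DatasetError(f"{path}: no data rows")
    return Dataset(records, list(split_columns))


def write_dataset(dataset: Dataset, path: str | Path, delimiter: str = ",") -> None:
    """Write a dataset back to a delimited table (roles as words)."""
    extra_cols: list[str] = []
    for rec in dataset.records:
        for col in rec.extra:
            if col not in extra_cols:
                extra_cols.append(col)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["id", "smiles", "pic50", *dataset.splits, *extra_cols])
        for rec in dataset.records:
            row = [rec.id, rec.smiles,
                   "" if rec.activity is None else repr(rec.activity)]
            row += [rec.roles.get(s, "") for s in dataset.splits]
            row += [repr(rec.extra[c]) if c in rec.extra else "" for c in extra_cols]
            writer.writerow(row)


def summarize(dataset: Dataset) -> dict:
    """Per-split set sizes plus activity range and mean."""
    activities = [r.activity for r in dataset.records if r.activity is not None]
    if not activities:
        raise DatasetError("no records with observed activity")
    return {
        "n": len(dataset),
        "n_with_activity": len(activities),
        "activity_min": min(activities),
        "activity_max": max(activities),
        "activity_mean": sum(activities) / len(activities),
        "set_sizes": {s: dataset.set_sizes(s) for s in dataset.splits},
    }


def load_flavonols() -> Dataset:
    """The packaged 80-compound flavonol / PC-3 table.

    Extra columns ``dcw_split{1,2,3}`` and ``pred_split{1,2,3}`` hold the
    published descriptor values and predictions of the three reported
    models; they are reference data, not inputs to training.
    """
    with resources.as_file(resources.files("mcqsar.data") / "flavonol_pc3.csv") as p:
        return parse_dataset(p)
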