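"""Mechanistic interpretation: promoters of activity increase/decrease.

A structural attribute whose correlation weight is positive in every one of
several independent optimization runs is read as a promoter of activity
increase; negative in every run, a promoter of decrease; a sign that is not
stable across runs carries no interpretation.  Records attach the
training / invisible-training / calibration prevalence counts and the
applicability-domain defect, mirroring the published interpretation table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import Dataset
from .descriptor import AttributeProfile, CWTable, dataset_profiles, prevalence
from .domain import DefectRecord, defect_table
from .keys import AttributeKey

#: Human-readable glosses for a few recurring attribute shapes.
_GLOSS = {
    ("SK", "N"): "aliphatic nitrogen",
    ("SK", "C"): "aliphatic carbon",
    ("SK", "O"): "aliphatic oxygen",
    ("SSK", "=.C"): "aliphatic carbon at a double bond",
    ("SSK", "C.O"): "aliphatic oxygen bonded to aliphatic carbon",
    ("SSK", "(.c"): "branching on aromatic ring",
}


@dataclass
class PromoterRecord:
    key: AttributeKey
    weights: list[float]
    classification: str             # "increase" | "decrease" | "undefined"
    n_trn: int = 0
    n_itrn: int = 0
    n_cal: int = 0
    defect: float = 0.0
    gloss: str = ""

    @property
    def mean_weight(self) -> float:
        return float(np.mean(self.weights))


def classify(weights: list[float]) -> str:
    """Sign-unanimity rule; an exact zero gives no sign evidence."""
    if not weights:
        raise ValueError("no weights to classify")
    if all(w > 0 for w in weights):
        return "increase"
    if all(w < 0 for w in weights):
        return "decrease"
    return "undefined"


def extract_promoters(tables: list[CWTable], dataset: Dataset, split: str,
                      profiles: Mapping[str, AttributeProfile] | None = None
                      ) -> list[PromoterRecord]:
    """One record per attribute unblocked in every run, sorted by |mean CW|.

    Expects runs with identical (threshold, epochs) and distinct seeds; with
    fewer than three runs the classification is still computed but a
    warning notes the weaker evidence.
    """
    if not tables:
        raise ValueError("no runs supplied")
    if len(tables) < 3:
        warnings.warn("promoter classification from fewer than 3 runs is weak "
                      "evidence", stacklevel=2)
    if len({(t.threshold, t.epochs) for t in tables}) > 1:
        raise ValueError("runs differ in (threshold, epochs)")
    profiles = profiles or dataset_profiles(dataset)
    sets = {role: [profiles[r.id] for r in dataset.subset(split, role)]
            for role in ("TRN", "ITRN", "CAL")}
    prev = {role: prevalence(p) if p else {} for role, p in sets.items()}
    defects = defect_table(prev["TRN"], len(sets["TRN"]),
                           prev["CAL"], len(sets["CAL"]))

    keys = set(tables[0].weights)
    for t in tables[1:]:
        keys &= set(t.weights)
    records = []
    for key in keys:
        if any(key in t.blocked for t in tables):
            continue
        ws = [t.weights[key] for t in tables]
        rec = PromoterRecord(
            key, ws, classify(ws),
            n_trn=prev["TRN"].get(key, 0),
            n_itrn=prev["ITRN"].get(key, 0),
            n_cal=prev["CAL"].get(key, 0),
            defect=defects[key].defect if key in defects else 1.0,
            gloss=_GLOSS.get((key.namespace, key.payload), ""),
        )
        records.append(rec)
    records.sort(key=lambda r: abs(r.mean_weight), reverse=True)
    return records


def promoter_report(records: list[PromoterRecord]) -> str:
    """Tab-separated report mirroring the published interpretation table."""
    n_runs = len(records[0].weights) if records else 0
    header = ["attribute"] + [f"cw_run{i + 1}" for i in range(n_runs)]
    header += ["n_trn", "n_itrn", "n_cal", "defect", "interpretation", "gloss"]
    lines = ["\t".join(header)]
    for r in records:
        row = [str(r.key)] + [f"{w:.4f}" for w in r.weights]
        row += [str(r.n_trn), str(r.n_itrn), str(r.n_cal),
                f"{r.defect:.4f}", r.classification, r.gloss]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
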