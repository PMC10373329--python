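"""Applicability domain by statistical defect, plus residual outliers.

An attribute's statistical defect measures how differently it is spread
over the training and calibration sets:

    defect(A) = |P_TRN(A) - P_CAL(A)| / (N_TRN(A) + N_CAL(A))

where P is the fraction of a set's molecules containing the attribute and
N the corresponding count; an attribute never seen in training has defect
1.  A molecule's defect is the sum over its distinct attributes, and a
molecule falls outside the applicability domain when its defect exceeds
twice the training-set average.  Separately, residual outliers are flagged
at |observed - predicted| > k * s (k = 3 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .descriptor import AttributeProfile
from .keys import AttributeKey
from .validation import LinearModel, std_error


@dataclass
class DefectRecord:
    key: AttributeKey
    n_trn: int
    n_cal: int
    p_trn: float
    p_cal: float
    defect: float


@dataclass
class MoleculeDefect:
    molecule_id: str
    defect: float
    outlier: bool = False


def attribute_defect(n_trn: int, size_trn: int, n_cal: int, size_cal: int) -> float:
    if size_trn <= 0 or size_cal <= 0:
        raise ValueError("set sizes must be positive")
    if n_trn == 0:
        return 1.0
    p_trn = n_trn / size_trn
    p_cal = n_cal / size_cal
    return abs(p_trn - p_cal) / (n_trn + n_cal)


def defect_table(prev_trn: Mapping[AttributeKey, int], size_trn: int,
                 prev_cal: Mapping[AttributeKey, int], size_cal: int) -> dict[AttributeKey, DefectRecord]:
    """Defect records for every attribute seen in either set."""
    out = {}
    for key in set(prev_trn) | set(prev_cal):
        n_t = prev_trn.get(key, 0)
        n_c = prev_cal.get(key, 0)
        out[key] = DefectRecord(key, n_t, n_c, n_t / size_trn, n_c / size_cal,
                                attribute_defect(n_t, size_trn, n_c, size_cal))
    return out


def molecule_defect(profile: AttributeProfile,
                    defects: Mapping[AttributeKey, DefectRecord]) -> MoleculeDefect:
    """Sum of defects over the molecule's distinct attributes.

    Attributes absent from the defect table were never seen in training or
    calibration and carry the unit defect.
    """
    total = 0.0
    for key in profile.counts:
        rec = defects.get(key)
        total += rec.defect if rec is not None else 1.0
    return MoleculeDefect(profile.molecule_id, total)


def domain_flags(profiles: Iterable[AttributeProfile],
                 trn_ids: Iterable[str],
                 defects: Mapping[AttributeKey, DefectRecord]) -> dict[str, MoleculeDefect]:
    """Flag molecules whose defect exceeds twice the training average."""
    profiles = list(profiles)
    trn_ids = set(trn_ids)
    if not trn_ids:
        raise ValueError("empty training set")
    per_molecule = {p.molecule_id: molecule_defect(p, defects) for p in profiles}
    trn_defects = [per_molecule[i].defect for i in trn_ids if i in per_molecule]
    if not trn_defects:
        raise ValueError("no training molecules among the profiles")
    cutoff = 2.0 * float(np.mean(trn_defects))
    for md in per_molecule.values():
        md.outlier = md.defect > cutoff
    return per_molecule


def residual_outliers(model: LinearModel, dcw: Mapping[str, float],
                      observed: Mapping[str, float],
                      trn_ids: Iterable[str], k: float = 3.0) -> list[str]:
    """Molecules with |observed - predicted| > k * s (s from training residuals)."""
    trn_ids = [i for i in trn_ids if i in observed]
    obs_trn = np.array([observed[i] for i in trn_ids])
    pred_trn = model.predict([dcw[i] for i in trn_ids])
    s = std_error(obs_trn, pred_trn)
    flagged = []
    for mid, y in observed.items():
        pred = float(model.predict(dcw[mid]))
        if abs(y - pred) > k * s:
            flagged.append(mid)
    return flagged
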