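"""Correlation-weight tables and the hybrid optimal descriptor DCW.

The descriptor of correlation weights of a molecule is the plain sum of the
learned weights of its structural attributes,

    DCW(T*, N*) = sum_k  CW(A_k),

where local attributes (single symbols, symbol pairs, per-vertex graph
invariants) enter with their multiplicity and whole-molecule codes enter
once.  T* is the prevalence threshold: attributes present in fewer than T*
training molecules are *blocked* — their weight is frozen at zero and never
updated — so the model cannot lean on rare features.  N* is the number of
Monte Carlo epochs used to optimize the unblocked weights.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np

from .dataset import CompoundRecord, Dataset
from .graph import build_graph, graph_attributes
from .keys import AttributeKey
from .smiles import smiles_attributes


@dataclass
class AttributeProfile:
    """Multiset of attribute keys for one molecule."""

    molecule_id: str
    counts: Counter[AttributeKey]


def molecule_profile(molecule_id: str, smiles: str, include_halo: bool = True,
                     ec_orders: tuple[int, int] = (1, 2)) -> AttributeProfile:
    """Hybrid profile: SMILES-side plus graph-side attributes."""
    counts = smiles_attributes(smiles, include_halo=include_halo)
    counts.update(graph_attributes(build_graph(smiles), ec_orders=ec_orders))
    return AttributeProfile(molecule_id, counts)


def dataset_profiles(dataset: Dataset | Iterable[CompoundRecord],
                     include_halo: bool = True,
                     ec_orders: tuple[int, int] = (1, 2)) -> dict[str, AttributeProfile]:
    records = dataset.records if isinstance(dataset, Dataset) else list(dataset)
    return {rec.id: molecule_profile(rec.id, rec.smiles, include_halo, ec_orders)
            for rec in records}


def prevalence(profiles: Iterable[AttributeProfile]) -> Counter[AttributeKey]:
    """Molecule-presence count per key (presence, not occurrence multiplicity)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("prevalence of an empty set of profiles")
    counts: Counter[AttributeKey] = Counter()
    for prof in profiles:
        for key in prof.counts:
            counts[key] += 1
    return counts


def apply_threshold(counts: Mapping[AttributeKey, int], threshold: int) -> set[AttributeKey]:
    """Keys whose training presence falls below the threshold are blocked."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return {key for key, n in counts.items() if n < threshold}


@dataclass
class CWTable:
    """Trained (or initialized) state of one Monte Carlo run."""

    weights: dict[AttributeKey, float]
    blocked: set[AttributeKey] = field(default_factory=set)
    threshold: int = 1
    epochs: int = 0
    seed: int = 0
    run_id: int = 0

    def weight(self, key: AttributeKey) -> float:
        return self.weights.get(key, 0.0)

    def unblocked_keys(self) -> list[AttributeKey]:
        return sorted((k for k in self.weights if k not in self.blocked),
                      key=str)


def init_cw(keys: Iterable[AttributeKey], blocked: set[AttributeKey],
            seed: int, init_range: tuple[float, float] = (0.1, 1.1),
            threshold: int = 1, run_id: int = 0) -> CWTable:
    """Fresh table: uniform random weights for unblocked keys, zero for blocked."""
    lo, hi = init_range
    if lo > hi:
        raise ValueError("empty initialization range")
    rng = np.random.default_rng(seed)
    weights: dict[AttributeKey, float] = {}
    for key in sorted(set(keys), key=str):  # stable order => reproducible draws
        weights[key] = 0.0 if key in blocked else float(rng.uniform(lo, hi))
    return CWTable(weights, set(blocked), threshold=threshold, seed=seed, run_id=run_id)


class DCWValue(NamedTuple):
    molecule_id: str
    value: float
    active_keys: int
    unseen_keys: int


def compute_dcw(profile: AttributeProfile, table: CWTable) -> DCWValue:
    """Sum of weights over the profile, multiplicity-weighted.

    Keys absent from the table (never seen in training) contribute zero and
    are counted as unseen — the signal the applicability domain turns into
    a unit defect.
    """
    value = 0.0
    active = 0
    unseen = 0
    for key, mult in profile.counts.items():
        if key in table.weights:
            value += mult * table.weights[key]
            active += 1
        else:
            unseen += 1
    return DCWValue(profile.molecule_id, value, active, unseen)


# --- model file serialization -------------------------------------------

def save_model(path: str | Path, table: CWTable, c0: float, c1: float,
               metadata: Mapping[str, object] | None = None) -> None:
    """Text model file: header key=value lines, then one weight per line."""
    lines = [
        f"#threshold={table.threshold}",
        f"#epochs={table.epochs}",
        f"#seed={table.seed}",
        f"#run_id={table.run_id}",
        f"#c0={c0!r}",
        f"#c1={c1!r}",
    ]
    for k, v in (metadata or {}).items():
        lines.append(f"#{k}={v}")
    for key in sorted(table.weights, key=str):
        flag = "B" if key in table.blocked else "W"
        lines.append(f"{flag}\t{key}\t{table.weights[key]!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> tuple[CWTable, float, float, dict[str, str]]:
    weights: dict[AttributeKey, float] = {}
    blocked: set[AttributeKey] = set()
    meta: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            name, _, value = line[1:].partition("=")
            meta[name] = value
            continue
        flag, key_text, value = line.split("\t")
        key = AttributeKey.parse(key_text)
        weights[key] = float(value)
        if flag == "B":
            blocked.add(key)
    table = CWTable(weights, blocked,
                    threshold=int(meta.get("threshold", 1)),
                    epochs=int(meta.get("epochs", 0)),
                    seed=int(meta.get("seed", 0)),
                    run_id=int(meta.get("run_id", 0)))
    return table, float(meta["c0"]), float(meta["c1"]), meta
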