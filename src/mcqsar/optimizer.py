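"""Monte Carlo optimization of correlation weights.

The weights start as uniform random draws and are improved by a greedy hill
climb: one epoch visits every unblocked attribute in a seeded-shuffled
order, perturbs its weight by a uniform step, refits the one-descriptor
regression on the training set, and keeps the step only if the target
function strictly increases.  Two target functions are supported:

    TF1 = R_TRN + R_iTRN - |R_TRN - R_iTRN| * const        (balance of correlation)
    TF2 = TF1 + w_iic * IIC_CAL                            (with the ideality index)

R are Pearson correlations of observed versus predicted activity on the
training and invisible-training sets; the index of ideality of correlation
is computed on the calibration set.  The validation set is never seen by
the optimizer.  A grid search over (threshold, epochs) picks the cell with
the best calibration statistic (R² without the IIC term, IIC with it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .dataset import Dataset, ROLES
from .descriptor import (
    AttributeProfile, CWTable, apply_threshold, compute_dcw, dataset_profiles,
    init_cw, prevalence,
)
from .keys import AttributeKey
from .validation import (
    LinearModel, MetricsReport, fit, iic, pearson, set_metrics, y_scramble,
)


class OptimizationError(RuntimeError):
    pass


@dataclass
class OptimizationConfig:
    threshold: int = 1
    epochs: int = 10
    const: float = 0.1          # weight of the |R_TRN - R_iTRN| penalty
    w_iic: float = 0.2          # weight of IIC_CAL; 0 gives TF1
    seed: int = 0
    n_runs: int = 3
    perturbation: float = 0.5   # uniform step half-width on one weight
    init_range: tuple[float, float] = (0.1, 1.1)
    t_grid: Sequence[int] = (1,)
    n_grid: Sequence[int] = (10,)
    include_halo: bool = True
    y_scramble_iter: int = 10

    @property
    def tf_kind(self) -> str:
        return "TF1" if self.w_iic == 0.0 else "TF2"


@dataclass
class TFState:
    """Target-function value and its components for the current weights."""

    tf: float
    c0: float
    c1: float
    r_trn: float
    r_itrn: float
    r_cal: float
    iic_cal: float


def target_function(r_trn: float, r_itrn: float, iic_cal: float,
                    const: float, w_iic: float) -> float:
    tf1 = r_trn + r_itrn - abs(r_trn - r_itrn) * const
    return tf1 + w_iic * iic_cal


@dataclass
class OptimizationResult:
    table: CWTable
    model: LinearModel
    report: MetricsReport
    state: TFState
    journal: list[tuple] = field(default_factory=list)
    dcw: dict[str, float] = field(default_factory=dict)
    config: OptimizationConfig | None = None


class MonteCarloOptimizer:
    """Hill climb over correlation weights for one split of one dataset."""

    def __init__(self, dataset: Dataset, split: str, config: OptimizationConfig,
                 profiles: dict[str, AttributeProfile] | None = None):
        self.config = config
        self.split = split
        records = [r for r in dataset.records
                   if r.roles.get(split) in ROLES and r.activity is not None]
        roles_present = {r.roles[split] for r in records}
        if roles_present != set(ROLES):
            missing = set(ROLES) - roles_present
            raise OptimizationError(f"split {split!r} lacks roles {sorted(missing)}")
        self.records = records
        self.profiles = profiles or dataset_profiles(
            records, include_halo=config.include_halo)
        self.y = np.array([r.activity for r in records])
        self.masks = {role: np.array([r.roles[split] == role for r in records])
                      for role in ROLES}

        trn_profiles = [self.profiles[r.id] for r in records
                        if r.roles[split] == "TRN"]
        self.prevalence_trn = prevalence(trn_profiles)
        self.blocked = apply_threshold(self.prevalence_trn, config.threshold)
        self.universe = set(self.prevalence_trn)

        # sparse membership: key -> (molecule indices, multiplicities)
        self._members: dict[AttributeKey, tuple[np.ndarray, np.ndarray]] = {}
        for i, rec in enumerate(records):
            for key, mult in self.profiles[rec.id].counts.items():
                if key in self.universe:
                    self._members.setdefault(key, ([], []))  # type: ignore
                    self._members[key][0].append(i)           # type: ignore
                    self._members[key][1].append(mult)        # type: ignore
        for key, (idx, mul) in list(self._members.items()):
            self._members[key] = (np.array(idx, dtype=int), np.array(mul, dtype=float))

        self.table = init_cw(self.universe, self.blocked, seed=config.seed,
                             init_range=config.init_range,
                             threshold=config.threshold)
        self._dcw = self._full_dcw()
        self.state = self.evaluate()
        if self.state is None:
            raise OptimizationError("degenerate descriptor at initialization "
                                    "(zero variance on the training set)")
        self.journal: list[tuple] = []
        self._epoch = 0
        self._evals = 0

    def _full_dcw(self) -> np.ndarray:
        dcw = np.zeros(len(self.records))
        for key, (idx, mul) in self._members.items():
            w = self.table.weights[key]
            if w != 0.0:
                dcw[idx] += mul * w
        return dcw

    def evaluate(self) -> TFState | None:
        """TF of the current weights; None when the TRN fit is degenerate."""
        x = self._dcw
        trn = self.masks["TRN"]
        xt = x[trn]
        yt = self.y[trn]
        sxx = float(np.sum((xt - xt.mean()) ** 2))
        if sxx == 0.0:
            return None
        c1 = float(np.sum((xt - xt.mean()) * (yt - yt.mean())) / sxx)
        c0 = float(yt.mean() - c1 * xt.mean())
        pred = c0 + c1 * x
        r_trn = pearson(yt, pred[trn])
        r_itrn = pearson(self.y[self.masks["ITRN"]], pred[self.masks["ITRN"]])
        cal = self.masks["CAL"]
        r_cal = pearson(self.y[cal], pred[cal])
        iic_cal = iic(self.y[cal], pred[cal], r_value=r_cal)
        tf = target_function(r_trn, r_itrn, iic_cal,
                             self.config.const, self.config.w_iic)
        return TFState(tf, c0, c1, r_trn, r_itrn, r_cal, iic_cal)

    def run_epoch(self, rng: np.random.Generator) -> TFState:
        """One pass over all unblocked keys; keeps strictly improving steps."""
        keys = self.table.unblocked_keys()
        order = rng.permutation(len(keys))
        p = self.config.perturbation
        for j in order:
            key = keys[j]
            delta = float(rng.uniform(-p, p))
            if delta == 0.0:
                continue
            idx, mul = self._members[key]
            self._dcw[idx] += mul * delta
            self.table.weights[key] += delta
            self._evals += 1
            candidate = self.evaluate()
            if candidate is not None and candidate.tf > self.state.tf:
                self.state = candidate
            else:  # revert
                self._dcw[idx] -= mul * delta
                self.table.weights[key] -= delta
        self._epoch += 1
        self.journal.append((self._epoch, self._evals, self.state.tf,
                             self.state.r_trn, self.state.r_itrn,
                             self.state.r_cal, self.state.iic_cal))
        return self.state

    def run(self) -> OptimizationResult:
        rng = np.random.default_rng(self.config.seed + 1)
        for _ in range(self.config.epochs):
            self.run_epoch(rng)
        self.table.epochs = self.config.epochs
        return self.finalize()

    def finalize(self) -> OptimizationResult:
        state = self.state
        model = LinearModel(state.c0, state.c1, split=self.split,
                            tf_kind=self.config.tf_kind,
                            threshold=self.config.threshold,
                            epochs=self.config.epochs)
        pred = model.predict(self._dcw)
        trn = self.masks["TRN"]
        train_mean = float(self.y[trn].mean())
        report = MetricsReport(split=self.split, tf_kind=self.config.tf_kind)
        for role in ROLES:
            m = self.masks[role]
            report.sets[role] = set_metrics(
                self.y[m], pred[m], role, train_mean=train_mean,
                dcw=self._dcw[m] if role == "TRN" else None)
        report.rr2_mean, report.crp2 = y_scramble(
            self._dcw[trn], self.y[trn],
            n_iter=self.config.y_scramble_iter, seed=self.config.seed + 2)
        dcw_map = {rec.id: float(self._dcw[i]) for i, rec in enumerate(self.records)}
        return OptimizationResult(self.table, model, report, state,
                                  journal=list(self.journal), dcw=dcw_map,
                                  config=self.config)


def optimize(dataset: Dataset, split: str, config: OptimizationConfig,
             profiles: dict[str, AttributeProfile] | None = None) -> OptimizationResult:
    """Train one model: initialize, run the configured epochs, report."""
    return MonteCarloOptimizer(dataset, split, config, profiles=profiles).run()


def run_seed(seed: int, run_id: int) -> int:
    """Derived per-run seed, kept inside 32-bit range."""
    return (seed * 9973 + 101 * run_id + 7) % (2 ** 31)


def optimize_runs(dataset: Dataset, split: str, config: OptimizationConfig,
                  profiles: dict[str, AttributeProfile] | None = None
                  ) -> list[OptimizationResult]:
    """Independent runs with distinct derived seeds (for interpretation)."""
    profiles = profiles or dataset_profiles(dataset, include_halo=config.include_halo)
    results = []
    for run_id in range(config.n_runs):
        cfg = replace(config, seed=run_seed(config.seed, run_id))
        result = optimize(dataset, split, cfg, profiles=profiles)
        result.table.run_id = run_id
        results.append(result)
    return results


def grid_search(dataset: Dataset, split: str, config: OptimizationConfig,
                profiles: dict[str, AttributeProfile] | None = None
                ) -> tuple[tuple[int, int], dict[tuple[int, int], OptimizationResult]]:
    """Pick (T*, N*) over the configured grids.

    Selection statistic: calibration R² for TF1, calibration IIC for TF2;
    ties broken by smaller N then smaller T.  Returns the winning cell and
    every cell's result.
    """
    if not config.t_grid or not config.n_grid:
        raise ValueError("empty grid")
    profiles = profiles or dataset_profiles(dataset, include_halo=config.include_halo)
    results: dict[tuple[int, int], OptimizationResult] = {}
    best: tuple[float, int, int] | None = None
    best_cell: tuple[int, int] | None = None
    for t in config.t_grid:
        for n in config.n_grid:
            cfg = replace(config, threshold=t, epochs=n)
            res = optimize(dataset, split, cfg, profiles=profiles)
            results[(t, n)] = res
            cal = res.report.sets["CAL"]
            stat = cal.r2 if config.w_iic == 0.0 else cal.iic
            rank = (stat, -n, -t)
            if best is None or rank > best:
                best = rank
                best_cell = (t, n)
    assert best_cell is not None
    return best_cell, results
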