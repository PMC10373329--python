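"""The one-descriptor linear model and the validation-metric battery.

The model is ordinary least squares on a single descriptor,

    pIC50 = C0 + C1 * DCW(T*, N*),

fitted on the training set only.  Model quality is judged with the metric
battery customary for this family of QSAR models: R² (both the
training-mean formula and squared Pearson correlation), leave-one-out Q²,
Lin's concordance correlation coefficient, the index of ideality of
correlation, standard error s, MAE, Fisher F, Roy's rm² pair on the
validation set, and Y-scrambling summarized by cRp².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class FitError(ValueError):
    """Degenerate regression input."""


@dataclass
class LinearModel:
    c0: float
    c1: float
    split: str = ""
    tf_kind: str = ""
    threshold: int = 1
    epochs: int = 0

    def predict(self, dcw):
        return self.c0 + self.c1 * np.asarray(dcw, dtype=float)


def fit(dcw_values, activities, **meta) -> LinearModel:
    """Univariate OLS of activity on descriptor."""
    x = np.asarray(dcw_values, dtype=float)
    y = np.asarray(activities, dtype=float)
    if x.size != y.size:
        raise FitError("length mismatch")
    if x.size < 3:
        raise FitError("need at least 3 points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise FitError("descriptor has zero variance")
    c1 = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    c0 = float(y.mean() - c1 * x.mean())
    return LinearModel(c0, c1, **meta)


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def r2_pearson(obs, pred) -> float:
    return pearson(obs, pred) ** 2


def r2_reference(obs, pred, reference_mean: float | None = None) -> float:
    """R² = 1 - SSres / SStot with the stated reference mean.

    With ``reference_mean=None`` the mean of ``obs`` itself is used — the
    classic coefficient of determination; passing the training mean gives
    the external-set variant of the formula.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    mean = obs.mean() if reference_mean is None else reference_mean
    sstot = float(np.sum((obs - mean) ** 2))
    if sstot == 0.0:
        raise FitError("zero total sum of squares")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sstot


def ccc(obs, pred) -> float:
    """Lin's concordance correlation coefficient."""
    x = np.asarray(obs, dtype=float)
    y = np.asarray(pred, dtype=float)
    vx = x.var()
    vy = y.var()
    cov = float(np.mean((x - x.mean()) * (y - y.mean())))
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom == 0.0:
        return 1.0
    return float(2.0 * cov / denom)


def mae(obs, pred) -> float:
    return float(np.mean(np.abs(np.asarray(obs, float) - np.asarray(pred, float))))


def std_error(obs, pred, ddof: int = 0) -> float:
    """s = sqrt(SSres / (n - ddof)); ddof=0 by default, 2 for the n-2 variant."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    n = obs.size
    if n <= ddof:
        raise FitError("too few points for this ddof")
    return float(math.sqrt(np.sum((obs - pred) ** 2) / (n - ddof)))


def fisher_f(r2: float, n: int) -> float:
    if r2 >= 1.0:
        return math.inf
    return r2 * (n - 2) / (1.0 - r2)


def q2_loo(dcw_values, activities) -> float:
    """Leave-one-out Q² for the univariate OLS fit, via the hat identity.

    For OLS the LOO residual is e_i / (1 - h_i) with leverage
    h_i = 1/n + (x_i - x̄)² / Sxx, so no refitting is needed.
    """
    x = np.asarray(dcw_values, float)
    y = np.asarray(activities, float)
    model = fit(x, y)
    resid = y - model.predict(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    h = 1.0 / x.size + (x - x.mean()) ** 2 / sxx
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / sstot


def iic(observed, predicted, r_value: float | None = None) -> float:
    """Index of ideality of correlation.

    The correlation coefficient is scaled by the ratio of the smaller to the
    larger of the two signed mean absolute errors (over negative and
    non-negative residuals observed - predicted).  Perfectly symmetric
    errors leave the correlation untouched; one-sided errors zero it.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.size == 0:
        raise FitError("empty residual list")
    r = pearson(obs, pred) if r_value is None else r_value
    delta = obs - pred
    neg = delta[delta < 0]
    pos = delta[delta >= 0]
    if neg.size == 0 or pos.size == 0:
        return 0.0
    neg_mae = float(np.mean(np.abs(neg)))
    pos_mae = float(np.mean(pos))
    hi = max(neg_mae, pos_mae)
    if hi == 0.0:
        return r
    return r * min(neg_mae, pos_mae) / hi


def _r0_through_origin(x, y) -> float:
    """Squared correlation of y with its through-origin regression on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    k = float(np.sum(x * y) / np.sum(x * x))
    sstot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum((y - k * x) ** 2)) / sstot


def rm2_metrics(observed, predicted) -> tuple[float, float]:
    """Roy's (mean rm², Δrm²) for an external set.

    rm² = r² (1 - sqrt(r² - r0²)) with r0² from the through-origin fit of
    predicted on observed; the primed variant interchanges the axes.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.size < 3:
        raise FitError("need at least 3 points for rm2")
    r2 = pearson(obs, pred) ** 2
    r0 = _r0_through_origin(obs, pred)
    r0p = _r0_through_origin(pred, obs)
    rm2 = r2 * (1.0 - math.sqrt(max(r2 - r0, 0.0)))
    rm2p = r2 * (1.0 - math.sqrt(max(r2 - r0p, 0.0)))
    return (rm2 + rm2p) / 2.0, abs(rm2 - rm2p)


def y_scramble(dcw_values, activities, n_iter: int = 10, seed: int = 0) -> tuple[float, float]:
    """Y-scrambling on the training set with the descriptor held fixed.

    Returns (mean scrambled R², cRp²) where cRp² = R sqrt(R² - Rr²); the
    difference is clamped at zero for the pure-noise case where sampling
    noise can push the mean scrambled R² above the true R².
    """
    x = np.asarray(dcw_values, float)
    y = np.asarray(activities, float)
    r = pearson(x, y)
    r2 = r * r
    rng = np.random.default_rng(seed)
    scrambled = []
    for _ in range(n_iter):
        perm = rng.permutation(y.size)
        scrambled.append(pearson(x, y[perm]) ** 2)
    rr2 = float(np.mean(scrambled))
    crp2 = abs(r) * math.sqrt(max(r2 - rr2, 0.0))
    return rr2, crp2


@dataclass
class SetMetrics:
    n: int
    r2: float                    # squared Pearson correlation
    r2_train_mean: float | None  # Table-formula variant (external sets)
    ccc: float
    iic: float
    q2: float | None
    s: float
    mae: float
    f: float | None
    rm2_mean: float | None = None
    rm2_delta: float | None = None


@dataclass
class MetricsReport:
    split: str
    tf_kind: str
    sets: dict[str, SetMetrics] = field(default_factory=dict)
    rr2_mean: float | None = None
    crp2: float | None = None

    def rows(self) -> list[tuple[str, str, float]]:
        out = []
        for set_name, m in self.sets.items():
            for metric in ("n", "r2", "r2_train_mean", "ccc", "iic", "q2",
                           "s", "mae", "f", "rm2_mean", "rm2_delta"):
                value = getattr(m, metric)
                if value is not None:
                    out.append((set_name, metric, float(value)))
        if self.crp2 is not None:
            out.append(("model", "crp2", float(self.crp2)))
            out.append(("model", "rr2_mean", float(self.rr2_mean)))
        return out


def set_metrics(obs, pred, role: str, train_mean: float | None = None,
                dcw=None) -> SetMetrics:
    """The full battery for one modelling set.

    ``role`` controls the extras: Q² and F for TRN, the rm² pair for VAL.
    ``dcw`` is required for the training Q² (LOO refits use the raw
    descriptor, not the predictions).
    """
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.size != pred.size or obs.size < 2:
        raise FitError("need >= 2 matched observations")
    r2 = r2_pearson(obs, pred)
    is_train = role == "TRN"
    return SetMetrics(
        n=int(obs.size),
        r2=r2,
        r2_train_mean=None if is_train or train_mean is None
        else r2_reference(obs, pred, train_mean),
        ccc=ccc(obs, pred),
        iic=iic(obs, pred),
        q2=q2_loo(dcw, obs) if is_train and dcw is not None else None,
        s=std_error(obs, pred),
        mae=mae(obs, pred),
        f=fisher_f(r2, int(obs.size)) if is_train else None,
        rm2_mean=rm2_metrics(obs, pred)[0] if role == "VAL" and obs.size >= 3 else None,
        rm2_delta=rm2_metrics(obs, pred)[1] if role == "VAL" and obs.size >= 3 else None,
    )


def select_best_model(reports: list[MetricsReport]) -> int:
    """Index of the report with the highest validation mean rm² (ties: VAL R²)."""
    if not reports:
        raise ValueError("no reports to select from")
    def sort_key(i: int):
        val = reports[i].sets["VAL"]
        if val.rm2_mean is None:
            raise ValueError("report lacks validation rm2")
        return (val.rm2_mean, val.r2)
    return max(range(len(reports)), key=sort_key)
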