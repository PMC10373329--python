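"""Linear model fitting and the validation-metric battery."""

import math

import numpy as np
import pytest

from mcqsar import (
    FitError, LinearModel, MetricsReport, ccc, fit, iic, q2_loo, r2_pearson,
    r2_reference, rm2_metrics, select_best_model, set_metrics, y_scramble,
)
from mcqsar.validation import SetMetrics, fisher_f, std_error

RNG = np.random.default_rng(2024)


class TestFit:
    def test_exact_line(self):
        m = fit([0, 1, 2, 3], [1, 3, 5, 7])
        assert (m.c0, m.c1) == pytest.approx((1.0, 2.0))

    def test_intercept_is_mean_for_antisymmetric_data(self):
        m = fit([-2, -1, 1, 2], [5.3, 4.9, 5.1, 4.7])
        assert m.c0 + m.c1 * 0.0 == pytest.approx(5.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(FitError):
            fit([1.0, 1.0, 1.0], [1, 2, 3])

    def test_residuals_orthogonal_to_descriptor(self):
        x = RNG.normal(size=40)
        y = 2 * x + RNG.normal(size=40)
        m = fit(x, y)
        resid = y - m.predict(x)
        assert float(resid @ x) == pytest.approx(0.0, abs=1e-9)


class TestPredict:
    def test_linear_application(self):
        m = LinearModel(c0=1.0, c1=0.5)
        assert float(m.predict(4.0)) == 3.0

    def test_zero_slope_constant(self):
        m = LinearModel(c0=4.2, c1=0.0)
        assert list(m.predict([1, 100])) == [4.2, 4.2]


class TestR2:
    def test_training_formula_equals_squared_pearson_for_ols(self):
        """OLS identity, checked by brute force on random data."""
        for _ in range(20):
            x = RNG.normal(size=25)
            y = 1.3 * x + RNG.normal(size=25)
            m = fit(x, y)
            pred = m.predict(x)
            assert r2_reference(y, pred) == pytest.approx(r2_pearson(y, pred))

    def test_perfect_predictions(self):
        y = [1.0, 2.0, 3.0]
        assert r2_pearson(y, y) == pytest.approx(1.0)
        assert r2_reference(y, y) == pytest.approx(1.0)


class TestIIC:
    def test_worked_example(self):
        """+MAE=0.1, -MAE=0.2 at r=0.9 gives 0.45."""
        obs = np.array([1.1, 2.1, 2.8])
        pred = obs - np.array([0.1, 0.1, -0.2])
        assert iic(obs, pred, r_value=0.9) == pytest.approx(0.45)

    def test_symmetric_residuals_keep_r(self):
        obs = np.array([1.0, 2.0])
        pred = np.array([1.2, 1.8])
        assert iic(obs, pred, r_value=0.7) == pytest.approx(0.7)

    def test_one_sided_residuals_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert iic(obs, obs - 0.5, r_value=0.9) == 0.0

    def test_bound_and_equality_condition(self):
        for _ in range(50):
            obs = RNG.normal(size=12)
            pred = obs + RNG.normal(scale=0.5, size=12)
            r = abs(np.corrcoef(obs, pred)[0, 1])
            value = iic(obs, pred)
            assert abs(value) <= r + 1e-12
        with pytest.raises(FitError):
            iic([], [])


class TestCCC:
    def test_identity(self):
        y = [1.0, 2.0, 3.0]
        assert ccc(y, y) == pytest.approx(1.0)

    def test_bounded_by_pearson(self):
        for _ in range(30):
            x = RNG.normal(size=15)
            y = x + RNG.normal(scale=0.4, size=15) + 0.3
            assert abs(ccc(x, y)) <= abs(np.corrcoef(x, y)[0, 1]) + 1e-12

    def test_shift_penalized(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ccc(y, y + 1.0) < 1.0


class TestQ2:
    def test_perfect_data(self):
        x = np.array([0.0, 1, 2, 3, 4])
        assert q2_loo(x, 2 * x + 1) == pytest.approx(1.0)

    def test_below_r2_on_noisy_data(self):
        x = RNG.normal(size=30)
        y = x + RNG.normal(scale=0.5, size=30)
        m = fit(x, y)
        assert q2_loo(x, y) < r2_pearson(y, m.predict(x))


class TestRm2:
    def test_perfect(self):
        y = [1.0, 2.0, 3.0]
        mean, delta = rm2_metrics(y, y)
        assert (mean, delta) == pytest.approx((1.0, 0.0))

    def test_proportional_data_scale_free(self):
        """obs = k*pred exactly: through-origin fit is perfect, rm2 = 1."""
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        mean, delta = rm2_metrics(2.0 * pred, pred)
        assert mean == pytest.approx(1.0)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_penalizes_offset(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        mean, _ = rm2_metrics(pred + 2.0, pred)
        assert mean < 1.0


class TestStdErrorAndF:
    def test_s_definition(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = obs + np.array([1.0, -1.0, 1.0])
        assert std_error(obs, pred) == pytest.approx(1.0)
        assert std_error(obs, pred, ddof=2) == pytest.approx(math.sqrt(3.0))

    def test_fisher_ratio_published_example(self):
        # R2 = 0.782 at n = 30 sits at ~100 (printed 101 within R2 rounding)
        assert fisher_f(0.782, 30) == pytest.approx(100.4, abs=0.1)


class TestYScramble:
    def test_planted_signal_survives(self):
        x = RNG.normal(size=30)
        y = 2 * x + RNG.normal(scale=0.2, size=30)
        rr2, crp2 = y_scramble(x, y, n_iter=20, seed=1)
        assert rr2 < 0.3 and crp2 > 0.5

    def test_noise_only_near_zero(self):
        x = RNG.normal(size=30)
        y = RNG.normal(size=30)
        _, crp2 = y_scramble(x, y, n_iter=20, seed=1)
        assert crp2 < 0.5

    def test_deterministic_given_seed(self):
        x = RNG.normal(size=20)
        y = RNG.normal(size=20)
        assert y_scramble(x, y, 5, seed=9) == y_scramble(x, y, 5, seed=9)


def _report(rm2_mean, r2):
    rep = MetricsReport("s", "TF2")
    rep.sets["VAL"] = SetMetrics(n=10, r2=r2, r2_train_mean=None, ccc=0, iic=0,
                                 q2=None, s=0, mae=0, f=None,
                                 rm2_mean=rm2_mean, rm2_delta=0.0)
    return rep


class TestSelectBestModel:
    def test_argmax_of_validation_rm2(self):
        reports = [_report(0.555, 0.7), _report(0.613, 0.7), _report(0.615, 0.7)]
        assert select_best_model(reports) == 2

    def test_single_report(self):
        assert select_best_model([_report(0.5, 0.7)]) == 0

    def test_tie_broken_by_r2(self):
        reports = [_report(0.6, 0.8), _report(0.6, 0.9)]
        assert select_best_model(reports) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_model([])


def test_metrics_permutation_equivariant():
    obs = RNG.normal(size=15)
    pred = obs + RNG.normal(scale=0.3, size=15)
    perm = RNG.permutation(15)
    a = set_metrics(obs, pred, "VAL")
    b = set_metrics(obs[perm], pred[perm], "VAL")
    for name in ("r2", "ccc", "iic", "s", "mae", "rm2_mean"):
        assert getattr(a, name) == pytest.approx(getattr(b, name))
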