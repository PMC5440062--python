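"""Force-profile analysis: coefficients, gain decomposition, epochs, stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from primadapt.analysis import (
    AnalysisWindow,
    EpochDef,
    adaptation_coefficient,
    epoch_average,
    epoch_compare,
    gain_decomposition,
    goal_components,
    normalize_series,
    trajectory_angle,
)
from primadapt.kinematics import FieldSpec, field_force, min_jerk_reach
from primadapt.model import GainState


@pytest.fixture(scope="module")
def windowed_reach():
    """Criterion reach windowed on the canonical +/-750 ms grid."""
    kin = min_jerk_reach(0.10, 0.30)
    w = AnalysisWindow()
    center = kin.peak_speed_time
    return (
        w.extract(kin.t, kin.pos, center),
        w.extract(kin.t, kin.vel, center),
        w,
    )


class TestAdaptationCoefficient:
    def test_full_compensation_gives_unity(self, windowed_reach):
        pos, vel, _ = windowed_reach
        ideal = 45 * pos + 15 * vel
        assert adaptation_coefficient(ideal, ideal) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("scale", [0.5, 0.72, -0.3, 2.0])
    def test_scale_equivariance(self, windowed_reach, scale):
        pos, vel, _ = windowed_reach
        ideal = 45 * pos + 15 * vel
        assert adaptation_coefficient(scale * ideal, ideal) == pytest.approx(scale, abs=1e-12)

    def test_cross_projection_matches_quadrature_oracle(self, windowed_reach):
        # velocity-field ideal regressed on position-field ideal must equal
        # the continuous-time projection integral of the two known profiles
        pos, vel, _ = windowed_reach
        coef = adaptation_coefficient(15 * vel, 45 * pos)

        D, v_peak = 0.10, 0.30
        T = 1.875 * D / v_peak

        def p(t):
            tau = t / T
            return 45 * D * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)

        def v(t):
            tau = t / T
            return 15 * (D / T) * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)

        num, _ = integrate.quad(lambda t: v(t) * p(t), 0, T)
        den, _ = integrate.quad(lambda t: p(t) ** 2, 0, T)
        assert coef == pytest.approx(num / den, rel=5e-3)

    def test_zero_ideal_rejected(self, windowed_reach):
        pos, _, _ = windowed_reach
        with pytest.raises(ValueError):
            adaptation_coefficient(pos, np.zeros_like(pos))


class TestGainDecomposition:
    def test_single_regressor_recovery(self, windowed_reach):
        pos, vel, w = windowed_reach
        f = 0.7 * 45 * pos
        dec = gain_decomposition(f, pos, vel)
        assert dec.k == pytest.approx(0.7, abs=1e-12)
        assert dec.b == pytest.approx(0.0, abs=1e-12)

    def test_two_gain_recovery_matches_normal_equations_oracle(self, windowed_reach):
        pos, vel, _ = windowed_reach
        f = 0.5 * 45 * pos + 0.2 * 15 * vel
        dec = gain_decomposition(f, pos, vel)
        assert dec.k == pytest.approx(0.5, abs=1e-10)
        assert dec.b == pytest.approx(0.2, abs=1e-10)
        assert dec.r2 == pytest.approx(1.0, abs=1e-12)
        # independent oracle: explicit normal-equations solve
        X = np.column_stack([pos, vel])
        beta = np.linalg.solve(X.T @ X, X.T @ f)
        assert dec.k == pytest.approx(beta[0] / 45, abs=1e-12)
        assert dec.b == pytest.approx(beta[1] / 15, abs=1e-12)

    def test_round_trip_any_gain_state(self, windowed_reach):
        pos, vel, _ = windowed_reach
        rng = np.random.default_rng(0)
        for _ in range(10):
            k, b = rng.uniform(-1, 1, size=2)
            dec = gain_decomposition(k * 45 * pos + b * 15 * vel, pos, vel)
            assert dec.k == pytest.approx(k, abs=1e-9)
            assert dec.b == pytest.approx(b, abs=1e-9)

    def test_acceleration_regressor_reported_separately(self, windowed_reach):
        pos, vel, w = windowed_reach
        rng = np.random.default_rng(1)
        f = 0.6 * 45 * pos + 0.3 * 15 * vel + rng.normal(0, 0.1, size=pos.shape)
        dec = gain_decomposition(f, pos, vel, include_acceleration=True, dt=w.dt)
        assert dec.accel_coef is not None
        # gains come from the two-regressor fit; acceleration adds little
        assert dec.r2_with_accel - dec.r2 <= 0.03
        assert dec.r2_with_accel >= dec.r2

    def test_collinear_regressors_rejected(self):
        x = np.linspace(0, 1, 100)
        with pytest.raises(ValueError):
            gain_decomposition(x, x, 2 * x)


class TestGainSpaceGeometry:
    def test_goal_components_for_each_field(self):
        assert goal_components(GainState(0.69, 0.10), "pFF") == (0.69, 0.10)
        assert goal_components(GainState(0.05, 0.66), "vFF") == (0.66, 0.05)
        aligned, misaligned = goal_components(GainState(0.5, 0.0), "pFF")
        assert misaligned == 0.0

    def test_goal_components_rejects_combination_fields(self):
        with pytest.raises(ValueError):
            goal_components(GainState(0.5, 0.5), "ucFF")

    @pytest.mark.parametrize(
        "g, ff, expected",
        [
            (GainState(0.0, 0.5), "vFF", 0.0),
            (GainState(0.5, 0.5), "pFF", 45.0),
            (GainState(1.0, 0.62), "pFF", np.degrees(np.arctan2(0.62, 1.0))),
        ],
    )
    def test_trajectory_angle(self, g, ff, expected):
        from primadapt.model import goal_for

        assert trajectory_angle(g, goal_for(ff)) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_angle_undefined(self):
        from primadapt.model import goal_for

        with pytest.raises(ValueError):
            trajectory_angle(GainState(0.0, 0.0), goal_for("pFF"))


class TestEpochAverage:
    @staticmethod
    def _df(records):
        return pd.DataFrame(records, columns=["subject", "training_index", "coef"])

    def test_constant_series_single_subject(self):
        df = self._df([(1, i, 0.4) for i in range(1, 16)])
        mean, sem, n = epoch_average(df, EpochDef("early", 1, 15), "coef")
        assert (mean, sem, n) == (pytest.approx(0.4), 0.0, 1)

    def test_two_subject_sem(self):
        df = self._df([(1, 1, 0.3), (2, 1, 0.5)])
        mean, sem, n = epoch_average(df, EpochDef("e", 1, 1), "coef")
        assert mean == pytest.approx(0.4)
        assert sem == pytest.approx(0.1)  # |a-b|/2 for n = 2
        assert n == 2

    def test_subject_first_averaging_order(self):
        # subject 1 contributes many trials, subject 2 one: equal weight
        df = self._df([(1, i, 0.2) for i in range(1, 11)] + [(2, 5, 0.6)])
        mean, _, n = epoch_average(df, EpochDef("e", 1, 10), "coef")
        assert mean == pytest.approx(0.4)
        assert n == 2

    def test_empty_epoch_rejected(self):
        df = self._df([(1, 1, 0.3)])
        with pytest.raises(ValueError):
            epoch_average(df, EpochDef("late", 150, 160), "coef")


class TestNormalizeSeries:
    def test_first_trial_cross_subject_mean_is_one(self):
        rng = np.random.default_rng(2)
        series = rng.uniform(0.2, 0.9, size=(5, 20))
        out = normalize_series(series)
        assert out[:, 0].mean() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        series = np.random.default_rng(3).uniform(0.1, 1.0, size=(4, 10))
        np.testing.assert_allclose(normalize_series(series), normalize_series(3.7 * series))

    def test_two_subject_example(self):
        out = normalize_series(np.array([[0.8, 0.4], [0.4, 0.2]]))
        np.testing.assert_allclose(out[:, 0], [4 / 3, 2 / 3])

    def test_zero_divisor_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_series(np.array([[0.5, 0.2], [-0.5, 0.1]]))


class TestEpochCompare:
    def test_identical_groups(self):
        a = np.array([0.1, 0.2, 0.3])
        res = epoch_compare(a, a.copy(), paired=True)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_constant_nonzero_paired_difference_flagged(self):
        a = np.array([0.5, 0.6, 0.7])
        res = epoch_compare(a, a - 0.1, paired=True)
        assert res.zero_variance
        assert np.isinf(res.t)

    def test_welch_matches_direct_formula(self):
        a = np.array([19.8, 20.4, 19.6, 17.8, 18.5, 18.9, 18.3, 18.9, 19.5, 22.0])
        b = np.array([28.2, 26.6, 20.1, 23.3, 25.2, 22.1, 17.7, 27.6, 20.6, 13.7])
        res = epoch_compare(a, b)
        # direct Welch formula oracle
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        dof = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.dof == pytest.approx(dof, abs=1e-10)
        # two-tailed p from the t CDF (regularized incomplete beta)
        from scipy.special import betainc

        p = betainc(dof / 2, 0.5, dof / (dof + t**2))
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_bonferroni_correction(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        res = epoch_compare(a, b, n_comparisons=3)
        assert res.p_corrected == pytest.approx(min(1.0, res.p * 3))

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            epoch_compare([1.0], [2.0, 3.0])
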