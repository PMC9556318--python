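import math

import numpy as np
import pytest
from scipy.integrate import quad

from burden_of_proof.data_model import ExposureInterval, PairConfig, RiskObservation
from burden_of_proof.signal_model import (
    FittingError,
    SignalModel,
    SplineMember,
    _n_basis,
    design_matrix,
    ensemble_weights,
    evaluate_signal,
    fit_ensemble,
    fit_member,
    linear_member,
    ranged_design_value,
)


def _obs(study, y, lo, hi, se=0.1, ref=(0.0, 0.0)):
    return RiskObservation(
        study_id=study,
        effect=math.exp(y),
        se_log=se,
        alt=ExposureInterval(lo, hi),
        ref=ExposureInterval(*ref),
    )


def _random_member(rng, monotone=False):
    n_int = int(rng.integers(2, 5))
    interior = np.sort(rng.uniform(5, 45, n_int))
    knots = np.r_[0.0, interior, 50.0]
    nb = _n_basis(knots)
    coef = rng.normal(0, 0.1, nb)
    if monotone:
        coef = np.abs(coef)
    return SplineMember(knots=knots, degree=3, coefficients=coef)


class TestRangedDesignValue:
    def test_zero_curve_gives_zero_contrast(self):
        member = SplineMember(
            knots=np.array([0.0, 25.0, 50.0]), degree=3,
            coefficients=np.zeros(_n_basis(np.array([0.0, 25.0, 50.0]))),
        )
        assert ranged_design_value(
            member, ExposureInterval(3, 17), ExposureInterval(0, 5)
        ) == pytest.approx(0.0, abs=1e-14)

    def test_linear_curve_interval_mean_is_midpoint(self):
        member = linear_member(50.0)  # s(x) = x
        val = ranged_design_value(member, ExposureInterval(10, 20), ExposureInterval(0, 0))
        assert val == pytest.approx(15.0, abs=1e-10)

    def test_matches_adaptive_quadrature_on_random_members(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            member = _random_member(rng)
            a, b = np.sort(rng.uniform(0, 50, 2))
            c, d = np.sort(rng.uniform(0, 50, 2))
            alt, ref = ExposureInterval(a, b), ExposureInterval(c, d)
            got = ranged_design_value(member, alt, ref)
            want = 0.0
            for sign, (lo, hi) in ((1.0, (a, b)), (-1.0, (c, d))):
                if hi > lo:
                    val, _ = quad(
                        lambda t: float(member.evaluate(t)), lo, hi,
                        limit=200, epsabs=1e-12, epsrel=1e-12,
                    )
                    want += sign * val / (hi - lo)
                else:
                    want += sign * float(member.evaluate(lo))
            assert got == pytest.approx(want, abs=1e-8)

    def test_degenerate_interval_is_point_evaluation(self):
        rng = np.random.default_rng(3)
        member = _random_member(rng)
        val = ranged_design_value(member, ExposureInterval(12.0, 12.0), ExposureInterval(0, 0))
        assert val == pytest.approx(float(member.evaluate(12.0)), abs=1e-12)


class TestFitMember:
    def _line_obs(self, slope=0.05, n=20, seed=0, se=0.1):
        rng = np.random.default_rng(seed)
        obs = []
        for i in range(n):
            lo = rng.uniform(0, 40)
            hi = lo + rng.uniform(0, 15)
            y = slope * 0.5 * (lo + hi)  # exact interval mean of a line
            obs.append(_obs(f"s{i % 5}", y, lo, hi, se=se))
        return obs

    def test_noiseless_monotone_data_fits_exactly(self):
        obs = self._line_obs()
        knots = np.array([0.0, 15.0, 30.0, 55.0])
        config = PairConfig(outcome_name="x", trim_fraction=0.1)
        member = fit_member(obs, knots, config)
        A = design_matrix(knots, obs)
        resid = np.array([o.log_effect for o in obs]) - A @ member.coefficients
        untrimmed = [i for i in range(len(obs)) if i not in member.trimmed_ids]
        assert np.max(np.abs(resid[untrimmed])) < 1e-8

    def test_trims_exactly_ceil_fraction(self):
        obs = self._line_obs(n=10)
        knots = np.array([0.0, 20.0, 55.0])
        member = fit_member(obs, knots, PairConfig(outcome_name="x", trim_fraction=0.1))
        assert len(member.trimmed_ids) == 1  # ceil(0.1 * 10)

    def test_gross_outlier_is_the_trimmed_row(self):
        obs = self._line_obs(n=10)
        bad = 4
        shifted = obs[bad]
        obs[bad] = _obs(
            shifted.study_id,
            shifted.log_effect + 5.0,
            shifted.alt.lower,
            shifted.alt.upper,
            se=shifted.se_log,
        )
        knots = np.array([0.0, 20.0, 55.0])
        config = PairConfig(outcome_name="x", trim_fraction=0.1)
        member = fit_member(obs, knots, config)
        assert member.trimmed_ids == {bad}
        # brute-force oracle: the leave-one-out fit with the smallest SSE
        # leaves out the same row
        A = design_matrix(knots, obs)
        y = np.array([o.log_effect for o in obs])
        w = np.array([1 / o.se_log for o in obs])
        sse = []
        for i in range(len(obs)):
            keep = np.ones(len(obs), bool)
            keep[i] = False
            m = fit_member(
                obs, knots, config, include=keep, trim=False
            )
            r = (y[keep] - A[keep] @ m.coefficients) * w[keep]
            sse.append(np.sum(r**2))
        assert int(np.argmin(sse)) == bad

    def test_trimming_is_permutation_invariant(self):
        obs = self._line_obs(n=20, seed=5)
        rng = np.random.default_rng(9)
        noisy = [
            _obs(o.study_id, o.log_effect + rng.normal(0, o.se_log), o.alt.lower, o.alt.upper)
            for o in obs
        ]
        knots = np.array([0.0, 15.0, 30.0, 55.0])
        config = PairConfig(outcome_name="x", trim_fraction=0.1)
        ref = fit_member(noisy, knots, config)
        perm = rng.permutation(len(noisy))
        shuffled = [noisy[i] for i in perm]
        other = fit_member(shuffled, knots, config)
        assert {int(perm[i]) for i in other.trimmed_ids} == set(ref.trimmed_ids)
        np.testing.assert_allclose(other.coefficients, ref.coefficients, atol=1e-10)

    def test_underdetermined_system_raises(self):
        obs = self._line_obs(n=4)
        knots = np.array([0.0, 15.0, 30.0, 55.0])
        with pytest.raises(FittingError):
            fit_member(obs, knots, PairConfig(outcome_name="x"))


class TestEnsemble:
    def test_single_member_weight_is_one(self):
        rng = np.random.default_rng(0)
        obs = TestFitMember()._line_obs(n=25)
        model = fit_ensemble(obs, PairConfig(outcome_name="x", n_ensemble=1), rng=rng)
        np.testing.assert_allclose(model.weights, [1.0])

    def test_identical_fit_and_tv_share_weight_equally(self):
        w = ensemble_weights(np.array([3.7, 3.7]), np.array([0.2, 0.2]))
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-15)

    def test_better_fit_gets_more_weight(self):
        w = ensemble_weights(np.array([10.0, 3.0]), np.array([0.1, 0.1]))
        assert w[0] > w[1]

    def test_recovers_noiseless_log_linear_curve(self):
        obs = TestFitMember()._line_obs(slope=0.05, n=40, seed=2)
        config = PairConfig(outcome_name="x", n_ensemble=10, trim_fraction=0.1)
        model = fit_ensemble(obs, config, rng=np.random.default_rng(1))
        grid = np.linspace(2, 50, 60)
        np.testing.assert_allclose(evaluate_signal(model, grid), 0.05 * grid, atol=1e-3)

    def test_weighted_monotone_ensemble_is_monotone(self, fitted_pair):
        result, _ = fitted_pair
        grid = np.linspace(0, 100, 500)
        s = evaluate_signal(result.signal, grid)
        assert np.all(np.diff(s) >= -1e-10)

    def test_anchored_at_zero_exposure(self, fitted_pair):
        result, _ = fitted_pair
        assert evaluate_signal(result.signal, np.array([0.0]))[0] == 0.0


class TestEvaluateSignal:
    def test_grid_matches_pointwise_evaluation(self):
        rng = np.random.default_rng(8)
        member = _random_member(rng, monotone=True)
        model = SignalModel(members=[member], weights=np.array([1.0]))
        grid = rng.uniform(0, 60, 40)
        vec = evaluate_signal(model, grid)
        pts = np.array([evaluate_signal(model, np.array([x]))[0] for x in grid])
        np.testing.assert_allclose(vec, pts, rtol=1e-12)

    def test_negative_exposure_rejected(self):
        member = linear_member(10.0)
        model = SignalModel(members=[member], weights=np.array([1.0]))
        with pytest.raises(ValueError):
            evaluate_signal(model, np.array([-1.0]))

    def test_linear_tail_beyond_last_knot(self):
        member = linear_member(10.0)  # slope 1 everywhere
        assert float(member.evaluate(25.0)) == pytest.approx(25.0, abs=1e-10)
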