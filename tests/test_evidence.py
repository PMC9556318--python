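import math

import numpy as np
import pytest
from scipy import stats

from burden_of_proof.data_model import ExposureInterval, PairConfig, RiskObservation
from burden_of_proof.evidence import (
    DEFAULT_GRID,
    average_bprf_from_ros,
    binary_ros,
    bprf_quantile,
    classify_summary_rows,
    compute_bprf,
    compute_ros,
    draw_curves,
    exposure_percentiles,
    load_reference_summary,
    risk_at_doses,
    star_rating,
)
from burden_of_proof.heterogeneity import HeterogeneityFit


def _het(beta=1.0, var_beta=0.01, gamma=0.0, sd_gamma=0.0):
    return HeterogeneityFit(
        beta_hat=beta, var_beta=var_beta, gamma_hat=gamma, sd_gamma=sd_gamma,
        tau2=0.0, loglik=0.0, n_studies=10, n_obs=30,
    )


class TestStarRating:
    @pytest.mark.parametrize(
        "ros,stars",
        [
            (0.73, 5),    # lung-cancer scale
            (0.54, 4),    # COPD scale
            (-0.06, 1),   # prostate-cancer scale
            (0.0, 2),
            (0.14, 2),
            (0.1401, 3),
            (0.41, 3),
            (0.4101, 4),
            (0.62, 4),
            (0.6201, 5),
            (-1e-9, 1),
        ],
    )
    def test_thresholds(self, ros, stars):
        assert star_rating(ros) == stars

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        for ros in rng.uniform(-2, 2, 500):
            assert star_rating(float(ros)) in (1, 2, 3, 4, 5)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            star_rating(float("nan"))


class TestBinaryRos:
    @pytest.mark.parametrize(
        "log_bprf,direction,expected",
        [(0.0, "harmful", 0.0), (0.40, "harmful", 0.20), (-0.10, "harmful", -0.05),
         (-0.40, "protective", 0.20)],
    )
    def test_halving_rule(self, log_bprf, direction, expected):
        assert binary_ros(log_bprf, direction) == pytest.approx(expected, abs=1e-15)


class TestExposurePercentiles:
    def test_single_value_collapses(self):
        obs = [
            RiskObservation(
                study_id="a", effect=1.5, se_log=0.1,
                alt=ExposureInterval(10, 14), ref=ExposureInterval(0, 0),
            )
        ]
        assert exposure_percentiles(obs) == (12.0, 12.0)

    def test_linear_interpolation_convention(self):
        obs = [
            RiskObservation(
                study_id="a", effect=1.5, se_log=0.1,
                alt=ExposureInterval(m, m), ref=ExposureInterval(0, 0),
            )
            for m in range(1, 101)
        ]
        p15, p85 = exposure_percentiles(obs)
        assert p85 == pytest.approx(85.15)
        assert p15 == pytest.approx(15.85)

    def test_calibrated_set_reproduces_reported_p85(self):
        # 21 midpoints placed so the interpolated 85th percentile lands exactly
        # on the published lung-cancer value of 50.88 pack-years
        mids = np.r_[np.linspace(1, 50, 17), 50.88, np.linspace(60, 112, 3)]
        obs = [
            RiskObservation(
                study_id="a", effect=2.0, se_log=0.2,
                alt=ExposureInterval(m, m), ref=ExposureInterval(0, 0),
            )
            for m in mids
        ]
        _, p85 = exposure_percentiles(obs)
        assert p85 == pytest.approx(50.88)

    def test_trimmed_rows_are_excluded(self):
        obs = [
            RiskObservation(
                study_id="a", effect=1.5, se_log=0.1,
                alt=ExposureInterval(m, m), ref=ExposureInterval(0, 0),
            )
            for m in (10.0, 20.0, 500.0)
        ]
        _, p85 = exposure_percentiles(obs, trimmed_ids={2})
        assert p85 <= 20.0


class TestComputeRos:
    def test_constant_bprf_averages_to_itself(self):
        grid = DEFAULT_GRID
        assert compute_ros(np.full_like(grid, 0.54), grid, 10, 40, "harmful") == pytest.approx(0.54)

    def test_protective_sign_convention(self):
        grid = DEFAULT_GRID
        assert compute_ros(np.full_like(grid, -0.16), grid, 10, 40, "protective") == pytest.approx(0.16)

    def test_matches_independent_trapezoid_oracle(self):
        grid = DEFAULT_GRID
        bprf = 0.02 * grid - 1e-4 * grid**2
        p15, p85 = 7.33, 62.19
        got = compute_ros(bprf, grid, p15, p85, "harmful")
        xs = np.r_[p15, grid[(grid > p15) & (grid < p85)], p85]
        ys = 0.02 * xs - 1e-4 * xs**2
        oracle = 0.0
        for i in range(len(xs) - 1):
            oracle += 0.5 * (ys[i] + ys[i + 1]) * (xs[i + 1] - xs[i])
        oracle /= p85 - p15
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_window_outside_grid_errors(self):
        with pytest.raises(ValueError):
            compute_ros(np.zeros_like(DEFAULT_GRID), DEFAULT_GRID, 10, 200, "harmful")


class TestDrawsAndBprf:
    def test_same_seed_same_draws(self):
        het = _het(gamma=0.02, sd_gamma=0.005)
        cfg = PairConfig(outcome_name="x", seed=3)
        s_grid = 0.03 * DEFAULT_GRID
        a = draw_curves(s_grid, het, cfg, rng=np.random.default_rng(3))
        b = draw_curves(s_grid, het, cfg, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_degenerate_distribution_collapses_draws(self):
        het = _het(var_beta=1e-30)
        cfg = PairConfig(outcome_name="x")
        s_grid = 0.03 * DEFAULT_GRID
        out = draw_curves(s_grid, het, cfg, rng=np.random.default_rng(0))
        np.testing.assert_allclose(
            out.draws, np.broadcast_to(out.mean_log_rr, out.draws.shape), atol=1e-10
        )
        np.testing.assert_allclose(out.ui_lower, out.ui_upper, atol=1e-10)

    def test_ui_matches_analytic_normal_quantiles(self):
        het = _het(beta=1.0, var_beta=0.04, gamma=0.01, sd_gamma=0.0)
        cfg = PairConfig(outcome_name="x", n_draws=100_000)
        s_grid = np.array([0.0, 1.0, 2.0])
        out = draw_curves(s_grid, het, cfg, rng=np.random.default_rng(1))
        sigma = math.sqrt(het.var_beta + het.gamma_star)
        for q, arr in ((0.025, out.ui_lower), (0.975, out.ui_upper)):
            want = stats.norm.ppf(q, 1.0, sigma) * s_grid
            mc_se = sigma * 3 / math.sqrt(cfg.n_draws * 0.025)
            np.testing.assert_allclose(arr, want, atol=4 * mc_se * max(s_grid))

    def test_mean_within_ui_pointwise(self, fitted_pair):
        result, _ = fitted_pair
        c = result.curves
        assert np.all(c.mean_log_rr >= c.ui_lower - 1e-12)
        assert np.all(c.mean_log_rr <= c.ui_upper + 1e-12)
        assert np.all(c.draws[:, 0] == 0.0)  # anchored at zero exposure

    def test_bprf_quantile_matches_monte_carlo(self):
        het = _het(beta=1.0, var_beta=0.02, gamma=0.03, sd_gamma=0.004)
        q = bprf_quantile(het)
        rng = np.random.default_rng(7)
        draws = rng.normal(het.beta_hat, math.sqrt(het.var_beta + het.gamma_star), 100_000)
        assert q == pytest.approx(float(np.quantile(draws, 0.05)), abs=3e-3)

    def test_bprf_limit_without_heterogeneity_is_ci_bound(self):
        het = _het(beta=1.0, var_beta=0.04)
        bprf = compute_bprf(np.array([1.0]), het, "harmful")
        assert bprf[0] == pytest.approx(1.0 - 1.6448536 * 0.2, abs=1e-6)

    def test_bprf_below_mean_for_harmful(self, fitted_pair):
        result, _ = fitted_pair
        pos = result.curves.mean_log_rr > 1e-9
        assert np.all(
            result.evidence.bprf_log[pos] <= result.curves.mean_log_rr[pos] + 1e-12
        )

    def test_negative_quantile_propagates_to_negative_ros(self):
        het = _het(beta=0.2, var_beta=0.25)  # weak, uncertain effect
        assert bprf_quantile(het) < 0
        bprf = compute_bprf(0.02 * DEFAULT_GRID, het, "harmful")
        ros = compute_ros(bprf, DEFAULT_GRID, 10, 40, "harmful")
        assert ros < 0
        assert star_rating(ros) == 1


class TestSummaries:
    def test_exp_log_round_trip_identity(self):
        for ros in (-0.3, 0.0, 0.54):
            assert math.log(average_bprf_from_ros(ros, "harmful")) == pytest.approx(ros, abs=1e-12)

    @pytest.mark.parametrize(
        "ros,direction,bprf",
        [(0.54, "harmful", 1.72), (0.16, "protective", 0.85), (0.0, "harmful", 1.0)],
    )
    def test_average_bprf_consistency(self, ros, direction, bprf):
        assert average_bprf_from_ros(ros, direction) == pytest.approx(bprf, abs=0.005)

    def test_risk_at_dose_table_rounds_to_two_decimals(self, fitted_pair):
        result, _ = fitted_pair
        table = risk_at_doses(result.curves, [5, 10, 20, 40])
        assert (table["mean_rr"] == table["mean_rr"].round(2)).all()
        assert (table["ui_lower"] <= table["mean_rr"]).all()


class TestPublishedSummaryClassification:
    def test_star_partition_matches_published_counts(self):
        summary = load_reference_summary()
        stars = classify_summary_rows(summary)
        counts = stars.value_counts().to_dict()
        assert counts == {1: 7, 2: 6, 3: 15, 4: 3, 5: 5}

    def test_per_row_agreement_with_published_ratings(self):
        summary = load_reference_summary()
        stars = classify_summary_rows(summary)
        assert (stars == summary["stars_published"]).all()

    def test_positive_ros_and_high_evidence_counts(self):
        summary = load_reference_summary()
        stars = classify_summary_rows(summary)
        assert int((summary["ros"] > 0).sum()) == 29
        assert int((stars >= 4).sum()) == 8
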