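"""Scenario registry, frailty generator, censoring calibration, runners."""

import numpy as np
import pytest
from scipy import stats

from saddleperm import (
    GenConfig,
    SCENARIOS,
    calibrate_censoring_rate,
    coverage_experiment,
    draw_frailties,
    get_scenario,
    scenario_table,
    simulate_components,
    simulate_dataset,
    type1_error_experiment,
)


class TestRegistry:
    def test_twenty_scenarios(self):
        assert sorted(SCENARIOS) == list(range(1, 21))
        assert len(scenario_table()) == 20

    def test_weight_scheme_blocks(self):
        assert all(SCENARIOS[i].weight_scheme == "logrank" for i in range(1, 7))
        assert all(SCENARIOS[i].weight_scheme == "gehan" for i in range(7, 14))
        assert all(SCENARIOS[i].weight_scheme == "prentice" for i in range(14, 21))

    def test_scenario_8_row(self):
        sc = SCENARIOS[8]
        assert (sc.k, sc.n_clusters) == (6, 30)
        assert sc.cluster_size_rule == ("uniform", 3, 7)
        assert sc.theta == 0.75
        assert sc.censoring_target == pytest.approx(0.40)
        assert sc.weight_scheme == "gehan"

    def test_group_sizes_equal_split_with_low_index_remainder(self):
        assert get_scenario(1).group_sizes() == (5, 5, 5, 5, 5)
        sc = get_scenario(2)  # N=30, k=5
        assert sc.group_sizes() == (6, 6, 6, 6, 6)
        sc17 = get_scenario(17)  # N=60, k=6
        assert sc17.group_sizes() == (10,) * 6

    def test_override(self):
        sc = get_scenario(8, endpoint="logproduct", component_dist="exponential")
        assert sc.endpoint == "logproduct"
        assert SCENARIOS[8].endpoint == "ratio"  # registry untouched


class TestFrailties:
    def test_theta_zero_all_ones(self, rng):
        assert draw_frailties(10, 0.0, rng).tolist() == [1.0] * 10

    def test_moments_match_gamma(self, rng):
        u = draw_frailties(100_000, 0.5, rng)
        assert u.mean() == pytest.approx(1.0, abs=0.01)
        assert u.var() == pytest.approx(0.5, abs=0.02)

    def test_reproducible(self):
        a = draw_frailties(5, 0.3, np.random.default_rng(3))
        b = draw_frailties(5, 0.3, np.random.default_rng(3))
        assert a.tolist() == b.tolist()

    def test_negative_theta_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_frailties(5, -0.1, rng)


class TestComponents:
    def test_ratio_gives_two_columns(self, rng):
        sc = get_scenario(1)
        comp = simulate_components(sc, GenConfig(), np.ones(50), rng)
        assert comp.shape == (50, 2)
        assert (comp > 0).all()

    def test_weibull_and_exponential_ratios_rank_equivalent(self):
        """Hazard-scaled frailty: the Weibull ratio is a monotone
        transform of the exponential one, so ranks coincide exactly."""
        sc_w = get_scenario(1, component_dist="weibull")
        sc_e = get_scenario(1, component_dist="exponential")
        cfg = GenConfig()
        u = draw_frailties(200, 0.5, np.random.default_rng(5))
        cw = simulate_components(sc_w, cfg, u, np.random.default_rng(42))
        ce = simulate_components(sc_e, cfg, u, np.random.default_rng(42))
        rw = cw[:, 0] / cw[:, 1]
        re = ce[:, 0] / ce[:, 1]
        assert stats.spearmanr(rw, re).statistic == pytest.approx(1.0)

    def test_intracluster_correlation_zero_when_theta_zero(self, rng):
        sc = get_scenario(1, theta=0.0)
        n_pairs = 4000
        u = np.ones(2 * n_pairs)
        comp = simulate_components(sc, GenConfig(), u, rng)
        t = comp[:, 0] / comp[:, 1]
        r = np.log(t).reshape(n_pairs, 2)
        icc = np.corrcoef(r[:, 0], r[:, 1])[0, 1]
        assert abs(icc) < 0.04

    def test_intracluster_correlation_positive_under_frailty(self, rng):
        sc = get_scenario(1, theta=0.75)
        n_pairs = 4000
        u = np.repeat(draw_frailties(n_pairs, 0.75, rng), 2)
        comp = simulate_components(sc, GenConfig(), u, rng)
        t = np.log(comp[:, 0] / comp[:, 1]).reshape(n_pairs, 2)
        icc = np.corrcoef(t[:, 0], t[:, 1])[0, 1]
        assert icc > 0.1

    def test_frailty_on_both_ratio_components_cancels(self, rng):
        """Scaling both components identically leaves the ratio
        independent of the cluster effect (why numerator-only is the
        default)."""
        sc = get_scenario(1, theta=0.75)
        cfg = GenConfig(frailty_mechanism="all-components")
        n_pairs = 4000
        u = np.repeat(draw_frailties(n_pairs, 0.75, rng), 2)
        comp = simulate_components(sc, cfg, u, rng)
        t = np.log(comp[:, 0] / comp[:, 1]).reshape(n_pairs, 2)
        icc = np.corrcoef(t[:, 0], t[:, 1])[0, 1]
        assert abs(icc) < 0.04


class TestCensoringCalibration:
    def test_target_achieved(self):
        sc = get_scenario(1)
        rate = calibrate_censoring_rate(sc, GenConfig(), target=0.20)
        rng = np.random.default_rng(123)
        u = draw_frailties(50_000, sc.theta, rng)
        comp = simulate_components(sc, GenConfig(), u, rng)
        t = comp[:, 0] / comp[:, 1]
        c = rng.exponential(scale=1.0 / rate, size=t.size)
        achieved = float(np.mean(t > c))
        assert 0.18 <= achieved <= 0.22

    def test_monotone_in_target(self):
        sc = get_scenario(1)
        r20 = calibrate_censoring_rate(sc, GenConfig(), target=0.20)
        r40 = calibrate_censoring_rate(sc, GenConfig(), target=0.40)
        assert r40 > r20

    def test_rejects_extreme_target(self):
        with pytest.raises(ValueError):
            calibrate_censoring_rate(get_scenario(1), GenConfig(), target=0.95)


class TestSimulateDataset:
    def test_scenario_1_shape(self):
        ds = simulate_dataset(get_scenario(1), seed=0)
        assert ds.n_subjects == 125  # 25 clusters x 5 subjects
        assert ds.spec.group_sizes == (5, 5, 5, 5, 5)
        assert len(set(ds.cluster_index)) == 25

    def test_same_seed_identical(self):
        a = simulate_dataset(get_scenario(8), seed=9)
        b = simulate_dataset(get_scenario(8), seed=9)
        assert np.array_equal(a.t_obs, b.t_obs)
        assert a.assignment.labels == b.assignment.labels

    def test_censoring_fraction_near_target(self):
        sc = get_scenario(2)  # 40% target
        fracs = [
            1.0 - simulate_dataset(sc, seed=s).delta.mean() for s in range(60)
        ]
        assert abs(float(np.mean(fracs)) - 0.40 ) < 0.03

    def test_logproduct_times_positive(self):
        ds = simulate_dataset(get_scenario(14, endpoint="logproduct"), seed=1)
        assert (ds.t_obs > 0).all()
        assert ds.components.shape[1] == 2


@pytest.fixture(scope="module")
def small_run():
    return type1_error_experiment(
        get_scenario(1), reps=500, engines=("chisq",), seed=21
    )


class TestExperimentRunners:
    def test_rates_and_se(self, small_run):
        rate = small_run.rejection_rate("chisq")
        assert 0.0 <= rate <= 1.0
        assert small_run.standard_error("chisq") == pytest.approx(
            np.sqrt(rate * (1 - rate) / 500)
        )

    def test_alpha_one_rejects_everything(self, small_run):
        p = small_run.p_values["chisq"]
        assert np.mean(p[np.isfinite(p)] <= 1.0) == 1.0

    def test_coverage_is_complement_of_type1(self, small_run):
        cov = coverage_experiment(get_scenario(1), from_type1=small_run)
        assert cov["coverage"]["chisq"] == pytest.approx(
            1.0 - small_run.rejection_rate("chisq")
        )

    def test_rejects_too_few_reps(self):
        with pytest.raises(ValueError):
            type1_error_experiment(get_scenario(1), reps=100)

    def test_summary_table(self, small_run):
        df = small_run.summary()
        assert list(df["engine"]) == ["chisq"]
        assert df["reps"].iloc[0] == 500
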