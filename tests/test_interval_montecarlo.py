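import numpy as np
import pytest

from concindex.core_index import ValidationError, build_seg_profile, wls_slope
from concindex.core_index import concentration_index_formula
from concindex.interval_montecarlo import (
    MultiYearRates,
    ReplicateSet,
    SimulationConfig,
    draw_bin,
    draw_mc,
    draw_mc_rate,
    draw_mn,
    draw_pois,
    empirical_rate_variance,
    percentile_interval,
    run_interval,
)
from concindex.synthetic_register import default_standard_population

from conftest import make_table, profile_from_rates, uniform_stdpop


def mc_standard_error_of_median(values):
    # asymptotic MCSE of the sample median of a normal-ish distribution
    return 1.2533 * np.std(values) / np.sqrt(len(values))


class TestSimulationConfig:
    def test_mc_with_formula_estimator_rejected(self):
        with pytest.raises(ValidationError, match="wls"):
            SimulationConfig(method="MC", estimator="formula")

    def test_mc_defaults_to_wls(self):
        assert SimulationConfig(method="MC").resolved_estimator == "wls"
        assert SimulationConfig(method="BIN").resolved_estimator == "formula"

    def test_unknown_method(self):
        with pytest.raises(ValidationError, match="unknown simulation method"):
            SimulationConfig(method="BOOT")

    @pytest.mark.parametrize("bad", [{"n_replicates": 0}, {"alpha": 0.0},
                                     {"alpha": 1.0}, {"variance_divisor": 0.0}])
    def test_invalid_settings(self, bad):
        with pytest.raises(ValidationError):
            SimulationConfig(method="BIN", **bad)


class TestPercentileInterval:
    def test_degenerate_distribution(self):
        reps = ReplicateSet(values=np.full(100, 0.3), method="MC")
        iv = percentile_interval(reps)
        assert iv.lower == iv.upper == pytest.approx(0.3)
        assert iv.length == 0.0

    def test_order_statistic_interpolation(self):
        # type-7 linear interpolation: quantile q sits at 1 + q*(N-1)
        reps = ReplicateSet(values=np.arange(1.0, 10_001.0), method="MC")
        iv = percentile_interval(reps, alpha=0.05)
        assert iv.lower == pytest.approx(250.975, abs=1e-9)
        assert iv.upper == pytest.approx(9750.025, abs=1e-9)

    def test_symmetric_distribution_roughly_symmetric_interval(self):
        rng = np.random.default_rng(0)
        reps = ReplicateSet(values=rng.normal(0.0, 1.0, 50_000), method="MC")
        iv = percentile_interval(reps)
        med = iv.replicate_median
        assert abs((iv.upper - med) - (med - iv.lower)) < 0.05

    def test_empty_raises(self):
        with pytest.raises(ValidationError, match="no successful replicates"):
            percentile_interval(ReplicateSet(values=np.array([]), method="MC"))

    def test_median_recorded_and_bracketed(self):
        reps = ReplicateSet(values=np.array([1.0, 2.0, 3.0]), method="MC")
        iv = percentile_interval(reps, point_estimate=2.5)
        assert iv.C == 2.5
        assert iv.replicate_median == 2.0
        assert iv.lower <= iv.replicate_median <= iv.upper


@pytest.fixture(scope="module")
def small_table():
    """Register-flavoured but tiny: 3 ages x 4 groups, ~600 events."""
    rng = np.random.default_rng(123)
    p = np.full((3, 4), 50_000.0)
    lam = np.outer([20.0, 50.0, 80.0], [1.6, 1.2, 0.9, 0.7])
    return make_table(rng.poisson(lam), p)


@pytest.fixture(scope="module")
def small_profile(small_table):
    return build_seg_profile(small_table, uniform_stdpop(3))


class TestDrawMC:
    def test_zero_variance_reproduces_observed(self, small_profile):
        c_obs = concentration_index_formula(small_profile).C
        cfg = SimulationConfig(method="MC", n_replicates=50, seed=1,
                               variance_divisor=1e18)
        reps = draw_mc(small_profile, cfg)
        np.testing.assert_allclose(reps.values, c_obs, atol=1e-7)

    def test_median_matches_observed(self, small_profile):
        c_obs = concentration_index_formula(small_profile).C
        cfg = SimulationConfig(method="MC", n_replicates=8000, seed=2)
        reps = draw_mc(small_profile, cfg)
        tol = 3 * mc_standard_error_of_median(reps.values)
        assert abs(np.median(reps.values) - c_obs) < tol

    def test_variance_inflation_widens_without_moving_median(self, small_profile):
        base = SimulationConfig(method="MC", n_replicates=8000, seed=3)
        inflated = SimulationConfig(
            method="MC", n_replicates=8000, seed=3,
            variance_divisor=small_profile.n / 4.0,
        )
        iv0 = percentile_interval(draw_mc(small_profile, base))
        iv1 = percentile_interval(draw_mc(small_profile, inflated))
        assert iv1.length > 1.5 * iv0.length
        tol = 3 * mc_standard_error_of_median(draw_mc(small_profile, base).values)
        assert abs(iv1.replicate_median - iv0.replicate_median) < 2 * tol

    def test_zero_event_group_needs_override(self):
        prof = profile_from_rates([2.0, 1.0, 0.0], n=np.array([20, 10, 0]))
        cfg = SimulationConfig(method="MC", n_replicates=10, seed=4)
        with pytest.raises(ValidationError, match="seg_2"):
            draw_mc(prof, cfg)
        ok = SimulationConfig(method="MC", n_replicates=10, seed=4,
                              variance_divisor=np.array([20.0, 10.0, 5.0]))
        assert draw_mc(prof, ok).values.shape == (10,)

    def test_wrong_method_config_rejected(self, small_profile):
        with pytest.raises(ValidationError, match="expected 'MC'"):
            draw_mc(small_profile, SimulationConfig(method="BIN"))


class TestDrawMCRate:
    def test_zero_rate_group_stays_zero(self):
        # y = 0 implies sd = 0: the group's simulated rate is exactly zero
        prof = profile_from_rates([2.0, 1.0, 0.0], n=np.array([20, 10, 1]))
        cfg = SimulationConfig(method="MC_RATE", n_replicates=200, seed=5)
        rng = np.random.default_rng(5)
        div = prof.n.astype(float)
        y_star = rng.normal(prof.y, prof.y / np.sqrt(div), size=(200, 3))
        assert np.all(y_star[:, 2] == 0.0)
        reps = draw_mc_rate(prof, cfg)
        assert reps.values.shape[0] == 200

    def test_formula_and_wls_agree_per_replicate(self, small_profile):
        kw = dict(n_replicates=500, seed=6)
        r_formula = draw_mc_rate(
            small_profile, SimulationConfig(method="MC_RATE", estimator="formula", **kw)
        )
        r_wls = draw_mc_rate(
            small_profile, SimulationConfig(method="MC_RATE", estimator="wls", **kw)
        )
        np.testing.assert_allclose(r_formula.values, r_wls.values, atol=1e-10)

    def test_similar_length_to_mc(self, small_profile):
        iv_mc = percentile_interval(
            draw_mc(small_profile, SimulationConfig(method="MC", n_replicates=6000, seed=7))
        )
        iv_rate = percentile_interval(
            draw_mc_rate(small_profile,
                         SimulationConfig(method="MC_RATE", n_replicates=6000, seed=8))
        )
        assert iv_rate.length == pytest.approx(iv_mc.length, rel=0.25)

    def test_failure_rate_threshold(self):
        # huge variance makes simulated mean rates go negative often
        prof = profile_from_rates([2.0, 1.0], n=np.array([2, 1]))
        cfg = SimulationConfig(method="MC_RATE", n_replicates=2000, seed=9,
                               variance_divisor=0.05)
        with pytest.raises(ValidationError, match="undefined index"):
            draw_mc_rate(prof, cfg)
        relaxed = SimulationConfig(method="MC_RATE", n_replicates=2000, seed=9,
                                   variance_divisor=0.05, max_failure_rate=0.9)
        reps = draw_mc_rate(prof, relaxed)
        assert reps.n_failed > 0
        assert reps.values.size + reps.n_failed == 2000


class TestDrawBin:
    def test_degenerate_probabilities_reproduce_table(self):
        # one group holds every death in each age band: rho in {0, 1}
        deaths = np.array([[5, 0], [0, 7]])
        t = make_table(deaths, np.full((2, 2), 1000.0))
        cfg = SimulationConfig(method="BIN", n_replicates=300, seed=10)
        iv = percentile_interval(draw_bin(t, uniform_stdpop(2), cfg))
        assert iv.length == pytest.approx(0.0, abs=1e-14)

    def test_zero_total_age_groups_contribute_nothing(self, small_table):
        deaths = small_table.deaths.copy()
        deaths[1, :] = 0  # middle age band has no events at all
        t = make_table(deaths, small_table.person_years)
        cfg = SimulationConfig(method="BIN", n_replicates=100, seed=11)
        reps = draw_bin(t, uniform_stdpop(3), cfg)
        expected_max = deaths.sum() * 2  # totals vary but stay finite
        assert np.all(reps.extras["total_events"] <= expected_max)

    def test_total_events_vary_between_replicates(self, small_table):
        cfg = SimulationConfig(method="BIN", n_replicates=200, seed=12)
        reps = draw_bin(small_table, uniform_stdpop(3), cfg)
        assert len(np.unique(reps.extras["total_events"])) > 1

    def test_deterministic_under_fixed_seed(self, small_table):
        cfg = SimulationConfig(method="BIN", n_replicates=200, seed=13)
        a = draw_bin(small_table, uniform_stdpop(3), cfg)
        b = draw_bin(small_table, uniform_stdpop(3), cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_all_zero_events_error(self):
        t = make_table(np.zeros((2, 2)), np.full((2, 2), 100.0))
        with pytest.raises(ValidationError, match="no events"):
            draw_bin(t, uniform_stdpop(2), SimulationConfig(method="BIN", seed=1))


class TestDrawPois:
    def test_zero_count_cells_stay_zero(self):
        deaths = np.array([[0, 10], [0, 20]])
        t = make_table(deaths, np.full((2, 2), 1000.0))
        cfg = SimulationConfig(method="POIS", n_replicates=500, seed=14)
        reps = draw_pois(t, uniform_stdpop(2), cfg)
        # totals never exceed what the nonzero cells can produce alone and the
        # zero-rate group never gains events: C stays at its maximum
        assert np.all(reps.values == reps.values[0])

    def test_replicate_mean_matches_observed_total(self, small_table):
        cfg = SimulationConfig(method="POIS", n_replicates=4000, seed=15)
        reps = draw_pois(small_table, uniform_stdpop(3), cfg)
        total = small_table.deaths.sum()
        se = np.sqrt(total / 4000)
        assert abs(reps.extras["total_events"].mean() - total) < 4 * se


class TestDrawMN:
    def test_age_totals_held_fixed_every_replicate(self, small_table):
        cfg = SimulationConfig(method="MN", n_replicates=300, seed=16)
        reps = draw_mn(small_table, uniform_stdpop(3), cfg)
        np.testing.assert_array_equal(
            reps.extras["total_events"], small_table.deaths.sum()
        )

    def test_zero_probability_groups_receive_nothing(self):
        deaths = np.array([[4, 0, 6]])
        t = make_table(deaths, np.full((1, 3), 1000.0))
        cfg = SimulationConfig(method="MN", n_replicates=400, seed=17)
        reps = draw_mn(t, uniform_stdpop(1), cfg)
        # middle group has rho = 0; redistribution happens only between the
        # outer groups, so the curve ordinate at the middle never moves
        assert reps.values.size == 400

    def test_interval_close_to_bin(self, small_table):
        sp = uniform_stdpop(3)
        iv_bin = percentile_interval(draw_bin(
            small_table, sp, SimulationConfig(method="BIN", n_replicates=6000, seed=18)))
        iv_mn = percentile_interval(draw_mn(
            small_table, sp, SimulationConfig(method="MN", n_replicates=6000, seed=19)))
        assert iv_mn.length == pytest.approx(iv_bin.length, rel=0.25)


class TestEmpiricalRateVariance:
    def make_panel(self, rates):
        rates = np.asarray(rates, dtype=float)
        G, J = rates.shape
        return MultiYearRates(
            tuple(f"g{i}" for i in range(G)),
            tuple(str(2000 + j) for j in range(J)),
            rates,
        )

    def test_constant_rates_zero_variance(self):
        panel = self.make_panel([[5.0, 5.0, 5.0], [2.0, 2.0, 2.0]])
        np.testing.assert_allclose(
            empirical_rate_variance(panel, ("2000", "2001", "2002")), 0.0
        )

    def test_two_point_closed_form(self):
        a, b = 7.0, 3.0
        panel = self.make_panel([[a, b]])
        got = empirical_rate_variance(panel, ("2000", "2001"))
        assert got[0] == pytest.approx((a - b) ** 2 / 2)

    def test_missing_year_listed(self):
        panel = self.make_panel([[1.0, 2.0, 3.0]])
        with pytest.raises(ValidationError, match="1999"):
            empirical_rate_variance(panel, ("1999", "2000"))

    def test_window_too_small(self):
        panel = self.make_panel([[1.0, 2.0]])
        with pytest.raises(ValidationError, match=">= 2"):
            empirical_rate_variance(panel, ("2000",))


class TestRunInterval:
    def test_single_replicate_degenerate_interval(self, small_table):
        cfg = SimulationConfig(method="BIN", n_replicates=1, seed=20)
        iv = run_interval(small_table, uniform_stdpop(3), cfg)
        assert iv.lower == iv.upper == iv.replicate_median

    def test_deterministic(self, small_table):
        cfg = SimulationConfig(method="MN", n_replicates=500, seed=21)
        a = run_interval(small_table, uniform_stdpop(3), cfg)
        b = run_interval(small_table, uniform_stdpop(3), cfg)
        assert a == b

    def test_point_estimate_is_observed_C(self, small_table):
        sp = uniform_stdpop(3)
        c_obs = concentration_index_formula(build_seg_profile(small_table, sp)).C
        for method in ("MC", "MC_RATE", "BIN", "POIS", "MN"):
            cfg = SimulationConfig(method=method, n_replicates=50, seed=22)
            iv = run_interval(small_table, sp, cfg)
            assert iv.C == pytest.approx(c_obs, abs=1e-12)
            assert iv.method == method

    def test_median_bracketed(self, small_table):
        cfg = SimulationConfig(method="POIS", n_replicates=1000, seed=23)
        iv = run_interval(small_table, uniform_stdpop(3), cfg)
        assert iv.lower <= iv.replicate_median <= iv.upper


def test_shrinkage_with_scaled_counts(small_table):
    """Multiplying counts and person-years by k shrinks lengths ~ 1/sqrt(k)."""
    k = 9
    sp = uniform_stdpop(3)
    big = make_table(small_table.deaths * k, small_table.person_years * k)
    for method in ("MC", "MC_RATE"):
        cfg = SimulationConfig(method=method, n_replicates=6000, seed=24)
        iv_small = run_interval(small_table, sp, cfg)
        iv_big = run_interval(big, sp, cfg)
        assert iv_big.length / iv_small.length == pytest.approx(
            1 / np.sqrt(k), rel=0.15
        )


def test_preset_methods_agree_smoke(preset_synthetic, stdpop_default):
    """Cheap version of the register-scale agreement check (full in acceptance)."""
    lengths = {}
    for method in ("MC", "BIN", "MN"):
        cfg = SimulationConfig(method=method, n_replicates=2000, seed=25)
        lengths[method] = run_interval(
            preset_synthetic.table, stdpop_default, cfg
        ).length
    vals = np.array(list(lengths.values()))
    assert vals.max() / vals.min() < 1.25
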