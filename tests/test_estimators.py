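"""Rate-constant estimation: exactness, round trips, censoring, Monte Carlo."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glykin import (
    AminoacylRateEstimator,
    DataError,
    InitialComposition,
    InputDomainError,
    InsufficientDataError,
    LogLinearRateEstimator,
    NoiseModel,
    ObservedTimeCourse,
    RateConstants,
    UncertaintySpec,
    censor_ligation,
    fit_k1,
    fit_kobs,
    fold_change,
    gen_extension_experiment,
    half_life,
    mc_propagate,
    simulate_trajectory,
)
from glykin.synth import ExperimentDesign

from conftest import (
    K1_ZERO_MG,
    K2_DEFAULT,
    K3_ZERO_MG,
    make_timecourse,
    timecourses_from_table,
)


def decay_timecourse(k, times, condition="decay"):
    times = np.asarray(times, dtype=float)
    return ObservedTimeCourse(
        condition=condition, replicate="rep1", t=times,
        observables={"primer": np.exp(-k * times)},
    )


class TestFitKObs:
    def test_exact_exponential(self):
        tc = decay_timecourse(1.81, np.arange(0, 1.05, 0.1))
        fit = fit_kobs(tc, "primer")
        assert fit.k_obs == pytest.approx(1.81, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.n_points == 11

    def test_constant_signal_gives_zero_rate(self):
        tc = ObservedTimeCourse(
            condition="flat", replicate="rep1", t=np.array([0.0, 1.0, 2.0]),
            observables={"primer": np.array([0.8, 0.8, 0.8])},
        )
        assert fit_kobs(tc, "primer").k_obs == pytest.approx(0.0, abs=1e-14)

    def test_noisy_recovery_within_fifteen_percent(self):
        k_true = 0.0288
        times = np.linspace(0, 48, 10)
        rng = np.random.default_rng(7)
        p = np.exp(-k_true * times) * rng.lognormal(0, 0.05, size=times.size)
        est = LogLinearRateEstimator().fit(times, p)
        assert abs(est.k_obs_ - k_true) / k_true < 0.15

    def test_nonpositive_points_raise_with_times(self):
        times = np.array([0.0, 1.0, 2.0])
        with pytest.raises(DataError, match="2.0"):
            LogLinearRateEstimator().fit(times, np.array([1.0, 0.5, 0.0]))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            LogLinearRateEstimator().fit(np.array([0.0]), np.array([1.0]))

    def test_missing_observable(self):
        tc = decay_timecourse(1.0, [0, 1, 2])
        with pytest.raises(DataError):
            fit_kobs(tc, "np1")

    def test_predict_inverts_fit(self):
        times = np.arange(0, 2.05, 0.25)
        est = LogLinearRateEstimator().fit(times, np.exp(-0.9 * times))
        assert np.allclose(est.predict(times), np.exp(-0.9 * times),
                           atol=1e-12)


class TestHalfLife:
    def test_unit_half_life(self):
        assert half_life(math.log(2)) == pytest.approx(1.0, rel=1e-15)

    def test_double_rate_halves_life(self):
        assert half_life(2 * math.log(2)) == pytest.approx(0.5, rel=1e-15)

    def test_printed_duplex_internal_half_life(self):
        # 72 h: duplex internal-linkage half-life at 2.5 mM Mg2+
        assert half_life(math.log(2) / 72) == pytest.approx(72.0, rel=1e-12)

    def test_involution(self):
        for k in (0.01, 0.5, 12.0):
            assert half_life(half_life(k)) == pytest.approx(k, rel=1e-12)

    def test_domain_error(self):
        for k in (0.0, -1.0, math.nan):
            with pytest.raises(InputDomainError):
                half_life(k)


K1_GRID = [0.1, 1.0, 12.0]
K2_GRID = [0.2, 0.7]
K3_GRID = [0.05, 0.118, 9.0]
P0_GRID = [0.26, 0.45, 0.60]


class TestFitK1:
    @pytest.mark.parametrize("k1", K1_GRID)
    @pytest.mark.parametrize("k2", K2_GRID)
    @pytest.mark.parametrize("k3", K3_GRID)
    @pytest.mark.parametrize("p0", P0_GRID)
    def test_noiseless_round_trip_grid(self, k1, k2, k3, p0):
        """fit_k1 on noiseless generator output recovers k1 to 1e-4 rel."""
        t_max = 4.0 / (k1 + k2)
        times = np.linspace(t_max / 10, t_max, 8)
        design = ExperimentDesign(
            experiment_type="extension", condition="grid",
            rates=RateConstants(k1, k2, k3), times=times, p_gly0=p0,
            n_replicates=1, noise=NoiseModel(0.0, 0.0), seed=1,
        )
        table, manifest = gen_extension_experiment(design)
        tcs = timecourses_from_table(table, "extension")
        fit = fit_k1(tcs, k2=k2, k3=k3, p_gly0=p0)
        assert fit.converged
        assert fit.k1 == pytest.approx(k1, rel=1e-4)

    def test_no_product_pins_k1_to_boundary(self):
        # primer hydrolyzes and the native fraction extends, but no NP+1
        # band ever appears: the only consistent k1 is 0, flagged at bound
        k2, k3, p0 = 0.5, 0.3, 0.4
        tc = make_timecourse(RateConstants(0.0, k2, k3), p0,
                             np.linspace(0.1, 3, 8))
        fit = fit_k1(tc, k2=k2, k3=k3, p_gly0=p0)
        assert fit.converged
        assert fit.k1 == pytest.approx(0.0, abs=1e-6)
        assert fit.at_bound

    def test_ligation_round_trip_on_censored_points(self, ligation_design):
        from glykin import gen_ligation_experiment

        amino, control, _, manifest = gen_ligation_experiment(ligation_design)
        amino_tcs = timecourses_from_table(amino, "ligation")
        ctrl_tcs = timecourses_from_table(control, "ligation")
        censored = [censor_ligation(a, c)
                    for a, c in zip(amino_tcs, ctrl_tcs)]
        fit = fit_k1(censored, k2=manifest["k2"], k3=manifest["k3"],
                     p_gly0=manifest["p_gly0"])
        assert fit.k1 == pytest.approx(1.81, rel=1e-3)

    def test_pools_replicates(self):
        rates = RateConstants(2.0, 0.5, 0.1)
        tcs = [
            make_timecourse(rates, 0.4, np.linspace(0.1, 2, 6),
                            replicate=f"rep{i}")
            for i in (1, 2)
        ]
        fit = fit_k1(tcs, k2=0.5, k3=0.1, p_gly0=0.4)
        assert fit.n_points == 12
        assert fit.k1 == pytest.approx(2.0, rel=1e-6)

    def test_nonpositive_primer_points_excluded_not_fatal(self):
        rates = RateConstants(2.0, 0.5, 0.1)
        tc = make_timecourse(rates, 0.4, np.linspace(0.1, 2, 6))
        observables = {k: v.copy() for k, v in tc.observables.items()}
        observables["primer"][-1] = 0.0
        tc = ObservedTimeCourse("c", "rep1", tc.t, observables)
        fit = fit_k1(tc, k2=0.5, k3=0.1, p_gly0=0.4)
        assert fit.n_excluded == 1
        assert fit.n_points == 5
        assert fit.k1 == pytest.approx(2.0, rel=1e-4)

    def test_noise_robustness_median_bias(self):
        """Median |relative bias| < 10% with 5% band noise, triplicates."""
        biases = []
        for rep in range(20):
            design = ExperimentDesign(
                experiment_type="extension", condition="noisy",
                rates=RateConstants(K1_ZERO_MG, K2_DEFAULT, K3_ZERO_MG),
                times=(0.05, 0.1, 0.2, 0.33, 0.5, 0.75, 1.0), p_gly0=0.4,
                n_replicates=3, noise=NoiseModel(0.05, 0.0), seed=1000 + rep,
            )
            table, _ = gen_extension_experiment(design)
            tcs = timecourses_from_table(table, "extension")
            fit = fit_k1(tcs, k2=K2_DEFAULT, k3=K3_ZERO_MG, p_gly0=0.4)
            biases.append(abs(fit.k1 - K1_ZERO_MG) / K1_ZERO_MG)
        assert np.median(biases) < 0.10


class TestMonteCarlo:
    def setup_method(self):
        self.tc = make_timecourse(
            RateConstants(K1_ZERO_MG, K2_DEFAULT, K3_ZERO_MG), 0.4,
            np.linspace(0.05, 1.0, 7),
        )

    def test_zero_sd_degenerates_to_point_fit(self):
        spec = UncertaintySpec(p_gly0=(0.4, 0.0), k2=(K2_DEFAULT, 0.0),
                               k3=(K3_ZERO_MG, 0.0), n_draws=25, seed=3)
        mc = mc_propagate(self.tc, spec)
        point = fit_k1(self.tc, K2_DEFAULT, K3_ZERO_MG, 0.4)
        assert mc.sd == 0.0
        assert mc.k1 == pytest.approx(point.k1, rel=1e-9)

    def test_deterministic_under_seed(self):
        spec = UncertaintySpec(p_gly0=(0.4, 0.03), k2=(K2_DEFAULT, 0.05),
                               k3=(K3_ZERO_MG, 0.01), n_draws=60, seed=11)
        a = mc_propagate(self.tc, spec)
        b = mc_propagate(self.tc, spec)
        assert (a.k1, a.sd, a.q16, a.q84) == (b.k1, b.sd, b.q16, b.q84)

    def test_spread_from_p_gly0_uncertainty(self):
        spec = UncertaintySpec(p_gly0=(0.4, 0.05), k2=(K2_DEFAULT, 0.0),
                               k3=(K3_ZERO_MG, 0.0), n_draws=1000, seed=5)
        mc = mc_propagate(self.tc, spec)
        assert mc.sd > 0
        assert mc.k1 == pytest.approx(K1_ZERO_MG, rel=0.05)
        assert mc.q16 < mc.k1 < mc.q84

    def test_invalid_spec_rejected(self):
        with pytest.raises(InputDomainError):
            UncertaintySpec(p_gly0=(0.4, -0.1), k2=(1, 0), k3=(1, 0))
        with pytest.raises(InputDomainError):
            UncertaintySpec(p_gly0=(0.4, 0.1), k2=(1, 0), k3=(1, 0),
                            n_draws=0)


def ligation_pair(control_ligated, times=None):
    control_ligated = np.asarray(control_ligated, dtype=float)
    if times is None:
        times = np.arange(1, control_ligated.size + 1, dtype=float) / 10
    amino = ObservedTimeCourse(
        condition="amino", replicate="rep1", t=times,
        observables={"primer": np.linspace(1, 0.5, times.size),
                     "ligated": np.linspace(0, 0.5, times.size)},
    )
    control = ObservedTimeCourse(
        condition="ctrl", replicate="rep1", t=times,
        observables={"primer": 1 - control_ligated,
                     "ligated": control_ligated},
    )
    return amino, control


class TestCensorLigation:
    def test_threshold_application(self):
        times = np.array([0.05, 0.1, 0.25, 0.5, 1.0])
        amino, control = ligation_pair(
            [0.001, 0.005, 0.019, 0.030, 0.080], times
        )
        kept = censor_ligation(amino, control)
        assert np.array_equal(kept.t, times[:3])

    def test_all_censored_raises(self):
        amino, control = ligation_pair([0.02, 0.05, 0.9])
        with pytest.raises(InsufficientDataError):
            censor_ligation(amino, control)

    def test_identity_when_control_never_ligates(self):
        amino, control = ligation_pair([0.0, 0.0, 0.0, 0.0])
        kept = censor_ligation(amino, control)
        assert np.array_equal(kept.t, amino.t)
        for name in amino.observables:
            assert np.array_equal(kept.observables[name],
                                  amino.observables[name])

    def test_mismatched_grids_rejected(self):
        amino, _ = ligation_pair([0.0, 0.0, 0.0])
        _, control = ligation_pair([0.0, 0.0, 0.0],
                                   times=np.array([0.1, 0.2, 0.31]))
        with pytest.raises(DataError):
            censor_ligation(amino, control)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 0.5), min_size=1, max_size=12))
    def test_subsequence_and_strict_threshold(self, fractions):
        amino, control = ligation_pair(fractions)
        try:
            kept = censor_ligation(amino, control)
        except InsufficientDataError:
            assert all(f >= 0.02 for f in fractions)
            return
        # kept times are a subsequence of the input grid
        assert set(kept.t).issubset(set(amino.t))
        assert np.all(np.diff(kept.t) > 0)
        # every retained point satisfies the strict control threshold
        retained = np.isin(control.t, kept.t)
        assert np.all(control.observables["ligated"][retained] < 0.02)


class TestFoldChange:
    def test_activation_group_contrast(self):
        assert fold_change(1.81, 0.281) == pytest.approx(6.44, abs=0.01)

    def test_zero_mg_contrast_two_orders_of_magnitude(self):
        assert fold_change(12.0, 0.118) == pytest.approx(101.7, abs=0.1)

    def test_identity(self):
        assert fold_change(3.7, 3.7) == 1.0

    def test_domain_error(self):
        with pytest.raises(InputDomainError):
            fold_change(1.0, 0.0)
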