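"""Ensemble Kalman filter primitives, the expansion-parameter guard, and
the window loop."""

import warnings

import numpy as np
import pytest

from maizelai import crop, enkf
from maizelai.enkf import (
    CallableAdapter,
    CropEnsembleAdapter,
    EnkfConfig,
    Ensemble,
    ObservationSeries,
    analysis_update,
    assimilate_window,
    ensemble_covariance,
    expansion_parameter,
    initial_lai_ensemble,
    kalman_gain,
)
from maizelai.errors import InputError


class TestCovariance:
    def test_degenerate_ensemble_is_zero(self):
        assert ensemble_covariance(np.array([2.0, 2.0, 2.0])) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "members,expected",
        [([1.0, 3.0], 2.0), ([0.0, 0.0, 3.0], 3.0)],
    )
    def test_scalar_hand_cases(self, members, expected):
        cov = ensemble_covariance(np.array(members))
        assert cov.reshape(()) == pytest.approx(expected, abs=1e-12)

    def test_single_member_rejected(self):
        with pytest.raises(InputError):
            ensemble_covariance(np.array([1.0]))

    def test_matrix_case_symmetric_psd(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(40, 3))
        cov = ensemble_covariance(a)
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > -1e-10
        assert np.allclose(cov, np.cov(a.T, ddof=1))


class TestKalmanGain:
    @pytest.mark.parametrize(
        "a_c,d_c,h,expected",
        [(1.0, 1.0, 1.0, 0.5), (2.0, 1.0, 1.0, 2.0 / 3.0), (1.0, 0.0, 2.0, 0.5)],
    )
    def test_scalar_cases(self, a_c, d_c, h, expected):
        k = kalman_gain(a_c, d_c, h)
        assert k.reshape(()) == pytest.approx(expected, abs=1e-12)

    def test_singular_innovation_raises(self):
        from maizelai.errors import NumericalError

        with pytest.raises(NumericalError):
            kalman_gain(0.0, 0.0, 1.0)


class TestAnalysisUpdate:
    def test_zero_innovation_is_identity(self):
        a_f = np.array([1.0, 2.0, 3.0])
        out = analysis_update(a_f, a_f.copy(), 0.7, 1.0)
        assert np.array_equal(out, a_f)

    def test_zero_gain_is_identity(self):
        a_f = np.array([1.0, 2.0])
        out = analysis_update(a_f, np.array([9.0, 9.0]), 0.0, 1.0)
        assert np.array_equal(out, a_f)

    def test_hand_case(self):
        out = analysis_update(np.array([2.0]), np.array([3.0]), 0.5, 1.0)
        assert out[0] == pytest.approx(2.5, abs=1e-12)

    def test_negative_results_floored_at_zero(self):
        out = analysis_update(np.array([0.2]), np.array([0.0]), 2.0, 1.0)
        assert out[0] == 0.0

    def test_size_mismatch_rejected(self):
        with pytest.raises(InputError):
            analysis_update(np.array([1.0, 2.0]), np.array([1.0]), 0.5, 1.0)

    def test_analysis_mean_between_forecast_and_observation_means(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a_f = rng.uniform(0.5, 4.0, 50)
            d_t = rng.uniform(0.5, 4.0, 50)
            k = rng.uniform(0.0, 1.0)
            out = analysis_update(a_f, d_t, k, 1.0)
            lo, hi = sorted((a_f.mean(), d_t.mean()))
            assert lo - 1e-12 <= out.mean() <= hi + 1e-12


class TestExpansionParameter:
    def test_ratio_exactly_four_not_applied(self):
        e, applied = expansion_parameter(0.9, 10, 10, 4.0, 1.0)
        assert not applied  # the trigger is strict

    def test_hand_case_applied(self):
        e, applied = expansion_parameter(0.5, 10, 10, 10.0, 1.0)
        assert e == pytest.approx(5.0, abs=1e-12)
        assert applied

    def test_small_e_not_applied(self):
        e, applied = expansion_parameter(0.01, 100, 1, 5.0, 1.0)
        assert e == pytest.approx(0.0005, abs=1e-12)
        assert not applied

    def test_e_exactly_one_applied(self):
        e, applied = expansion_parameter(0.2, 1, 1, 5.0, 1.0)
        assert e == pytest.approx(1.0, abs=1e-12)
        assert applied

    def test_zero_model_variance_skips_with_warning(self):
        with pytest.warns(RuntimeWarning):
            e, applied = expansion_parameter(0.5, 10, 5, 1.0, 0.0)
        assert not applied

    @pytest.mark.parametrize("bad_r", [0.0, 1.0, -0.3])
    def test_invalid_draw_rejected(self, bad_r):
        with pytest.raises(InputError):
            expansion_parameter(bad_r, 10, 5, 1.0, 1.0)


def _identity_adapter() -> CallableAdapter:
    return CallableAdapter(fn=lambda x, t: x)


class TestAssimilateWindow:
    def test_zero_noise_identical_members_stay_identical(self):
        cfg = EnkfConfig(n_members=5, init_spread=0.0, process_noise_frac=0.0)
        ens = Ensemble(members=[2.0] * 5)
        rng = np.random.default_rng(0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = assimilate_window(ens, _identity_adapter(), [1, 2, 3], None, cfg, rng)
        assert np.allclose(res.mean_lai, 2.0)

    def test_process_noise_increases_spread(self):
        doys = list(range(1, 11))
        members = [1.0] * 50
        for sd, expect_spread in [(0.0, False), (0.3, True)]:
            cfg = EnkfConfig(
                n_members=50, init_spread=0.0, process_noise_frac=0.0, process_noise_sd=sd
            )
            rng = np.random.default_rng(1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = assimilate_window(
                    Ensemble(members=list(members)), _identity_adapter(), doys, None, cfg, rng
                )
            spread = np.var([m for m in res.final_members])
            assert (spread > 0) == expect_spread

    def test_no_observations_warns_and_returns_forecast(self):
        cfg = EnkfConfig(n_members=3, init_spread=0.0, process_noise_frac=0.0)
        growth = CallableAdapter(fn=lambda x, t: 1.1 * x)
        with pytest.warns(RuntimeWarning):
            res = assimilate_window(
                Ensemble(members=[1.0, 1.0, 1.0]), growth, [1, 2, 3], None, cfg,
                np.random.default_rng(0),
            )
        assert np.allclose(res.mean_lai, [1.1, 1.21, 1.331])
        assert res.gain_records == []

    def test_noise_free_self_consistent_observations_leave_trajectory_unchanged(self):
        """Observing exactly the forecast with a zero-variance observation
        ensemble leaves the analysis-mean trajectory on the free run."""
        growth = CallableAdapter(fn=lambda x, t: 1.05 * x)
        doys = np.arange(1, 16)
        free = 2.0 * 1.05 ** np.arange(1, 16)
        obs = ObservationSeries(doys=doys, lai=free, obs_noise_sd=0.0)
        cfg = EnkfConfig(n_members=10, init_spread=0.0, process_noise_frac=0.0, guard=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = assimilate_window(
                Ensemble(members=[2.0] * 10), growth, doys, obs, cfg, np.random.default_rng(0)
            )
        assert np.allclose(res.mean_lai, free)

    def test_fixed_seed_bit_identical(self):
        doys = np.arange(1, 21)
        obs = ObservationSeries(doys=doys, lai=np.full(20, 2.0), obs_noise_sd=0.2)
        cfg = EnkfConfig(n_members=20, process_noise_sd=0.05)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            res = assimilate_window(
                Ensemble(members=list(np.linspace(1.0, 3.0, 20))),
                _identity_adapter(), doys, obs, cfg, rng,
            )
            outs.append(res.mean_lai)
        assert np.array_equal(outs[0], outs[1])

    def test_update_shrinks_ensemble_variance_without_guard(self):
        """The analysis step contracts the ensemble when the guard stays
        off (Kalman analysis variance is below the forecast variance)."""
        rng = np.random.default_rng(2)
        members = list(2.0 + rng.normal(0, 0.5, 4000))
        var_before = np.var(members, ddof=1)
        doys = np.array([1])
        obs = ObservationSeries(doys=doys, lai=np.array([2.5]), obs_noise_sd=0.5)
        cfg = EnkfConfig(n_members=4000, init_spread=0.0, process_noise_frac=0.0, guard=False)
        res = assimilate_window(Ensemble(members=members), _identity_adapter(), doys, obs, cfg, rng)
        var_after = np.var(res.final_members, ddof=1)
        assert var_after < var_before * 1.02

    def test_member_lai_floored_at_zero(self):
        doys = np.array([1])
        obs = ObservationSeries(doys=doys, lai=np.array([0.0]), obs_noise_sd=2.0)
        cfg = EnkfConfig(n_members=200, init_spread=0.0, process_noise_frac=0.0, guard=False, clip_gain=False)
        res = assimilate_window(
            Ensemble(members=list(np.linspace(0.1, 1.0, 200))), _identity_adapter(), doys, obs,
            cfg, np.random.default_rng(4),
        )
        assert min(res.final_members) >= 0.0

    def test_empty_window_rejected(self):
        cfg = EnkfConfig(n_members=2)
        with pytest.raises(InputError):
            assimilate_window(Ensemble(members=[1.0, 2.0]), _identity_adapter(), [], None, cfg,
                              np.random.default_rng(0))


class TestCropAdapter:
    def test_members_share_phenology_and_differ_in_lai(self, default_params, season_weather):
        adapter = CropEnsembleAdapter(params=default_params, weather=season_weather)
        state0 = crop.initial_state(default_params, season_weather[0].doy)
        cfg = EnkfConfig(n_members=5, init_spread=0.2, process_noise_frac=0.0)
        ens = initial_lai_ensemble(state0, adapter, cfg, np.random.default_rng(0))
        stepped = [adapter.step(m, 0) for m in ens.members]
        assert len({s.dvs for s in stepped}) == 1
        assert len({round(s.lai_green, 9) for s in stepped}) == 5

    def test_observation_series_validation(self):
        with pytest.raises(InputError):
            ObservationSeries(doys=np.array([3, 2]), lai=np.array([1.0, 1.0]))
        with pytest.raises(InputError):
            ObservationSeries(doys=np.array([1]), lai=np.array([-0.5]))
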