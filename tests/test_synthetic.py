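"""Synthetic scene generator: determinism, physical invariants, and the
saturation/senescence behaviours the late-season estimators must cope with."""

import numpy as np
import pytest

from maizelai import crop, synthetic
from maizelai.errors import InputError
from maizelai.indices import BandReflectance, compute_vi

BANDS = ("blue", "green", "red", "rededge", "nir")


class TestWeather:
    def test_single_day_has_valid_invariants(self):
        (day,) = synthetic.gen_weather(1, seed=42)
        assert day.tmax >= day.tmin
        assert day.radiation >= 0 and day.precip >= 0

    def test_same_seed_is_bit_identical(self):
        a = synthetic.gen_weather(50, seed=7)
        b = synthetic.gen_weather(50, seed=7)
        assert a == b
        c = synthetic.gen_weather(50, seed=8)
        assert a != c

    def test_invariants_hold_all_season(self, season_weather):
        for day in season_weather:
            assert day.tmax >= day.tmin
            assert day.radiation >= 0 and day.precip >= 0

    def test_seasonal_mean_temperature_matches_configuration(self):
        """The generated mean of (tmax+tmin)/2 tracks the configured
        seasonal sinusoid (the noise is zero-mean)."""
        cfg = synthetic.WeatherConfig()
        days = synthetic.gen_weather(160, start_doy=152, seed=1, config=cfg)
        gen_mean = np.mean([(d.tmax + d.tmin) / 2 for d in days])
        expected = cfg.seasonal_tmean(np.arange(152, 152 + 160)).mean()
        assert abs(gen_mean - expected) < 3 * cfg.temp_noise_sd / np.sqrt(160) + 0.5

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InputError):
            synthetic.gen_weather(0, seed=1)


class TestReflectance:
    def test_bare_soil_limit_is_exact(self, noise_free_scene):
        rho = synthetic.synth_reflectance(0.0, 0.0, noise_free_scene)
        assert np.allclose(rho, noise_free_scene.rho_soil)

    def test_dense_green_canopy_approaches_leaf_asymptote(self, noise_free_scene):
        rho = synthetic.synth_reflectance(50.0, 0.0, noise_free_scene)
        assert np.allclose(rho, noise_free_scene.rho_green, rtol=0.01)

    def test_one_optical_depth_formula(self, noise_free_scene):
        """At LAI = 1/k_b band b sits exactly at soil + (leaf-soil)(1-1/e)."""
        scene = noise_free_scene
        for b in range(5):
            lai = 1.0 / scene.k_b[b]
            rho = synthetic.synth_reflectance(lai, 0.0, scene)
            expected = scene.rho_soil[b] + (scene.rho_green[b] - scene.rho_soil[b]) * (
                1.0 - np.exp(-scene.k_b[b] * lai)
            )
            assert rho[b] == pytest.approx(expected, abs=1e-12)

    def test_negative_lai_rejected(self, noise_free_scene):
        with pytest.raises(InputError):
            synthetic.synth_reflectance(-0.1, 0.0, noise_free_scene)

    def test_ndvi_saturates_concavely_in_green_lai(self, noise_free_scene):
        """NDVI from noise-free reflectance rises with green LAI but with
        strictly shrinking increments — the saturation that breaks
        index-based retrieval at high LAI."""
        lais = np.arange(0.2, 6.0, 0.2)
        ndvi = []
        for lai in lais:
            rho = synthetic.synth_reflectance(lai, 0.0, noise_free_scene)
            ndvi.append(compute_vi(BandReflectance(**dict(zip(BANDS, rho))), "NDVI"))
        inc = np.diff(ndvi)
        assert np.all(inc > 0)
        assert np.all(np.diff(inc) < 0)

    def test_browning_shifts_spectrum(self, noise_free_scene):
        """At fixed total LAI more brown leaf lowers NIR toward the brown
        asymptote and raises red reflectance."""
        total = 4.0
        fracs = np.linspace(0.0, 1.0, 6)
        rho = np.array(
            [synthetic.synth_reflectance(total * (1 - f), total * f, noise_free_scene) for f in fracs]
        )
        nir, red = rho[:, 4], rho[:, 2]
        assert np.all(np.diff(nir) < 0)
        assert np.all(np.diff(red) > 0)


@pytest.fixture(scope="module")
def small_scene(default_params, season_weather, noise_free_scene):
    san = synthetic.gen_san(4, seed=5)
    return synthetic.gen_truth_and_obs(default_params, season_weather, san, scene=noise_free_scene)


class TestTruthAndObs:

    def test_zero_noise_obs_equal_truth_on_campaign_days(self, small_scene):
        merged = small_scene.field_obs.merge(
            small_scene.truth, on=["quadrat_id", "doy"], how="left"
        )
        assert np.allclose(merged["lai"], merged["lai_green"])

    def test_identical_san_and_seed_give_identical_trajectories(
        self, default_params, season_weather, noise_free_scene
    ):
        rec = crop.SanRecord("QA", 200.0, 40.0, 150.0)
        twin = crop.SanRecord("QB", 200.0, 40.0, 150.0)
        out = synthetic.gen_truth_and_obs(
            default_params, season_weather, [rec, twin], scene=noise_free_scene
        )
        a = out.truth_for("QA")["lai_green"].to_numpy()
        b = out.truth_for("QB")["lai_green"].to_numpy()
        assert np.array_equal(a, b)

    def test_richer_soil_gives_larger_peak_lai(self, default_params, season_weather, noise_free_scene):
        lo = crop.SanRecord("LO", 40.0, 10.0, 20.0)
        hi = crop.SanRecord("HI", 410.0, 80.0, 340.0)
        out = synthetic.gen_truth_and_obs(
            default_params, season_weather, [lo, hi], scene=noise_free_scene
        )
        assert out.truth_for("HI")["lai_green"].max() > out.truth_for("LO")["lai_green"].max()

    def test_brown_lai_appears_only_later_in_season(self, small_scene):
        truth = small_scene.truth_for(small_scene.san[0].quadrat_id)
        early = truth[truth.dvs < 0.5]["lai_brown"]
        late = truth[truth.dvs > 1.5]["lai_brown"]
        assert np.all(early == 0)
        assert late.min() > 0

    def test_campaign_outside_season_rejected(self, default_params, season_weather, noise_free_scene):
        san = synthetic.gen_san(2, seed=0)
        with pytest.raises(InputError):
            synthetic.gen_truth_and_obs(
                default_params, season_weather, san, campaign_doys=(999,), scene=noise_free_scene
            )

    def test_scene_determinism(self, default_params, season_weather):
        scene = synthetic.SceneParams(seed=9)
        san = synthetic.gen_san(3, seed=9)
        a = synthetic.gen_truth_and_obs(default_params, season_weather, san, scene=scene)
        b = synthetic.gen_truth_and_obs(default_params, season_weather, san, scene=scene)
        assert a.field_obs.equals(b.field_obs)
        assert a.reflectance.equals(b.reflectance)


class TestRoundTrips:
    def test_weather_and_san_csv_round_trip(self, season_weather, tmp_path):
        p = tmp_path / "weather.csv"
        synthetic.write_weather_csv(season_weather, p)
        back = synthetic.read_weather_csv(p)
        assert [w.doy for w in back] == [w.doy for w in season_weather]
        for field in ("tmin", "tmax", "radiation", "precip"):
            assert np.allclose(
                [getattr(w, field) for w in back],
                [getattr(w, field) for w in season_weather],
                rtol=1e-12, atol=1e-12,
            )
        san = synthetic.gen_san(5, seed=2)
        q = tmp_path / "san.csv"
        synthetic.write_san_csv(san, q)
        back_san = synthetic.read_san_csv(q)
        assert [r.quadrat_id for r in back_san] == [r.quadrat_id for r in san]
        assert np.allclose(
            [(r.n_avail, r.p_avail, r.k_avail) for r in back_san],
            [(r.n_avail, r.p_avail, r.k_avail) for r in san],
            rtol=1e-12,
        )

    def test_observation_and_reflectance_csv_round_trip(self, small_scene, tmp_path):
        p_obs, p_refl = tmp_path / "obs.csv", tmp_path / "refl.csv"
        synthetic.write_observations_csv(small_scene.field_obs, p_obs)
        back = synthetic.read_observations_csv(p_obs)
        assert list(back.columns) == ["quadrat_id", "doy", "lai"]
        assert np.allclose(back["lai"], small_scene.field_obs["lai"])
        synthetic.write_reflectance_csv(small_scene.reflectance, p_refl)
        back = synthetic.read_reflectance_csv(p_refl)
        assert list(back.columns) == ["quadrat_id", "doy", *BANDS]
        assert np.allclose(back["nir"], small_scene.reflectance["nir"])
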