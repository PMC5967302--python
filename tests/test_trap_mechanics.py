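"""Equipartition calibration, trap force, and force-extension analysis."""

import numpy as np
import pytest
from scipy import stats

from myoquant import (
    BOLTZMANN_PN_UM,
    BeadTrack,
    DegenerateTrackError,
    ForceExtensionCurve,
    InvalidParameterError,
    NoLinearRegionError,
    StageTrack,
    TetherSimParams,
    TrapCalibration,
    TrapSimParams,
    force_extension_curve,
    force_from_displacement,
    linear_region_fit,
    simulate_tether_pull,
    simulate_trapped_bead,
    stiffness_equipartition,
    thermal_energy,
)


class TestThermalEnergy:
    @pytest.mark.parametrize(
        "temperature, expected",
        [(0.0, 0.0), (298.15, 4.1164e-3), (296.15, 4.0888e-3)],
    )
    def test_kbt_values(self, temperature, expected):
        assert thermal_energy(temperature) == pytest.approx(expected, rel=1e-4)

    def test_negative_temperature_rejected(self):
        with pytest.raises(InvalidParameterError):
            thermal_energy(-1.0)


def _gaussian_track(variance, n=20_000, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, np.sqrt(variance), n)
    return BeadTrack(times=np.arange(n) * 1e-3, x=x)


class TestStiffnessEquipartition:
    def test_exact_gaussian_sample_recovers_k(self):
        track = _gaussian_track(1.0e-2, seed=1)
        calib = stiffness_equipartition(track, temperature=298.15)
        assert calib.k_x == pytest.approx(4.1164e-3 / 1.0e-2, rel=0.02)

    def test_gaussian_fit_and_direct_variance_agree(self):
        track = _gaussian_track(5.0e-4, seed=2)
        k_fit = stiffness_equipartition(track, method="gaussian_fit").k_x
        k_dir = stiffness_equipartition(track, method="direct_variance").k_x
        assert k_fit == pytest.approx(k_dir, rel=0.02)

    def test_constant_positions_are_degenerate(self):
        track = BeadTrack(times=np.arange(200) * 1e-3, x=np.zeros(200))
        with pytest.raises(DegenerateTrackError):
            stiffness_equipartition(track)

    def test_too_few_samples_rejected(self):
        track = BeadTrack(times=np.arange(50) * 1e-3, x=np.random.default_rng(0).normal(size=50))
        with pytest.raises(InvalidParameterError):
            stiffness_equipartition(track)

    def test_recovers_calibration_stiffness_on_ou_fixture(self):
        # 10 s at 1000 frames/s, the recording condition behind k = 7.29 pN/um
        params = TrapSimParams(stiffness=7.29, temperature=296.15, seed=13)
        track = simulate_trapped_bead(params)
        calib = stiffness_equipartition(track, temperature=296.15)
        assert abs(calib.k_x - 7.29) < 0.50

    def test_unbiased_across_seeds_direct_variance(self):
        ks = []
        for seed in range(20):
            track = simulate_trapped_bead(
                TrapSimParams(stiffness=7.29, temperature=296.15, seed=seed)
            )
            ks.append(
                stiffness_equipartition(
                    track, temperature=296.15, method="direct_variance"
                ).k_x
            )
        ks = np.asarray(ks)
        assert np.mean(ks) == pytest.approx(
            7.29, abs=3 * np.std(ks, ddof=1) / np.sqrt(len(ks))
        )

    def test_position_rescaling_divides_k_by_square(self):
        # dimensional audit: x -> c*x implies variance -> c^2 var, k -> k/c^2
        track = _gaussian_track(1e-3, seed=3)
        scaled = BeadTrack(times=track.times, x=track.x * 2.0)
        k1 = stiffness_equipartition(track, method="direct_variance").k_x
        k2 = stiffness_equipartition(scaled, method="direct_variance").k_x
        assert k2 == pytest.approx(k1 / 4.0, rel=1e-12)

    def test_second_axis_calibrated_independently(self):
        rng = np.random.default_rng(5)
        n = 20_000
        track = BeadTrack(
            times=np.arange(n) * 1e-3,
            x=rng.normal(0, 0.02, n),
            y=rng.normal(0, 0.01, n),
        )
        calib = stiffness_equipartition(track, method="direct_variance")
        assert calib.k_y == pytest.approx(4 * calib.k_x, rel=0.1)


class TestTrapForce:
    def test_zero_displacement_zero_force(self):
        assert force_from_displacement(7.29, 0.0) == 0.0

    def test_linear_readout(self):
        assert force_from_displacement(7.29, 0.5) == pytest.approx(3.645)
        assert force_from_displacement(7.29, 1.0) == pytest.approx(
            2 * force_from_displacement(7.29, 0.5)
        )
        assert force_from_displacement(5.0, -0.1) == pytest.approx(-0.5)

    def test_nonpositive_stiffness_rejected(self):
        with pytest.raises(InvalidParameterError):
            force_from_displacement(0.0, 0.1)


def _external_calib(k):
    return TrapCalibration(
        k_x=k, temperature=296.15, n_frames=0, method="external", variance_x=1.0
    )


class TestForceExtensionCurve:
    def test_stationary_bead_gives_zero_force(self):
        times = np.arange(0.0, 5.0, 0.01)
        bead = BeadTrack(times=times, x=np.zeros_like(times))
        stage = StageTrack(times=times, position=1.0 * times)
        curve = force_extension_curve(bead, stage, _external_calib(10.0))
        assert np.all(curve.force == 0.0)

    def test_series_spring_slope(self):
        bead, stage = simulate_tether_pull(
            TetherSimParams(stiffness=10.0, tether_stiffness=10.0, noise_sd=0.0)
        )
        curve = force_extension_curve(bead, stage, _external_calib(10.0))
        fit = linear_region_fit(curve)
        assert fit.slope == pytest.approx(5.0, rel=1e-9)

    def test_tether_axis_recovers_tether_stiffness(self):
        p = TetherSimParams(stiffness=7.29, tether_stiffness=13.0, noise_sd=0.0)
        bead, stage = simulate_tether_pull(p)
        curve = force_extension_curve(
            bead, stage, _external_calib(7.29), axis="tether"
        )
        fit = linear_region_fit(curve)
        assert fit.slope == pytest.approx(13.0, rel=1e-6)

    def test_constant_deviation_constant_force(self):
        times = np.arange(0.0, 2.0, 0.01)
        bead = BeadTrack(times=times, x=np.full_like(times, 0.1))
        stage = StageTrack(times=times, position=times)
        curve = force_extension_curve(bead, stage, _external_calib(5.0))
        np.testing.assert_allclose(curve.force, 0.5)

    def test_disjoint_time_support_rejected(self):
        bead = BeadTrack(times=np.arange(0.0, 1.0, 0.01), x=np.zeros(100))
        stage = StageTrack(times=np.arange(5.0, 6.0, 0.01), position=np.arange(100.0))
        with pytest.raises(InvalidParameterError):
            force_extension_curve(bead, stage, _external_calib(5.0))

    def test_slope_invariant_to_time_origin(self):
        p = TetherSimParams(stiffness=8.0, tether_stiffness=12.0, noise_sd=0.0)
        bead, stage = simulate_tether_pull(p)
        shifted_bead = BeadTrack(times=bead.times + 3.0, x=bead.x)
        shifted_stage = StageTrack(times=stage.times + 3.0, position=stage.position)
        s0 = linear_region_fit(
            force_extension_curve(bead, stage, _external_calib(8.0))
        ).slope
        s1 = linear_region_fit(
            force_extension_curve(shifted_bead, shifted_stage, _external_calib(8.0))
        ).slope
        assert s1 == pytest.approx(s0, rel=1e-12)


def _curve(x, y):
    return ForceExtensionCurve(
        times=np.asarray(x, float), extension=np.asarray(x, float),
        force=np.asarray(y, float), axis="stage", stiffness=1.0,
    )


class TestLinearRegionFit:
    def test_exact_line_uses_full_curve(self):
        x = np.linspace(0.0, 2.0, 60)
        fit = linear_region_fit(_curve(x, 2.0 * x))
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert (fit.start, fit.stop) == (0, 60)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noiseless_changepoint_localized_within_one_sample(self):
        x = np.arange(0.0, 2.0 + 1e-9, 0.02)  # 101 samples, kink at index 50
        y = np.where(x <= 1.0, 3.0 * x, 3.0)
        fit = linear_region_fit(_curve(x, y))
        assert fit.slope == pytest.approx(3.0, rel=1e-9)
        assert abs(fit.stop - 51) <= 1  # stop is exclusive; x[50] = 1.0

    def test_noisy_line_slope_within_ols_confidence_interval(self):
        rng = np.random.default_rng(17)
        x = np.linspace(0.0, 1.0, 200)
        y = 4.0 * x + rng.normal(0.0, 0.02, x.size)
        fit = linear_region_fit(_curve(x, y))
        oracle = stats.linregress(x[: fit.stop], y[: fit.stop])
        assert fit.slope == pytest.approx(oracle.slope, rel=1e-9)
        assert abs(fit.slope - 4.0) < 1.96 * oracle.stderr * 1.3

    def test_too_short_curve_rejected(self):
        with pytest.raises(NoLinearRegionError):
            linear_region_fit(_curve(np.arange(5.0), np.arange(5.0)))

    def test_immediately_nonlinear_curve_rejected(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0.0, 1.0, 50)
        y = rng.normal(0.0, 1.0, x.size)  # pure noise: no linear prefix
        with pytest.raises(NoLinearRegionError):
            linear_region_fit(_curve(x, y), r2_min=0.98)
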