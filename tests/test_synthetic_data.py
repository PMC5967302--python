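"""Generators: physical correctness, ground-truth bookkeeping, determinism."""

import numpy as np
import pytest

from myoquant import (
    BOLTZMANN_PN_UM,
    CellSpec,
    CorticalSpec,
    FieldSpec,
    GenerationError,
    InvalidParameterError,
    PopulationSpec,
    TetherSimParams,
    TraceSpec,
    TrapSimParams,
    fraction_positive,
    generate_cortical_image,
    generate_fura2_trace,
    generate_intensity_population,
    generate_syncytium_field,
    sample_field_spec,
    simulate_tether_pull,
    simulate_trapped_bead,
    stokes_drag,
)


class TestTrappedBeadOU:
    def test_zero_temperature_from_trap_centre_stays_at_zero(self):
        track = simulate_trapped_bead(
            TrapSimParams(temperature=0.0, x0=0.0, n_frames=500, seed=1)
        )
        assert np.all(track.x == 0.0)

    def test_zero_temperature_relaxes_exponentially(self):
        p = TrapSimParams(temperature=0.0, x0=0.2, n_frames=100, seed=1)
        track = simulate_trapped_bead(p)
        tau = p.drag / p.stiffness
        expected = 0.2 * np.exp(-track.times / tau)
        np.testing.assert_allclose(track.x, expected, rtol=1e-10)

    def test_same_seed_reproduces_identical_track(self):
        p = TrapSimParams(n_frames=2000, seed=42)
        a = simulate_trapped_bead(p)
        b = simulate_trapped_bead(p)
        np.testing.assert_array_equal(a.x, b.x)

    def test_stationary_variance_matches_equipartition(self):
        # dt >> tau (~2 ms) so samples are nearly independent
        p = TrapSimParams(
            stiffness=7.29, temperature=298.15, dt=0.05, n_frames=100_000, seed=7
        )
        track = simulate_trapped_bead(p)
        expected = BOLTZMANN_PN_UM * 298.15 / 7.29  # ~5.65e-4 um^2
        se = expected * np.sqrt(2.0 / (p.n_frames - 1))
        assert abs(np.var(track.x, ddof=1) - expected) < 3 * se

    def test_lag_autocorrelation_decays_at_rate_k_over_gamma(self):
        p = TrapSimParams(dt=1e-3, n_frames=200_000, seed=11)
        track = simulate_trapped_bead(p)
        tau = p.drag / p.stiffness
        x = track.x - track.x.mean()
        for lag in (1, 2, 4):
            rho_hat = np.dot(x[:-lag], x[lag:]) / np.dot(x, x)
            assert rho_hat == pytest.approx(np.exp(-lag * p.dt / tau), abs=0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dt": 0.0},
            {"drag": -1.0},
            {"stiffness": 0.0},
            {"n_frames": 1},
            {"temperature": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            TrapSimParams(**kwargs)

    def test_stokes_drag_for_study_bead_gives_2ms_relaxation(self):
        gamma = stokes_drag()  # 1.76-um bead in water at 23 C
        tau = gamma / 7.29
        assert 1e-3 < tau < 4e-3


class TestTetherPull:
    def test_no_tether_means_no_bead_motion(self):
        bead, stage = simulate_tether_pull(TetherSimParams(tether_stiffness=0.0))
        assert np.all(bead.x == 0.0)
        assert stage.position[-1] == pytest.approx(5.0)  # 1 um/s for 5 s

    def test_force_vs_stage_slope_is_series_stiffness(self):
        p = TetherSimParams(stiffness=10.0, tether_stiffness=10.0, noise_sd=0.0)
        bead, stage = simulate_tether_pull(p)
        force = p.stiffness * bead.x
        slope = np.polyfit(stage.position, force, 1)[0]
        assert slope == pytest.approx(5.0, rel=1e-12)

    def test_force_vs_tether_extension_slope_is_tether_stiffness(self):
        p = TetherSimParams(stiffness=7.29, tether_stiffness=13.0, noise_sd=0.0)
        bead, stage = simulate_tether_pull(p)
        force = p.stiffness * bead.x
        extension = stage.position - bead.x
        slope = np.polyfit(extension[1:], force[1:], 1)[0]
        assert slope == pytest.approx(13.0, rel=1e-9)

    def test_negative_speed_rejected(self):
        with pytest.raises(InvalidParameterError):
            TetherSimParams(speed=-1.0)


def _three_cell_spec(counts=(60, 10, 5), seed=0):
    cells = [
        CellSpec(center=(60.0, 64.0), semi_axes=(40.0, 15.0), orientation=0.0,
                 nucleus_count=counts[0]),
        CellSpec(center=(160.0, 60.0), semi_axes=(20.0, 10.0), orientation=1.0,
                 nucleus_count=counts[1]),
        CellSpec(center=(180.0, 180.0), semi_axes=(25.0, 12.0), orientation=2.0,
                 nucleus_count=counts[2]),
    ]
    return FieldSpec(image_shape=(256, 256), cells=cells, noise_sd=0.0, seed=seed)


class TestSyncytiumField:
    def test_ground_truth_fusion_index_by_direct_count(self):
        from myoquant import MorphometryConfig

        field = generate_syncytium_field(
            _three_cell_spec(), MorphometryConfig(fusion_nuclei_threshold=50)
        )
        assert field.truth.fusion_index == pytest.approx(100 * 60 / 75)

    def test_all_mononucleated_gives_zero_fusion(self):
        spec = _three_cell_spec(counts=(1, 1, 1))
        field = generate_syncytium_field(spec)
        assert field.truth.fusion_index == 0.0

    def test_ground_truth_aspect_ratio_is_semi_axis_ratio(self):
        cell = CellSpec(center=(0, 0), semi_axes=(40.0, 10.0))
        assert cell.aspect_ratio == 4.0

    def test_nuclei_land_inside_their_own_cell(self):
        field = generate_syncytium_field(_three_cell_spec())
        rows = np.rint(field.nuclei["y_px"]).astype(int)
        cols = np.rint(field.nuclei["x_px"]).astype(int)
        assert np.array_equal(
            field.label_mask[rows, cols], field.nuclei["label"].to_numpy()
        )

    def test_fixed_seed_reproduces_field_exactly(self):
        a = generate_syncytium_field(_three_cell_spec(seed=5))
        b = generate_syncytium_field(_three_cell_spec(seed=5))
        np.testing.assert_array_equal(a.label_mask, b.label_mask)
        np.testing.assert_array_equal(a.myhc, b.myhc)
        assert a.nuclei.equals(b.nuclei)

    def test_overlapping_cells_raise_generation_error(self):
        cells = [
            CellSpec(center=(100.0, 100.0), semi_axes=(30.0, 20.0)),
            CellSpec(center=(110.0, 110.0), semi_axes=(30.0, 20.0)),
        ]
        with pytest.raises(GenerationError):
            generate_syncytium_field(FieldSpec(cells=cells))

    def test_sampled_layouts_are_valid_and_deterministic(self):
        spec_a = sample_field_spec(seed=9, n_cells=4)
        spec_b = sample_field_spec(seed=9, n_cells=4)
        assert spec_a == spec_b
        field = generate_syncytium_field(spec_a)
        assert field.label_mask.max() == 4


class TestCorticalImage:
    def test_equal_levels_give_uniform_interior(self):
        spec = CorticalSpec(cortex_level=50.0, interior_level=50.0, noise_sd=0.0)
        mask, image = generate_cortical_image(spec)
        assert np.all(image[mask] == 50.0)
        assert np.all(image[~mask] == 0.0)

    def test_fixed_seed_reproduces_image(self):
        spec = CorticalSpec(noise_sd=3.0, seed=2)
        _, a = generate_cortical_image(spec)
        _, b = generate_cortical_image(spec)
        np.testing.assert_array_equal(a, b)

    def test_cortex_depth_must_fit_inside_minor_axis(self):
        with pytest.raises(InvalidParameterError):
            CorticalSpec(semi_axes=(30.0, 5.0), cortex_depth=5.0)


class TestFura2Trace:
    def test_zero_amplitude_gives_constant_baseline(self):
        trace = generate_fura2_trace(TraceSpec(amplitude=0.0, noise_sd=0.0))
        assert np.all(trace.values == 1.0)

    def test_sampling_grid_is_inclusive(self):
        trace = generate_fura2_trace(
            TraceSpec(sampling_interval=10.0, duration=600.0)
        )
        assert trace.times.size == 61
        assert trace.times[-1] == 600.0

    def test_onset_beyond_duration_rejected(self):
        with pytest.raises(InvalidParameterError):
            TraceSpec(onset_time=700.0, duration=600.0)


class TestIntensityPopulation:
    def test_zero_positive_fraction_draws_only_negatives(self):
        pop = generate_intensity_population(
            PopulationSpec(positive_fraction=0.0, n_cells=5000, seed=3)
        )
        assert not pop.is_positive.any()

    def test_fixed_seed_reproduces_population(self):
        spec = PopulationSpec(seed=8)
        a = generate_intensity_population(spec)
        b = generate_intensity_population(spec)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_gated_fraction_recovers_mixture_weight(self):
        spec = PopulationSpec(positive_fraction=0.2, n_cells=100_000, seed=4)
        pop = generate_intensity_population(spec)
        threshold = np.exp(
            0.5 * (spec.log_mean_negative + spec.log_mean_positive)
        )  # geometric midpoint of the well-separated components
        se_pct = 100 * np.sqrt(0.2 * 0.8 / spec.n_cells)
        assert fraction_positive(pop.intensities, threshold) == pytest.approx(
            20.0, abs=3 * se_pct + 0.3
        )
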