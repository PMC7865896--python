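"""Backpropagation decoding and the support-constrained recovery loop."""

import numpy as np
import pytest

from holochip import (
    ObjectClass,
    RecoveryConfig,
    backpropagate_hologram,
    estimate_support,
    iterate_phase_recovery,
    make_disc_phantom,
    normalize_hologram,
    phantom_from_discs,
    record_background,
    record_hologram,
)
from holochip.simulator import DiscObject, SensorImage


@pytest.fixture
def disc_scene(geometry_256):
    """A seeded 8-disc phantom with its hologram and background."""
    phantom = make_disc_phantom(
        geometry_256,
        n_cells=5,
        n_particles=3,
        seed=21,
        margin_px=12,
        min_separation_m=10e-6,
    )
    hologram = record_hologram(phantom)
    background = record_background(geometry_256)
    return phantom, hologram, background


class TestNormalize:
    def test_empty_field_divides_to_unity(self, geometry_256):
        background = record_background(geometry_256)
        hologram = SensorImage(
            background.intensity.copy(), geometry_256, kind="hologram"
        )
        out = normalize_hologram(hologram, background, mode="divide")
        np.testing.assert_allclose(out, 1.0, atol=1e-12)

    def test_absent_background_none_mode_is_identity(self, geometry_256):
        hologram = record_background(geometry_256)
        out = normalize_hologram(hologram, None, mode="none")
        np.testing.assert_array_equal(out, hologram.intensity)

    def test_absent_background_warns(self, geometry_256):
        hologram = record_background(geometry_256)
        with pytest.warns(UserWarning, match="background"):
            normalize_hologram(hologram, None, mode="divide")

    def test_divide_flattens_far_field(self, disc_scene, geometry_256):
        phantom, hologram, background = disc_scene
        out = normalize_hologram(hologram, background, mode="divide")
        rr, cc = np.mgrid[0 : geometry_256.grid_rows, 0 : geometry_256.grid_cols]
        far = np.ones(geometry_256.shape, dtype=bool)
        pitch = geometry_256.pixel_pitch
        for obj in phantom.objects:
            r_px = obj.radius_m / pitch
            far &= (rr - obj.center_row) ** 2 + (cc - obj.center_col) ** 2 > (
                8 * r_px
            ) ** 2
        assert far.any()
        assert abs(out[far].mean() - 1.0) < 1e-3
        assert abs(np.median(out[far]) - 1.0) < 1e-3

    def test_subtract_mode_keeps_scale(self, disc_scene):
        _, hologram, background = disc_scene
        out = normalize_hologram(hologram, background, mode="subtract")
        assert np.all(out >= 0)
        assert out.mean() == pytest.approx(hologram.intensity.mean(), rel=1e-2)

    def test_shape_mismatch_rejected(self, geometry_256, geometry_32):
        hologram = record_background(geometry_256)
        background = record_background(geometry_32)
        with pytest.raises(ValueError, match="shape"):
            normalize_hologram(hologram, background, mode="divide")

    def test_all_zero_background_rejected(self, geometry_256):
        hologram = record_background(geometry_256)
        zero = SensorImage(
            np.zeros(geometry_256.shape), geometry_256, kind="background"
        )
        with pytest.raises(ValueError, match="zero"):
            normalize_hologram(hologram, zero, mode="divide")


class TestBackpropagate:
    def test_uniform_intensity_gives_uniform_modulus(self, geometry_256):
        out = backpropagate_hologram(np.full(geometry_256.shape, 4.0), geometry_256)
        np.testing.assert_allclose(out.modulus, 2.0, atol=1e-10)

    def test_disc_localized_at_ground_truth_position(self, geometry_256):
        phantom = phantom_from_discs(
            geometry_256,
            [DiscObject(130.0, 105.0, 7.5e-6, ObjectClass.PARTICLE, 0.3)],
        )
        hologram = record_hologram(phantom)
        background = record_background(geometry_256)
        normalized = normalize_hologram(hologram, background, "divide")
        field = backpropagate_hologram(normalized, geometry_256)
        # mild smoothing makes the argmin robust to single-pixel twin ringing
        from scipy.ndimage import gaussian_filter

        smoothed = gaussian_filter(field.modulus, 2.0)
        r, c = np.unravel_index(np.argmin(smoothed), smoothed.shape)
        assert abs(r - 130.0) <= 2 and abs(c - 105.0) <= 2

    def test_negative_intensity_rejected(self, geometry_256):
        bad = np.full(geometry_256.shape, -1.0)
        with pytest.raises(ValueError):
            backpropagate_hologram(bad, geometry_256)


class TestSupport:
    def test_constant_field_yields_empty_flagged_support(self, geometry_256):
        field = backpropagate_hologram(np.ones(geometry_256.shape), geometry_256)
        with pytest.warns(UserWarning, match="constant"):
            support = estimate_support(field)
        assert support.is_empty

    def test_components_match_ground_truth_discs(self, disc_scene, geometry_256):
        from skimage.measure import label, regionprops

        phantom, hologram, background = disc_scene
        normalized = normalize_hologram(hologram, background, "divide")
        field = backpropagate_hologram(normalized, geometry_256)
        support = estimate_support(field)
        components = label(support.mask, connectivity=2)
        assert components.max() == len(phantom.objects)
        pitch = geometry_256.pixel_pitch
        for prop in regionprops(components):
            cy, cx = prop.centroid
            hits = [
                obj
                for obj in phantom.objects
                if (cy - obj.center_row) ** 2 + (cx - obj.center_col) ** 2
                <= (obj.radius_m / pitch) ** 2
            ]
            assert len(hits) == 1

    def test_dilation_covers_every_disc(self, disc_scene, geometry_256):
        phantom, hologram, background = disc_scene
        normalized = normalize_hologram(hologram, background, "divide")
        field = backpropagate_hologram(normalized, geometry_256)
        support = estimate_support(field)
        pitch = geometry_256.pixel_pitch
        rr, cc = np.mgrid[0 : geometry_256.grid_rows, 0 : geometry_256.grid_cols]
        for obj in phantom.objects:
            disc = (rr - obj.center_row) ** 2 + (cc - obj.center_col) ** 2 <= (
                obj.radius_m / pitch
            ) ** 2
            assert support.mask[disc].sum() >= disc.sum()


class TestIteration:
    def test_empty_phantom_converges_immediately(self, geometry_256):
        phantom = make_disc_phantom(geometry_256, 0, 0, seed=0)
        hologram = record_hologram(phantom)
        background = record_background(geometry_256)
        with pytest.warns(UserWarning):
            result = iterate_phase_recovery(
                hologram, background, geometry_256, RecoveryConfig()
            )
        assert result.converged
        assert result.iterations_run == 1
        assert np.ptp(result.object_field.modulus) < 1e-6

    def test_converges_within_budget(self, disc_scene, geometry_256):
        _, hologram, background = disc_scene
        result = iterate_phase_recovery(
            hologram, background, geometry_256, RecoveryConfig()
        )
        assert result.converged
        assert result.iterations_run <= 15
        assert len(result.residual_history) == result.iterations_run
        assert all(r >= 0 for r in result.residual_history)
        assert result.residual_history[-1] <= result.residual_history[0]
        assert result.residual_history[-1] < RecoveryConfig().convergence_tol

    def test_twin_image_suppression_lowers_rmse(self, disc_scene, geometry_256):
        phantom, hologram, background = disc_scene
        result = iterate_phase_recovery(
            hologram, background, geometry_256, RecoveryConfig()
        )
        truth = np.abs(phantom.transmittance)
        rmse_recovered = np.sqrt(np.mean((result.object_field.modulus - truth) ** 2))
        rmse_naive = np.sqrt(np.mean((result.naive_field.modulus - truth) ** 2))
        assert rmse_recovered < rmse_naive

    def test_ringing_variance_outside_support_reduced(self, disc_scene, geometry_256):
        _, hologram, background = disc_scene
        result = iterate_phase_recovery(
            hologram, background, geometry_256, RecoveryConfig()
        )
        outside = ~result.support.mask
        assert result.object_field.modulus[outside].var() < result.naive_field.modulus[
            outside
        ].var()

    def test_sensor_modulus_constraint_held_exactly(self, disc_scene, geometry_256):
        _, hologram, background = disc_scene
        result = iterate_phase_recovery(
            hologram, background, geometry_256, RecoveryConfig()
        )
        assert result.sensor_constraint_error < 1e-12

    def test_bit_identical_determinism(self, disc_scene, geometry_256):
        _, hologram, background = disc_scene
        a = iterate_phase_recovery(hologram, background, geometry_256, RecoveryConfig())
        b = iterate_phase_recovery(hologram, background, geometry_256, RecoveryConfig())
        np.testing.assert_array_equal(a.object_field.values, b.object_field.values)
        assert a.residual_history == b.residual_history
        assert a.iterations_run == b.iterations_run

    def test_recovered_modulus_rank_orders_transmittance(self, geometry_256):
        # three discs at three transmittance levels: recovered per-object
        # means must sort identically to ground truth (Spearman rho = 1)
        levels = [0.3, 0.5, 0.7]
        discs = [
            DiscObject(64.0, 64.0, 9e-6, ObjectClass.CELL, levels[0]),
            DiscObject(128.0, 160.0, 9e-6, ObjectClass.CELL, levels[1]),
            DiscObject(192.0, 80.0, 9e-6, ObjectClass.CELL, levels[2]),
        ]
        phantom = phantom_from_discs(geometry_256, discs)
        hologram = record_hologram(phantom)
        background = record_background(geometry_256)
        result = iterate_phase_recovery(
            hologram, background, geometry_256, RecoveryConfig()
        )
        rr, cc = np.mgrid[0 : geometry_256.grid_rows, 0 : geometry_256.grid_cols]
        pitch = geometry_256.pixel_pitch
        recovered_means = []
        for obj in discs:
            disc = (rr - obj.center_row) ** 2 + (cc - obj.center_col) ** 2 <= (
                obj.radius_m / pitch
            ) ** 2
            recovered_means.append(result.object_field.modulus[disc].mean())
        assert np.argsort(recovered_means).tolist() == [0, 1, 2]

    def test_missing_background_falls_back_with_warning(self, disc_scene, geometry_256):
        _, hologram, _ = disc_scene
        with pytest.warns(UserWarning, match="background"):
            result = iterate_phase_recovery(
                hologram, None, geometry_256, RecoveryConfig()
            )
        assert result.iterations_run >= 1

    def test_non_convergence_reported_not_raised(self, disc_scene, geometry_256):
        _, hologram, background = disc_scene
        config = RecoveryConfig(max_iterations=2, convergence_tol=1e-9)
        result = iterate_phase_recovery(hologram, background, geometry_256, config)
        assert not result.converged
        assert result.iterations_run == 2

    def test_support_update_option_still_converges(self, disc_scene, geometry_256):
        _, hologram, background = disc_scene
        config = RecoveryConfig(support_update_every=3)
        result = iterate_phase_recovery(hologram, background, geometry_256, config)
        assert result.iterations_run <= 15

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RecoveryConfig(max_iterations=0)
        with pytest.raises(ValueError):
            RecoveryConfig(convergence_tol=-1.0)
        with pytest.raises(ValueError):
            RecoveryConfig(background_mode="multiply")
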