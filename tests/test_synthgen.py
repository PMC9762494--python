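"""Generators: analytic porosities, determinism, curve and record round trips."""

import numpy as np
import pytest

from eecm import (
    CurveSpec,
    NoiseSpec,
    PhantomSpec,
    generate_channel_phantom,
    generate_falling_head_record,
    generate_fiber_phantom,
    generate_plate_phantom,
    generate_stress_strain,
    render_grayscale,
)
from eecm.mechanics import uniaxial_stress
from eecm.morphometry import compute_porosity, compute_tortuosity, percolates
from eecm.permeability import falling_head_permeability


class TestChannelPhantom:
    def test_pore_fraction_matches_cylinder_area(self):
        vol = generate_channel_phantom((64, 64, 64), 1.0, 16.0, axis="z")
        analytic = np.pi * 16.0**2 / 64.0**2
        assert compute_porosity(vol) == pytest.approx(analytic, rel=0.03)

    def test_channel_runs_straight_along_requested_axis(self):
        vol = generate_channel_phantom((32, 32, 32), 1.0, 0.4 * 32, axis="x")
        assert percolates(vol.pore, "x")
        assert compute_tortuosity(vol, "pore", "x") == pytest.approx(1.0)

    def test_deterministic(self):
        a = generate_channel_phantom((32, 32, 32), 1.0, 8.0)
        b = generate_channel_phantom((32, 32, 32), 1.0, 8.0)
        assert np.array_equal(a.solid, b.solid)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            generate_channel_phantom((32, 32, 32), 1.0, 17.0)


class TestPlatePhantom:
    def test_porosity_exact_slab_fraction(self):
        vol = generate_plate_phantom((64, 64, 64), 1.0, 16.0, normal_axis="z")
        assert compute_porosity(vol) == 16.0 / 64.0

    def test_full_gap_degenerates_to_all_pore(self):
        vol = generate_plate_phantom((32, 32, 32), 1.0, 32.0, normal_axis="z")
        assert compute_porosity(vol) == 1.0

    def test_subvoxel_gap_rejected(self):
        with pytest.raises(ValueError):
            generate_plate_phantom((32, 32, 32), 1.0, 0.5)


class TestFiberPhantom:
    def test_porosity_hits_reference_target(self):
        vol, rep = generate_fiber_phantom(PhantomSpec(seed=1))
        assert rep.converged
        assert 0.335 <= rep.achieved_porosity <= 0.375
        assert compute_porosity(vol) == rep.achieved_porosity

    def test_straight_tubes_have_unit_axial_tortuosity(self):
        spec = PhantomSpec(
            shape=(32, 32, 32), waviness=0.0, radius_modulation=0.0, seed=3
        )
        vol, rep = generate_fiber_phantom(spec)
        assert rep.percolating
        assert compute_tortuosity(vol, "pore", "z") == pytest.approx(1.0, abs=0.02)

    def test_seed_reproducibility_and_variation(self):
        a, _ = generate_fiber_phantom(PhantomSpec(shape=(32, 32, 32), seed=5))
        b, _ = generate_fiber_phantom(PhantomSpec(shape=(32, 32, 32), seed=5))
        c, _ = generate_fiber_phantom(PhantomSpec(shape=(32, 32, 32), seed=6))
        assert np.array_equal(a.solid, b.solid)
        assert not np.array_equal(a.solid, c.solid)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(target_porosity=1.2)
        with pytest.raises(ValueError):
            PhantomSpec(shape=(8, 64, 64))
        with pytest.raises(ValueError):
            PhantomSpec(tube_radius_mean=0.5, voxel_size=1.0)


class TestRenderGrayscale:
    def test_noiseless_rendering_is_two_level(self, fiber_phantom32):
        binary, _ = fiber_phantom32
        img = render_grayscale(binary, NoiseSpec(blur_sigma=0, noise_sd=0,
                                                 fg_level=200, bg_level=50))
        assert set(np.unique(img.values)) == {50, 200}
        assert np.array_equal(img.values == 200, binary.solid)

    def test_midpoint_threshold_misclassifies_under_one_percent(self, fiber_phantom32):
        binary, _ = fiber_phantom32
        img = render_grayscale(binary, NoiseSpec(blur_sigma=0.0, noise_sd=10,
                                                 fg_level=200, bg_level=50, seed=7))
        recovered = img.values > 125
        err = np.mean(recovered != binary.solid)
        assert err < 0.01

    def test_swapped_levels_invert_segmentation(self, fiber_phantom32):
        binary, _ = fiber_phantom32
        img = render_grayscale(binary, NoiseSpec(blur_sigma=0, noise_sd=0,
                                                 fg_level=50, bg_level=200))
        assert np.array_equal(img.values > 125, ~binary.solid)


class TestStressStrainGenerator:
    def test_yeoh_sample_matches_closed_form(self):
        # C10-only Yeoh at stretch 2: sigma = 2(2 - 1/4) * 1 = 3.5 MPa
        spec = CurveSpec(model_name="yeoh3",
                         params={"C10": 1.0, "C20": 0.0, "C30": 0.0},
                         linear_modulus=None, max_strain=1.0, n_points=51)
        curve = generate_stress_strain(spec)
        i = np.argmin(np.abs(curve.stretch - 2.0))
        assert curve.stretch[i] == pytest.approx(2.0)
        assert curve.nominal_stress[i] == pytest.approx(3.5, rel=1e-12)

    def test_piecewise_post_toe_slope_equals_linear_modulus(self):
        spec = CurveSpec(toe_strain=0.13, linear_modulus=38.5, max_strain=0.25,
                         n_points=100)
        curve = generate_stress_strain(spec)
        eps = curve.strain
        post = eps > 0.14
        slope = np.polyfit(eps[post], curve.nominal_stress[post], 1)[0]
        assert slope == pytest.approx(38.5, rel=1e-9)

    def test_undeformed_point_has_zero_stress(self):
        curve = generate_stress_strain(CurveSpec(noise_rel_sd=0.05, seed=3))
        assert curve.stretch[0] == 1.0
        assert curve.nominal_stress[0] == 0.0

    def test_noise_is_seeded_and_clipped(self):
        spec = CurveSpec(noise_rel_sd=0.5, seed=11)
        a = generate_stress_strain(spec)
        b = generate_stress_strain(spec)
        assert np.array_equal(a.nominal_stress, b.nominal_stress)
        assert (a.nominal_stress >= 0).all()


class TestFallingHeadGenerator:
    def test_round_trip_recovers_permeability(self):
        k_true = 3.17e-12
        rec = generate_falling_head_record(
            k_true, a=2.16e-4, A=2.74e-6, H=1.00e-2, L1=1.46, L2=1.44
        )
        assert falling_head_permeability(rec) == pytest.approx(k_true, rel=1e-3)

    def test_equal_heads_give_zero_time(self):
        rec = generate_falling_head_record(1e-12, a=1e-4, A=1e-6, H=1e-2,
                                           L1=0.5, L2=0.5)
        assert rec.t == 0.0

    def test_time_linear_in_standpipe_area(self):
        r1 = generate_falling_head_record(1e-12, a=1e-4, A=1e-6, H=1e-2,
                                          L1=0.5, L2=0.4)
        r2 = generate_falling_head_record(1e-12, a=2e-4, A=1e-6, H=1e-2,
                                          L1=0.5, L2=0.4)
        assert r2.t == pytest.approx(2.0 * r1.t)


def test_generated_model_curve_matches_direct_evaluation():
    spec = CurveSpec(model_name="mooney_rivlin", params={"C10": 1.0, "C01": 0.5},
                     linear_modulus=None, max_strain=0.5, n_points=20)
    curve = generate_stress_strain(spec)
    expected = uniaxial_stress(spec.params, curve.stretch, "mooney_rivlin")
    np.testing.assert_allclose(curve.nominal_stress, expected, rtol=1e-12)
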