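"""Permeability: Darcy/falling-head algebra and the Stokes solver at small size."""

import numpy as np
import pytest

from eecm import (
    FallingHeadTest,
    FluidProperties,
    aggregate_permeability,
    conductivity_to_permeability,
    darcy_permeability,
    falling_head_conductivity,
    generate_plate_phantom,
    reynolds_number,
    solve_stokes_flow,
)
from eecm.stokes import NonPercolatingPoreError
from eecm.volumes import BinaryMicrostructure


class TestFallingHead:
    def test_triplicate_sample1_trial1(self):
        test = FallingHeadTest(a=3.58e-3, A=1.42e-5, H=1.00e-2,
                               L1=0.45, L2=0.425, t=950.0)
        assert falling_head_conductivity(test) == pytest.approx(1.51e-4, rel=5e-3)

    def test_triplicate_sample3_trial3(self):
        test = FallingHeadTest(a=3.58e-3, A=5.20e-5, H=1.00e-2,
                               L1=0.45, L2=0.425, t=5480.0)
        assert falling_head_conductivity(test) == pytest.approx(7.18e-6, rel=5e-3)

    def test_no_head_drop_means_zero_conductivity(self):
        test = FallingHeadTest(a=1e-4, A=1e-6, H=1e-2, L1=0.5, L2=0.5, t=0.0)
        assert falling_head_conductivity(test) == 0.0

    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError):
            FallingHeadTest(a=1e-4, A=1e-6, H=1e-2, L1=0.4, L2=0.5, t=10.0)
        with pytest.raises(ValueError):
            FallingHeadTest(a=1e-4, A=1e-6, H=1e-2, L1=0.5, L2=0.4, t=0.0)


class TestConductivityConversion:
    @pytest.mark.parametrize("K,k", [(3.11e-5, 3.17e-12), (9.89e-6, 1.01e-12),
                                     (2.36e-5, 2.41e-12)])
    def test_reference_conversions(self, K, k):
        assert conductivity_to_permeability(K) == pytest.approx(k, rel=5e-3)

    def test_identity_scaling(self):
        fluid = FluidProperties()
        K = fluid.density * fluid.gravity / fluid.dynamic_viscosity
        assert conductivity_to_permeability(K, fluid) == pytest.approx(1.0)


class TestAggregate:
    def test_reference_mean_and_population_sd(self):
        mean, sd = aggregate_permeability([3.29e-12, 2.84e-12, 3.18e-12])
        assert mean == pytest.approx(3.10e-12, rel=5e-3)
        assert sd == pytest.approx(1.91e-13, rel=5e-3)

    def test_identical_values_zero_sd(self):
        mean, sd = aggregate_permeability([2.0e-12] * 4)
        assert sd == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            aggregate_permeability([1e-12])


class TestStokesSolver:
    def test_slit_matches_plane_poiseuille(self, slit32):
        sol = solve_stokes_flow(slit32, "x", 1e-12, lateral_bc="free_slip")
        k = darcy_permeability(sol).k
        analytic = (8e-6) ** 3 / (12 * 32e-6)  # gap^3 / (12 H), in m^2
        assert k == pytest.approx(analytic, rel=0.10)
        assert sol.residuals["divergence"] < 1e-8
        assert sol.residuals["momentum"] < 1e-6

    def test_pressure_drop_linear_in_flow_rate(self, slit32):
        s1 = solve_stokes_flow(slit32, "x", 1e-12)
        s2 = solve_stokes_flow(slit32, "x", 2e-12)
        assert s2.pressure_drop == pytest.approx(2.0 * s1.pressure_drop, rel=1e-6)

    def test_permeability_invariant_under_voxel_rescaling(self):
        # k scales as voxel_size^2: same geometry at 1 um and 2 um voxels
        a = generate_plate_phantom((24, 24, 24), 1.0, 6.0, normal_axis="z")
        b = generate_plate_phantom((24, 24, 24), 2.0, 12.0, normal_axis="z")
        ka = darcy_permeability(solve_stokes_flow(a, "x", 1e-12)).k
        kb = darcy_permeability(solve_stokes_flow(b, "x", 1e-12)).k
        assert kb / ka == pytest.approx(4.0, rel=1e-3)

    def test_dilating_pore_never_decreases_k(self):
        narrow = generate_plate_phantom((24, 24, 24), 1.0, 4.0, normal_axis="z")
        wide = generate_plate_phantom((24, 24, 24), 1.0, 8.0, normal_axis="z")
        kn = darcy_permeability(solve_stokes_flow(narrow, "x", 1e-12)).k
        kw = darcy_permeability(solve_stokes_flow(wide, "x", 1e-12)).k
        assert kw >= kn

    def test_non_percolating_pore_rejected(self, half_slab):
        # pore half-space does not cross the solid half -> no path along z
        solid = np.zeros((16, 16, 16), dtype=bool)
        solid[8] = True  # full blocking wall
        vol = BinaryMicrostructure(solid, 1.0)
        with pytest.raises(NonPercolatingPoreError):
            solve_stokes_flow(vol, "z", 1e-12)

    def test_no_slip_walls_reduce_flow_below_free_slip(self, slit32):
        k_ns = darcy_permeability(solve_stokes_flow(slit32, "x", 1e-12)).k
        k_fs = darcy_permeability(
            solve_stokes_flow(slit32, "x", 1e-12, lateral_bc="free_slip")
        ).k
        assert k_ns < k_fs


class TestDarcyAndReynolds:
    def test_darcy_identity(self):
        from eecm.stokes import FlowSolution, FluidProperties as FP

        sol = FlowSolution(
            velocity=np.zeros((3, 1, 1, 1)), pressure=np.zeros((1, 1, 1)),
            inlet_flow_rate=1.0, pressure_drop=1.0, axis="z", residuals={},
            voxel_size_um=1.0, flow_length=1.0, cross_section=1.0,
            porosity=1.0, fluid=FP(dynamic_viscosity=1.0),
        )
        assert darcy_permeability(sol).k == pytest.approx(1.0)

    def test_reference_reynolds_number_is_creeping(self):
        # mass flow 8.75e-9 kg/s of water through a (300 um)^2 RVE at
        # porosity 0.355 with d = 11.8 um pores: deep creeping flow
        from eecm.stokes import FlowSolution

        fluid = FluidProperties()
        Q = 8.75e-9 / fluid.density  # m^3/s
        sol = FlowSolution(
            velocity=np.zeros((3, 1, 1, 1)), pressure=np.zeros((1, 1, 1)),
            inlet_flow_rate=Q, pressure_drop=1.0, axis="z", residuals={},
            voxel_size_um=3.0, flow_length=300e-6, cross_section=(300e-6) ** 2,
            porosity=0.355, fluid=fluid,
        )
        re = reynolds_number(sol, 11.8e-6)
        assert re == pytest.approx(
            fluid.density * Q / (0.355 * (300e-6) ** 2) * 11.8e-6
            / fluid.dynamic_viscosity
        )
        assert re < 1e-2  # deep creeping flow, far below the Darcy limit Re=1

    def test_reynolds_linear_in_flow_and_validity_flag(self):
        from eecm.stokes import FlowSolution

        def make(Q):
            return FlowSolution(
                velocity=np.zeros((3, 1, 1, 1)), pressure=np.zeros((1, 1, 1)),
                inlet_flow_rate=Q, pressure_drop=1.0, axis="z", residuals={},
                voxel_size_um=1.0, flow_length=1e-4, cross_section=1e-8,
                porosity=0.5, fluid=FluidProperties(),
            )

        re1 = reynolds_number(make(1e-12), 1e-5)
        re2 = reynolds_number(make(1e-6), 1e-5)
        assert re2 == pytest.approx(1e6 * re1)
        res = darcy_permeability(make(1e-3), characteristic_length=1e-2)
        assert res.reynolds >= 1 and res.valid_darcy is False
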