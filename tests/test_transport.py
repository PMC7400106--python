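"""Closed-form transport and drag calculations for the flow cell."""

import math

import numpy as np
import pytest

from flowadhesion import (
    DomainError,
    ParameterError,
    analytic_shear_rate,
    average_velocity,
    drag_force,
    local_reynolds,
    make_condition,
    microbial_radius,
    peclet_number,
    sl_deposition_rate,
    transport_table,
)
from flowadhesion.transport import ChannelGeometry, FluidProperties

from conftest import CELL, FLOW_RATES_ML_S, FLUID, GEOMETRY, SHEAR_RATES_S


class TestAverageVelocity:
    @pytest.mark.parametrize(
        "q, expected",
        [(1e-6, 7.8125e-3), (1e-5, 7.8125e-2)],
    )
    def test_plug_mean(self, q, expected, geometry):
        assert average_velocity(q, geometry) == pytest.approx(expected, rel=1e-12)

    def test_linearity(self, geometry):
        assert average_velocity(2e-6, geometry) == 2 * average_velocity(1e-6, geometry)

    def test_rejects_nonpositive_flow(self, geometry):
        with pytest.raises(ParameterError):
            average_velocity(0.0, geometry)


class TestAnalyticShearRate:
    def test_slot_formula(self, geometry):
        # differs from the CFD-derived 7.5/s for the same channel by design:
        # the slot formula ignores side walls
        assert analytic_shear_rate(1e-6, geometry) == pytest.approx(5.859, rel=1e-3)

    def test_linearity(self, geometry):
        g1 = analytic_shear_rate(0.5e-6, geometry)
        g10 = analytic_shear_rate(1e-5, geometry)
        assert g1 == pytest.approx(2.93, rel=1e-2)
        assert g10 == pytest.approx(58.6, rel=1e-2)


class TestMicrobialRadius:
    def test_rod_cell(self):
        # L=2 um, b=1 um: R_b = (L/2)/(ln 2 - 0.11)
        assert microbial_radius(2e-6, 1e-6) == pytest.approx(1.715e-6, rel=1e-3)

    def test_unit_denominator(self):
        length = 3e-6
        b = length / math.exp(1.11)
        assert microbial_radius(length, b) == pytest.approx(length / 2, rel=1e-12)

    def test_domain_error_for_stubby_cells(self):
        with pytest.raises(DomainError):
            microbial_radius(1e-6, 1e-6)


class TestPecletNumber:
    def test_reference_value(self, geometry):
        pe = peclet_number(7.8125e-3, 4.5e-7, geometry.height, 4.0e-13)
        assert pe == pytest.approx(1.6685e-4, rel=1e-3)

    def test_zero_velocity(self, geometry):
        assert peclet_number(0.0, 4.5e-7, geometry.height, 4.0e-13) == 0.0

    def test_linearity_in_velocity(self, geometry):
        pe1 = peclet_number(1e-3, 4.5e-7, geometry.height, 4.0e-13)
        pe10 = peclet_number(1e-2, 4.5e-7, geometry.height, 4.0e-13)
        assert pe10 == pytest.approx(10 * pe1, rel=1e-12)


class TestDepositionRate:
    def test_low_flow_endpoint(self, fluid, geometry):
        pe = peclet_number(average_velocity(1e-6, geometry), 4.5e-7, geometry.height, 4.0e-13)
        sl = sl_deposition_rate(fluid, 4.5e-7, pe, geometry)
        assert round(sl, -1) == 80.0

    def test_high_flow_endpoint(self, fluid, geometry):
        pe = peclet_number(average_velocity(1e-5, geometry), 4.5e-7, geometry.height, 4.0e-13)
        sl = sl_deposition_rate(fluid, 4.5e-7, pe, geometry)
        assert round(sl, -1) == 170.0

    def test_zero_peclet(self, fluid, geometry):
        assert sl_deposition_rate(fluid, 4.5e-7, 0.0, geometry) == 0.0

    def test_cube_root_flow_scaling(self, fluid, geometry):
        """SL(Q2)/SL(Q1) = (Q2/Q1)^(1/3) when only Q varies."""
        def sl_at(q):
            pe = peclet_number(average_velocity(q, geometry), 4.5e-7, geometry.height, 4.0e-13)
            return sl_deposition_rate(fluid, 4.5e-7, pe, geometry)

        ratio = sl_at(8e-6) / sl_at(1e-6)
        assert ratio == pytest.approx(8 ** (1 / 3), rel=1e-12)

    def test_unit_round_trip(self, fluid, geometry):
        """SI computation then cm^2 conversion == computation with converted constants."""
        pe = 1.6685e-4
        sl_cm2 = sl_deposition_rate(fluid, 4.5e-7, pe, geometry)
        # direct evaluation in cm-based units: D [cm^2/s], C_b [cells/cm^3], R_b [cm]
        d_cm = fluid.diffusion_coefficient * 1e4
        cb_cm = fluid.cell_concentration * 1e-6
        rb_cm = 4.5e-7 * 1e2
        h0_cm, x_cm = geometry.height * 1e2, geometry.axial_position * 1e2
        direct = 0.538 * (d_cm * cb_cm / rb_cm) * (pe * h0_cm / x_cm) ** (1 / 3)
        assert sl_cm2 == pytest.approx(direct, rel=1e-12)


class TestDragForce:
    @pytest.mark.parametrize(
        "gamma, expected",
        [(7.5, 3.37e-14), (100.8, 4.53e-13)],
    )
    def test_newtonian_wall_values(self, gamma, expected, fluid):
        tau = fluid.viscosity * gamma
        assert drag_force(tau, 4.5e-7) == pytest.approx(expected, rel=1e-2)

    def test_linear_in_stress(self):
        assert drag_force(0.2, 4.5e-7) == 2 * drag_force(0.1, 4.5e-7)
        assert drag_force(0.0, 4.5e-7) == 0.0

    def test_rejects_negative_stress(self):
        with pytest.raises(ParameterError):
            drag_force(-1.0, 4.5e-7)


class TestLocalReynolds:
    def test_highest_shear(self, fluid):
        re = local_reynolds(fluid.density, 100.8, 4.5e-7, fluid.viscosity)
        assert re == pytest.approx(2.92e-5, rel=1e-2)

    def test_all_conditions_creeping(self, fluid):
        """Every assay shear rate sits deep in the Stokes regime."""
        for gamma in SHEAR_RATES_S:
            assert local_reynolds(fluid.density, gamma, 4.5e-7, fluid.viscosity) < 1

    def test_linear_in_shear(self, fluid):
        r1 = local_reynolds(fluid.density, 10.0, 4.5e-7, fluid.viscosity)
        r2 = local_reynolds(fluid.density, 20.0, 4.5e-7, fluid.viscosity)
        assert r2 == 2 * r1
        assert local_reynolds(fluid.density, 0.0, 4.5e-7, fluid.viscosity) == 0.0


class TestConditionsAndTable:
    def test_analytic_source_ties_stress_to_shear(self, geometry, fluid):
        cond = make_condition(1e-6, geometry, fluid)
        assert cond.shear_source == "analytic"
        assert cond.wall_shear_stress == fluid.viscosity * cond.shear_rate

    def test_supplied_shear_is_respected(self, geometry, fluid):
        cond = make_condition(1e-6, geometry, fluid, shear_rate=7.5)
        assert cond.shear_source == "supplied"
        assert cond.shear_rate == 7.5

    def test_six_condition_ranges(self, geometry, fluid, cell):
        conds = [
            make_condition(q * 1e-6, geometry, fluid, shear_rate=g)
            for q, g in zip(FLOW_RATES_ML_S, SHEAR_RATES_S)
        ]
        table = transport_table(conds, fluid, cell, geometry)
        assert len(table) == 6
        sl = table["SL_cells_cm2_s"].to_numpy()
        assert round(sl.min(), -1) == 80.0
        assert round(sl.max(), -1) == 170.0
        assert np.all(np.diff(sl) > 0)  # strictly increasing in Q
        drag = table["drag_N"].to_numpy()
        assert drag.min() >= 3e-14
        assert drag.max() <= 5e-13
        assert np.all(np.diff(drag) > 0)

    def test_single_condition(self, geometry, fluid, cell):
        cond = make_condition(1e-6, geometry, fluid)
        assert len(transport_table([cond], fluid, cell, geometry)) == 1

    def test_empty_condition_list_rejected(self, geometry, fluid, cell):
        with pytest.raises(ParameterError):
            transport_table([], fluid, cell, geometry)


class TestTypeInvariants:
    def test_geometry_validation(self):
        with pytest.raises(ParameterError):
            ChannelGeometry(0.016, 0.008, 0.25, 0.3)  # x > length
        with pytest.raises(ParameterError):
            ChannelGeometry(0.008, 0.016, 0.25, 0.1)  # h0 > w

    def test_fluid_validation(self):
        with pytest.raises(ParameterError):
            FluidProperties(0.0, 6.94e-4, 4e-13, 7.6e13)
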