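"""Hydrodynamics and mass transport in a parallel-plate flow cell (PPFC).

Closed-form estimates for the transport of suspended cells to the bottom
plate of a rectangular flow channel and for the hydrodynamic load on cells
that have already adhered:

* Smoluchowski-Levich (SL) deposition flux — the perfect-sink solution of
  the convective-diffusion equation for a parallel-plate geometry,
  ``SL = 0.538 * (D_inf * C_b / R_b) * (Pe * h0 / x)**(1/3)``.
* Péclet number for the same geometry,
  ``Pe = 3 * v_av * R_b**3 / (2 * (h0/2)**2 * D_inf)``.
* Stokes-regime drag on a wall-attached sphere, ``D = 32 * tau_w * R_b**2``,
  valid while the shear-based local Reynolds number
  ``Re_c = rho * gamma * R_b**2 / mu`` stays well below 1.
* Equivalent spherical radius of a rod-shaped cell,
  ``R_b = (L/2) / (ln(L/b) - 0.11)``.

All computations are in SI units internally; the deposition flux is reported
in cells/(cm^2*s), the unit in which such fluxes are conventionally quoted.

Wall shear rate and shear stress in a real channel are best taken from CFD
or experiment and can be supplied per flow condition; an analytic
infinite-slot approximation (``6*Q/(w*h0^2)``) is available as an explicit
fallback but is never substituted silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, ParameterError

__all__ = [
    "ChannelGeometry",
    "FluidProperties",
    "CellMorphology",
    "FlowCondition",
    "TransportEstimate",
    "average_velocity",
    "analytic_shear_rate",
    "microbial_radius",
    "peclet_number",
    "sl_deposition_rate",
    "drag_force",
    "local_reynolds",
    "make_condition",
    "transport_estimate",
    "transport_table",
]

#: m^2 per cm^2 — flux conversion at the reporting boundary.
_M2_PER_CM2 = 1.0e4


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular flow-channel geometry.

    Parameters
    ----------
    width : float
        Channel width ``w`` in metres (the long side of the cross-section).
    height : float
        Channel height ``h0`` in metres (plate separation).
    length : float
        Total channel length in metres.
    axial_position : float
        Distance ``x`` from the inlet, in metres, at which transport is
        evaluated (the observation position on the bottom plate).
    """

    width: float
    height: float
    length: float
    axial_position: float

    def __post_init__(self) -> None:
        for name in ("width", "height", "length", "axial_position"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"ChannelGeometry.{name} must be > 0")
        if self.height > self.width:
            raise ParameterError("channel height h0 must not exceed width w")
        if self.axial_position > self.length:
            raise ParameterError("axial_position x must not exceed channel length")

    @property
    def cross_section(self) -> float:
        """Cross-sectional area w*h0 in m^2."""
        return self.width * self.height


@dataclass(frozen=True)
class FluidProperties:
    """Suspending-fluid properties and bulk cell concentration (SI units)."""

    density: float  # kg/m^3
    viscosity: float  # kg/(m*s)
    diffusion_coefficient: float  # m^2/s
    cell_concentration: float  # cells/m^3

    def __post_init__(self) -> None:
        for name in (
            "density",
            "viscosity",
            "diffusion_coefficient",
            "cell_concentration",
        ):
            if not getattr(self, name) > 0:
                raise ParameterError(f"FluidProperties.{name} must be > 0")


@dataclass(frozen=True)
class CellMorphology:
    """Rod-shaped cell dimensions and the equivalent spherical radius.

    ``equivalent_radius`` may be given directly (the usual route, since it is
    what the transport formulas consume) or computed from length and diameter
    with :func:`microbial_radius`.
    """

    length: float | None = None  # m
    diameter: float | None = None  # m
    equivalent_radius: float | None = None  # m

    def __post_init__(self) -> None:
        if self.equivalent_radius is None:
            if self.length is None or self.diameter is None:
                raise ParameterError(
                    "either equivalent_radius or both length and diameter required"
                )
            object.__setattr__(
                self, "equivalent_radius", microbial_radius(self.length, self.diameter)
            )
        if not self.equivalent_radius > 0:
            raise ParameterError("equivalent_radius must be > 0")
        if self.length is not None and self.diameter is not None:
            if not self.diameter > 0 or self.length < self.diameter:
                raise ParameterError("cell length L >= diameter b > 0 required")


@dataclass(frozen=True)
class FlowCondition:
    """One hydraulic operating point of the flow cell.

    ``shear_source`` records whether shear rate / wall shear stress came from
    an external source ("supplied", e.g. CFD) or from the analytic slot
    approximation ("analytic").
    """

    flow_rate: float  # m^3/s
    average_velocity: float  # m/s
    shear_rate: float  # 1/s
    wall_shear_stress: float  # Pa
    shear_source: str = "supplied"

    def __post_init__(self) -> None:
        if not self.flow_rate > 0:
            raise ParameterError("flow_rate must be > 0")
        if not self.average_velocity > 0:
            raise ParameterError("average_velocity must be > 0")
        if self.shear_rate < 0 or self.wall_shear_stress < 0:
            raise ParameterError("shear_rate and wall_shear_stress must be >= 0")
        if self.shear_source not in ("analytic", "supplied"):
            raise ParameterError("shear_source must be 'analytic' or 'supplied'")


@dataclass(frozen=True)
class TransportEstimate:
    """Transport and force quantities for one flow condition."""

    peclet: float
    sl_flux: float  # cells/(cm^2*s)
    drag_force: float  # N
    local_reynolds: float

    def __post_init__(self) -> None:
        for name in ("peclet", "sl_flux", "drag_force", "local_reynolds"):
            if getattr(self, name) < 0:
                raise ParameterError(f"TransportEstimate.{name} must be >= 0")


def average_velocity(flow_rate: float, geom: ChannelGeometry) -> float:
    """Cross-section mean velocity ``v_av = Q / (w*h0)`` in m/s."""
    if not flow_rate > 0:
        raise ParameterError("flow_rate must be > 0")
    return flow_rate / geom.cross_section


def analytic_shear_rate(flow_rate: float, geom: ChannelGeometry) -> float:
    """Wall shear rate of plane Poiseuille flow in a wide slot, ``6Q/(w*h0^2)``.

    An idealisation that ignores side walls and entrance effects; CFD values
    for a finite-aspect-ratio channel will differ (tens of percent).  Use as
    an explicit fallback when no supplied shear rate is available.
    """
    if not flow_rate > 0:
        raise ParameterError("flow_rate must be > 0")
    return 6.0 * flow_rate / (geom.width * geom.height**2)


def microbial_radius(length: float, diameter: float) -> float:
    """Equivalent spherical radius of a rod-shaped (cylindrical) cell.

    ``R_b = (L/2) / (ln(L/b) - 0.11)`` where ``L`` is the cell length and
    ``b`` its diameter.  Defined only for aspect ratios ``L/b > e**0.11``
    (~1.116), where the denominator is positive.
    """
    if not diameter > 0 or not length > 0:
        raise ParameterError("length and diameter must be > 0")
    denom = math.log(length / diameter) - 0.11
    if denom <= 0:
        raise DomainError(
            "microbial_radius requires L/b > e**0.11 (ln(L/b) - 0.11 > 0); "
            f"got L/b = {length / diameter:.4g}"
        )
    return (length / 2.0) / denom


def peclet_number(
    v_av: float, equivalent_radius: float, channel_height: float, diffusion_coefficient: float
) -> float:
    """Péclet number for a parallel-plate channel.

    ``Pe = 3 * v_av * R_b^3 / (2 * (h0/2)^2 * D_inf)`` — the ratio of
    convective to diffusive transport of a particle of radius ``R_b`` carried
    at mean velocity ``v_av`` between plates ``h0`` apart.
    """
    if v_av < 0:
        raise ParameterError("average velocity must be >= 0")
    for name, value in (
        ("equivalent_radius", equivalent_radius),
        ("channel_height", channel_height),
        ("diffusion_coefficient", diffusion_coefficient),
    ):
        if not value > 0:
            raise ParameterError(f"{name} must be > 0")
    return 3.0 * v_av * equivalent_radius**3 / (2.0 * (channel_height / 2.0) ** 2 * diffusion_coefficient)


def sl_deposition_rate(
    fluid: FluidProperties,
    equivalent_radius: float,
    peclet: float,
    geom: ChannelGeometry,
) -> float:
    """Smoluchowski-Levich deposition flux in cells/(cm^2*s).

    ``SL = 0.538 * (D_inf * C_b / R_b) * (Pe * h0 / x)^(1/3)`` evaluated at
    axial position ``x``; assumes every cell reaching the wall adheres
    irreversibly (perfect sink) and neglects interception and gravity.
    The SI result (cells/(m^2*s)) is divided by 1e4 at return.
    """
    if peclet < 0:
        raise ParameterError("peclet must be >= 0")
    if not equivalent_radius > 0:
        raise ParameterError("equivalent_radius must be > 0")
    if not geom.axial_position > 0:
        raise ParameterError("axial_position x must be > 0")
    flux_si = (
        0.538
        * (fluid.diffusion_coefficient * fluid.cell_concentration / equivalent_radius)
        * (peclet * geom.height / geom.axial_position) ** (1.0 / 3.0)
    )
    return flux_si / _M2_PER_CM2


def drag_force(wall_shear_stress: float, equivalent_radius: float) -> float:
    """Drag on a sphere resting on the wall in linear shear, ``D = 32*tau_w*R_b^2``.

    Valid in the Stokes regime (local Reynolds number well below 1), where
    higher-order inertial corrections are negligible.
    """
    if wall_shear_stress < 0:
        raise ParameterError("wall_shear_stress must be >= 0")
    if not equivalent_radius > 0:
        raise ParameterError("equivalent_radius must be > 0")
    return 32.0 * wall_shear_stress * equivalent_radius**2


def local_reynolds(
    density: float, shear_rate: float, equivalent_radius: float, viscosity: float
) -> float:
    """Shear-based particle Reynolds number ``Re_c = rho*gamma*R_b^2/mu``."""
    if not viscosity > 0:
        raise ParameterError("viscosity must be > 0")
    if density < 0 or shear_rate < 0 or equivalent_radius < 0:
        raise ParameterError("density, shear_rate and equivalent_radius must be >= 0")
    return density * shear_rate * equivalent_radius**2 / viscosity


def make_condition(
    flow_rate: float,
    geom: ChannelGeometry,
    fluid: FluidProperties,
    shear_rate: float | None = None,
    wall_shear_stress: float | None = None,
) -> FlowCondition:
    """Assemble a :class:`FlowCondition` for a volumetric flow rate.

    If ``shear_rate`` is omitted, the analytic slot approximation is used and
    the condition is tagged ``shear_source="analytic"``.  If
    ``wall_shear_stress`` is omitted it is derived as ``mu * gamma``
    (Newtonian wall relation).
    """
    v_av = average_velocity(flow_rate, geom)
    if shear_rate is None:
        gamma = analytic_shear_rate(flow_rate, geom)
        source = "analytic"
    else:
        gamma = float(shear_rate)
        source = "supplied"
    tau_w = fluid.viscosity * gamma if wall_shear_stress is None else float(wall_shear_stress)
    return FlowCondition(
        flow_rate=flow_rate,
        average_velocity=v_av,
        shear_rate=gamma,
        wall_shear_stress=tau_w,
        shear_source=source,
    )


def transport_estimate(
    condition: FlowCondition,
    fluid: FluidProperties,
    cell: CellMorphology,
    geom: ChannelGeometry,
) -> TransportEstimate:
    """All four transport/force quantities for one flow condition."""
    r_b = cell.equivalent_radius
    pe = peclet_number(condition.average_velocity, r_b, geom.height, fluid.diffusion_coefficient)
    return TransportEstimate(
        peclet=pe,
        sl_flux=sl_deposition_rate(fluid, r_b, pe, geom),
        drag_force=drag_force(condition.wall_shear_stress, r_b),
        local_reynolds=local_reynolds(fluid.density, condition.shear_rate, r_b, fluid.viscosity),
    )


def transport_table(
    conditions: Sequence[FlowCondition] | Iterable[FlowCondition],
    fluid: FluidProperties,
    cell: CellMorphology,
    geom: ChannelGeometry,
) -> pd.DataFrame:
    """Tabulate Pe, SL flux, drag force and Re_c for a list of flow conditions.

    Returns a DataFrame with one row per condition and columns
    ``Q_mL_per_s, v_av_m_s, shear_rate_per_s, tau_w_Pa, Pe, SL_cells_cm2_s,
    drag_N, Re_c``.
    """
    conditions = list(conditions)
    if not conditions:
        raise ParameterError("transport_table requires at least one FlowCondition")
    rows = []
    for i, cond in enumerate(conditions):
        try:
            est = transport_estimate(cond, fluid, cell, geom)
        except (ParameterError, DomainError) as exc:
            raise ParameterError(f"condition {i}: {exc}") from exc
        rows.append(
            {
                "Q_mL_per_s": cond.flow_rate * 1.0e6,
                "v_av_m_s": cond.average_velocity,
                "shear_rate_per_s": cond.shear_rate,
                "tau_w_Pa": cond.wall_shear_stress,
                "Pe": est.peclet,
                "SL_cells_cm2_s": est.sl_flux,
                "drag_N": est.drag_force,
                "Re_c": est.local_reynolds,
            }
        )
    return pd.DataFrame(rows)
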