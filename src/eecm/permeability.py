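"""Permeability of porous volumes: image-based (Stokes + Darcy) and experimental
(falling-head permeametry).

The image-based route solves creeping flow through the segmented pore space
(:func:`solve_stokes_flow`, re-exported from :mod:`eecm.stokes`) and converts
the resulting pressure drop to an effective permeability with Darcy's law

    k = mu * L * Q / (A * dP)          [m^2]

valid for Reynolds numbers below one.  The experimental route evaluates a
falling-head permeameter record: a standpipe of cross-section ``a`` drains
through a sample of height ``H`` and cross-section ``A`` while the head falls
from ``L1`` to ``L2`` over a time ``t``, giving the hydraulic conductivity

    K = a * H / (A * t) * ln(L1 / L2)  [m/s]

which converts to intrinsic permeability via k = K * mu / (rho * g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stokes import (  # noqa: F401  (re-exported solver API)
    FlowSolution,
    FluidProperties,
    NonPercolatingPoreError,
    SolverConvergenceError,
    solve_stokes_flow,
)

WATER = FluidProperties()


@dataclass
class PermeabilityResult:
    """Effective permeability of a sample with its Darcy-validity check."""

    k: float  # m^2
    L: float  # m, sample thickness
    A: float  # m^2, cross-section
    Q: float  # m^3/s
    delta_p: float  # Pa
    reynolds: float | None = None
    valid_darcy: bool | None = None

    def to_dict(self) -> dict:
        return {
            "k_m2": self.k,
            "L_m": self.L,
            "A_m2": self.A,
            "Q_m3_s": self.Q,
            "delta_p_Pa": self.delta_p,
            "reynolds": self.reynolds,
            "valid_darcy": self.valid_darcy,
        }


@dataclass
class FallingHeadTest:
    """One falling-head permeameter record (SI units).

    Attributes
    ----------
    a, A : m^2
        Cross-sections of the standpipe and of the sample.
    H : m
        Height (thickness) of the sample.
    L1, L2 : m
        Initial and final water-column heads, ``L1 > L2``.
    t : s
        Elapsed time over which the head fell from L1 to L2.
    fluid : FluidProperties
        Fluid constants used for the conductivity-to-permeability conversion.
    """

    a: float
    A: float
    H: float
    L1: float
    L2: float
    t: float
    fluid: FluidProperties = None

    def __post_init__(self) -> None:
        if self.fluid is None:
            self.fluid = WATER
        if min(self.a, self.A, self.H, self.L1, self.L2) <= 0:
            raise ValueError("all geometry and heads must be positive")
        if self.L1 < self.L2:
            raise ValueError("initial head L1 must be >= final head L2")
        if self.t < 0 or (self.t == 0 and self.L1 > self.L2):
            raise ValueError("elapsed time must be positive")


def darcy_permeability(
    sol: FlowSolution,
    L: float | None = None,
    A: float | None = None,
    fluid: FluidProperties | None = None,
    characteristic_length: float | None = None,
) -> PermeabilityResult:
    """Effective permeability k = mu*L*Q/(A*dP) from a flow solution.

    ``L`` and ``A`` default to the solution's own flow length (between the
    two pressure-averaging planes) and full domain cross-section.  If
    ``characteristic_length`` (m) is given, the Reynolds number and the
    Darcy-validity flag (Re < 1) are attached.
    """
    fluid = fluid or sol.fluid
    L = sol.flow_length if L is None else L
    A = sol.cross_section if A is None else A
    if sol.pressure_drop <= 0:
        raise ValueError("pressure drop must be positive to evaluate Darcy's law")
    k = fluid.dynamic_viscosity * L * sol.inlet_flow_rate / (A * sol.pressure_drop)
    result = PermeabilityResult(
        k=k, L=L, A=A, Q=sol.inlet_flow_rate, delta_p=sol.pressure_drop
    )
    if characteristic_length is not None:
        re = reynolds_number(sol, characteristic_length, fluid)
        result.reynolds = re
        result.valid_darcy = bool(re < 1.0)
    return result


def reynolds_number(
    sol: FlowSolution,
    characteristic_length: float,
    fluid: FluidProperties | None = None,
) -> float:
    """Pore Reynolds number Re = rho * v * d / mu with v = Q / (phi * A).

    ``characteristic_length`` d is in meters; a natural choice is the mean
    pore equivalent spherical diameter from morphometry.
    """
    if characteristic_length <= 0:
        raise ValueError("characteristic length must be positive")
    fluid = fluid or sol.fluid
    if sol.porosity <= 0:
        raise ValueError("zero porosity: mean pore velocity undefined")
    v_mean = sol.inlet_flow_rate / (sol.porosity * sol.cross_section)
    return fluid.density * v_mean * characteristic_length / fluid.dynamic_viscosity


def falling_head_conductivity(test: FallingHeadTest) -> float:
    """Hydraulic conductivity K = a*H/(A*t) * ln(L1/L2) in m/s.

    The degenerate no-drop record (L1 == L2, t == 0) yields K = 0.
    """
    if test.L1 == test.L2:
        return 0.0
    return test.a * test.H / (test.A * test.t) * float(np.log(test.L1 / test.L2))


def conductivity_to_permeability(K: float, fluid: FluidProperties | None = None) -> float:
    """Intrinsic permeability k = K * mu / (rho * g) in m^2."""
    if K < 0:
        raise ValueError("hydraulic conductivity must be non-negative")
    fluid = fluid or WATER
    return K * fluid.dynamic_viscosity / (fluid.density * fluid.gravity)


def falling_head_permeability(test: FallingHeadTest) -> float:
    """Permeability of a falling-head record (conductivity then conversion)."""
    return conductivity_to_permeability(falling_head_conductivity(test), test.fluid)


def aggregate_permeability(values) -> tuple[float, float]:
    """Arithmetic mean and population (divide-by-n) SD of permeabilities."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values to aggregate")
    return float(arr.mean()), float(arr.std(ddof=0))
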