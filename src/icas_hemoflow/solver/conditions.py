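"""Fluid properties, inlet/outlet boundary treatment and analytic references.

The inlet flow rate follows the duplex-ultrasound convention: mean velocity =
PSV/3 + 2*EDV/3, flow rate Q = mean velocity x cross-sectional area.  The
absolute pressure level is anchored at the mean arterial pressure
MAP = diastolic + (systolic - diastolic)/3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InputError

MMHG_TO_PA = 133.322


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood: density (kg/m^3) and dynamic viscosity (Pa s)."""

    density: float = 1060.0
    dynamic_viscosity: float = 3.5e-3

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise InputError("fluid properties must be strictly positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


@dataclass(frozen=True)
class InletCondition:
    """Fully developed inflow carrying the ultrasound-derived flow rate."""

    psv: float                    # m/s
    edv: float                    # m/s
    mean_velocity: float          # m/s
    flow_rate: float              # m^3/s (axisymmetric) or m^2/s (planar)
    mean_arterial_pressure: float  # Pa
    inlet_radius: float           # m


@dataclass(frozen=True)
class OutletModel:
    """Downstream closure.

    ``reference_pressure``: the pressure field is anchored at the inlet mean
    arterial pressure (translesional ratios are then FFR-like absolute
    ratios).  ``resistance``: a linear lumped-parameter closure
    ``P_out = distal_pressure + distal_resistance * Q`` anchored at the
    outlet instead.
    """

    kind: str = "reference_pressure"
    distal_pressure: float = 0.0      # Pa
    distal_resistance: float = 0.0    # Pa s / m^3

    def __post_init__(self):
        if self.kind not in ("reference_pressure", "resistance"):
            raise InputError(f"unknown outlet kind {self.kind!r}")
        if self.distal_pressure < 0 or self.distal_resistance < 0:
            raise InputError("outlet parameters must be non-negative")


def mean_arterial_pressure(systolic_bp: float, diastolic_bp: float) -> float:
    """MAP in Pa from brachial systolic/diastolic pressures in mmHg."""
    if not systolic_bp > diastolic_bp > 0:
        raise InputError("require systolic > diastolic > 0")
    map_mmhg = diastolic_bp + (systolic_bp - diastolic_bp) / 3.0
    return map_mmhg * MMHG_TO_PA


def inlet_condition(psv: float, edv: float, inlet_radius: float,
                    systolic_bp: float, diastolic_bp: float) -> InletCondition:
    """Build the inlet condition from ultrasound velocities and cuff pressure."""
    if not psv >= edv > 0:
        raise InputError("require psv >= edv > 0")
    if inlet_radius <= 0:
        raise InputError("inlet_radius must be > 0")
    mean_velocity = psv / 3.0 + 2.0 * edv / 3.0
    flow_rate = mean_velocity * np.pi * inlet_radius ** 2
    return InletCondition(
        psv=psv, edv=edv, mean_velocity=mean_velocity, flow_rate=flow_rate,
        mean_arterial_pressure=mean_arterial_pressure(systolic_bp, diastolic_bp),
        inlet_radius=inlet_radius)


def poiseuille_reference(Q: float, R: float, L: float, mu: float
                         ) -> tuple[float, float]:
    """Closed-form Hagen-Poiseuille pressure drop and wall shear stress.

    ``dP = 8 mu L Q / (pi R^4)``, ``tau_w = 4 mu Q / (pi R^3)``.  ``Q = 0``
    returns (0, 0); the remaining inputs must be positive.
    """
    if R <= 0 or L <= 0 or mu <= 0 or Q < 0:
        raise InputError("poiseuille_reference requires R, L, mu > 0 and Q >= 0")
    dp = 8.0 * mu * L * Q / (np.pi * R ** 4)
    tau = 4.0 * mu * Q / (np.pi * R ** 3)
    return float(dp), float(tau)


def channel_poiseuille_reference(q: float, H: float, L: float, mu: float
                                 ) -> tuple[float, float]:
    """Plane-Poiseuille analogue for the 2-D eccentric (planar) mode.

    ``q`` is the flow rate per unit depth (m^2/s), ``H`` the wall gap.
    ``dP = 12 mu L q / H^3``, ``tau_w = 6 mu q / H^2``.
    """
    if H <= 0 or L <= 0 or mu <= 0 or q < 0:
        raise InputError("channel reference requires H, L, mu > 0 and q >= 0")
    return float(12.0 * mu * L * q / H ** 3), float(6.0 * mu * q / H ** 2)
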