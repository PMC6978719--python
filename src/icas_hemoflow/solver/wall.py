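"""Wall shear stress and wall pressure along the prominent-side wall.

At a rigid no-slip wall of an incompressible flow the wall shear stress
magnitude equals ``mu * |omega_wall|``, so the WSS profile follows directly
from the converged vorticity field; wall pressure is sampled from the
recovered pressure field at the wall nodes.  Arc length is measured along
the chosen wall from the vessel inlet.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..errors import InputError, UnconvergedFieldError
from .core import FlowField


@dataclass
class WallProfile:
    """Longitudinal WSS/pressure profile along one wall.

    ``arc_length`` is strictly increasing, measured from the inlet;
    ``axial_positions`` retains the matching z coordinates so lesion extents
    (defined axially) can be mapped onto the arc.
    """

    arc_length: np.ndarray      # m
    wss: np.ndarray             # Pa, magnitude
    wall_pressure: np.ndarray   # Pa
    side_label: str
    axial_positions: np.ndarray  # m

    def arc_of_axial(self, z: float | np.ndarray) -> np.ndarray | float:
        """Arc position(s) of the given axial coordinate(s)."""
        return np.interp(z, self.axial_positions, self.arc_length)

    def to_csv(self, path: str | Path) -> None:
        data = np.column_stack([self.arc_length, self.wss, self.wall_pressure])
        np.savetxt(path, data, delimiter=",",
                   header="s_m,wss_pa,pressure_pa", comments="")


def wall_profile(field: FlowField, side: str = "prominent") -> WallProfile:
    """Extract the wall profile from a converged flow field.

    ``side`` is "prominent" (default), "upper", "lower", or "wall"
    (axisymmetric single wall).  Refuses unconverged fields.
    """
    if not field.converged:
        raise UnconvergedFieldError(
            f"refusing to profile an unconverged field "
            f"(residual {field.final_residual:.2e})")
    if side == "prominent":
        side = field.geometry.prominent_wall()
    if field.mode == "axisymmetric":
        if side not in ("wall", "upper", "lower"):
            raise InputError(f"unknown side {side!r}")
        j = -1
        label = "wall"
    else:
        if side == "upper":
            j = -1
        elif side == "lower":
            j = 0
        else:
            raise InputError(f"unknown side {side!r} for planar mode")
        label = side

    z = field.z
    y_wall = field.y[:, j]
    ds = np.sqrt(1.0 + np.gradient(y_wall, z) ** 2)
    s = np.concatenate([[0.0], np.cumsum(
        0.5 * (ds[1:] + ds[:-1]) * np.diff(z))])
    wss = field.fluid.dynamic_viscosity * np.abs(field.vorticity[:, j])
    return WallProfile(arc_length=s, wss=wss,
                       wall_pressure=field.pressure[:, j].copy(),
                       side_label=label, axial_positions=z.copy())
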