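"""Parametric stenosed-vessel geometry.

A lesion is modelled as a smooth cosine-shaped encroachment of the lumen wall
of an otherwise straight middle-cerebral-artery-scale tube.  Severity follows
the WASID convention: percent stenosis = (1 - D_stenosed / D_reference) x 100,
with the unstenosed proximal lumen as the reference diameter.

Two lumen modes are supported:

* ``axisymmetric`` — a body of revolution; ``wall_offset`` is the lumen radius
  R(z).  This is the default mode of the analysis pipeline.
* ``planar`` — a 2-D channel with independently shaped lower/upper walls for
  eccentric (one-sided) plaques; ``wall_offset`` holds the two signed wall
  half-heights about the centreline.  A deep one-sided plaque may legitimately
  cross the centreline, so only the residual gap is required to stay positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    AmbiguousLesionError,
    InputError,
    InvalidGeometryError,
    NoLesionError,
)

SIDES = ("axisymmetric", "upper", "lower", "both")


def percent_stenosis_wasid(d_stenosed: float, d_reference: float) -> float:
    """WASID percent stenosis from stenosed and reference lumen diameters.

    Parameters are diameters in any common length unit.  Returns percent in
    [0, 100).
    """
    if d_reference <= 0 or d_stenosed <= 0:
        raise InvalidGeometryError(
            f"diameters must be positive, got ({d_stenosed}, {d_reference})")
    if d_stenosed > d_reference:
        raise InvalidGeometryError(
            f"stenosed diameter {d_stenosed} exceeds reference {d_reference}")
    return (1.0 - d_stenosed / d_reference) * 100.0


@dataclass(frozen=True)
class StenosisSpec:
    """Parametric description of a single focal stenosis.

    Attributes
    ----------
    reference_radius : float
        Unstenosed lumen radius (m).
    percent_stenosis : float
        WASID diameter stenosis in percent, 0 <= s < 100.
    lesion_length : float
        Axial footprint of the lesion (m).
    center_position : float
        Axial coordinate of the lesion centre / throat (m, origin at inlet).
    side : str
        One of {"axisymmetric", "upper", "lower", "both"}.
    shape : str
        Lesion profile family; only "cosine" is implemented.
    """

    reference_radius: float
    percent_stenosis: float
    lesion_length: float
    center_position: float
    side: str = "axisymmetric"
    shape: str = "cosine"

    def __post_init__(self):
        if self.reference_radius <= 0:
            raise InvalidGeometryError("reference_radius must be > 0")
        if not (0.0 <= self.percent_stenosis < 100.0):
            raise InvalidGeometryError(
                f"percent_stenosis must be in [0, 100), got {self.percent_stenosis}")
        if self.lesion_length <= 0:
            raise InvalidGeometryError("lesion_length must be > 0")
        if self.side not in SIDES:
            raise InvalidGeometryError(f"side must be one of {SIDES}")
        if self.shape != "cosine":
            raise InvalidGeometryError(f"unknown lesion shape {self.shape!r}")

    @property
    def severity(self) -> float:
        """Diameter-loss fraction s = percent_stenosis / 100."""
        return self.percent_stenosis / 100.0


@dataclass
class VesselGeometry:
    """Discretised lumen boundary of a single-lesion vessel.

    ``wall_offset`` is shape (n,) in axisymmetric mode (lumen radius) and
    (n, 2) in planar mode (signed distances of the lower and upper wall from
    the centreline; the lumen gap is their sum).
    """

    axial_samples: np.ndarray
    wall_offset: np.ndarray
    mode: str
    reference_radius: float
    spec: StenosisSpec | None = field(default=None, repr=False)

    def __post_init__(self):
        self.axial_samples = np.asarray(self.axial_samples, dtype=float)
        self.wall_offset = np.asarray(self.wall_offset, dtype=float)
        if self.axial_samples.ndim != 1 or len(self.axial_samples) < 2:
            raise InvalidGeometryError("need at least two axial samples")
        if np.any(np.diff(self.axial_samples) <= 0):
            raise InvalidGeometryError("axial_samples must be strictly increasing")
        if self.mode not in ("axisymmetric", "planar"):
            raise InvalidGeometryError(f"unknown mode {self.mode!r}")
        if self.mode == "axisymmetric":
            if self.wall_offset.shape != self.axial_samples.shape:
                raise InvalidGeometryError("wall_offset shape mismatch")
            if np.any(self.wall_offset <= 0):
                raise InvalidGeometryError("lumen radius must be positive everywhere")
        else:
            if self.wall_offset.shape != (len(self.axial_samples), 2):
                raise InvalidGeometryError("planar wall_offset must be (n, 2)")
        if np.any(self.gap() <= 0):
            raise InvalidGeometryError("lumen gap must be positive everywhere")

    @property
    def total_length(self) -> float:
        return float(self.axial_samples[-1] - self.axial_samples[0])

    def gap(self) -> np.ndarray:
        """Lumen diameter (axisymmetric) or wall-to-wall gap (planar)."""
        if self.mode == "axisymmetric":
            return 2.0 * self.wall_offset
        return self.wall_offset.sum(axis=1)

    def reference_gap(self) -> float:
        return 2.0 * self.reference_radius

    def percent_stenosis(self) -> float:
        """WASID percent stenosis measured on the discretised lumen."""
        return percent_stenosis_wasid(float(self.gap().min()), self.reference_gap())

    def prominent_wall(self) -> str:
        """Wall carrying the greater share of the luminal narrowing.

        Axisymmetric lumens have a single wall; for planar lumens the deeper
        wall wins, with ties broken toward the upper wall.
        """
        if self.mode == "axisymmetric":
            return "wall"
        depth_lower = self.reference_radius - self.wall_offset[:, 0].min()
        depth_upper = self.reference_radius - self.wall_offset[:, 1].min()
        return "upper" if depth_upper >= depth_lower else "lower"

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write (z, wall_offset) columns in metres."""
        if self.mode == "axisymmetric":
            data = np.column_stack([self.axial_samples, self.wall_offset])
            header = "z_m,wall_offset_m"
        else:
            data = np.column_stack([self.axial_samples, self.wall_offset])
            header = "z_m,lower_wall_m,upper_wall_m"
        np.savetxt(path, data, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path: str | Path, reference_radius: float,
                 mode: str = "axisymmetric") -> "VesselGeometry":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        wall = data[:, 1] if mode == "axisymmetric" else data[:, 1:3]
        return cls(data[:, 0], wall, mode, reference_radius)

    def to_vtk(self, path: str | Path, radial_lines: int = 9) -> None:
        """Export the lumen cross-section as a legacy structured-grid VTK."""
        from .solver.vtkio import write_structured_grid

        z = self.axial_samples
        eta = np.linspace(0.0, 1.0, radial_lines)
        if self.mode == "axisymmetric":
            lower, upper = np.zeros_like(self.wall_offset), self.wall_offset
        else:
            lower, upper = -self.wall_offset[:, 0], self.wall_offset[:, 1]
        y = lower[:, None] + eta[None, :] * (upper - lower)[:, None]
        zz = np.broadcast_to(z[:, None], y.shape)
        write_structured_grid(path, zz, y, point_data={})


def make_stenosis_profile(spec: StenosisSpec, vessel_length: float,
                          axial_resolution: int = 1025) -> VesselGeometry:
    """Discretise a cosine-bump stenosis into a :class:`VesselGeometry`.

    The fractional lumen reduction is
    ``f(z) = (s/2) * (1 + cos(2*pi*(z - z0)/L))`` for ``|z - z0| <= L/2`` and
    zero outside, which is C^1 at the lesion edges and reaches the WASID
    severity ``s`` exactly at the throat.  The vessel must leave at least five
    unstenosed reference diameters on each side of the lesion.
    """
    if axial_resolution < 2:
        raise InputError("axial_resolution must be >= 2")
    D = 2.0 * spec.reference_radius
    if vessel_length < spec.lesion_length + 10.0 * D:
        raise InvalidGeometryError(
            "vessel_length must be >= lesion_length + 10 reference diameters")
    z_start = spec.center_position - spec.lesion_length / 2.0
    z_end = spec.center_position + spec.lesion_length / 2.0
    if z_start < 5.0 * D or z_end > vessel_length - 5.0 * D:
        raise InvalidGeometryError(
            "lesion must leave >= 5 unstenosed reference diameters at each end")

    z = np.linspace(0.0, vessel_length, axial_resolution)
    s = spec.severity
    f = np.zeros_like(z)
    inside = np.abs(z - spec.center_position) <= spec.lesion_length / 2.0
    f[inside] = 0.5 * s * (
        1.0 + np.cos(2.0 * np.pi * (z[inside] - spec.center_position)
                     / spec.lesion_length))

    R = spec.reference_radius
    if spec.side == "axisymmetric":
        return VesselGeometry(z, R * (1.0 - f), "axisymmetric", R, spec)
    lower = np.full_like(z, R)
    upper = np.full_like(z, R)
    if spec.side == "both":
        lower -= R * f
        upper -= R * f
    elif spec.side == "upper":
        upper -= 2.0 * R * f
    else:  # lower
        lower -= 2.0 * R * f
    return VesselGeometry(z, np.column_stack([lower, upper]), "planar", R, spec)


def detect_lesion_extent(geometry: VesselGeometry,
                         deficit_threshold: float = 0.02
                         ) -> tuple[float, float, float]:
    """Locate the stenosis entrance, apex (throat) and exit.

    The entrance/exit are the axial positions where the relative lumen
    deficit ``1 - gap(z)/gap_ref`` first/last crosses ``deficit_threshold``
    (linearly interpolated between samples); the apex is the sampled position
    of minimum lumen gap, ties broken toward the most upstream sample.
    """
    if not (0.0 < deficit_threshold < 0.5):
        raise InputError("deficit_threshold must be in (0, 0.5)")
    z = geometry.axial_samples
    deficit = 1.0 - geometry.gap() / geometry.reference_gap()
    above = deficit > deficit_threshold
    if not above.any():
        raise NoLesionError(
            f"no lumen deficit exceeds threshold {deficit_threshold}")
    idx = np.flatnonzero(above)
    if np.any(np.diff(idx) > 1):
        raise AmbiguousLesionError("multiple disjoint lesions detected")

    def cross(i_out: int, i_in: int) -> float:
        """Interpolate the threshold crossing between two adjacent samples."""
        d0, d1 = deficit[i_out], deficit[i_in]
        if d1 == d0:
            return float(z[i_in])
        w = (deficit_threshold - d0) / (d1 - d0)
        return float(z[i_out] + w * (z[i_in] - z[i_out]))

    z_origin = float(z[idx[0]]) if idx[0] == 0 else cross(idx[0] - 1, idx[0])
    z_terminal = (float(z[idx[-1]]) if idx[-1] == len(z) - 1
                  else cross(idx[-1] + 1, idx[-1]))
    i_apex = int(np.argmin(geometry.gap()))
    z_apex = float(z[i_apex])
    if not (z_origin < z_apex < z_terminal):
        raise InvalidGeometryError(
            f"degenerate lesion extent ({z_origin}, {z_apex}, {z_terminal})")
    return z_origin, z_apex, z_terminal
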