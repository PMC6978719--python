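"""The five-point measurement scheme on the prominent-side wall.

Each lesion is measured along the wall carrying the greater share of the
luminal narrowing: five points — the stenosis entrance (origin), the
midpoint of the upstream section (M_up), the point of maximal encroachment
(apex), the midpoint of the downstream section (M_down) and the stenosis
exit (terminal) — plus the wall-profile extrema of WSS and pressure between
origin and terminal.  Derived indices normalise by the origin-point value
(WSS ratio max/origin, pressure ratio terminal/origin) or measure absolute
translesional losses (pressure drop origin-to-terminal and its four
segment contributions).

Conventions (resolution-controlled, deterministic): point values are
linearly interpolated between profile samples; extrema are taken over the
sampled profile with ties broken toward the most upstream position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cohort import LesionCase
from .errors import InputError, InvalidGeometryError
from .solver.wall import WallProfile

POINT_NAMES = ("origin", "m_up", "apex", "m_down", "terminal")

FINE_LABELS = (
    "Origin", "Origin-to-Mup", "Mup", "Mup-to-apex", "Apex",
    "Apex-to-Mdown", "Mdown", "Mdown-to-terminal", "Terminal",
)

#: Table-style coarse vocabulary: the two downstream open sections merge
#: into "Downstream"; the M_up point reports as "Upstream".
COARSE_MAP = {
    "Origin": "Origin",
    "Origin-to-Mup": "Origin-to-Mup",
    "Mup": "Upstream",
    "Mup-to-apex": "Mup-to-apex",
    "Apex": "Apex",
    "Apex-to-Mdown": "Downstream",
    "Mdown": "Mdown",
    "Mdown-to-terminal": "Downstream",
    "Terminal": "Terminal",
}


@dataclass(frozen=True)
class FivePoints:
    """Arc positions (m) of the five measuring points along the wall."""

    s_origin: float
    s_m_up: float
    s_apex: float
    s_m_down: float
    s_terminal: float

    def __post_init__(self):
        seq = (self.s_origin, self.s_m_up, self.s_apex, self.s_m_down,
               self.s_terminal)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise InvalidGeometryError(
                f"five points must be strictly ordered, got {seq}")

    @property
    def positions(self) -> tuple[float, ...]:
        return (self.s_origin, self.s_m_up, self.s_apex, self.s_m_down,
                self.s_terminal)

    @property
    def lesion_length(self) -> float:
        return self.s_terminal - self.s_origin


@dataclass(frozen=True)
class Extremum:
    """An extremum value, its arc position and its section label."""

    value: float
    arc_position: float
    label: str


@dataclass
class LesionIndices:
    """Every per-lesion index of the measurement scheme.

    When the origin WSS or pressure is zero the normalised ratios are
    undefined and reported as NaN (``ratios_defined`` False); the absolute
    indices are always populated.
    """

    wss_at: dict[str, float]
    pressure_at: dict[str, float]
    wss_max: Extremum
    wss_min: Extremum
    pressure_max: Extremum
    pressure_min: Extremum
    wss_ratio_max_over_origin: float
    wss_ratio_min_over_origin: float
    pressure_ratio_terminal_over_origin: float
    pressure_drop_total: float
    segment_drops: tuple[float, float, float, float]
    ratios_defined: bool
    point_positions: tuple[float, float, float, float, float] = (
        float("nan"),) * 5


def locate_five_points(profile: WallProfile,
                       extent: tuple[float, float, float]) -> FivePoints:
    """Map an axial lesion extent onto the wall arc and place the points.

    ``extent`` is (z_origin, z_apex, z_terminal) in axial coordinates; the
    mid-points are arc-length midpoints of the upstream and downstream
    sections.
    """
    z_origin, z_apex, z_terminal = extent
    z_lo, z_hi = profile.axial_positions[0], profile.axial_positions[-1]
    if not (z_lo <= z_origin and z_terminal <= z_hi):
        raise InputError("lesion extent outside the profiled wall")
    s_origin = float(profile.arc_of_axial(z_origin))
    s_apex = float(profile.arc_of_axial(z_apex))
    s_terminal = float(profile.arc_of_axial(z_terminal))
    return FivePoints(
        s_origin=s_origin,
        s_m_up=0.5 * (s_origin + s_apex),
        s_apex=s_apex,
        s_m_down=0.5 * (s_apex + s_terminal),
        s_terminal=s_terminal,
    )


def classify_extremum_location(s: float, points: FivePoints,
                               point_tolerance: float = 0.02) -> str:
    """Assign an arc position to a named point or enclosing open section.

    Positions within ``point_tolerance`` (a fraction of the lesion length)
    of a named point get that point's label; otherwise the enclosing open
    section.  Total on [s_origin, s_terminal].
    """
    if not (points.s_origin <= s <= points.s_terminal):
        raise InputError(
            f"position {s} outside lesion [{points.s_origin}, "
            f"{points.s_terminal}]")
    tol = point_tolerance * points.lesion_length
    named = list(zip(points.positions,
                     ("Origin", "Mup", "Apex", "Mdown", "Terminal")))
    dists = [abs(s - p) for p, _ in named]
    i_near = int(np.argmin(dists))
    if dists[i_near] <= tol:
        return named[i_near][1]
    sections = ("Origin-to-Mup", "Mup-to-apex", "Apex-to-Mdown",
                "Mdown-to-terminal")
    for (p_lo, _), (p_hi, _), name in zip(named, named[1:], sections):
        if p_lo < s < p_hi:
            return name
    # numerically on a point boundary after the tolerance test
    return named[i_near][1]


def coarse_label(fine: str) -> str:
    """Coarse table vocabulary for a fine section label."""
    return COARSE_MAP[fine]


def extract_indices(profile: WallProfile, points: FivePoints,
                    point_tolerance: float = 0.02) -> LesionIndices:
    """Compute all WSS/pressure indices of one lesion.

    Extrema are searched over [s_origin, s_terminal] only, on the sampled
    profile (endpoints included by interpolation), ties broken upstream.
    """
    s = profile.arc_length
    if not (s[0] <= points.s_origin and points.s_terminal <= s[-1]):
        raise InputError("profile does not cover the lesion")

    def interp(arr, pos):
        return float(np.interp(pos, s, arr))

    wss_at = {name: interp(profile.wss, pos)
              for name, pos in zip(POINT_NAMES, points.positions)}
    pressure_at = {name: interp(profile.wall_pressure, pos)
                   for name, pos in zip(POINT_NAMES, points.positions)}

    inside = (s > points.s_origin) & (s < points.s_terminal)
    cand_s = np.concatenate([[points.s_origin], s[inside],
                             [points.s_terminal]])
    cand_wss = np.concatenate([[wss_at["origin"]], profile.wss[inside],
                               [wss_at["terminal"]]])
    cand_p = np.concatenate([[pressure_at["origin"]],
                             profile.wall_pressure[inside],
                             [pressure_at["terminal"]]])

    def extremum(values, arg_fn) -> Extremum:
        i = int(arg_fn(values))          # first occurrence = most upstream
        return Extremum(
            value=float(values[i]), arc_position=float(cand_s[i]),
            label=classify_extremum_location(float(cand_s[i]), points,
                                             point_tolerance))

    wss_max = extremum(cand_wss, np.argmax)
    wss_min = extremum(cand_wss, np.argmin)
    pressure_max = extremum(cand_p, np.argmax)
    pressure_min = extremum(cand_p, np.argmin)

    p_pts = [pressure_at[k] for k in POINT_NAMES]
    segment_drops = tuple(float(a - b) for a, b in zip(p_pts, p_pts[1:]))
    pressure_drop_total = float(p_pts[0] - p_pts[-1])

    defined = wss_at["origin"] > 0 and pressure_at["origin"] > 0
    if defined:
        wr_max = wss_max.value / wss_at["origin"]
        wr_min = wss_min.value / wss_at["origin"]
        p_ratio = pressure_at["terminal"] / pressure_at["origin"]
    else:
        wr_max = wr_min = p_ratio = float("nan")

    return LesionIndices(
        wss_at=wss_at, pressure_at=pressure_at,
        wss_max=wss_max, wss_min=wss_min,
        pressure_max=pressure_max, pressure_min=pressure_min,
        wss_ratio_max_over_origin=float(wr_max),
        wss_ratio_min_over_origin=float(wr_min),
        pressure_ratio_terminal_over_origin=float(p_ratio),
        pressure_drop_total=pressure_drop_total,
        segment_drops=segment_drops,
        ratios_defined=bool(defined),
        point_positions=points.positions,
    )


TANDEM_DISTANCE_LIMIT = 0.02  # m: tandem lesions closer than 2 cm interfere


def exclusion_filter(cases: Iterable[LesionCase]
                     ) -> tuple[list[LesionCase],
                                list[tuple[LesionCase, str]]]:
    """Apply the lesion exclusion rules before any flow is solved.

    Lesions with a neighbouring lesion closer than 2 cm (tandem) or sitting
    at a bifurcation/branch opening are excluded, each with a
    machine-readable reason; a missing neighbour distance means no
    neighbour.
    """
    retained: list[LesionCase] = []
    excluded: list[tuple[LesionCase, str]] = []
    for case in cases:
        dist = case.distance_to_nearest_lesion
        if dist is not None and dist < TANDEM_DISTANCE_LIMIT:
            excluded.append((case, "tandem"))
        elif case.at_bifurcation:
            excluded.append((case, "bifurcation"))
        else:
            retained.append(case)
    return retained, excluded
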