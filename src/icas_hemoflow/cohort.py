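"""Synthetic lesion cohorts.

Emulates the study population that the original measurements came from:
middle-cerebral-artery lesions with WASID percent stenosis ~ Normal(43.2,
17.3^2)% clipped to [10, 85]%, MCA-scale lumen radii, carotid-ultrasound
peak-systolic/end-diastolic velocities for the inlet flow-rate formula,
brachial blood pressure for pressure anchoring, age/sex covariates, and
tandem-lesion / bifurcation flags for the exclusion rules.

All randomness flows from one root seed split into named substreams, so that
adding a sampling stage never perturbs another stage's draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .geometry import StenosisSpec

# Stable substream identifiers: appending new streams keeps old draws intact.
_STREAMS = {
    "stenosis": 0,
    "geometry": 1,
    "velocity": 2,
    "pressure": 3,
    "covariates": 4,
    "flags": 5,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of a root seed (independent, reproducible)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],)))


@dataclass(frozen=True)
class Population:
    """Distribution parameters of the synthetic cohort.

    Stenosis mean/SD, mean age and the sex ratio are anchored to the study
    demographics; the remaining values are standard adult cerebrovascular
    physiology.  Units: m, m/s, mmHg, years.
    """

    stenosis_mean: float = 43.2          # % (WASID)
    stenosis_sd: float = 17.3
    stenosis_range: tuple[float, float] = (10.0, 85.0)
    radius_mean: float = 1.5e-3          # m
    radius_sd: float = 0.15e-3
    lesion_length_mean: float = 8.0e-3   # m
    lesion_length_sd: float = 1.5e-3
    lesion_length_range: tuple[float, float] = (4.0e-3, 12.0e-3)
    psv_mean: float = 0.9                # m/s
    psv_sd: float = 0.2
    psv_min: float = 0.3
    edv_frac_range: tuple[float, float] = (0.3, 0.6)
    systolic_mean: float = 130.0         # mmHg
    systolic_sd: float = 15.0
    diastolic_mean: float = 80.0
    diastolic_sd: float = 10.0
    age_mean: float = 65.5               # years
    age_sd: float = 8.0
    male_prob: float = 0.545
    tandem_prob: float = 0.1
    tandem_distance_range: tuple[float, float] = (0.005, 0.04)  # m
    bifurcation_prob: float = 0.1
    side_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)  # upper/lower/both

    def __post_init__(self):
        for name in ("stenosis_sd", "radius_sd", "lesion_length_sd", "psv_sd",
                     "systolic_sd", "diastolic_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError("standard deviation must be >= 0", name)
        for name in ("stenosis_range", "lesion_length_range", "edv_frac_range",
                     "tandem_distance_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError("range must satisfy low < high", name)
        for name in ("male_prob", "tandem_prob", "bifurcation_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError("probability must be in [0, 1]", name)
        if abs(sum(self.side_probs) - 1.0) > 1e-9:
            raise ConfigurationError("side_probs must sum to 1", "side_probs")

    @classmethod
    def from_dict(cls, overrides: dict) -> "Population":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(overrides) - known
        if bad:
            raise ConfigurationError("unknown population parameter",
                                     f"population.{sorted(bad)[0]}")
        values = {k: tuple(v) if isinstance(v, list) else v
                  for k, v in overrides.items()}
        return cls(**values)


@dataclass(frozen=True)
class LesionCase:
    """One synthetic patient lesion: geometry, inlet data and covariates."""

    case_id: str
    spec: StenosisSpec
    psv: float                  # peak-systolic velocity, m/s
    edv: float                  # end-diastolic velocity, m/s
    inlet_radius: float         # m
    systolic_bp: float          # mmHg
    diastolic_bp: float         # mmHg
    age: float                  # years
    sex: str                    # "M" / "F"
    distance_to_nearest_lesion: float | None  # m, None = no neighbour
    at_bifurcation: bool

    def __post_init__(self):
        if not (self.psv >= self.edv > 0):
            raise ConfigurationError("require psv >= edv > 0", "psv/edv")
        if not (self.systolic_bp > self.diastolic_bp > 0):
            raise ConfigurationError("require systolic > diastolic > 0", "bp")


def sample_cohort(n: int = 55, seed: int = 0,
                  population: Population | None = None) -> list[LesionCase]:
    """Draw ``n`` synthetic lesion cases, bit-reproducible for a fixed seed.

    Stenosis severities are clipped to ``population.stenosis_range``;
    ``psv >= edv > 0`` and ``systolic > diastolic`` hold per case by
    construction.  Lesions are centred in a vessel long enough for the flow
    solver's entry/exit requirements (set later by the pipeline).
    """
    if n < 1:
        raise ConfigurationError("cohort size must be >= 1", "n")
    pop = population or Population()

    rng_sten = substream(seed, "stenosis")
    rng_geom = substream(seed, "geometry")
    rng_vel = substream(seed, "velocity")
    rng_bp = substream(seed, "pressure")
    rng_cov = substream(seed, "covariates")
    rng_flag = substream(seed, "flags")

    stenosis = np.clip(rng_sten.normal(pop.stenosis_mean, pop.stenosis_sd, n),
                       *pop.stenosis_range)
    radius = np.clip(rng_geom.normal(pop.radius_mean, pop.radius_sd, n),
                     0.5e-3, None)
    length = np.clip(rng_geom.normal(pop.lesion_length_mean,
                                     pop.lesion_length_sd, n),
                     *pop.lesion_length_range)
    psv = np.clip(rng_vel.normal(pop.psv_mean, pop.psv_sd, n), pop.psv_min, None)
    edv = psv * rng_vel.uniform(*pop.edv_frac_range, n)
    sbp = np.clip(rng_bp.normal(pop.systolic_mean, pop.systolic_sd, n), 90.0, None)
    dbp = np.clip(rng_bp.normal(pop.diastolic_mean, pop.diastolic_sd, n),
                  40.0, None)
    dbp = np.minimum(dbp, sbp - 10.0)
    age = np.clip(rng_cov.normal(pop.age_mean, pop.age_sd, n), 18.0, 95.0)
    sex = np.where(rng_cov.uniform(size=n) < pop.male_prob, "M", "F")
    side = rng_cov.choice(["upper", "lower", "both"], size=n, p=pop.side_probs)
    tandem = rng_flag.uniform(size=n) < pop.tandem_prob
    tandem_dist = rng_flag.uniform(*pop.tandem_distance_range, n)
    at_bif = rng_flag.uniform(size=n) < pop.bifurcation_prob

    cases = []
    for i in range(n):
        # Six unstenosed diameters upstream of the lesion; the pipeline adds
        # a longer downstream run-out for the post-stenotic jet.
        spec = StenosisSpec(
            reference_radius=float(radius[i]),
            percent_stenosis=float(stenosis[i]),
            lesion_length=float(length[i]),
            center_position=float(length[i] / 2.0 + 12.0 * radius[i]),
            side=str(side[i]),
        )
        cases.append(LesionCase(
            case_id=f"L{i + 1:03d}",
            spec=spec,
            psv=float(psv[i]),
            edv=float(edv[i]),
            inlet_radius=float(radius[i]),
            systolic_bp=float(sbp[i]),
            diastolic_bp=float(dbp[i]),
            age=float(age[i]),
            sex=str(sex[i]),
            distance_to_nearest_lesion=float(tandem_dist[i]) if tandem[i] else None,
            at_bifurcation=bool(at_bif[i]),
        ))
    return cases


# -- flat-table I/O --------------------------------------------------------

_COLUMNS = [
    "case_id", "percent_stenosis", "reference_radius_m", "lesion_length_m",
    "center_position_m", "side", "psv_m_s", "edv_m_s", "inlet_radius_m",
    "systolic_bp_mmhg", "diastolic_bp_mmhg", "age_years", "sex",
    "distance_to_nearest_lesion_m", "at_bifurcation",
]


def cohort_to_frame(cases: Sequence[LesionCase]) -> pd.DataFrame:
    """One row per lesion; documented column names with units."""
    rows = [{
        "case_id": c.case_id,
        "percent_stenosis": c.spec.percent_stenosis,
        "reference_radius_m": c.spec.reference_radius,
        "lesion_length_m": c.spec.lesion_length,
        "center_position_m": c.spec.center_position,
        "side": c.spec.side,
        "psv_m_s": c.psv,
        "edv_m_s": c.edv,
        "inlet_radius_m": c.inlet_radius,
        "systolic_bp_mmhg": c.systolic_bp,
        "diastolic_bp_mmhg": c.diastolic_bp,
        "age_years": c.age,
        "sex": c.sex,
        "distance_to_nearest_lesion_m": c.distance_to_nearest_lesion,
        "at_bifurcation": c.at_bifurcation,
    } for c in cases]
    return pd.DataFrame(rows, columns=_COLUMNS)


def cohort_to_csv(cases: Sequence[LesionCase], path: str | Path) -> None:
    # %.17g keeps every float bit-exact through the round trip
    cohort_to_frame(cases).to_csv(path, index=False, float_format="%.17g")


def cohort_from_csv(path: str | Path) -> list[LesionCase]:
    df = pd.read_csv(path, float_precision="round_trip")
    cases = []
    for _, r in df.iterrows():
        spec = StenosisSpec(
            reference_radius=float(r["reference_radius_m"]),
            percent_stenosis=float(r["percent_stenosis"]),
            lesion_length=float(r["lesion_length_m"]),
            center_position=float(r["center_position_m"]),
            side=str(r["side"]),
        )
        dist = r["distance_to_nearest_lesion_m"]
        cases.append(LesionCase(
            case_id=str(r["case_id"]), spec=spec,
            psv=float(r["psv_m_s"]), edv=float(r["edv_m_s"]),
            inlet_radius=float(r["inlet_radius_m"]),
            systolic_bp=float(r["systolic_bp_mmhg"]),
            diastolic_bp=float(r["diastolic_bp_mmhg"]),
            age=float(r["age_years"]), sex=str(r["sex"]),
            distance_to_nearest_lesion=None if pd.isna(dist) else float(dist),
            at_bifurcation=bool(r["at_bifurcation"]),
        ))
    return cases
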