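import numpy as np
import pytest

from icas_hemoflow import (
    FluidProperties,
    NumericsConfig,
    StenosisSpec,
    VesselGeometry,
    inlet_condition,
    make_stenosis_profile,
    solve_steady_flow,
    wall_profile,
)


@pytest.fixture(scope="session")
def coarse_numerics():
    """Fast grid for unit tests; acceptance tests use the default grid."""
    return NumericsConfig(axial_cells=96, radial_cells=24)


@pytest.fixture(scope="session")
def straight_tube():
    R, L = 0.002, 0.02
    z = np.linspace(0.0, L, 257)
    return VesselGeometry(z, np.full_like(z, R), "axisymmetric", R)


@pytest.fixture(scope="session")
def reference_inlet():
    """psv = edv = 0.4 m/s in a 2 mm tube: Q ~ 5.027e-6 m^3/s."""
    return inlet_condition(psv=0.4, edv=0.4, inlet_radius=0.002,
                           systolic_bp=130.0, diastolic_bp=80.0)


@pytest.fixture(scope="session")
def stenosed_case_50(coarse_numerics):
    """One solved 50% axisymmetric lesion shared across test modules."""
    R, length = 1.5e-3, 8e-3
    D = 2.0 * R
    spec = StenosisSpec(R, 50.0, length, 6.0 * D + length / 2.0)
    geom = make_stenosis_profile(spec, length + 36.0 * D, 2049)
    inlet = inlet_condition(psv=0.4, edv=0.16, inlet_radius=R,
                            systolic_bp=130.0, diastolic_bp=80.0)
    field = solve_steady_flow(geom, inlet, None, FluidProperties(),
                              coarse_numerics)
    profile = wall_profile(field)
    return geom, inlet, field, profile
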