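"""Validate the flow solver against the closed-form Poiseuille solution.

Builds a straight 2 mm-radius tube, drives it with a fully developed inflow
at Q ~ 5.03e-6 m^3/s, and compares the computed translesional pressure drop
and wall shear stress with the analytic values dP = 8 mu L Q / (pi R^4) and
tau_w = 4 mu Q / (pi R^3).  Relative errors of a fraction of a percent mean
the discretisation reproduces the viscous physics it is built on.
"""

import numpy as np

from icas_hemoflow import (
    VesselGeometry,
    inlet_condition,
    poiseuille_reference,
    solve_steady_flow,
    wall_profile,
)

R, L = 0.002, 0.02
z = np.linspace(0.0, L, 257)
tube = VesselGeometry(z, np.full_like(z, R), "axisymmetric", R)
inlet = inlet_condition(psv=0.4, edv=0.4, inlet_radius=R,
                        systolic_bp=130.0, diastolic_bp=80.0)

field = solve_steady_flow(tube, inlet)
profile = wall_profile(field)

dp = profile.wall_pressure[0] - profile.wall_pressure[-1]
tau = profile.wss[64:192].mean()
dp_ref, tau_ref = poiseuille_reference(inlet.flow_rate, R, L, 3.5e-3)

print(f"flow rate Q            = {inlet.flow_rate:.3e} m^3/s")
print(f"pressure drop          = {dp:.3f} Pa (analytic {dp_ref:.3f} Pa, "
      f"error {100 * abs(dp - dp_ref) / dp_ref:.3f}%)")
print(f"wall shear stress      = {tau:.4f} Pa (analytic {tau_ref:.4f} Pa, "
      f"error {100 * abs(tau - tau_ref) / tau_ref:.3f}%)")
print(f"mass conservation      = {100 * field.mass_conservation_error:.4f}% "
      f"in-vs-out imbalance")
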