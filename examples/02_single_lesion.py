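"""Solve one 50% stenosed MCA-scale vessel and print its wall indices.

The lesion is a cosine-shaped axisymmetric plaque.  The printed indices are
the five-point measurement scheme: WSS and wall pressure at the stenosis
entrance (origin), upstream midpoint (M_up), throat (apex), downstream
midpoint (M_down) and exit (terminal), the profile extrema with their
section labels, and the translesional pressure ratio/drop — an FFR-like
summary of the lesion's functional severity.
"""

from icas_hemoflow import RunConfig, default_sweep_template, solve_and_measure
import dataclasses

template = default_sweep_template()
case = dataclasses.replace(
    template, spec=dataclasses.replace(template.spec, percent_stenosis=50.0))

indices, diag = solve_and_measure(case, RunConfig(seed=0))

print(f"throat-jet Reynolds number: {diag['re_jet']:.0f} "
      f"({diag['solver_iterations']} solver iterations)")
for name in ("origin", "m_up", "apex", "m_down", "terminal"):
    print(f"  {name:9s}: WSS = {indices.wss_at[name]:7.2f} Pa, "
          f"p = {indices.pressure_at[name]:9.1f} Pa")
print(f"WSS_max  = {indices.wss_max.value:.2f} Pa at {indices.wss_max.label}")
print(f"WSS_min  = {indices.wss_min.value:.2f} Pa at {indices.wss_min.label}")
print(f"WSS ratio (max/origin)          = "
      f"{indices.wss_ratio_max_over_origin:.2f}")
print(f"pressure ratio (terminal/origin) = "
      f"{indices.pressure_ratio_terminal_over_origin:.4f}")
print(f"pressure drop (origin->terminal) = "
      f"{indices.pressure_drop_total:.1f} Pa")
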