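# Example run configuration for `icas-hemoflow run --config ...`.
# Every omitted field keeps the default documented in docs/methods.md.

seed: 1
n_lesions: 55

population:
  stenosis_mean: 43.2        # % WASID
  stenosis_sd: 17.3
  stenosis_range: [10.0, 85.0]
  radius_mean: 1.5e-3        # m
  psv_mean: 0.9              # m/s
  age_mean: 65.5             # years
  male_prob: 0.545

geometry:
  mode: axisymmetric         # or: planar (eccentric plaques)
  upstream_diameters: 6.0
  downstream_diameters: 30.0
  deficit_threshold: 0.02    # lesion entrance/exit detection

solver:
  axial_cells: 256
  radial_cells: 48
  convergence_tolerance: 1.0e-6
  reynolds_cap: 2000.0
  density: 1060.0            # kg/m^3
  dynamic_viscosity: 3.5e-3  # Pa s
  outlet_kind: reference_pressure   # or: resistance

measurement:
  point_tolerance: 0.02      # fraction of lesion length

stats:
  cutoff_percent: 50.0
  alpha: 0.05
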