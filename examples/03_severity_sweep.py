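"""Sweep stenosis severity on a fixed vessel and show the index trends.

At a fixed flow rate the translesional pressure drop and peak WSS grow
superlinearly with percent stenosis, and the pressure ratio falls — the
hallmark nonlinearity that makes ~50% diameter stenosis a hemodynamic
turning point.
"""

from icas_hemoflow import RunConfig, sweep_stenosis

table = sweep_stenosis([20, 30, 40, 50, 60, 70, 80], RunConfig(seed=0),
                       progress=True)
cols = ["percent_stenosis", "wss_max_pa", "wss_ratio_max_origin",
        "pressure_drop_pa", "pressure_ratio"]
print(table[cols].to_string(index=False,
                            float_format=lambda v: f"{v:.3f}"))
print("\nEach added decade of severity multiplies the normalised WSS peak;"
      "\nthe pressure ratio only departs from ~1 beyond moderate stenosis.")
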