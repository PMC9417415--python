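"""Rank components by concentration-gradient sensitivity.

Computes S = 1 - (normalized area under the cubic gradient fit) for every
component and growth parameter, sums them into the global sensitivity
S_g, and reports the balance criteria that say whether a component acts
evenly across the three growth phases.
"""

import ecogrowth as eg

design = eg.generate_design(n_components=20, levels_per_gradient=6,
                            n_backgrounds=6, seed=3)
model = eg.ResponseModel(determinant_map={"tau": "alanine", "rate": "glutamate",
                                          "capacity": "glycine"}, noise_sd=0.0)
truth = eg.ground_truth_parameters(design, model)

table = eg.component_sensitivity_table(design, truth)
cols = ["s_tau", "s_rate", "s_capacity", "s_g", "v_s", "crit4_deg"]
print(table[cols].sort_values("s_g", ascending=False)
      .to_string(float_format=lambda v: f"{v:.3f}"))
print("\nLarge S_g: growth responds strongly to that component's gradient. "
      "V_s near 0 and crit4 near 60 deg: the sensitivity is balanced over "
      "lag, exponential and stationary phases.")

fits = eg.sensitivity.power_law_summary(table)
print("\nTail fits of the sensitivity distributions:")
print(fits.to_string(float_format=lambda v: f"{v:.3f}"))
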