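"""Risk diversification: single vs multiple growth decision makers.

Simulates 24 h lag-logistic population dynamics where the three growth
parameters are set by one shared random variable (single decision maker)
or by three variables (independent, or coupled with the observed
correlation strengths), and compares survival across extinction
thresholds and final population sizes.
"""

import numpy as np

import ecogrowth as eg

cfg = eg.SimulationConfig(seed=0)

single = eg.survival_probability("single", cfg, n_sims=1000)
triple = eg.survival_probability("triple_independent", cfg, n_sims=1000)
print("d_r   single  triple_independent")
for d in (0.0, 0.2, 0.4, 0.6, 0.8):
    s = single.loc[np.isclose(single.d_r, d), "survival"].iloc[0]
    t = triple.loc[np.isclose(triple.d_r, d), "survival"].iloc[0]
    print(f"{d:.2f}  {s:6.3f}  {t:6.3f}")
print("At high extinction thresholds the three independent decision makers "
      "keep a markedly larger fraction of populations alive.\n")

out = eg.compare_final_sizes(cfg, n_sims=10_000)
m_triple = np.median(out.sizes["triple_correlated"])
m_single = np.median(out.sizes["single"])
print(f"median N(24): triple_correlated={m_triple:.3f}  single={m_single:.3f}")
print(f"Mann-Whitney U p-value: {out.p_value:.2e}")
print("Even with the observed parameter correlations, distributing fate "
      "decisions over three cues yields larger final populations.")
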