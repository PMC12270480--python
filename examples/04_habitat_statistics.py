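"""Habitat x quadrant mixed-model analysis on a simulated scene survey.

Simulates a magnitude table with known effects (ventral flow strongest,
open habitats brightest, scenes sharing random intercepts), fits
``magnitude ~ habitat * quadrant + (1 | scene)`` by maximum likelihood,
compares it against the reduced models by AIC, and prints Tukey-adjusted
pairwise contrasts of the marginal means.
"""

from tunnelvision import StatsDesign, TableEffects, fit_lmm, lmm_pairwise, simulate_metric_table

design = StatsDesign()
effects = TableEffects(
    grand_mean=2.0,
    habitat={"open": 1.0, "closed": -0.5},
    quadrant={"ventral": 1.5, "dorsal": -1.0},
    sd_scene=0.5,
    sd_residual=1.0,
)
table = simulate_metric_table(design, effects, n_per_cell=6, seed=17)

lmm = fit_lmm(table, design)
print("model AICs:", {k: round(v, 1) for k, v in lmm.model_aics.items()})
print("full model preferred (lowest AIC and deviance):", lmm.full_model_preferred)
print(f"scene variance {lmm.scene_variance:.3f}, residual variance {lmm.residual_variance:.3f}")

contrasts = lmm_pairwise(lmm)
print(contrasts[["factor", "level_a", "level_b", "estimate", "se", "p_tukey", "stars"]]
      .round(4).to_string(index=False))

# The ventral-dorsal contrast is the strongest (***): ventral fields carry
# the most optic flow in this simulated survey, as the generating effects
# dictate.  Habitat contrasts are tested against the between-scene error.
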