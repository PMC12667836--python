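"""Rostro-caudal abundance gradients with a random-intercept mixed model.

Simulates sections at five levels (AC+2 ... AC-8) for three animals; the
generator gives D2-Matrix a caudal enrichment while D1-Matrix stays flat.
Percentages are computed per section within the MSN group, and the slope of
percent on the rostral-to-caudal section index is tested with an
animal-random-intercept LMM.
"""

import pandas as pd

from striatlas import synth
from striatlas.spatialstats import abundance_gradient, lmm_fit, loess_smooth

cfg = synth.demo_config(seed=1)
panel = synth.make_reference(cfg)
levels = [2.0, 0.0, -2.0, -4.0, -8.0]
sections = synth.make_rc_series(panel, cfg, levels, n_animals=3, n_species=2)
obs = pd.concat([s.obs for s in sections])

grad = abundance_gradient(obs, group=list(synth.DEMO_MSN_TYPES),
                          pair=("D1-VS-RGS6", "D1-VS"), label_col="true_type")
rc_index = {lev: i for i, lev in enumerate(sorted(levels, reverse=True))}
animal_of = obs.groupby("section_id", observed=True)["animal_id"].first()

for t in ("D1-Matrix", "D2-Matrix"):
    block = grad.per_section[grad.per_section["cell_type"] == t]
    fit = lmm_fit(block["percent"].to_numpy(),
                  block["rc_level_mm"].map(rc_index).to_numpy(dtype=float),
                  animal_of.loc[block["section_id"]].to_numpy())
    smooth = loess_smooth(block["rc_level_mm"].to_numpy(),
                          block["percent"].to_numpy(), span=0.9)
    print(f"{t:10s}: beta = {fit.beta:+.2f} %/level (se {fit.se_beta:.2f}), "
          f"p = {fit.p_value:.3g}; LOESS range "
          f"{smooth.min():.1f}-{smooth.max():.1f}%")
# beta is the change in the type's share of MSNs per caudal section step:
# positive and significant for the caudally enriched type, near zero for the
# flat one.
print()
print("per-level mean percent and SEM across sections:")
print(grad.sem_by_level.to_string(index=False))
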