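"""Two-round ATAC-style QC with the negative-binomial outlier model.

Round 1 keeps nuclei with at least 10^3.5 fragments; round 2 fits
nFrags ~ TSS enrichment + promoter ratio + doublet enrichment (NB, log link)
and drops nuclei whose standardized residual exceeds 2.
"""

import numpy as np
import pandas as pd

from striatlas.qc import nb_outlier_flags, rna_qc_filter

rng = np.random.default_rng(1)
n = 4000
tss = rng.normal(0, 1, n)
pr = rng.normal(0, 1, n)
de = rng.normal(0, 1, n)
mu = np.exp(8.6 + 0.3 * tss - 0.2 * pr + 0.1 * de)
y = rng.poisson(rng.gamma(10.0, mu / 10.0))
cells = pd.DataFrame({"nFrags": y, "TSSEnrichment": tss,
                      "PromoterRatio": pr, "DoubletEnrichment": de})

out, fit = nb_outlier_flags(cells)
print("NB fit:", ", ".join(f"{k}={v:.3f}" for k, v in fit.coef.items()),
      f"theta={fit.theta:.1f}")
print(f"round 1 (nFrags >= 10^3.5): {out['round1_pass'].sum()} / {n} pass")
print(f"round 2 (|residual| <= 2):  {out['round2_pass'].sum()} / {n} pass")
# The flagged fraction approximates P(|Pearson residual| > 2) under the
# fitted NB model (~4-5% for well-behaved data).

rna = pd.DataFrame({"nFeature": [2400, 3000, 11000, 5200],
                    "percent_mito": [1.0, 2.0, 1.0, 6.5]})
passed, summary = rna_qc_filter(rna)
print(f"\nRNA rule filter (2500 < nFeature < 10000 & mito < 5): "
      f"{summary['n_pass']} / {summary['n_cells']} pass")
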