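"""Demarcate the striatum with the spatial niche assay.

Each cell's microenvironment is the label composition of its 30 nearest
labeled neighbors; k-means over these compositions yields niches, and the
niche with the highest MSN proportion is the striatum mask.
"""

import warnings

from striatlas import synth
from striatlas.label import label_cells
from striatlas.niche import cluster_niches, neighborhood_composition

cfg = synth.demo_config(seed=1)
panel = synth.make_reference(cfg)
section = synth.make_section(panel, cfg, rc_level_mm=0.0, section_id="AC+0")
obs = section.obs.copy()
obs["assigned_label"] = label_cells(section, panel, classify=False)["assigned_label"]
# the niche assay runs on major classes: collapse MSN subtypes
obs["major_class"] = obs["assigned_label"].map(
    lambda v: "MSN" if v in set(synth.DEMO_MSN_TYPES) else v
)

composition = neighborhood_composition(obs, k_neighbors=30, label_col="major_class")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model = cluster_niches(composition, n_clusters=30, seed=0, msn_labels="MSN")

mask = model.striatum_mask().to_numpy()
truth = obs["true_type"].isin(synth.DEMO_MSN_TYPES).to_numpy()
print(f"niches used: {model.n_clusters}; striatal niche id: {model.striatal_niche}")
print(f"striatum mask sensitivity:     {100 * mask[truth].mean():.1f}%")
print(f"non-striatal false inclusion:  {100 * mask[~truth].mean():.1f}%")
# Sensitivity is the fraction of true striatal (MSN) cells inside the mask;
# false inclusion the fraction of cortical glia erroneously swept in.
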