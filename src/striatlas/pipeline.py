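"""End-to-end orchestration from a single config, with seed logging.

Stages run in dependency order (simulate -> qc -> label -> niche ->
rdd / gradients / de / relatedness / enrich / score_cells); each stage writes
its outputs plus a manifest entry recording parameters, its derived seed, and
sha256 checksums, so every file is traceable.  A single global seed is split
into per-stage substreams by hashing the stage name, so inserting a stage
does not perturb the draws of the others.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import io as slio
from . import synth
from .diffexp import pairwise_relatedness, pseudobulk_de
from .enrich import double_zscore_plus, gene_set_cell_score, signed_logfdr_matrix
from .label import label_cells
from .niche import cluster_niches, neighborhood_composition
from .spatialstats import AxisSpec, abundance_gradient, lmm_fit, rdd_pipeline

__all__ = ["STAGE_ORDER", "run_pipeline", "load_config", "demo_pipeline_config"]

STAGE_ORDER = [
    "simulate",
    "qc",
    "label",
    "niche",
    "rdd",
    "gradients",
    "de",
    "relatedness",
    "enrich",
    "score_cells",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stage-name-hashed substream seed (stable under stage insertion)."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def demo_pipeline_config(seed: int = 0, outdir: str = "striatlas_demo") -> dict:
    """Config for the bundled demo scenario (all stages, small sizes)."""
    return {
        "seed": seed,
        "outdir": outdir,
        "stages": list(STAGE_ORDER),
        "simulate": {"levels": [2.0, 0.0, -2.0, -4.0, -8.0], "n_animals": 3,
                     "n_species": 2},
        "label": {},
        "niche": {"k_neighbors": 30, "n_clusters": 10},
        "rdd": {"gene": "gene0010", "types": ["D1-VS", "D1-VS-RGS6"], "axis": "axis_x"},
        "gradients": {"group": list(synth.DEMO_MSN_TYPES),
                      "pair": ["D1-Matrix", "D2-Matrix"]},
        "de": {"min_cells": 15},
        "relatedness": {"min_cells": 15},
        "enrich": {"n_celltypes": 6, "n_studies": 24, "n_categories": 4},
        "score_cells": {"set_type": "D1-VS-RGS6"},
    }


# ---------------------------------------------------------------------------
# stages (file based; each returns {output name: path})


def stage_simulate(params: dict, outdir: Path, seed: int) -> dict:
    cfg = synth.demo_config(seed=seed)
    panel = synth.make_reference(cfg)
    levels = params.get("levels", [2.0, 0.0, -2.0, -4.0, -8.0])
    sections = synth.make_rc_series(
        panel, cfg, levels,
        n_animals=params.get("n_animals", 3),
        n_species=params.get("n_species", 2),
    )
    cells = ad.concat(sections, join="outer", merge="first")
    cells.obs_names_make_unique()
    cells.uns["seed"] = seed
    paths = slio.write_cells(cells, outdir)
    paths["reference"] = slio.write_reference(panel, outdir / "reference.tsv")
    return paths


def stage_qc(params: dict, outdir: Path, seed: int) -> dict:
    # spatial demo data carry no per-nucleus QC metrics; record the rule set
    rules = {
        "rna": {"min_features": 2500, "max_features": 10000, "max_mito": 5.0},
        "atac": {"fragment_threshold": 10**3.5, "residual_cutoff": 2.0},
        "applied": False,
    }
    path = slio.write_json(rules, outdir / "qc_rules.json")
    return {"qc_rules": path}


def stage_label(params: dict, outdir: Path, seed: int) -> dict:
    cells = slio.read_cells(outdir)
    panel = slio.read_reference(outdir / "reference.tsv")
    res = label_cells(cells, panel, classify=params.get("classify", False),
                      threshold=params.get("threshold", 0.5))
    res.index.name = "cell_id"
    path = outdir / "labels.tsv"
    res.to_csv(path, sep="\t")
    cells.obs["assigned_label"] = res["assigned_label"]
    slio.write_cells(cells, outdir)
    labeled = res["assigned_label"].notna() & (res["assigned_label"] != "UNCLASSIFIED")
    summary = {
        "n_cells": int(len(res)),
        "n_labeled": int(labeled.sum()),
        "accuracy_vs_truth": float(
            (res.loc[labeled, "assigned_label"] == cells.obs.loc[labeled, "true_type"]).mean()
        ),
    }
    spath = slio.write_json(summary, outdir / "label_summary.json")
    return {"labels": str(path), "label_summary": spath}


def stage_niche(params: dict, outdir: Path, seed: int) -> dict:
    cells = slio.read_cells(outdir)
    k = params.get("k_neighbors", 30)
    n_clusters = params.get("n_clusters", 10)
    # major-class annotations drive the niche assay: collapse MSN subtypes
    obs = cells.obs.copy()
    obs["major_class"] = obs["assigned_label"].astype(object).map(
        lambda v: "MSN" if v in set(synth.DEMO_MSN_TYPES) else v
    )
    frames = []
    for sec, block in obs.groupby("section_id", observed=True):
        comp = neighborhood_composition(block, k_neighbors=k, label_col="major_class")
        model = cluster_niches(comp, n_clusters=n_clusters, seed=seed,
                               msn_labels="MSN")
        frames.append(pd.DataFrame({
            "cell_id": comp.index,
            "section_id": sec,
            "niche_id": model.niche_of_cell.to_numpy(),
            "in_striatum": model.striatum_mask().to_numpy(),
        }))
    out = pd.concat(frames, ignore_index=True)
    path = outdir / "niches.tsv"
    out.to_csv(path, sep="\t", index=False)
    return {"niches": str(path)}


def stage_rdd(params: dict, outdir: Path, seed: int) -> dict:
    cells = slio.read_cells(outdir)
    spec = AxisSpec(mode=params.get("axis", "axis_x"), seed=seed)
    results = rdd_pipeline(
        cells,
        gene=params["gene"],
        type_pair=tuple(params["types"]),
        spec=spec,
        label_col=params.get("label_col", "assigned_label"),
    )
    rows = [vars(r) for r in results]
    df = pd.DataFrame(rows)
    path = outdir / "rdd.tsv"
    df.to_csv(path, sep="\t", index=False)
    jpath = slio.write_json(rows, outdir / "rdd.json")
    return {"rdd": str(path), "rdd_json": jpath}


def stage_gradients(params: dict, outdir: Path, seed: int) -> dict:
    cells = slio.read_cells(outdir)
    group = params.get("group", list(synth.DEMO_MSN_TYPES))
    pair = tuple(params["pair"]) if "pair" in params else None
    summary = abundance_gradient(cells.obs, group=group, pair=pair)
    path = outdir / "gradients.tsv"
    summary.per_section.to_csv(path, sep="\t", index=False)
    # per-type mixed-model slope of percent on rostral->caudal section index
    fits = {}
    ps = summary.per_section
    levels = sorted(ps["rc_level_mm"].unique(), reverse=True)  # rostral first
    rc_index = {lev: i for i, lev in enumerate(levels)}
    animal_of_sec = cells.obs.groupby("section_id", observed=True)["animal_id"].first()
    for t, block in ps.groupby("cell_type"):
        fit = lmm_fit(
            block["percent"].to_numpy(),
            block["rc_level_mm"].map(rc_index).to_numpy(dtype=float),
            animal_of_sec.loc[block["section_id"]].to_numpy(),
        )
        fits[t] = {"beta": fit.beta, "se": fit.se_beta, "p_value": fit.p_value,
                   "n_obs": fit.n_obs, "n_groups": fit.n_groups}
    jpath = slio.write_json(fits, outdir / "gradient_lmm.json")
    from .spatialstats import plot_gradient

    svg = plot_gradient(summary, str(outdir / "gradients.svg"))
    return {"gradients": str(path), "gradient_lmm": jpath, "gradient_plot": svg}


def stage_de(params: dict, outdir: Path, seed: int) -> dict:
    cells = slio.read_cells(outdir)
    lab = cells.obs["assigned_label"].astype(object)
    keep = lab.notna() & (lab != "UNCLASSIFIED")
    sub = cells[keep.to_numpy()]
    res = pseudobulk_de(
        sub.X, sub.obs["assigned_label"], sub.obs["animal_id"],
        list(sub.var_names), min_cells=params.get("min_cells", 15), seed=seed,
    )
    path = outdir / "de.tsv"
    res.table.to_csv(path, sep="\t", index=False)
    meta = {"d0": res.d0, "s02": res.s02, "n_sv": res.n_sv}
    jpath = slio.write_json(meta, outdir / "de_moderation.json")
    return {"de": str(path), "de_moderation": jpath}


def stage_relatedness(params: dict, outdir: Path, seed: int) -> dict:
    cells = slio.read_cells(outdir)
    lab = cells.obs["assigned_label"].astype(object)
    keep = (lab.notna() & (lab != "UNCLASSIFIED")).to_numpy()
    sub = cells[keep]
    rel = pairwise_relatedness(
        sub.X, sub.obs["assigned_label"], list(sub.var_names),
        mode="moderated_t", animal_ids=sub.obs["animal_id"],
        min_cells=params.get("min_cells", 15),
    )
    path = outdir / "relatedness.tsv"
    rel.counts.rename_axis("cell_type").to_csv(path, sep="\t")
    return {"relatedness": str(path)}


def stage_enrich(params: dict, outdir: Path, seed: int) -> dict:
    # synthetic cell-type x study association grid with one planted block
    rng = np.random.default_rng(seed)
    T = params.get("n_celltypes", 6)
    S = params.get("n_studies", 24)
    ncat = params.get("n_categories", 4)
    types = [f"ct{i + 1}" for i in range(T)]
    studies = [f"gwas{j + 1}" for j in range(S)]
    p = rng.uniform(size=(T, S))
    p[0, :3] = rng.uniform(1e-8, 1e-5, 3)  # planted enriched pairs
    sign = rng.choice([-1.0, 1.0], size=(T, S))
    sign[0, :3] = 1.0
    category_map = {s: f"cat{j % ncat + 1}" for j, s in enumerate(studies)}
    enr = signed_logfdr_matrix(
        pd.DataFrame(p, index=types, columns=studies),
        pd.DataFrame(sign, index=types, columns=studies),
    )
    enr = double_zscore_plus(enr, category_map, alpha=params.get("alpha", 0.05))
    path = outdir / "enrichment.tsv"
    long = enr.signed_score.stack().rename("signed_score").to_frame()
    long["adj_p"] = enr.adj_p.stack()
    long["plus"] = enr.plus_call.stack()
    long.rename_axis(["cell_type", "study"]).to_csv(path, sep="\t")
    from .enrich import plot_enrichment_heatmap

    svg = plot_enrichment_heatmap(enr, str(outdir / "enrichment.svg"))
    return {"enrichment": str(path), "enrichment_plot": svg}


def stage_score_cells(params: dict, outdir: Path, seed: int) -> dict:
    cells = slio.read_cells(outdir)
    panel = slio.read_reference(outdir / "reference.tsv")
    set_type = params.get("set_type", "D1-VS-RGS6")
    gene_set = panel.marker_map.get(set_type, [])
    if len(gene_set) < 10:  # pad with the type's highest-expression genes
        row = panel.to_frame().loc[set_type].nlargest(12)
        gene_set = sorted(set(gene_set) | set(row.index))
    from .spatialstats import log1p_norm

    expr = pd.DataFrame(log1p_norm(cells.X), index=cells.obs_names,
                        columns=cells.var_names)
    res = gene_set_cell_score(expr, gene_set, n_controls=params.get("n_controls", 50),
                              seed=seed)
    path = outdir / "cell_scores.tsv"
    res.scores.rename_axis("cell_id").to_csv(path, sep="\t")
    return {"cell_scores": str(path)}


_STAGE_FN = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "label": stage_label,
    "niche": stage_niche,
    "rdd": stage_rdd,
    "gradients": stage_gradients,
    "de": stage_de,
    "relatedness": stage_relatedness,
    "enrich": stage_enrich,
    "score_cells": stage_score_cells,
}


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages in dependency order; return the manifest.

    On stage failure, the partial manifest (marked incomplete) is written
    before the exception propagates.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(config.get("outdir", "striatlas_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = [s for s in STAGE_ORDER if s in config.get("stages", STAGE_ORDER)]
    manifest: dict = {"global_seed": seed, "stages": {}, "complete": False}
    mpath = outdir / "manifest.json"
    for stage in stages:
        params = config.get(stage, {}) or {}
        sseed = stage_seed(seed, stage)
        try:
            outputs = _STAGE_FN[stage](params, outdir, sseed)
        except Exception as err:
            manifest["stages"][stage] = {"error": str(err), "seed": sseed,
                                         "params": params}
            mpath.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        manifest["stages"][stage] = {
            "params": params,
            "seed": sseed,
            "outputs": {k: {"path": v, "sha256": _sha256(Path(v))}
                        for k, v in outputs.items()},
        }
        mpath.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    manifest["complete"] = True
    mpath.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
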