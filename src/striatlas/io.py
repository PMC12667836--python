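"""Plain-text interchange: MatrixMarket counts, TSV metadata and references.

Counts travel as MatrixMarket (.mtx) with gene and cell TSVs alongside, cell
metadata as a tab-delimited table with a header row, and reference profiles
as a cell-type x gene TSV.  The generating seed is echoed into the .mtx
comment header and the metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

from .synth import ReferencePanel

__all__ = [
    "write_cells",
    "read_cells",
    "write_reference",
    "read_reference",
    "write_json",
]

META_COLUMNS = [
    "x_um",
    "y_um",
    "section_id",
    "rc_level_mm",
    "animal_id",
    "species_id",
    "true_type",
    "assigned_label",
]


def write_cells(adata: ad.AnnData, outdir: str | Path, prefix: str = "cells") -> dict:
    """Write counts.mtx + genes/cells TSVs + metadata TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = adata.uns.get("seed", None)
    comment = f"striatlas counts; seed={seed}" if seed is not None else "striatlas counts"
    mtx = outdir / f"{prefix}_counts.mtx"
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(np.asarray(adata.X))
    scio.mmwrite(str(mtx), X.astype(int), comment=comment, field="integer")
    genes = outdir / f"{prefix}_genes.tsv"
    pd.Series(adata.var_names, name="gene_id").to_csv(genes, sep="\t", index=False)
    meta = outdir / f"{prefix}_metadata.tsv"
    obs = adata.obs.copy()
    for col in META_COLUMNS:
        if col not in obs.columns:
            obs[col] = np.nan
    obs = obs[[c for c in META_COLUMNS if c in obs.columns]
              + [c for c in obs.columns if c not in META_COLUMNS]]
    obs.index.name = "cell_id"
    if seed is not None:
        obs["seed"] = seed
    obs.to_csv(meta, sep="\t")
    return {"counts": str(mtx), "genes": str(genes), "metadata": str(meta)}


def read_cells(outdir: str | Path, prefix: str = "cells") -> ad.AnnData:
    outdir = Path(outdir)
    X = sparse.csr_matrix(scio.mmread(outdir / f"{prefix}_counts.mtx"))
    genes = pd.read_csv(outdir / f"{prefix}_genes.tsv", sep="\t")["gene_id"].tolist()
    obs = pd.read_csv(outdir / f"{prefix}_metadata.tsv", sep="\t", index_col="cell_id")
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    if "seed" in obs.columns and obs["seed"].notna().any():
        adata.uns["seed"] = int(obs["seed"].iloc[0])
    return adata


def write_reference(panel: ReferencePanel, path: str | Path) -> str:
    """cell-type x gene TSV; marker genes listed in a sibling .markers.tsv."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    panel.to_frame().rename_axis("cell_type").to_csv(path, sep="\t")
    markers = pd.DataFrame(
        [(t, g) for t, gs in panel.marker_map.items() for g in gs],
        columns=["cell_type", "gene_id"],
    )
    markers.to_csv(path.with_suffix(".markers.tsv"), sep="\t", index=False)
    return str(path)


def read_reference(path: str | Path) -> ReferencePanel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="cell_type")
    marker_map: dict[str, list[str]] = {}
    mfile = path.with_suffix(".markers.tsv")
    if mfile.exists():
        md = pd.read_csv(mfile, sep="\t")
        for t, block in md.groupby("cell_type"):
            marker_map[t] = block["gene_id"].tolist()
    else:
        # fall back: top-2 genes per type as nominal markers
        for t in df.index:
            marker_map[t] = df.loc[t].nlargest(2).index.tolist()
    mu = df.to_numpy(dtype=float)
    mu = mu / mu.sum(axis=1, keepdims=True)
    return ReferencePanel(
        gene_ids=list(df.columns),
        type_ids=list(df.index),
        mu=mu,
        panel_mask=np.ones(df.shape[1], dtype=bool),
        marker_map=marker_map,
    )


def write_json(obj, path: str | Path) -> str:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return str(path)
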