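"""Cell-type x trait enrichment post-processing and per-cell gene-set scores.

Downstream of heritability partitioning, each (cell type, GWAS study) pair
carries an association p-value and a coefficient sign.  This module applies
Benjamini-Hochberg correction jointly across the whole grid, forms the signed
-log10 adjusted p score, and makes "+" calls by double z-scoring: a pair is
marked when its score is more than one standard deviation above the mean both
within its study (across cell types) and within its (cell type, trait
category) bin.  A simplified per-cell disease-relevance score aggregates the
covariate-residualized expression of a putative disease gene set against
expression-bin-matched random control sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentMatrix",
    "GeneSetScore",
    "signed_logfdr_matrix",
    "double_zscore_plus",
    "gene_set_cell_score",
    "plot_enrichment_heatmap",
]


@dataclass
class EnrichmentMatrix:
    raw_p: pd.DataFrame  # cell types x studies
    sign: pd.DataFrame
    adj_p: pd.DataFrame  # BH over the flattened grid
    signed_score: pd.DataFrame  # sign * (-log10 adj_p)
    category_map: dict | None = None
    z_within_study: pd.DataFrame | None = None
    z_within_celltype_bin: pd.DataFrame | None = None
    plus_call: pd.DataFrame | None = None
    alpha: float | None = None
    flags: list = field(default_factory=list)


def signed_logfdr_matrix(p_matrix: pd.DataFrame, sign_matrix: pd.DataFrame) -> EnrichmentMatrix:
    """BH over the flattened (cell type x study) grid, then signed -log10.

    NaN p-values are excluded from the BH family (its size m shrinks
    accordingly) and stay NaN in the output, flagged.
    """
    p = p_matrix.astype(float)
    s = sign_matrix.astype(float)
    if not p.index.equals(s.index) or not p.columns.equals(s.columns):
        raise ValueError("p and sign matrices must share index and columns")
    vals = p.to_numpy().ravel()
    ok = np.isfinite(vals)
    if np.any((vals[ok] < 0) | (vals[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    signs = s.to_numpy().ravel()
    if not np.all(np.isin(signs[np.isfinite(signs)], [-1.0, 1.0])):
        raise ValueError("signs must be -1 or +1")
    adj = np.full(vals.shape, np.nan)
    flags = []
    if ok.sum():
        adj[ok] = multipletests(vals[ok], method="fdr_bh")[1]
    if (~ok).any():
        flags.append(f"{int((~ok).sum())} NaN p-values excluded from BH")
    adj_df = pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)
    with np.errstate(divide="ignore"):
        score = s * (-np.log10(adj_df))
    score = score.where(np.isfinite(adj_df))
    # adj_p == 1 gives exactly 0, with the sign dropped
    score = score.mask(adj_df == 1.0, 0.0)
    return EnrichmentMatrix(raw_p=p, sign=s, adj_p=adj_df, signed_score=score, flags=flags)


def _masked_z(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """z-score of ``values`` using mean/sd over ``mask`` entries only.

    Bins with fewer than 2 usable entries or zero variance give z = 0.
    """
    z = np.zeros_like(values, dtype=float)
    sel = mask & np.isfinite(values)
    if sel.sum() < 2:
        return z
    mu = values[sel].mean()
    sd = values[sel].std(ddof=0)
    if sd == 0:
        return z
    z[sel] = (values[sel] - mu) / sd
    return z


def double_zscore_plus(
    enr: EnrichmentMatrix,
    category_map: dict,
    alpha: float = 0.05,
    significant_only: bool = True,
    use_absolute: bool = False,
) -> EnrichmentMatrix:
    """"+" calls from double z-scoring of the signed scores.

    z1: per study, z-score across cell types; z2: per (cell type, trait
    category) bin.  By default only pairs significant at ``alpha`` enter the
    mean/sd (and are eligible for calls); a pair is "+" when z1 > 1, z2 > 1
    and adj_p <= alpha.  Bins of size one or zero variance yield z = 0
    (flagged).
    """
    score = enr.signed_score.abs() if use_absolute else enr.signed_score
    studies = list(score.columns)
    missing = [c for c in studies if c not in category_map]
    if missing:
        raise ValueError(f"category map misses studies: {missing[:3]}...")
    sig = (enr.adj_p <= alpha).to_numpy() if significant_only else np.isfinite(
        enr.adj_p.to_numpy()
    )
    V = score.to_numpy(dtype=float)
    z1 = np.zeros_like(V)
    flags = list(enr.flags)
    for j in range(V.shape[1]):
        m = sig[:, j]
        if m.sum() == 1:
            flags.append(f"study {studies[j]!r}: single significant entry, z=0")
        z1[:, j] = _masked_z(V[:, j], m)
    z2 = np.zeros_like(V)
    cats = np.array([category_map[c] for c in studies])
    for i in range(V.shape[0]):
        for cat in np.unique(cats):
            cols = cats == cat
            m = sig[i] & cols
            if m.sum() == 1:
                flags.append(f"cell type {score.index[i]!r} x {cat!r}: single entry, z=0")
            zz = _masked_z(np.where(cols, V[i], np.nan), m)
            z2[i, cols] = zz[cols]
    plus = (z1 > 1) & (z2 > 1) & sig
    out = EnrichmentMatrix(
        raw_p=enr.raw_p,
        sign=enr.sign,
        adj_p=enr.adj_p,
        signed_score=enr.signed_score,
        category_map=dict(category_map),
        z_within_study=pd.DataFrame(z1, index=score.index, columns=score.columns),
        z_within_celltype_bin=pd.DataFrame(z2, index=score.index, columns=score.columns),
        plus_call=pd.DataFrame(plus, index=score.index, columns=score.columns),
        alpha=alpha,
        flags=flags,
    )
    return out


@dataclass
class GeneSetScore:
    scores: pd.DataFrame  # per cell: observed, control_mean, control_sd, z
    gene_set: list
    n_controls: int
    n_bins: int
    covariates: list
    flags: list = field(default_factory=list)


def gene_set_cell_score(
    expr: pd.DataFrame,
    gene_set: list[str],
    n_controls: int = 200,
    n_bins: int = 25,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    min_overlap: int = 10,
) -> GeneSetScore:
    """Per-cell aggregate disease-gene score against bin-matched controls.

    ``expr`` is a cells x genes normalized expression frame.  Covariates
    (default: log total expression and log features per cell) are regressed
    out of every gene; the observed score is the mean residualized expression
    over the set, and its null distribution comes from ``n_controls`` random
    gene sets matched to the set's mean-expression bin histogram exactly.
    z = (observed - control mean) / control sd.
    """
    genes = list(expr.columns)
    gs = [g for g in gene_set if g in genes]
    if len(gs) < min_overlap:
        raise ValueError(
            f"gene set overlaps measured genes in only {len(gs)} genes (< {min_overlap})"
        )
    flags = []
    if len(gs) < len(gene_set):
        flags.append(f"{len(gene_set) - len(gs)} set genes not measured; dropped")
    X = expr.to_numpy(dtype=float)
    n_cells = X.shape[0]
    if covariates is None:
        total = X.sum(axis=1)
        nfeat = (X > 0).sum(axis=1)
        covariates = pd.DataFrame(
            {"log_counts": np.log1p(total), "log_features": np.log1p(nfeat)},
            index=expr.index,
        )
    C = np.column_stack([np.ones(n_cells), covariates.to_numpy(dtype=float)])
    # one shared hat matrix residualizes every gene at once
    resid = X - C @ (np.linalg.pinv(C) @ X)
    mean_expr = X.mean(axis=0)
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(len(genes), dtype=int)
    bins[order] = np.minimum(
        (np.arange(len(genes)) * n_bins) // len(genes), n_bins - 1
    )
    gidx = np.array([genes.index(g) for g in gs])
    set_bins, set_counts = np.unique(bins[gidx], return_counts=True)
    rng = np.random.default_rng(seed)
    observed = resid[:, gidx].mean(axis=1)
    ctrl = np.empty((n_controls, n_cells))
    for b in range(n_controls):
        chosen = []
        for bin_id, cnt in zip(set_bins, set_counts):
            pool = np.flatnonzero(bins == bin_id)
            replace = pool.size < cnt
            if replace and f"bin {bin_id}" not in " ".join(flags):
                flags.append(f"bin {bin_id}: fewer eligible controls than set genes; "
                             "sampling with replacement")
            chosen.append(rng.choice(pool, cnt, replace=replace))
        chosen = np.concatenate(chosen)
        ctrl[b] = resid[:, chosen].mean(axis=1)
    cmean = ctrl.mean(axis=0)
    csd = ctrl.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(csd > 0, (observed - cmean) / csd, np.nan)
    scores = pd.DataFrame(
        {"observed": observed, "control_mean": cmean, "control_sd": csd, "z": z},
        index=expr.index,
    )
    return GeneSetScore(
        scores=scores,
        gene_set=gs,
        n_controls=n_controls,
        n_bins=n_bins,
        covariates=list(covariates.columns),
        flags=flags,
    )


def plot_enrichment_heatmap(enr: EnrichmentMatrix, path: str) -> str:
    """Signed -log10 adjusted-p heatmap with '+' overlays, written as SVG."""
    import matplotlib

    matplotlib.use("svg", force=False)
    import matplotlib.pyplot as plt

    V = enr.signed_score.to_numpy(dtype=float)
    lim = np.nanmax(np.abs(V)) or 1.0
    fig, ax = plt.subplots(figsize=(0.35 * V.shape[1] + 2, 0.35 * V.shape[0] + 1.5))
    im = ax.imshow(V, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_xticks(range(V.shape[1]), enr.signed_score.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(V.shape[0]), enr.signed_score.index, fontsize=7)
    if enr.plus_call is not None:
        for i in range(V.shape[0]):
            for j in range(V.shape[1]):
                if enr.plus_call.iloc[i, j]:
                    ax.text(j, i, "+", ha="center", va="center", fontsize=10)
    fig.colorbar(im, ax=ax, label="signed -log10 adj p", shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
    return str(path)
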