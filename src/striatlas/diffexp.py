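"""Pseudobulk differential expression and feature-level relatedness.

The DE pipeline mirrors the replicate-aware moderated-statistics workflow:
(1) sum raw counts into cell-type x animal pseudobulk aggregates (dropping
aggregates with fewer than 15 cells, recording the gene detection rate per
aggregate); (2) TMM-style scale factors, log2-CPM with a 0.5 prior count,
LOESS mean-variance precision weights and iterative sample quality weights;
(3) a ~0 + celltype + numCells + detection_rate design plus residual-PCA
surrogate variables; (4) weighted least squares with one-vs-all contrasts and
empirical-Bayes variance moderation s~^2 = (d0 s0^2 + d s^2)/(d0 + d);
(5) covariate-adaptive FDR in which the null proportion pi0 is regressed on
mean expression, applied within each cell type and (more conservatively)
across all cell types.  Pairwise relatedness counts significant features
between every pair of labels, with a Wilcoxon single-cell mode for
accessibility-style matrices (FDR <= 0.05 & log2FC >= 0.25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PseudobulkMatrix",
    "NormalizedExpression",
    "DEResult",
    "RelatednessMatrix",
    "aggregate_pseudobulk",
    "tmm_factors",
    "normalize_and_weight",
    "moderate_variance",
    "estimate_prior",
    "fit_moderated",
    "adaptive_fdr",
    "pseudobulk_de",
    "pairwise_relatedness",
    "cosine_region_similarity",
]

RIBO_MITO_PREFIXES = ("RPS", "RPL", "MRPS", "MRPL", "MT-", "MTRNR")


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class PseudobulkMatrix:
    counts: pd.DataFrame  # aggregates x genes, raw summed counts
    meta: pd.DataFrame  # cell_type, animal_id, n_cells, detection_rate
    excluded: list = field(default_factory=list)


def aggregate_pseudobulk(
    counts,
    labels: Sequence[str],
    animal_ids: Sequence[str],
    gene_ids: Sequence[str],
    min_cells: int = 15,
) -> PseudobulkMatrix:
    """Sum raw counts per (cell type, animal); drop small aggregates.

    detection_rate is the fraction of genes with count > 0 in the aggregate.
    """
    Y = counts.toarray() if sparse.issparse(counts) else np.asarray(counts)
    labels = pd.Series(list(labels), name="cell_type")
    animals = pd.Series(list(animal_ids), name="animal_id")
    key = labels.astype(str) + "|" + animals.astype(str)
    codes, uniq = pd.factorize(key)
    sums = np.zeros((len(uniq), Y.shape[1]))
    ncells = np.zeros(len(uniq), dtype=int)
    np.add.at(sums, codes, Y)
    np.add.at(ncells, codes, 1)
    meta_rows, keep_rows, excluded = [], [], []
    for i, k in enumerate(uniq):
        ct, an = k.split("|", 1)
        if ncells[i] < min_cells:
            excluded.append({"cell_type": ct, "animal_id": an, "n_cells": int(ncells[i])})
            continue
        meta_rows.append(
            {
                "cell_type": ct,
                "animal_id": an,
                "n_cells": int(ncells[i]),
                "detection_rate": float((sums[i] > 0).mean()),
            }
        )
        keep_rows.append(i)
    if not keep_rows:
        raise ValueError(f"no aggregate has >= {min_cells} cells")
    idx = [f"{r['cell_type']}|{r['animal_id']}" for r in meta_rows]
    cdf = pd.DataFrame(sums[keep_rows], index=idx, columns=list(gene_ids))
    meta = pd.DataFrame(meta_rows, index=idx)
    return PseudobulkMatrix(counts=cdf, meta=meta, excluded=excluded)


# ---------------------------------------------------------------------------
# normalization and precision weights


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, geometric mean normalized to 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean; M (log ratio) values are trimmed by 30% and A
    (abundance) values by 5% on each side, and the trimmed mean is weighted
    by asymptotic inverse variances.
    """
    Y = counts.to_numpy(dtype=float).T  # genes x samples
    lib = Y.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("a sample has all-zero counts")
    uq = np.array([np.quantile(Y[:, j][Y[:, j] > 0], 0.75) / lib[j] if (Y[:, j] > 0).any() else 0
                   for j in range(Y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    yr, nr = Y[:, ref], lib[ref]
    factors = np.ones(Y.shape[1])
    for j in range(Y.shape[1]):
        if j == ref:
            continue
        yj, nj = Y[:, j], lib[j]
        ok = (yj > 0) & (yr > 0)
        if ok.sum() < 10:
            continue
        m = np.log2((yj[ok] / nj) / (yr[ok] / nr))
        a = 0.5 * np.log2((yj[ok] / nj) * (yr[ok] / nr))
        w = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [abs_trim, 1 - abs_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.index, name="norm_factor")


@dataclass
class NormalizedExpression:
    logcpm: pd.DataFrame  # samples x genes (log2, prior count 0.5)
    weights: pd.DataFrame  # per-observation precision weights, same shape
    sample_weights: pd.Series
    norm_factors: pd.Series
    meta: pd.DataFrame
    kept_genes: list


def _design_celltype(meta: pd.DataFrame) -> np.ndarray:
    d = pd.get_dummies(meta["cell_type"]).to_numpy(dtype=float)
    return d


def normalize_and_weight(
    pb: PseudobulkMatrix,
    min_cpm: float = 1.0,
    min_samples: int = 2,
    drop_prefixes: tuple[str, ...] = RIBO_MITO_PREFIXES,
    span: float = 0.5,
    quality_rounds: int = 2,
) -> NormalizedExpression:
    """TMM factors, log2-CPM, LOESS precision weights and quality weights.

    Genes are filtered to CPM > ``min_cpm`` in at least ``min_samples``
    aggregates; ribosomal/mitochondrial symbols (by prefix) are dropped.
    Precision weights invert the fitted mean-variance trend (LOESS of
    sqrt(residual sd) on mean log2-CPM, to the fourth power, as in
    variance-stabilizing precision weighting).  Sample quality weights are
    estimated by two rounds of per-sample residual-variance rescaling,
    clamped to [0.1, 10] and normalized to geometric mean 1.
    """
    from .spatialstats import loess_smooth

    if pb.counts.shape[0] < 2:
        raise ValueError("need at least 2 aggregates")
    counts = pb.counts.loc[:, [g for g in pb.counts.columns
                               if not str(g).upper().startswith(drop_prefixes)]]
    lib = counts.sum(axis=1).to_numpy()
    if np.any(lib == 0):
        raise ValueError("a sample has all-zero counts")
    cpm = counts.to_numpy() / lib[:, None] * 1e6
    keep = (cpm > min_cpm).sum(axis=0) >= min_samples
    counts = counts.loc[:, keep.tolist()]
    if counts.shape[1] == 0:
        raise ValueError("no gene passes the low-count filter")
    nf = tmm_factors(counts)
    eff_lib = lib * nf.to_numpy()
    logcpm = np.log2((counts.to_numpy() + 0.5) / (eff_lib[:, None] + 1.0) * 1e6)
    X = _design_celltype(pb.meta)
    n, p = X.shape
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    resid = logcpm - H @ logcpm
    df = max(n - np.linalg.matrix_rank(X), 1)
    s = np.sqrt((resid**2).sum(axis=0) / df)
    mean_lcpm = logcpm.mean(axis=0)
    sqrt_s = np.sqrt(np.maximum(s, 1e-8))
    trend = loess_smooth(mean_lcpm, sqrt_s, span=span, x_query=mean_lcpm)
    trend = np.clip(trend, 1e-4, None)
    fitted = H @ logcpm
    # predicted sqrt-sd at each observation's fitted abundance, inverted
    order = np.argsort(mean_lcpm)
    W = np.empty_like(logcpm)
    for i in range(n):
        pred = np.interp(fitted[i], mean_lcpm[order], trend[order])
        W[i] = 1.0 / np.clip(pred, 1e-4, None) ** 4
    sw = np.ones(n)
    for _ in range(quality_rounds):
        Wtot = W * sw[:, None]
        beta = np.linalg.pinv(X.T @ X) @ X.T  # unweighted hat is adequate for rescaling
        r = logcpm - X @ (beta @ logcpm)
        z2 = (r**2) * Wtot
        per_sample = z2.mean(axis=1)
        if per_sample.mean() <= 1e-12:  # perfect fit: nothing to rescale
            break
        per_sample /= per_sample.mean()
        sw = sw / np.clip(per_sample, 1e-6, None)
        sw = np.clip(sw, 0.1, 10.0)
        sw /= np.exp(np.mean(np.log(sw)))
    return NormalizedExpression(
        logcpm=pd.DataFrame(logcpm, index=counts.index, columns=counts.columns),
        weights=pd.DataFrame(W, index=counts.index, columns=counts.columns),
        sample_weights=pd.Series(sw, index=counts.index, name="sample_weight"),
        norm_factors=nf,
        meta=pb.meta,
        kept_genes=list(counts.columns),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


def moderate_variance(s2: np.ndarray, d: np.ndarray, d0: float, s02: float) -> np.ndarray:
    """Posterior variance s~^2 = (d0 s0^2 + d s^2) / (d0 + d)."""
    s2 = np.asarray(s2, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s02)
    return (d0 * s02 + d * s2) / (d0 + d)


def _trigamma_inverse(v: float) -> float:
    if v <= 0:
        return np.inf
    x = 0.5 + 1.0 / v
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / v) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log sample variances.

    Matches the mean and variance of e_g = log s^2_g - psi(d_g/2) + log(d_g/2)
    to the scaled-inverse-chi-square prior; a non-positive excess variance
    yields d0 = inf (full pooling).
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.asarray(d, dtype=float)
    ok = (s2 > 0) & (d > 0)
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    e = np.log(s2[ok]) - special.digamma(d[ok] / 2) + np.log(d[ok] / 2)
    ev = np.var(e, ddof=1) - np.mean(special.polygamma(1, d[ok] / 2))
    if not np.isfinite(ev) or ev <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    half_d0 = _trigamma_inverse(ev)
    if not np.isfinite(half_d0):
        return np.inf, float(np.exp(np.mean(e)))
    d0 = 2 * half_d0
    s02 = float(np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0)))
    return float(d0), s02


@dataclass
class DEResult:
    table: pd.DataFrame  # gene, cell_type, log2fc, t, p_value, adj_p_within, adj_p_between
    d0: float
    s02: float
    n_sv: int
    design_columns: list


def _choose_n_sv(resid: np.ndarray, rng: np.random.Generator, cap: int = 5,
                 n_perm: int = 10) -> int:
    """Permutation parallel analysis on the residual matrix (genes permuted)."""
    n = resid.shape[0]
    if n < 3:
        return 0
    R = resid - resid.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(R, compute_uv=False)
    null = np.zeros((n_perm, len(sv)))
    for b in range(n_perm):
        P = np.apply_along_axis(rng.permutation, 0, R)
        null[b] = np.linalg.svd(P - P.mean(axis=0, keepdims=True), compute_uv=False)
    thresh = np.quantile(null, 0.95, axis=0)
    k = int(np.sum(sv > thresh))
    return min(k, cap, n - 2)


def fit_moderated(
    norm: NormalizedExpression,
    n_sv: int | str = "auto",
    d0_override: float | None = None,
    seed: int = 0,
) -> DEResult:
    """One-vs-all moderated contrasts on the pseudobulk design.

    Design: ~0 + celltype + scaled numCells + scaled detection_rate (+
    surrogate variables = top residual principal components, dimension by
    permutation parallel analysis, capped at 5).  Per gene the model is
    fitted by weighted least squares with the per-observation precision
    weights times sample quality weights; variances are shrunk toward the
    method-of-moments prior and t-statistics referred to d_g + d0 df.
    """
    meta = norm.meta
    Y = norm.logcpm.to_numpy()  # samples x genes
    W = (norm.weights.to_numpy() * norm.sample_weights.to_numpy()[:, None])
    types = sorted(meta["cell_type"].unique())
    D = pd.get_dummies(pd.Categorical(meta["cell_type"], categories=types)).to_numpy(float)
    covs = []
    cols = list(types)
    for c in ("n_cells", "detection_rate"):
        v = meta[c].to_numpy(dtype=float)
        sd = v.std()
        if sd > 0:  # a constant covariate carries no information; drop it
            covs.append((v - v.mean()) / sd)
            cols.append(c)
    X = np.column_stack([D] + covs) if covs else D
    # surrogate variables from the residuals of the full design
    rng = np.random.default_rng(seed)
    pinv = np.linalg.pinv(X)
    resid = Y - X @ (pinv @ Y)
    k = _choose_n_sv(resid.T, rng) if n_sv == "auto" else int(n_sv)
    if k > 0:
        R = resid - resid.mean(axis=1, keepdims=True)
        U, S, Vt = np.linalg.svd(R, full_matrices=False)
        SV = U[:, :k]
        X = np.column_stack([X, SV])
        cols += [f"SV{i + 1}" for i in range(k)]
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    G = Y.shape[1]
    T = len(types)
    contrasts = np.zeros((T, p))
    for i in range(T):
        contrasts[i, :T] = -1.0 / (T - 1)
        contrasts[i, i] = 1.0
    lfc = np.zeros((G, T))
    varc = np.zeros((G, T))
    s2 = np.zeros(G)
    d_g = np.full(G, float(n - p))
    for g in range(G):
        w = W[:, g]
        Xw = X * w[:, None]
        XtWX = Xw.T @ X
        XtWXi = np.linalg.pinv(XtWX)
        beta = XtWXi @ (Xw.T @ Y[:, g])
        r = Y[:, g] - X @ beta
        s2[g] = float((w * r**2).sum() / (n - p))
        lfc[g] = contrasts @ beta
        varc[g] = np.einsum("ij,jk,ik->i", contrasts, XtWXi, contrasts)
    if d0_override is not None:
        d0 = float(d0_override)
        _, s02 = estimate_prior(s2, d_g)
        if np.isinf(d0):
            pass
    else:
        d0, s02 = estimate_prior(s2, d_g)
    if not np.isfinite(d0) and d0_override is None:
        warnings.warn("prior df estimate non-finite; using full pooling (d0=inf)")
        d0 = np.inf
    s2_mod = moderate_variance(s2, d_g, d0, s02)
    tstat = lfc / np.sqrt(s2_mod[:, None] * varc)
    df_total = d_g + (0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        pvals = 2 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2 * stats.t.sf(np.abs(tstat), df_total[:, None])
    genes = list(norm.logcpm.columns)
    mean_expr = Y.mean(axis=0)
    recs = []
    for i, t in enumerate(types):
        for g in range(G):
            recs.append(
                {"gene": genes[g], "cell_type": t, "log2fc": lfc[g, i],
                 "t": tstat[g, i], "p_value": float(pvals[g, i]),
                 "mean_expr": mean_expr[g]}
            )
    table = pd.DataFrame(recs)
    # covariate-adaptive FDR: within each cell type and pooled across all
    table["adj_p_within"] = np.nan
    for t in types:
        m = table["cell_type"] == t
        table.loc[m, "adj_p_within"] = adaptive_fdr(
            table.loc[m, "p_value"].to_numpy(), table.loc[m, "mean_expr"].to_numpy()
        )
    table["adj_p_between"] = adaptive_fdr(
        table["p_value"].to_numpy(), table["mean_expr"].to_numpy()
    )
    return DEResult(table=table, d0=float(d0), s02=float(s02), n_sv=int(k),
                    design_columns=cols)


# ---------------------------------------------------------------------------
# covariate-adaptive FDR


def adaptive_fdr(
    p: np.ndarray,
    covariate: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    clamp: tuple[float, float] = (0.01, 1.0),
    fixed_pi0: float | None = None,
) -> np.ndarray:
    """q-values with a covariate-dependent null proportion pi0(x).

    For each lambda in the grid, the indicator 1[p > lambda] / (1 - lambda)
    is regressed on a linear basis of the covariate; predictions are averaged
    over the grid and clamped, and q = pi0(x) * BH(p).  A constant (or
    absent) covariate reduces to scalar-pi0 q-values; ``fixed_pi0`` bypasses
    estimation entirely (pi0 = 1 gives plain BH).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.95, 0.05)
    bh = multipletests(p, method="fdr_bh")[1]
    if fixed_pi0 is not None:
        return np.minimum(float(fixed_pi0) * bh, 1.0)
    if covariate is None:
        x = np.zeros(n)
    else:
        x = np.asarray(covariate, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("covariate must be finite")
    sd = x.std()
    if sd == 0:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), (x - x.mean()) / sd])
    preds = np.zeros(n)
    for lam in lambda_grid:
        z = (p > lam).astype(float) / (1.0 - lam)
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        preds += X @ beta
    pi0 = np.clip(preds / len(lambda_grid), clamp[0], clamp[1])
    return np.minimum(pi0 * bh, 1.0)


# ---------------------------------------------------------------------------
# high-level DE convenience


def pseudobulk_de(
    counts,
    labels: Sequence[str],
    animal_ids: Sequence[str],
    gene_ids: Sequence[str],
    min_cells: int = 15,
    n_sv: int | str = "auto",
    seed: int = 0,
) -> DEResult:
    """Aggregation -> normalization/weights -> moderated one-vs-all contrasts."""
    pb = aggregate_pseudobulk(counts, labels, animal_ids, gene_ids, min_cells=min_cells)
    norm = normalize_and_weight(pb)
    return fit_moderated(norm, n_sv=n_sv, seed=seed)


# ---------------------------------------------------------------------------
# pairwise relatedness


@dataclass
class RelatednessMatrix:
    counts: pd.DataFrame  # entry [A, B] = features significantly up in A vs B
    sig_rule: dict
    flags: list = field(default_factory=list)


def _wilcoxon_table(XA: np.ndarray, XB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature rank-sum p (normal approximation, tie-corrected) and log2FC."""
    pvals = np.ones(XA.shape[1])
    for g in range(XA.shape[1]):
        a, b = XA[:, g], XB[:, g]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[g] = 1.0
            continue
        pvals[g] = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").pvalue
    eps = 1e-9
    lfc = np.log2((XA.mean(axis=0) + eps) / (XB.mean(axis=0) + eps))
    return pvals, lfc


def pairwise_relatedness(
    data,
    labels: Sequence[str],
    gene_ids: Sequence[str],
    mode: str = "moderated_t",
    animal_ids: Sequence[str] | None = None,
    max_fdr: float = 0.05,
    min_log2fc: float = 0.0,
    min_cells: int = 15,
) -> RelatednessMatrix:
    """Count significantly up-regulated features for every ordered label pair.

    ``moderated_t`` runs the pseudobulk moderated pipeline per pair (needs
    animal_ids; pairs where a label keeps < 2 aggregates are skipped and
    flagged).  ``wilcoxon`` runs single-cell rank-sum tests on the provided
    (already normalized) feature matrix with the accessibility-style rule
    FDR <= max_fdr and log2FC >= min_log2fc.
    """
    X = data.toarray() if sparse.issparse(data) else np.asarray(data, dtype=float)
    lab = pd.Series(list(labels))
    types = sorted(lab.unique())
    if len(types) < 2:
        raise ValueError("need at least 2 labels")
    out = pd.DataFrame(0, index=types, columns=types, dtype=int)
    flags = []
    rule = {"max_fdr": max_fdr, "min_log2fc": min_log2fc, "mode": mode}
    for i, a in enumerate(types):
        for b in types[i + 1:]:
            ma = (lab == a).to_numpy()
            mb = (lab == b).to_numpy()
            if mode == "wilcoxon":
                if ma.sum() < 2 or mb.sum() < 2:
                    flags.append(f"pair ({a},{b}) skipped: too few cells")
                    continue
                pv, lfc = _wilcoxon_table(X[ma], X[mb])
                fdr = multipletests(pv, method="fdr_bh")[1]
                up_a = int(((fdr <= max_fdr) & (lfc >= min_log2fc)).sum())
                up_b = int(((fdr <= max_fdr) & (-lfc >= min_log2fc)).sum())
            elif mode == "moderated_t":
                if animal_ids is None:
                    raise ValueError("moderated_t mode requires animal_ids")
                an = pd.Series(list(animal_ids))
                sel = ma | mb
                try:
                    pb = aggregate_pseudobulk(
                        X[sel], lab[sel], an[sel], gene_ids, min_cells=min_cells
                    )
                except ValueError:
                    flags.append(f"pair ({a},{b}) skipped: no surviving aggregate")
                    continue
                na = (pb.meta["cell_type"] == a).sum()
                nb = (pb.meta["cell_type"] == b).sum()
                if na < 2 or nb < 2:
                    flags.append(f"pair ({a},{b}) skipped: <2 aggregates for a label")
                    continue
                norm = normalize_and_weight(pb)
                res = fit_moderated(norm, n_sv=0)
                ta = res.table[res.table["cell_type"] == a]
                sig = (ta["adj_p_within"] <= max_fdr) & (np.abs(ta["log2fc"]) >= min_log2fc)
                up_a = int((sig & (ta["log2fc"] > 0)).sum())
                up_b = int((sig & (ta["log2fc"] < 0)).sum())
            else:
                raise ValueError(f"unknown mode {mode!r}")
            out.loc[a, b] = up_a
            out.loc[b, a] = up_b
    return RelatednessMatrix(counts=out, sig_rule=rule, flags=flags)


# ---------------------------------------------------------------------------
# cosine similarity across regions


def cosine_region_similarity(
    counts,
    region_labels: Sequence[str],
    n_per_region: int = 500,
    n_pcs: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, list]:
    """Region-grouped mean cosine similarity of nuclei in PC space.

    Nuclei are down-sampled to ``n_per_region`` per region (all used, with a
    flag, when fewer are available), log-normalized, projected with PCA, and
    all pairwise cosine similarities are averaged within region pairs.  The
    display order comes from average-linkage hierarchical clustering on
    1 - similarity.
    """
    from scipy.cluster import hierarchy
    from sklearn.decomposition import PCA
    from sklearn.metrics.pairwise import cosine_similarity

    from .spatialstats import log1p_norm

    X = counts.toarray() if sparse.issparse(counts) else np.asarray(counts, dtype=float)
    regions = pd.Series(list(region_labels))
    rng = np.random.default_rng(seed)
    keep = []
    for r in sorted(regions.unique()):
        idx = np.flatnonzero((regions == r).to_numpy())
        if idx.size > n_per_region:
            idx = rng.choice(idx, n_per_region, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    Xs = log1p_norm(X[keep])
    reg = regions.iloc[keep].to_numpy()
    npc = min(n_pcs, Xs.shape[0] - 1, Xs.shape[1])
    pcs = PCA(n_components=npc, random_state=seed).fit_transform(Xs)
    norms = np.linalg.norm(pcs, axis=1)
    ok = norms > 0
    pcs, reg = pcs[ok], reg[ok]
    sim = cosine_similarity(pcs)
    uniq = sorted(pd.unique(reg))
    M = pd.DataFrame(np.nan, index=uniq, columns=uniq)
    for i, a in enumerate(uniq):
        ia = np.flatnonzero(reg == a)
        for b in uniq[i:]:
            ib = np.flatnonzero(reg == b)
            block = sim[np.ix_(ia, ib)]
            if a == b:
                v = block[np.triu_indices_from(block, k=1)]
                val = float(v.mean()) if v.size else 1.0
            else:
                val = float(block.mean())
            M.loc[a, b] = M.loc[b, a] = val
    dist = 1.0 - M.to_numpy()
    np.fill_diagonal(dist, 0.0)
    from scipy.spatial.distance import squareform

    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [uniq[i] for i in hierarchy.leaves_list(Z)]
    return M, order
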