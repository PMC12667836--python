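"""Spatial statistics: discontinuity testing, gradients, and mixed models.

The regression-discontinuity design (RDD) asks whether a gene's expression
jumps discretely at a spatial boundary or follows a smooth gradient: along a
declared axis (x, y, or a 1-D isomap embedding), a boundary is found by Otsu
thresholding of the coordinate distribution, the axis is centered on it, and

    expr ~ b0 + b1 * 1[coord > boundary] + b2 * (coord - boundary)

is fitted by least squares; the two-sided Wald p-value on b1 is the test.
The module also provides reference-correlation checks, per-section abundance
percentages with SEM and fold changes, local-linear LOESS smoothing, and a
random-intercept linear mixed model (profile-REML) for rostro-caudal
abundance-gradient slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "AxisSpec",
    "RDDResult",
    "GradientSummary",
    "MixedModelFit",
    "log1p_norm",
    "embed_1d",
    "otsu_boundary",
    "rdd_test",
    "rdd_pipeline",
    "reference_correlation",
    "abundance_gradient",
    "loess_smooth",
    "lmm_fit",
    "plot_gradient",
]


def log1p_norm(counts, target: float | None = None) -> np.ndarray:
    """log1p of depth-normalized counts (target = median depth by default)."""
    Y = counts.toarray() if sparse.issparse(counts) else np.asarray(counts, dtype=float)
    depth = Y.sum(axis=1)
    if target is None:
        pos = depth[depth > 0]
        target = float(np.median(pos)) if pos.size else 1.0
    scale = np.divide(target, depth, out=np.zeros_like(depth, dtype=float), where=depth > 0)
    return np.log1p(Y * scale[:, None])


# ---------------------------------------------------------------------------
# 1-D spatial axes


@dataclass(frozen=True)
class AxisSpec:
    mode: str = "axis_x"  # axis_x | axis_y | isomap_1d
    n_neighbors: int = 15
    max_cells: int = 2000  # landmark subsample for geodesic computation
    seed: int = 0


def embed_1d(cells: ad.AnnData | pd.DataFrame | np.ndarray, spec: AxisSpec) -> np.ndarray:
    """Per-cell 1-D coordinate along the declared or learned spatial axis.

    Axis modes return the raw coordinate.  Isomap mode builds a symmetric
    kNN graph on (x, y), computes geodesic (shortest-path) distances and
    returns the first classical-MDS coordinate, with the sign fixed so the
    embedding correlates positively with x (falling back to y on a tie).
    """
    if isinstance(cells, ad.AnnData):
        xy = cells.obs[["x_um", "y_um"]].to_numpy(dtype=float)
    elif isinstance(cells, pd.DataFrame):
        xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(cells, dtype=float)
    if spec.mode == "axis_x":
        return xy[:, 0].copy()
    if spec.mode == "axis_y":
        return xy[:, 1].copy()
    if spec.mode != "isomap_1d":
        raise ValueError(f"unknown axis mode {spec.mode!r}")
    n = xy.shape[0]
    if n < spec.n_neighbors + 1:
        raise ValueError("need at least n_neighbors+1 cells for isomap mode")
    from scipy.sparse.csgraph import connected_components
    from sklearn.manifold import Isomap
    from sklearn.neighbors import kneighbors_graph

    g = kneighbors_graph(xy, spec.n_neighbors, mode="connectivity")
    n_comp, _ = connected_components(g.maximum(g.T), directed=False)
    if n_comp > 1:
        raise ValueError(
            f"isomap kNN graph has {n_comp} components (disconnected); raise n_neighbors"
        )

    iso = Isomap(n_neighbors=spec.n_neighbors, n_components=1)
    try:
        if n > spec.max_cells:
            rng = np.random.default_rng(spec.seed)
            idx = rng.choice(n, spec.max_cells, replace=False)
            iso.fit(xy[idx])
            coord = iso.transform(xy)[:, 0]
        else:
            coord = iso.fit_transform(xy)[:, 0]
    except Exception as err:  # disconnected kNN graph
        raise ValueError(
            "isomap kNN graph appears disconnected; raise n_neighbors"
        ) from err
    if not np.all(np.isfinite(coord)):
        raise ValueError("isomap kNN graph appears disconnected; raise n_neighbors")
    cx = np.corrcoef(coord, xy[:, 0])[0, 1]
    if abs(cx) < 1e-12 or not np.isfinite(cx):
        cx = np.corrcoef(coord, xy[:, 1])[0, 1]
    if np.isfinite(cx) and cx < 0:
        coord = -coord
    return coord


# ---------------------------------------------------------------------------
# Otsu boundary


def otsu_boundary(coords: np.ndarray, n_bins: int = 128) -> float:
    """Histogram bin edge maximizing between-class variance of the coordinate.

    Equals an exhaustive scan over all interior bin edges.  Exactly tied
    maxima arise when the split falls in an empty stretch of the histogram
    (e.g. a spatial gap between two cell populations); the tie is broken by
    the edge closest to the midpoint of that empty stretch — the natural
    threshold position — then toward the data median, then the lower edge.
    """
    x = np.asarray(coords, dtype=float)
    x = x[np.isfinite(x)]
    if np.unique(x).size < 2:
        raise ValueError("Otsu thresholding needs at least 2 distinct values")
    hist, edges = np.histogram(x, bins=n_bins)
    p = hist.astype(float) / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]  # classes split at interior edges 1..n_bins-1
    w1 = 1.0 - w0
    csum = np.cumsum(p * centers)
    total = csum[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = csum[:-1] / w0
        m1 = (total - csum[:-1]) / w1
        sigma_b = w0 * w1 * (m0 - m1) ** 2
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, -np.inf)
    best = sigma_b.max()
    cand = np.flatnonzero(sigma_b >= best - 1e-12 * max(abs(best), 1.0))
    cand_edges = edges[cand + 1]
    if cand.size > 1:
        low = x[x < cand_edges[0]]
        high = x[x >= cand_edges[-1]]
        lo = low.max() if low.size else cand_edges[0]
        hi = high.min() if high.size else cand_edges[-1]
        target = 0.5 * (lo + hi)
    else:
        target = cand_edges[0]
    med = float(np.median(x))
    order = np.lexsort((cand_edges, np.abs(cand_edges - med),
                        np.abs(cand_edges - target)))
    return float(cand_edges[order[0]])


# ---------------------------------------------------------------------------
# RDD test


@dataclass
class RDDResult:
    gene: str
    boundary: float
    jump_beta: float
    slope_beta: float
    intercept: float
    jump_se: float
    p_value: float
    n_left: int
    n_right: int
    section_id: str | None = None
    type_pair: tuple[str, str] | None = None
    axis_mode: str = "axis_x"

    def __str__(self):
        return (
            f"RDD[{self.gene}] jump={self.jump_beta:.3g} (se {self.jump_se:.3g}), "
            f"slope={self.slope_beta:.3g}, p={self.p_value:.3g}, "
            f"n={self.n_left}+{self.n_right}"
        )


def rdd_test(
    expr: np.ndarray,
    coords: np.ndarray,
    boundary: float,
    min_side: int = 20,
    gene: str = "",
    separate_slopes: bool = False,
    **meta,
) -> RDDResult:
    """Gaussian RDD fit: expr ~ posmark + centered_axis (no interaction).

    The null model is linear-in-position only; the Wald test on the posmark
    coefficient asks whether a discrete jump at the boundary explains
    additional variance.  ``separate_slopes`` adds the posmark x position
    interaction (off by default, matching the additive formula).
    """
    y = np.asarray(expr, dtype=float)
    c = np.asarray(coords, dtype=float) - boundary
    pos = (c > 0).astype(float)
    n_right = int(pos.sum())
    n_left = int(y.size - n_right)
    if min(n_left, n_right) < min_side:
        raise ValueError(
            f"both sides need >= {min_side} cells (got {n_left} left, {n_right} right)"
        )
    cols = [np.ones_like(c), pos, c]
    if separate_slopes:
        cols.append(pos * c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient RDD design")
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    beta = fit.params
    rss = float(fit.ssr)
    if rss <= 1e-12 * max(float(y @ y), 1.0):
        # noiseless geometry: degenerate variance conventions
        p = 1.0 if abs(beta[1]) < 1e-10 else 0.0
        se = 0.0
    else:
        p = float(fit.pvalues[1])
        se = float(fit.bse[1])
    return RDDResult(
        gene=gene,
        boundary=float(boundary),
        jump_beta=float(beta[1]),
        slope_beta=float(beta[2]),
        intercept=float(beta[0]),
        jump_se=se,
        p_value=p,
        n_left=n_left,
        n_right=n_right,
        **meta,
    )


def rdd_pipeline(
    adata: ad.AnnData,
    gene: str,
    type_pair: tuple[str, str],
    spec: AxisSpec | None = None,
    label_col: str = "assigned_label",
    min_side: int = 20,
    n_bins: int = 128,
) -> list[RDDResult]:
    """Full RDD per section: axis -> Otsu boundary -> centered GLM fit.

    Cells of the two compared types are pooled; the bimodal spatial occupancy
    of the pair drives the Otsu boundary.  One result per section, never
    pooled across sections or animals.
    """
    spec = spec or AxisSpec()
    lab = adata.obs[label_col].astype(object)
    keep = lab.isin(list(type_pair)).to_numpy()
    if keep.sum() < 2 * min_side:
        raise ValueError("too few cells of the compared types")
    sub = adata[keep]
    gi = sub.var_names.get_loc(gene)
    expr_all = log1p_norm(sub.X)[:, gi]
    results = []
    for sec, idx in sub.obs.groupby("section_id", observed=True).groups.items():
        mask = sub.obs_names.isin(idx)
        cells = sub[mask]
        coord = embed_1d(cells, spec)
        boundary = otsu_boundary(coord, n_bins=n_bins)
        res = rdd_test(
            expr_all[mask],
            coord,
            boundary,
            min_side=min_side,
            gene=gene,
            section_id=str(sec),
            type_pair=tuple(type_pair),
            axis_mode=spec.mode,
        )
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# reference correlation


def reference_correlation(
    adata: ad.AnnData,
    panel,
    label_col: str = "assigned_label",
    min_cells: int = 20,
) -> pd.DataFrame:
    """Per-type Pearson correlation between spatial means and the reference.

    Compares log1p depth-normalized mean expression of a type's spatial cells
    with the log1p-scaled reference profile over shared panel genes.  Types
    with fewer than ``min_cells`` cells or zero-variance vectors are flagged
    (NaN r2).
    """
    shared = [g for g in panel.gene_ids if g in adata.var_names]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared panel genes")
    gidx_panel = panel.gene_index(shared)
    sub = adata[:, shared]
    Y = sub.X.toarray() if sparse.issparse(sub.X) else np.asarray(sub.X, dtype=float)
    depth = Y.sum(axis=1)
    target = float(np.median(depth[depth > 0])) if np.any(depth > 0) else 1.0
    rows = []
    for ti, t in enumerate(panel.type_ids):
        mask = (adata.obs[label_col] == t).to_numpy()
        n = int(mask.sum())
        if n < min_cells:
            rows.append({"cell_type": t, "n_cells": n, "r2": np.nan, "p_value": np.nan,
                         "flag": "too_few_cells"})
            continue
        d = depth[mask]
        norm = Y[mask] / np.maximum(d, 1)[:, None] * target
        spatial = np.log1p(norm.mean(axis=0))
        ref = np.log1p(panel.mu[ti, gidx_panel] * target)
        if spatial.std() == 0 or ref.std() == 0:
            rows.append({"cell_type": t, "n_cells": n, "r2": np.nan, "p_value": np.nan,
                         "flag": "zero_variance"})
            continue
        r, p = stats.pearsonr(spatial, ref)
        rows.append({"cell_type": t, "n_cells": n, "r2": r**2, "p_value": p, "flag": ""})
    return pd.DataFrame(rows).set_index("cell_type")


# ---------------------------------------------------------------------------
# abundance gradients


@dataclass
class GradientSummary:
    per_section: pd.DataFrame  # section_id, rc_level_mm, cell_type, count, percent
    sem_by_level: pd.DataFrame  # rc_level_mm, cell_type, mean_percent, sem, n_sections
    fold_change: pd.DataFrame | None  # per section: percent(B)/percent(A)
    pair: tuple[str, str] | None = None
    flags: list = field(default_factory=list)


def abundance_gradient(
    obs: pd.DataFrame,
    group: list[str],
    pair: tuple[str, str] | None = None,
    label_col: str = "assigned_label",
) -> GradientSummary:
    """Per-section percentages within a label group, SEM across sections.

    percent = 100 * count(type) / count(group) per section; fold change is
    percent(B) / percent(A) for the declared pair (flagged when A is absent);
    SEM of the percent is taken across sections within each rc level
    (sample sd / sqrt(n), ddof=1).
    """
    flags = []
    sub = obs[obs[label_col].isin(group)]
    recs = []
    for (sec, rc), block in sub.groupby(["section_id", "rc_level_mm"], observed=True):
        total = len(block)
        if total == 0:
            flags.append(f"empty group in section {sec}")
            continue
        counts = block[label_col].value_counts()
        for t in group:
            c = int(counts.get(t, 0))
            recs.append(
                {"section_id": sec, "rc_level_mm": rc, "cell_type": t,
                 "count": c, "percent": 100.0 * c / total}
            )
    per_section = pd.DataFrame(recs)
    if per_section.empty:
        raise ValueError("no cells of the requested group in any section")
    sem = (
        per_section.groupby(["rc_level_mm", "cell_type"], observed=True)["percent"]
        .agg(mean_percent="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
             n_sections="count")
        .reset_index()
    )
    fc = None
    if pair is not None:
        a, b = pair
        wide = per_section.pivot_table(
            index=["section_id", "rc_level_mm"], columns="cell_type", values="percent"
        )
        pa = wide.get(a)
        pb = wide.get(b)
        if pa is None or pb is None:
            flags.append(f"pair type missing: {pair}")
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = pb / pa
            bad = ~np.isfinite(ratio)
            if bad.any():
                flags.append(f"fold change undefined in {int(bad.sum())} section(s) (A count 0)")
            fc = ratio.rename("fold_change").reset_index()
    return GradientSummary(per_section=per_section, sem_by_level=sem, fold_change=fc,
                           pair=pair, flags=flags)


# ---------------------------------------------------------------------------
# LOESS


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    x_query: np.ndarray | None = None,
) -> np.ndarray:
    """Local linear regression with tricube weights (classic LOESS, degree 1).

    At each query point the span-fraction nearest data points are weighted by
    (1 - (d/d_max)^3)^3 and a weighted straight line is fitted; a degenerate
    local design falls back to the local weighted mean.  A globally linear
    signal is reproduced exactly at any span.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    xq = x if x_query is None else np.asarray(x_query, dtype=float)
    n = x.size
    k = max(2, int(np.ceil(span * n)))
    out = np.empty(xq.size)
    for i, x0 in enumerate(xq):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:k]
        dk = d[idx]
        dmax = dk.max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1 - np.clip(dk / dmax, 0, 1) ** 3) ** 3
        if (w > 0).sum() < 2 or np.unique(x[idx][w > 0]).size < 2:
            sw = w.sum()
            out[i] = float(np.dot(w, y[idx]) / sw) if sw > 0 else y[idx].mean()
            continue
        X = np.column_stack([np.ones(idx.size), x[idx] - x0])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y[idx], rcond=None)
        out[i] = beta[0]
    return out


# ---------------------------------------------------------------------------
# random-intercept linear mixed model


@dataclass
class MixedModelFit:
    beta: float
    se_beta: float
    p_value: float
    intercept: float
    random_intercept_sd: float
    residual_sd: float
    n_obs: int
    n_groups: int
    reml_loglik: float
    boundary: bool = False  # variance ratio pinned at 0

    def wald_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.beta - z * self.se_beta, self.beta + z * self.se_beta


def _reml_profile(phi: float, y, X, groups_idx):
    """REML criterion and GLS pieces at variance ratio phi = sig_b^2/sig_e^2.

    Per-group Woodbury: V_g^{-1} = I - phi/(1 + phi n_g) J.
    Returns (-2*restricted loglik up to constants, beta, cov_unscaled, sigma2).
    """
    n, p = X.shape
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdetV = 0.0
    for idx in groups_idx:
        Xg = X[idx]
        yg = y[idx]
        ng = len(idx)
        c = phi / (1.0 + phi * ng)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        XtVX += Xg.T @ Xg - c * np.outer(sx, sx)
        XtVy += Xg.T @ yg - c * sx * sy
        ytVy += yg @ yg - c * sy * sy
        logdetV += np.log1p(phi * ng)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - beta @ XtVy
    sigma2 = max(rss / (n - p), 1e-300)
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    crit = (n - p) * np.log(sigma2) + logdetV + logdetXtVX
    return crit, beta, np.linalg.inv(XtVX), sigma2


def lmm_fit(y: np.ndarray, x: np.ndarray, group: np.ndarray) -> MixedModelFit:
    """Random-intercept Gaussian LMM by profile-REML over the variance ratio.

    y ~ intercept + beta * x + (1 | group).  The restricted likelihood is
    profiled analytically over the fixed effects and the residual variance,
    leaving a one-dimensional optimization over phi = sigma_group^2 /
    sigma_resid^2 (log-scale golden search, boundary phi = 0 checked
    explicitly).  The Wald p on the slope uses the normal reference.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    group = np.asarray(group)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    X = np.column_stack([np.ones_like(x), x])
    codes, uniq = pd.factorize(group)
    groups_idx = [np.flatnonzero(codes == g) for g in range(len(uniq))]
    from scipy.optimize import minimize_scalar

    def crit_log(lp):
        return _reml_profile(np.exp(lp), y, X, groups_idx)[0]

    crit0 = _reml_profile(0.0, y, X, groups_idx)[0]
    res = minimize_scalar(crit_log, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    if res.fun < crit0 - 1e-10:
        phi = float(np.exp(res.x))
        boundary = False
        crit = res.fun
    else:
        phi = 0.0
        boundary = True
        crit = crit0
    _, beta, cov_u, sigma2 = _reml_profile(phi, y, X, groups_idx)
    se = float(np.sqrt(cov_u[1, 1] * sigma2))
    z = beta[1] / se if se > 0 else np.inf * np.sign(beta[1])
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return MixedModelFit(
        beta=float(beta[1]),
        se_beta=se,
        p_value=p,
        intercept=float(beta[0]),
        random_intercept_sd=float(np.sqrt(phi * sigma2)),
        residual_sd=float(np.sqrt(sigma2)),
        n_obs=int(y.size),
        n_groups=len(uniq),
        reml_loglik=-0.5 * float(crit),
        boundary=boundary,
    )


def plot_gradient(summary: GradientSummary, path: str, span: float = 0.75) -> str:
    """Abundance-gradient figure: per-level mean percent with SEM bars and a
    LOESS curve per type, written as SVG."""
    import matplotlib

    matplotlib.use("svg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for t, block in summary.sem_by_level.groupby("cell_type"):
        block = block.sort_values("rc_level_mm", ascending=False)
        x = block["rc_level_mm"].to_numpy(dtype=float)
        y = block["mean_percent"].to_numpy()
        ax.errorbar(x, y, yerr=block["sem"].to_numpy(), fmt="o", ms=4,
                    capsize=2, label=str(t))
        raw = summary.per_section[summary.per_section["cell_type"] == t]
        if len(raw) >= 3:
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, loess_smooth(raw["rc_level_mm"].to_numpy(dtype=float),
                                     raw["percent"].to_numpy(), span=span,
                                     x_query=xs), lw=1)
    ax.invert_xaxis()  # rostral on the left
    ax.set_xlabel("rostro-caudal level (mm from AC)")
    ax.set_ylabel("percent of group")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
    return str(path)
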