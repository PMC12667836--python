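"""Reference-based per-cell decomposition and two-round labeling.

Each cell's counts are modeled as a Poisson mixture over reference cell-type
profiles scaled by per-gene platform factors.  The mixture weights are fitted
on the probability simplex by a monotone majorize-minimize iteration (an EM
surrogate for the log term plus an exact one-dimensional dual solve for the
simplex constraint), so the likelihood never decreases across iterations.
Cells are then classed as singlet / doublet-certain / doublet-uncertain /
rejected by comparing best one-type and two-type fits, and labeled by the
strict weight > 0.5 rule; a first round assigns major classes and a second
round re-decomposes MSN cells against a subtype reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .synth import ReferencePanel

__all__ = [
    "UNCLASSIFIED",
    "PlatformFactors",
    "LabelResult",
    "estimate_platform_factors",
    "poisson_mixture_loglik",
    "decompose_cell",
    "decompose_cells",
    "classify_mode",
    "classify_modes",
    "assign_label",
    "label_cells",
    "hierarchical_label",
]

UNCLASSIFIED = "UNCLASSIFIED"

MODES = ("singlet", "doublet_certain", "doublet_uncertain", "rejected")


@dataclass
class PlatformFactors:
    """Per-gene multiplicative factors between spatial assay and reference."""

    gene_ids: list[str]
    gamma: np.ndarray
    smoothing_span: float = 0.0

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not np.all(np.isfinite(self.gamma)) or np.any(self.gamma <= 0):
            raise ValueError("platform factors must be finite and positive")

    @classmethod
    def ones(cls, gene_ids: Sequence[str]) -> "PlatformFactors":
        return cls(gene_ids=list(gene_ids), gamma=np.ones(len(gene_ids)))


@dataclass
class LabelResult:
    cell_id: str
    weights: np.ndarray
    mode: str
    assigned_label: str | None
    round: str = "major_class"


def estimate_platform_factors(
    spatial_pseudobulk: np.ndarray,
    reference_pseudobulk: np.ndarray,
    gene_ids: Sequence[str] | None = None,
    pseudocount: float = 0.5,
    span: float = 0.0,
    clamp: tuple[float, float] = (0.05, 20.0),
) -> PlatformFactors:
    """Ratio of depth-normalized pseudobulk means, regularized and clamped.

    Genes absent (zero) in either pseudobulk fall back to gamma = 1.  A small
    pseudocount stabilizes low-count ratios; ``span > 0`` additionally smooths
    log-gamma against log reference abundance with a local-linear smoother.
    """
    s = np.asarray(spatial_pseudobulk, dtype=float)
    r = np.asarray(reference_pseudobulk, dtype=float)
    if s.shape != r.shape:
        raise ValueError("pseudobulk vectors must have equal length")
    if np.any(s < 0) or np.any(r < 0):
        raise ValueError("pseudobulk vectors must be nonnegative")
    if s.sum() == 0 or r.sum() == 0:
        raise ValueError("all-zero pseudobulk")
    ps = s / s.sum()
    pr = r / r.sum()
    # pseudocount on the normalized scale, sized like one count per library
    eps_s = pseudocount / s.sum()
    eps_r = pseudocount / r.sum()
    gamma = (ps + eps_s) / (pr + eps_r)
    missing = (s == 0) | (r == 0)
    gamma[missing] = 1.0
    if span > 0:
        from .spatialstats import loess_smooth

        ok = ~missing & (pr > 0)
        if ok.sum() >= 3:
            lg = np.log(gamma[ok])
            lx = np.log(pr[ok])
            gamma[ok] = np.exp(loess_smooth(lx, lg, span=span))
    gamma = np.clip(gamma, clamp[0], clamp[1])
    ids = list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(s.size)]
    return PlatformFactors(gene_ids=ids, gamma=gamma, smoothing_span=span)


# ---------------------------------------------------------------------------
# Poisson-mixture decomposition


def _profiles(panel: ReferencePanel, factors: PlatformFactors | None) -> np.ndarray:
    m = panel.mu
    if factors is not None:
        g = np.asarray(factors.gamma, dtype=float)
        if g.size != panel.n_genes:
            raise ValueError("platform factors do not match panel genes")
        m = m * g[None, :]
    return m


def poisson_mixture_loglik(
    y: np.ndarray, w: np.ndarray, profiles: np.ndarray, total: float | None = None
) -> float:
    """Poisson log-likelihood (up to the log y! constant) of weights ``w``.

    mean_g = N * sum_t w_t * profiles[t, g] with N the cell's total counts.
    """
    y = np.asarray(y, dtype=float)
    N = float(y.sum()) if total is None else float(total)
    mean = N * (w @ profiles)
    pos = y > 0
    with np.errstate(divide="ignore"):
        ll = float(np.sum(y[pos] * np.log(mean[pos]))) - float(mean.sum())
    return ll


def _solve_dual(a: np.ndarray, ns: np.ndarray, iters: int = 60) -> np.ndarray:
    """Vectorized bisection for lambda in sum_t a_t / (ns_t + lam) = 1.

    a: (C, T) nonnegative with row sums ~ N; ns: (C, T) = N * s_t > 0.
    Root lies in [rowsum(a) - max(ns), rowsum(a) - min(ns)].
    """
    rs = a.sum(axis=1)
    lo = rs - ns.max(axis=1)
    hi = rs - ns.min(axis=1)
    span = hi - lo
    done = span <= 1e-12 * np.maximum(np.abs(hi), 1.0)
    if done.all():  # equal profile masses: closed form, plain EM step
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        val = (a / (ns + mid[:, None])).sum(axis=1)
        high = val > 1.0
        lo = np.where(high, mid, lo)
        hi = np.where(high, hi, mid)
        if np.max(hi - lo) <= 1e-12 * max(np.max(np.abs(hi)), 1.0):
            break
    return 0.5 * (lo + hi)


def decompose_cells(
    counts,
    panel: ReferencePanel,
    factors: PlatformFactors | None = None,
    min_counts: int = 1,
    tol: float = 1e-8,
    max_iter: int = 1000,
    check_ascent: bool = False,
) -> np.ndarray:
    """Fit simplex mixture weights for every row of ``counts``.

    Returns an (n_cells, n_types) array; rows of cells with total counts
    below ``min_counts`` are NaN (rejected before fitting).  The iteration is
    a majorize-minimize ascent on the exact fixed-N objective: the log term is
    minorized by the EM surrogate and the surrogate maximized in closed form
    up to a one-dimensional dual variable enforcing the simplex constraint.
    """
    Y = counts.toarray() if sparse.issparse(counts) else np.asarray(counts, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if np.any(Y < 0):
        raise ValueError("counts must be nonnegative")
    C, G = Y.shape
    m = _profiles(panel, factors)  # (T, G)
    T = m.shape[0]
    if m.shape[1] != G:
        raise ValueError("counts and panel gene dimensions differ")
    N = Y.sum(axis=1)
    ok = N >= max(min_counts, 1)
    W = np.full((C, T), np.nan)
    if not ok.any():
        return W
    Ya = Y[ok]
    Na = N[ok]
    s = m.sum(axis=1)  # profile mass per type (platform-scaled)
    w = np.full((Ya.shape[0], T), 1.0 / T)
    active = np.arange(Ya.shape[0])
    prev_obj = None
    if check_ascent:
        prev_obj = np.array(
            [poisson_mixture_loglik(Ya[i], w[i], m, Na[i]) for i in range(Ya.shape[0])]
        )
    for _ in range(max_iter):
        ya = Ya[active]
        na = Na[active]
        wa = w[active]
        denom = wa @ m  # (c, G) expected relative expression
        denom = np.maximum(denom, 1e-300)
        a = wa * ((ya / denom) @ m.T)  # EM sufficient statistics, rows sum to N
        ns = np.broadcast_to(na[:, None] * s[None, :], a.shape)
        lam = _solve_dual(a, ns)
        w_new = a / (ns + lam[:, None])
        w_new = np.clip(w_new, 0.0, None)
        w_new /= w_new.sum(axis=1, keepdims=True)
        delta = np.abs(w_new - wa).max(axis=1)
        if check_ascent:
            for j, i in enumerate(active):
                new_obj = poisson_mixture_loglik(Ya[i], w_new[j], m, Na[i])
                if new_obj < prev_obj[i] - 1e-6:
                    raise AssertionError("likelihood decreased during decomposition")
                prev_obj[i] = new_obj
        w[active] = w_new
        active = active[delta > tol]
        if active.size == 0:
            break
    W[ok] = w
    return W


def decompose_cell(
    counts,
    panel: ReferencePanel,
    factors: PlatformFactors | None = None,
    **kwargs,
) -> np.ndarray:
    """Single-cell convenience wrapper around :func:`decompose_cells`."""
    w = decompose_cells(np.atleast_2d(np.asarray(counts)), panel, factors, **kwargs)[0]
    if np.any(np.isnan(w)):
        raise ValueError("zero-count cell cannot be decomposed")
    return w


# ---------------------------------------------------------------------------
# doublet-mode classification


def _singlet_logliks(Y: np.ndarray, m: np.ndarray, N: np.ndarray) -> np.ndarray:
    """(C, T) log-likelihood of each pure-type model (constants dropped)."""
    logm = np.log(np.maximum(m, 1e-300))
    ll = Y @ logm.T
    ll += np.log(np.maximum(N, 1))[:, None] * Y.sum(axis=1)[:, None]
    ll -= N[:, None] * m.sum(axis=1)[None, :]
    return ll


def _loglik_null_moments(m_t: np.ndarray, N: float) -> tuple[float, float]:
    """Mean and sd of the fitted log-likelihood for data truly from profile m_t.

    Under the Poisson model E[y_g] = N m_tg, so the log-likelihood statistic
    sum_g y_g log(N m_tg) - N m_tg has expectation
    sum_g N m_tg log(N m_tg) - N m_tg and variance sum_g N m_tg log(N m_tg)^2.
    """
    mean = N * m_t
    pos = mean > 0
    lm = np.log(mean[pos])
    mu = float(np.sum(mean[pos] * lm)) - float(mean.sum())
    var = float(np.sum(mean[pos] * lm**2))
    return mu, np.sqrt(max(var, 1e-300))


def classify_modes(
    counts,
    panel: ReferencePanel,
    factors: PlatformFactors | None = None,
    ll_margin: float = 10.0,
    reject_floor: float = 3.0,
    top_k: int = 4,
) -> tuple[list[str], np.ndarray]:
    """Classify cells as singlet / doublet (certain, uncertain) / rejected.

    Compares each cell's best single-type log-likelihood with its best
    two-type fit (pairs searched among the ``top_k`` best singlet types;
    pair fits are batched across cells).  A cell is rejected when its fitted
    log-likelihood falls more than ``reject_floor`` standard deviations below
    the analytic expectation for data genuinely drawn from its best-fitting
    profile at the same depth (both moments have closed forms under the
    Poisson model).

    Returns (modes, full-simplex weight matrix).
    """
    Y = counts.toarray() if sparse.issparse(counts) else np.asarray(counts, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    C = Y.shape[0]
    N = Y.sum(axis=1)
    m = _profiles(panel, factors)
    T = m.shape[0]
    weights = decompose_cells(Y, panel, factors)
    ok = N >= 1
    modes = ["rejected"] * C
    if not ok.any():
        return modes, weights
    sll = _singlet_logliks(Y, m, N)
    best_t = np.argmax(sll, axis=1)
    best_singlet = sll[np.arange(C), best_t]
    k = min(max(2, top_k), T)
    top = np.argsort(sll, axis=1)[:, ::-1][:, :k]
    # batch two-type fits: group cells sharing a candidate pair
    best_pair_ll = np.full(C, -np.inf)
    best_pair_min_w = np.zeros(C)
    best_pair_profile = np.zeros((C, m.shape[1]))
    pair_cells: dict[tuple[int, int], list[int]] = {}
    for i in range(C):
        if not ok[i]:
            continue
        for t, u in combinations(sorted(top[i].tolist()), 2):
            pair_cells.setdefault((t, u), []).append(i)
    for (t, u), idx in pair_cells.items():
        sub = panel.subset_types([panel.type_ids[t], panel.type_ids[u]])
        Wp = decompose_cells(Y[idx], sub, factors)
        msub = _profiles(sub, factors)
        for j, i in enumerate(idx):
            ll = poisson_mixture_loglik(Y[i], Wp[j], msub, N[i])
            if ll > best_pair_ll[i]:
                best_pair_ll[i] = ll
                best_pair_min_w[i] = Wp[j].min()
                best_pair_profile[i] = Wp[j] @ msub
    for i in range(C):
        if not ok[i]:
            continue
        improvement = best_pair_ll[i] - best_singlet[i]
        # goodness-of-fit floor referenced to the best-fitting model's own
        # profile: data truly from that profile would score near null_mu
        if best_pair_ll[i] >= best_singlet[i]:
            best_ll, prof = best_pair_ll[i], best_pair_profile[i]
        else:
            best_ll, prof = best_singlet[i], m[best_t[i]]
        null_mu, null_sd = _loglik_null_moments(prof, N[i])
        if (best_ll - null_mu) / null_sd < -reject_floor:
            modes[i] = "rejected"
        elif improvement < ll_margin:
            modes[i] = "singlet"
        elif improvement >= 2 * ll_margin and best_pair_min_w[i] >= 0.25:
            modes[i] = "doublet_certain"
        else:
            modes[i] = "doublet_uncertain"
    return modes, weights


def classify_mode(
    counts,
    panel: ReferencePanel,
    factors: PlatformFactors | None = None,
    ll_margin: float = 10.0,
    reject_floor: float = 3.0,
    top_k: int = 4,
) -> tuple[str, np.ndarray]:
    """Single-cell convenience wrapper around :func:`classify_modes`."""
    modes, W = classify_modes(
        np.atleast_2d(np.asarray(counts, dtype=float)), panel, factors,
        ll_margin=ll_margin, reject_floor=reject_floor, top_k=top_k,
    )
    return modes[0], W[0]


def assign_label(
    weights: np.ndarray,
    mode: str,
    type_ids: Sequence[str],
    threshold: float = 0.5,
) -> str | None:
    """Strict-threshold label: the type with weight > threshold, else UNCLASSIFIED.

    Rejected cells get None (they are excluded from labeled outputs).
    """
    if mode == "rejected":
        return None
    w = np.asarray(weights, dtype=float)
    best = int(np.argmax(w))
    if w[best] > threshold:
        return str(type_ids[best])
    return UNCLASSIFIED


def label_cells(
    adata: ad.AnnData,
    panel: ReferencePanel,
    factors: PlatformFactors | None = None,
    threshold: float = 0.5,
    ll_margin: float = 10.0,
    reject_floor: float = 3.0,
    classify: bool = True,
    round_name: str = "major_class",
) -> pd.DataFrame:
    """Decompose, classify, and label every cell of a table.

    Returns a DataFrame indexed by cell id with columns mode, assigned_label,
    round, top3 (the three largest weights as "type:weight" strings), and the
    full weight matrix in attrs.  With ``classify=False`` every decomposable
    cell is treated as a singlet (fast path for large sections).
    """
    genes = panel.gene_ids
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"panel genes missing from data: {missing[:3]}...")
    sub = adata[:, genes]
    Y = sub.X.toarray() if sparse.issparse(sub.X) else np.asarray(sub.X, dtype=float)
    if classify:
        modes, W = classify_modes(
            Y, panel, factors, ll_margin=ll_margin, reject_floor=reject_floor
        )
    else:
        W = decompose_cells(Y, panel, factors)
        modes = ["rejected" if np.any(np.isnan(W[i])) else "singlet"
                 for i in range(Y.shape[0])]
    labels: list[str | None] = [
        None if modes[i] == "rejected"
        else assign_label(W[i], modes[i], panel.type_ids, threshold)
        for i in range(Y.shape[0])
    ]
    top3 = []
    for i in range(Y.shape[0]):
        if np.any(np.isnan(W[i])):
            top3.append("")
            continue
        order = np.argsort(W[i])[::-1][:3]
        top3.append(";".join(f"{panel.type_ids[t]}:{W[i, t]:.4f}" for t in order))
    out = pd.DataFrame(
        {
            "mode": modes,
            "assigned_label": labels,
            "round": round_name,
            "top3": top3,
        },
        index=adata.obs_names,
    )
    out.attrs["weights"] = pd.DataFrame(W, index=adata.obs_names, columns=panel.type_ids)
    return out


def hierarchical_label(
    adata: ad.AnnData,
    class_panel: ReferencePanel,
    subtype_panel: ReferencePanel,
    msn_class: str = "MSN",
    factors: PlatformFactors | None = None,
    threshold: float = 0.5,
    classify: bool = False,
) -> tuple[ad.AnnData, dict]:
    """Two-round labeling: major classes first, then MSN subtypes.

    Cells labeled ``msn_class`` in round 1 are re-decomposed against the
    subtype reference; all other cells keep their round-1 label.  The summary
    reports labeled counts, the MSN fraction of all labeled cells and of
    neurons (classes containing "MSN" or "neuron" in their id).
    """
    out = adata.copy()
    r1 = label_cells(out, class_panel, factors, threshold, classify=classify,
                     round_name="major_class")
    out.obs["major_class"] = r1["assigned_label"]
    out.obs["label_mode"] = r1["mode"]
    out.obs["assigned_label"] = r1["assigned_label"]
    out.obs["label_round"] = "major_class"
    is_msn = (r1["assigned_label"] == msn_class).to_numpy()
    n_msn = int(is_msn.sum())
    if n_msn == 0:
        import warnings

        warnings.warn("no cell labeled as MSN; subtype round skipped")
    else:
        sub = out[is_msn]
        r2 = label_cells(sub, subtype_panel, factors, threshold, classify=classify,
                         round_name="msn_subtype")
        out.obs.loc[is_msn, "assigned_label"] = r2["assigned_label"].to_numpy()
        out.obs.loc[is_msn, "label_round"] = "msn_subtype"
    labeled = out.obs["assigned_label"].notna() & (out.obs["assigned_label"] != UNCLASSIFIED)
    neuron_mask = out.obs["major_class"].astype(str).str.contains("MSN|neuron", case=False)
    n_labeled = int(labeled.sum())
    summary = {
        "n_cells": int(out.n_obs),
        "n_labeled": n_labeled,
        "n_msn": n_msn,
        "msn_fraction_of_cells": n_msn / max(n_labeled, 1),
        "msn_fraction_of_neurons": n_msn / max(int((labeled & neuron_mask).sum()), 1),
    }
    return out, summary
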