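"""Cell-level quality control: rule-based RNA filters and NB outlier scoring.

RNA nuclei pass when 2500 < genes detected < 10000 and mitochondrial
percentage < 5 (strict inequalities).  ATAC-style QC is two-round: round 1
keeps cells with at least 10^3.5 fragments (and an optional precomputed
doublet-filter flag); round 2 fits a negative-binomial regression of fragment
count on TSS enrichment, promoter ratio and doublet enrichment and excludes
cells whose standardized (Pearson) residual exceeds 2 in absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special

__all__ = ["NBFit", "rna_qc_filter", "nb_outlier_flags", "FRAGMENT_THRESHOLD"]

FRAGMENT_THRESHOLD = 10**3.5


def rna_qc_filter(
    cells: pd.DataFrame,
    feature_col: str = "nFeature",
    mito_col: str = "percent_mito",
    min_features: int = 2500,
    max_features: int = 10000,
    max_mito: float = 5.0,
) -> tuple[pd.Series, dict]:
    """Strict-threshold RNA filter: min < nFeature < max and percent_mito < 5."""
    for col in (feature_col, mito_col):
        if col not in cells.columns:
            raise ValueError(f"missing QC column {col!r}")
    nf = cells[feature_col]
    pm = cells[mito_col]
    if pm.isna().any():
        raise ValueError("mitochondrial percentage missing for some cells")
    passed = (nf > min_features) & (nf < max_features) & (pm < max_mito)
    summary = {
        "n_cells": int(len(cells)),
        "n_pass": int(passed.sum()),
        "n_fail_low_features": int((nf <= min_features).sum()),
        "n_fail_high_features": int((nf >= max_features).sum()),
        "n_fail_mito": int((pm >= max_mito).sum()),
    }
    return passed.rename("pass"), summary


@dataclass
class NBFit:
    coef: pd.Series
    theta: float
    converged: bool
    n_iter: int
    theta_at_bound: bool = False


def _nb_loglik_theta(theta: float, y: np.ndarray, mu: np.ndarray) -> float:
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    max_outer: int = 100,
    theta_max: float = 1e6,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """NB GLM (log link) by alternating IRLS and ML dispersion updates."""
    from scipy.optimize import minimize_scalar

    mu = np.maximum(y.astype(float), 0.5)
    m, v = mu.mean(), y.var()
    theta = m**2 / (v - m) if v > m else theta_max
    theta = float(np.clip(theta, 1e-3, theta_max))
    beta = None
    converged = False
    it = 0
    for it in range(1, max_outer + 1):
        fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
        glm = sm.GLM(y, X, family=fam).fit(start_params=beta)
        beta_new = glm.params
        mu = glm.mu
        res = minimize_scalar(
            lambda lt: -_nb_loglik_theta(np.exp(lt), y, mu),
            bounds=(np.log(1e-3), np.log(theta_max)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        theta_new = float(np.exp(res.x))
        moved = abs(np.log(theta_new) - np.log(theta))
        if beta is not None:
            moved = max(moved, float(np.max(np.abs(beta_new - beta))))
        beta = beta_new
        theta = theta_new
        if moved < tol:
            converged = True
            break
    return beta, mu, theta, converged, it


def nb_outlier_flags(
    cells: pd.DataFrame,
    residual_cutoff: float = 2.0,
    fragment_threshold: float = FRAGMENT_THRESHOLD,
    predictors: tuple[str, ...] = ("TSSEnrichment", "PromoterRatio", "DoubletEnrichment"),
    frag_col: str = "nFrags",
    doublet_pass_col: str | None = None,
    residual_scale: str = "pearson",
    two_sided: bool = True,
) -> tuple[pd.DataFrame, NBFit]:
    """Two-round ATAC QC: fragment threshold, then NB-regression outliers.

    The NB model nFrags ~ predictors (log link) is fitted on round-1 passing
    cells; standardized residuals are Pearson (y - mu) / sqrt(mu + mu^2/theta)
    by default (deviance residuals available).  round2_pass keeps cells whose
    residual magnitude is within ``residual_cutoff`` (one-sided upper cutoff
    when ``two_sided`` is False).
    """
    df = cells.copy()
    y_all = df[frag_col].to_numpy(dtype=float)
    r1 = y_all >= fragment_threshold
    if doublet_pass_col is not None:
        r1 &= df[doublet_pass_col].astype(bool).to_numpy()
    df["round1_pass"] = r1
    fit_df = df[r1]
    X = np.column_stack(
        [np.ones(len(fit_df))] + [fit_df[p].to_numpy(dtype=float) for p in predictors]
    )
    if len(fit_df) < 10 * X.shape[1]:
        raise ValueError("need at least 10x more cells than coefficients")
    y = fit_df[frag_col].to_numpy(dtype=float)
    beta, mu, theta, converged, n_iter = _fit_nb_glm(y, X)
    if residual_scale == "pearson":
        resid = (y - mu) / np.sqrt(mu + mu**2 / theta)
    elif residual_scale == "deviance":
        fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
        resid = fam.resid_dev(y, mu)
    else:
        raise ValueError("residual_scale must be 'pearson' or 'deviance'")
    df["nb_residual"] = np.nan
    df.loc[r1, "nb_residual"] = resid
    if two_sided:
        ok = np.abs(resid) <= residual_cutoff
    else:
        ok = resid <= residual_cutoff
    df["round2_pass"] = False
    df.loc[r1, "round2_pass"] = ok
    fit = NBFit(
        coef=pd.Series(beta, index=["intercept", *predictors]),
        theta=theta,
        converged=converged,
        n_iter=n_iter,
        theta_at_bound=theta >= 1e6 * 0.999,
    )
    if not converged:
        import warnings

        warnings.warn(f"NB outer iteration did not converge in {n_iter} rounds")
    return df, fit
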