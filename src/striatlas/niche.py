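"""Spatial niche assay: neighborhood composition + k-means demarcation.

A cell's microenvironment is summarized by the label composition of its k
nearest labeled neighbors; k-means over these composition vectors yields
spatial niches, and the niche with the highest MSN proportion demarcates the
striatum.  The same operation serves both uses in the workflow: validating
anatomical boundaries and refining the striatal crop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .label import UNCLASSIFIED

__all__ = ["NicheModel", "neighborhood_composition", "cluster_niches"]


@dataclass
class NicheModel:
    k_neighbors: int
    n_clusters: int
    composition: pd.DataFrame  # cells x labels, rows sum to k_neighbors
    niche_of_cell: pd.Series
    striatal_niche: int
    centroids: pd.DataFrame  # clusters x labels
    inertia: float

    def striatum_mask(self) -> pd.Series:
        """Boolean per cell: member of the MSN-richest niche."""
        return self.niche_of_cell == self.striatal_niche


def neighborhood_composition(
    cells: ad.AnnData | pd.DataFrame,
    k_neighbors: int = 30,
    label_col: str = "assigned_label",
) -> pd.DataFrame:
    """Count labels among each cell's k nearest labeled cells (self excluded).

    Unlabeled / UNCLASSIFIED cells contribute to nobody's composition but
    still get a composition row from their labeled neighbors.  Neighbors are
    found by Euclidean distance on (x_um, y_um); sklearn's kd-tree ordering
    provides a deterministic tie-break (distance, then insertion index, which
    follows cell order).
    """
    obs = cells.obs if isinstance(cells, ad.AnnData) else cells
    lab = obs[label_col].astype(object)
    labeled = lab.notna() & (lab != UNCLASSIFIED)
    n_labeled = int(labeled.sum())
    if n_labeled < k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors+1={k_neighbors + 1} labeled cells, have {n_labeled}"
        )
    xy = obs[["x_um", "y_um"]].to_numpy(dtype=float)
    xy_lab = xy[labeled.to_numpy()]
    lab_values = lab[labeled].to_numpy()
    labels_sorted = sorted(pd.unique(lab_values))
    lab_idx = pd.Categorical(lab_values, categories=labels_sorted).codes
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(xy_lab)
    _, ind = nn.kneighbors(xy)
    # a labeled cell finds itself at distance 0: drop self, keep k others
    self_pos = np.full(len(obs), -1)
    labeled_positions = np.flatnonzero(labeled.to_numpy())
    pos_of = {p: j for j, p in enumerate(labeled_positions)}
    for i in range(len(obs)):
        j = pos_of.get(i, -1)
        self_pos[i] = j
    comp = np.zeros((len(obs), len(labels_sorted)), dtype=int)
    for i in range(len(obs)):
        row = ind[i]
        row = row[row != self_pos[i]][:k_neighbors]
        np.add.at(comp[i], lab_idx[row], 1)
    return pd.DataFrame(comp, index=obs.index, columns=labels_sorted)


def cluster_niches(
    composition: pd.DataFrame,
    n_clusters: int = 30,
    seed: int = 0,
    msn_labels: tuple[str, ...] | str = "MSN",
    n_init: int = 10,
) -> NicheModel:
    """k-means over composition rows; the MSN-richest cluster is the striatum.

    ``msn_labels`` names the composition columns counted as MSN (a single
    class label, or the tuple of subtype labels).  If the requested number of
    clusters exceeds the number of distinct rows, the effective cluster count
    is reduced with a warning (degenerate composition).
    """
    X = composition.to_numpy(dtype=float)
    distinct = np.unique(X, axis=0).shape[0]
    k = n_clusters
    if distinct < n_clusters:
        warnings.warn(
            f"only {distinct} distinct composition rows; reducing clusters from {n_clusters}"
        )
        k = max(distinct, 1)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    niche = pd.Series(km.labels_, index=composition.index, name="niche_id")
    if isinstance(msn_labels, str):
        msn_cols = [c for c in composition.columns if msn_labels in str(c)]
    else:
        msn_cols = [c for c in composition.columns if c in set(msn_labels)]
    if not msn_cols:
        raise ValueError("no composition column matches the MSN labels")
    msn_frac_cell = composition[msn_cols].sum(axis=1) / composition.sum(axis=1).replace(0, np.nan)
    per_cluster = msn_frac_cell.groupby(niche).mean()
    striatal = int(per_cluster.idxmax())
    centroids = pd.DataFrame(km.cluster_centers_, columns=composition.columns)
    return NicheModel(
        k_neighbors=int(composition.sum(axis=1).iloc[0]) if len(composition) else 0,
        n_clusters=k,
        composition=composition,
        niche_of_cell=niche,
        striatal_niche=striatal,
        centroids=centroids,
        inertia=float(km.inertia_),
    )
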