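"""Synthetic data generation with complete ground truth.

Emulates the statistical structure of a targeted spatial-transcriptomics
experiment over coronal striatal sections (a ~366-gene panel, negative-binomial
count noise, per-gene platform factors) together with an snRNA-seq-like
reference: cell types with disjoint marker blocks, spatial territories built
from simple geometry (rectangles, discs, half-planes), logit-scale
rostro-caudal abundance gradients with animal/species random intercepts, and
expression discontinuities versus smooth gradients injected into single marker
genes.  Every generated cell carries its true type and every injected
discontinuity its true jump, so downstream recovery tests are closed.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Rect",
    "Disc",
    "HalfPlane",
    "Territory",
    "GradientSpec",
    "DiscontinuitySpec",
    "SimulationConfig",
    "ReferencePanel",
    "DEFAULT_MSN_TYPES",
    "make_reference",
    "simulate_reference_cells",
    "make_section",
    "inject_discontinuity",
    "make_rc_series",
    "nb_counts",
    "platform_factors",
]

#: Types of the bundled demo scenario: four MSN subtypes plus two glial classes.
DEMO_TYPES = ("D1-Matrix", "D2-Matrix", "D1-VS", "D1-VS-RGS6", "Astro", "Oligo")
DEMO_MSN_TYPES = ("D1-Matrix", "D2-Matrix", "D1-VS", "D1-VS-RGS6")

#: Conventional names for an 11-subtype medium-spiny-neuron reference.
DEFAULT_MSN_TYPES = [
    "D1-Matrix",
    "D2-Matrix",
    "D1-Striosome",
    "D2-Striosome",
    "D1-VS",
    "D2-VS",
    "D1-VS-RGS6",
    "D2-VS-RGS6",
    "D1-NUDAP",
    "D1-ICj",
    "D2-Hybrid",
]


def _substream(seed: int, *tokens) -> np.random.Generator:
    """Deterministic child generator keyed by (seed, tokens).

    Stage/section insertion must not perturb other draws, so each logical
    stream hashes its own name instead of consuming from a shared generator.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for t in tokens:
        ints.append(zlib.crc32(str(t).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class Rect:
    x0: float
    x1: float
    y0: float
    y1: float

    @property
    def area(self) -> float:
        return max(self.x1 - self.x0, 0.0) * max(self.y1 - self.y0, 0.0)

    def contains(self, x, y):
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    def sample(self, rng: np.random.Generator, n: int):
        x = rng.uniform(self.x0, self.x1, n)
        y = rng.uniform(self.y0, self.y1, n)
        return x, y

    @property
    def bounds(self):
        return self.x0, self.x1, self.y0, self.y1


@dataclass(frozen=True)
class Disc:
    cx: float
    cy: float
    r: float

    @property
    def area(self) -> float:
        return np.pi * self.r**2

    def contains(self, x, y):
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.r**2

    def sample(self, rng: np.random.Generator, n: int):
        # polar sampling is uniform over the disc
        u = rng.uniform(0.0, 1.0, n)
        th = rng.uniform(0.0, 2 * np.pi, n)
        rad = self.r * np.sqrt(u)
        return self.cx + rad * np.cos(th), self.cy + rad * np.sin(th)

    @property
    def bounds(self):
        return self.cx - self.r, self.cx + self.r, self.cy - self.r, self.cy + self.r


@dataclass(frozen=True)
class HalfPlane:
    """Half of a bounding rectangle, split along x or y at ``threshold``.

    ``side`` is "low" (coordinate <= threshold) or "high" (> threshold).
    """

    box: Rect
    axis: str  # "x" or "y"
    threshold: float
    side: str  # "low" | "high"

    def _clipped(self) -> Rect:
        b = self.box
        if self.axis == "x":
            if self.side == "low":
                return Rect(b.x0, min(self.threshold, b.x1), b.y0, b.y1)
            return Rect(max(self.threshold, b.x0), b.x1, b.y0, b.y1)
        if self.side == "low":
            return Rect(b.x0, b.x1, b.y0, min(self.threshold, b.y1))
        return Rect(b.x0, b.x1, max(self.threshold, b.y0), b.y1)

    @property
    def area(self) -> float:
        return self._clipped().area

    def contains(self, x, y):
        return self._clipped().contains(x, y)

    def sample(self, rng, n):
        return self._clipped().sample(rng, n)

    @property
    def bounds(self):
        return self._clipped().bounds


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class Territory:
    """A geometric region populated with cells of given types.

    density is in cells per square micrometre (1e-3 ~ 1000 cells/mm^2);
    type_weights are the baseline (rc-level-0) relative abundances within the
    territory, before gradient and random-intercept adjustment.
    """

    region: Rect | Disc | HalfPlane
    type_weights: dict[str, float]
    density: float

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("territory density must be >= 0")


@dataclass(frozen=True)
class GradientSpec:
    """Logit-scale abundance trend for one type along the rostro-caudal axis.

    abundance logit at level r: intercept + slope * r + animal + species
    random intercepts (drawn once per animal / species) + a per-section
    jitter with sd ``section_sd`` (tissue heterogeneity beyond counting noise).
    """

    intercept: float = 0.0
    slope: float = 0.0
    animal_sd: float = 0.0
    species_sd: float = 0.0
    section_sd: float = 0.0


@dataclass(frozen=True)
class DiscontinuitySpec:
    gene: str
    axis: str  # "x" | "y"
    boundary: float
    jump: float
    slope: float = 0.0
    noise_sd: float = 0.0
    intercept: float | None = None  # None: keep the gene's current mean


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed is echoed into every output.

    Defaults describe a targeted panel of 366 genes over 11 MSN-like subtypes
    with a mean depth of 300 transcripts per cell and NB overdispersion
    alpha = 0.1 (variance mu + alpha mu^2); per-gene platform factors are
    log-normal with sd 0.3 on the log scale.
    """

    seed: int = 0
    n_types: int = 11
    n_genes: int = 366
    n_marker_genes: int = 3
    marker_fold: float = 10.0
    library_size_mean: float = 300.0
    library_size_dispersion: float = 0.3  # sd of log library size
    nb_dispersion: float = 0.1
    platform_sd: float = 0.3
    type_names: tuple[str, ...] | None = None
    territory_spec: tuple[Territory, ...] | None = None
    gradient_spec: dict[str, GradientSpec] = field(default_factory=dict)
    discontinuity_spec: tuple[DiscontinuitySpec, ...] = ()

    def type_ids(self) -> list[str]:
        if self.type_names is not None:
            if len(self.type_names) != self.n_types:
                raise ValueError("type_names length must equal n_types")
            return list(self.type_names)
        if self.n_types == len(DEFAULT_MSN_TYPES):
            return list(DEFAULT_MSN_TYPES)
        return [f"type{i:02d}" for i in range(self.n_types)]

    def territories(self) -> tuple[Territory, ...]:
        if self.territory_spec is not None:
            return self.territory_spec
        region = Rect(0.0, 1000.0, 0.0, 1000.0)
        weights = {t: 1.0 for t in self.type_ids()}
        return (Territory(region=region, type_weights=weights, density=1e-3),)


# ---------------------------------------------------------------------------
# reference panel


@dataclass
class ReferencePanel:
    """Cell-type x gene expected relative expression (rows sum to 1)."""

    gene_ids: list[str]
    type_ids: list[str]
    mu: np.ndarray  # (n_types, n_genes), rows sum to 1
    panel_mask: np.ndarray  # bool per gene
    marker_map: dict[str, list[str]]

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.panel_mask = np.asarray(self.panel_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        T, G = self.mu.shape
        if T != len(self.type_ids) or G != len(self.gene_ids):
            raise ValueError("mu shape inconsistent with gene/type ids")
        if np.any(self.mu < 0):
            raise ValueError("mu entries must be nonnegative")
        if not np.allclose(self.mu.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each row of mu must sum to 1 (atol 1e-9)")
        gene_set = set(self.gene_ids)
        gidx = {g: i for i, g in enumerate(self.gene_ids)}
        for t, markers in self.marker_map.items():
            if not set(markers) <= gene_set:
                raise ValueError(f"marker genes of {t!r} not all in gene_ids")
            on_panel = sum(self.panel_mask[gidx[g]] for g in markers)
            if on_panel < 2:
                raise ValueError(f"panel_mask keeps fewer than 2 markers for {t!r}")

    @property
    def n_types(self) -> int:
        return len(self.type_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        gidx = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([gidx[g] for g in genes], dtype=int)

    def subset_types(self, types: Sequence[str]) -> "ReferencePanel":
        keep = [self.type_ids.index(t) for t in types]
        return ReferencePanel(
            gene_ids=list(self.gene_ids),
            type_ids=list(types),
            mu=self.mu[keep].copy(),
            panel_mask=self.panel_mask.copy(),
            marker_map={t: list(self.marker_map.get(t, [])) for t in types},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mu, index=self.type_ids, columns=self.gene_ids)


def make_reference(config: SimulationConfig) -> ReferencePanel:
    """Build a reference panel with disjoint elevated marker blocks per type."""
    T, G, k = config.n_types, config.n_genes, config.n_marker_genes
    if T < 2:
        raise ValueError("need at least 2 types")
    if G < 2 * T:
        raise ValueError("need n_genes >= 2 * n_types")
    if T * k > G:
        raise ValueError(
            f"marker blocks cannot be disjoint: {T} types x {k} markers > {G} genes"
        )
    types = config.type_ids()
    genes = [f"gene{i + 1:04d}" for i in range(G)]
    rng = _substream(config.seed, "reference")
    mu = np.ones((T, G), dtype=float)
    # mild baseline heterogeneity so no two types are exactly proportional
    mu *= np.exp(rng.normal(0.0, 0.1, size=(T, G)))
    marker_map: dict[str, list[str]] = {}
    for i, t in enumerate(types):
        block = slice(i * k, (i + 1) * k)
        mu[i, block] = config.marker_fold
        marker_map[t] = genes[block]
    mu /= mu.sum(axis=1, keepdims=True)
    panel_mask = np.ones(G, dtype=bool)
    return ReferencePanel(
        gene_ids=genes, type_ids=types, mu=mu, panel_mask=panel_mask, marker_map=marker_map
    )


# ---------------------------------------------------------------------------
# count noise


def nb_counts(rng: np.random.Generator, mean, alpha: float) -> np.ndarray:
    """NB counts with variance mu + alpha mu^2 (gamma-Poisson mixture).

    alpha = 0 is the Poisson limit.
    """
    mean = np.asarray(mean, dtype=float)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def platform_factors(config: SimulationConfig, n_genes: int | None = None) -> np.ndarray:
    """Per-gene log-normal spatial-platform multipliers (drawn once per config)."""
    G = config.n_genes if n_genes is None else n_genes
    rng = _substream(config.seed, "platform")
    if config.platform_sd == 0:
        return np.ones(G)
    return np.exp(rng.normal(0.0, config.platform_sd, size=G))


def _library_sizes(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    s = config.library_size_dispersion
    m = config.library_size_mean
    return np.exp(rng.normal(np.log(m) - s**2 / 2.0, s, size=n))


def _sample_counts(
    rng: np.random.Generator,
    panel: ReferencePanel,
    type_idx: np.ndarray,
    depths: np.ndarray,
    alpha: float,
    gamma: np.ndarray | None = None,
) -> sparse.csr_matrix:
    prof = panel.mu
    if gamma is not None:
        prof = prof * gamma[None, :]
        prof = prof / prof.sum(axis=1, keepdims=True)
    means = prof[type_idx] * depths[:, None]
    counts = nb_counts(rng, means, alpha)
    return sparse.csr_matrix(counts)


def _empty_table(panel: ReferencePanel) -> ad.AnnData:
    obs = pd.DataFrame(
        {
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "section_id": pd.Series(dtype=object),
            "rc_level_mm": pd.Series(dtype=float),
            "animal_id": pd.Series(dtype=object),
            "species_id": pd.Series(dtype=object),
            "true_type": pd.Series(dtype=object),
            "assigned_label": pd.Series(dtype=object),
        }
    )
    X = sparse.csr_matrix((0, panel.n_genes))
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=panel.gene_ids))


def simulate_reference_cells(
    panel: ReferencePanel,
    n_per_type: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ad.AnnData:
    """snRNA-seq-like reference cells: NB counts around each type's profile.

    Coordinates are NaN (dissociated nuclei carry no position).
    """
    if n_per_type < 0:
        raise ValueError("n_per_type must be >= 0")
    if n_per_type == 0:
        out = _empty_table(panel)
        out.uns["seed"] = config.seed
        return out
    rng = rng if rng is not None else _substream(config.seed, "reference_cells")
    T = panel.n_types
    type_idx = np.repeat(np.arange(T), n_per_type)
    n = type_idx.size
    depths = _library_sizes(rng, n, config)
    X = _sample_counts(rng, panel, type_idx, depths, config.nb_dispersion)
    obs = pd.DataFrame(
        {
            "x_um": np.nan,
            "y_um": np.nan,
            "section_id": "reference",
            "rc_level_mm": np.nan,
            "animal_id": "ref",
            "species_id": "ref",
            "true_type": [panel.type_ids[i] for i in type_idx],
            "assigned_label": pd.Series([None] * n, dtype=object),
        },
        index=[f"ref{i:06d}" for i in range(n)],
    )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=panel.gene_ids))
    adata.uns["seed"] = config.seed
    return adata


# ---------------------------------------------------------------------------
# spatial sections


def _territory_logits(
    territory: Territory,
    config: SimulationConfig,
    rc_level_mm: float,
    animal_effects: dict[str, float] | None,
    species_effects: dict[str, float] | None,
    section_rng: np.random.Generator | None = None,
) -> tuple[list[str], np.ndarray]:
    types = [t for t, w in territory.type_weights.items() if w > 0]
    logits = []
    for t in types:
        g = config.gradient_spec.get(t, GradientSpec())
        z = np.log(territory.type_weights[t]) + g.intercept + g.slope * rc_level_mm
        if animal_effects:
            z += animal_effects.get(t, 0.0)
        if species_effects:
            z += species_effects.get(t, 0.0)
        if section_rng is not None and g.section_sd > 0:
            z += section_rng.normal(0.0, g.section_sd)
        logits.append(z)
    return types, np.asarray(logits, dtype=float)


def make_section(
    panel: ReferencePanel,
    config: SimulationConfig,
    rc_level_mm: float,
    section_id: str = "S0",
    animal_id: str = "A1",
    species_id: str = "S1",
    animal_effects: dict[str, float] | None = None,
    species_effects: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> ad.AnnData:
    """One coronal section: spatial Poisson placement + gradient-tilted types.

    Cells are placed by a homogeneous Poisson process within each territory;
    the type of each cell is drawn from the territory's softmax-adjusted
    composition at this rc level.  Counts include the per-gene platform
    factors of the config.
    """
    rng = rng if rng is not None else _substream(config.seed, "section", section_id, animal_id)
    gamma = platform_factors(config, panel.n_genes)
    # per-section composition jitter, shared by all territories of the section
    section_effects = {
        t: rng.normal(0.0, g.section_sd)
        for t, g in config.gradient_spec.items()
        if g.section_sd > 0
    }
    merged_animal = dict(animal_effects or {})
    for t, e in section_effects.items():
        merged_animal[t] = merged_animal.get(t, 0.0) + e
    xs, ys, tidx = [], [], []
    for territory in config.territories():
        n = rng.poisson(territory.density * territory.region.area)
        if n == 0:
            continue
        x, y = territory.region.sample(rng, n)
        types, logits = _territory_logits(
            territory, config, rc_level_mm, merged_animal, species_effects
        )
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        ti = rng.choice([panel.type_ids.index(t) for t in types], size=n, p=probs)
        xs.append(x)
        ys.append(y)
        tidx.append(ti)
    if not xs:
        warnings.warn(f"section {section_id!r} is empty (all territory densities 0)")
        out = _empty_table(panel)
        out.uns["seed"] = config.seed
        return out
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    type_idx = np.concatenate(tidx)
    n = x.size
    depths = _library_sizes(rng, n, config)
    X = _sample_counts(rng, panel, type_idx, depths, config.nb_dispersion, gamma=gamma)
    obs = pd.DataFrame(
        {
            "x_um": x,
            "y_um": y,
            "section_id": section_id,
            "rc_level_mm": float(rc_level_mm),
            "animal_id": animal_id,
            "species_id": species_id,
            "true_type": [panel.type_ids[i] for i in type_idx],
            "assigned_label": pd.Series([None] * n, dtype=object),
        },
        index=[f"{section_id}_c{i:06d}" for i in range(n)],
    )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=panel.gene_ids))
    adata.uns["seed"] = config.seed
    for spec in config.discontinuity_spec:
        adata = inject_discontinuity(
            adata,
            spec.gene,
            spec.axis,
            spec.boundary,
            spec.jump,
            slope=spec.slope,
            intercept=spec.intercept,
            noise_sd=spec.noise_sd,
            alpha=config.nb_dispersion,
            rng=rng,
        )
    return adata


def inject_discontinuity(
    section: ad.AnnData,
    gene: str,
    axis: str,
    boundary: float,
    jump: float,
    slope: float = 0.0,
    intercept: float | None = None,
    noise_sd: float = 0.0,
    alpha: float = 0.1,
    rng: np.random.Generator | None = None,
) -> ad.AnnData:
    """Overwrite one gene's counts with a step-plus-gradient expression field.

    Expected depth-normalized expression at coordinate c is
    ``intercept + slope * (c - boundary) + jump * 1[c > boundary]``
    (clipped at 0); each cell's count mean is that field scaled by the cell's
    relative library size, so the injected pattern survives per-cell depth
    normalization, and counts are realized as NB with dispersion ``alpha``.
    ``noise_sd`` adds Gaussian jitter on the expected value before clipping.
    The true jump is recorded in ``uns['discontinuities']``.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if gene not in section.var_names:
        raise ValueError(f"gene {gene!r} not on panel")
    coord = section.obs["x_um"].to_numpy() if axis == "x" else section.obs["y_um"].to_numpy()
    if section.n_obs and not (coord.min() <= boundary <= coord.max()):
        raise ValueError("boundary outside the coordinate range of the section")
    rng = rng if rng is not None else np.random.default_rng(
        int(section.uns.get("seed", 0)) + zlib.crc32(gene.encode()) % 100003
    )
    out = section.copy()
    if intercept is None:
        gi = out.var_names.get_loc(gene)
        col = np.asarray(out.X[:, gi].todense()).ravel() if sparse.issparse(out.X) else out.X[:, gi]
        intercept = float(np.mean(col)) if out.n_obs else 0.0
    mean = intercept + slope * (coord - boundary) + jump * (coord > boundary)
    if noise_sd > 0:
        mean = mean + rng.normal(0.0, noise_sd, size=mean.size)
    mean = np.clip(mean, 0.0, None)
    # scale by relative depth so the field is on the depth-normalized scale
    depth = np.asarray(out.X.sum(axis=1)).ravel() if out.n_obs else np.array([])
    if depth.size and np.median(depth) > 0:
        mean = mean * depth / np.median(depth)
    newcol = nb_counts(rng, mean, alpha)
    X = sparse.lil_matrix(out.X) if sparse.issparse(out.X) else out.X.copy()
    gi = out.var_names.get_loc(gene)
    X[:, gi] = newcol[:, None]
    out.X = sparse.csr_matrix(X) if sparse.issparse(section.X) else X
    log = list(out.uns.get("discontinuities", []))
    log.append(
        {
            "gene": gene,
            "axis": axis,
            "boundary": float(boundary),
            "jump": float(jump),
            "slope": float(slope),
            "intercept": float(intercept),
            "noise_sd": float(noise_sd),
        }
    )
    out.uns["discontinuities"] = log
    return out


def make_rc_series(
    panel: ReferencePanel,
    config: SimulationConfig,
    levels: Sequence[float],
    n_animals: int = 2,
    n_species: int = 2,
) -> list[ad.AnnData]:
    """Sections at several rostro-caudal levels for several animals.

    Animal and species random intercepts (per type) are drawn once and reused
    at every level, matching the repeated-measures structure a mixed model
    assumes.  Animals are assigned to species round-robin.
    """
    if len(levels) < 2:
        raise ValueError("need at least 2 rc levels")
    n_species = min(n_species, n_animals)
    animals = [f"A{i + 1}" for i in range(n_animals)]
    species = [f"Sp{i % n_species + 1}" for i in range(n_animals)]
    rng = _substream(config.seed, "random_intercepts")
    a_eff: dict[str, dict[str, float]] = {}
    s_eff: dict[str, dict[str, float]] = {}
    for t, g in config.gradient_spec.items():
        a_eff[t] = {a: rng.normal(0.0, g.animal_sd) if g.animal_sd > 0 else 0.0 for a in animals}
    for t, g in config.gradient_spec.items():
        uniq = sorted(set(species))
        draws = {s: rng.normal(0.0, g.species_sd) if g.species_sd > 0 else 0.0 for s in uniq}
        s_eff[t] = draws
    sections = []
    for lev in levels:
        for a, sp in zip(animals, species):
            sec = make_section(
                panel,
                config,
                rc_level_mm=lev,
                section_id=f"{a}_L{lev:+g}",
                animal_id=a,
                species_id=sp,
                animal_effects={t: a_eff[t][a] for t in a_eff},
                species_effects={t: s_eff[t][sp] for t in s_eff},
            )
            sections.append(sec)
    return sections


# ---------------------------------------------------------------------------
# bundled demo scenario


def demo_config(seed: int = 0, density: float = 1.5e-3) -> SimulationConfig:
    """A small striatum-plus-cortex scenario exercising every analysis stage.

    Each section carries a striatal region (a medial band enriched in
    D1-VS-RGS6 plus matrix types, a lateral band enriched in D1-VS) and a
    separate cortical block of glia; D2-Matrix abundance rises caudally on
    the logit scale while D1-Matrix stays flat; and a TAC3-like jump in the
    first D1-VS-RGS6 marker gene sits at the medial/lateral divide (x = 350).
    """
    medial = Rect(50.0, 330.0, 200.0, 800.0)
    lateral = Rect(370.0, 650.0, 200.0, 800.0)
    cortex = Rect(750.0, 1000.0, 0.0, 1000.0)
    territories = (
        Territory(
            region=medial,
            type_weights={"D1-Matrix": 1.0, "D2-Matrix": 1.0, "D1-VS-RGS6": 1.0},
            density=density,
        ),
        Territory(
            region=lateral,
            type_weights={"D1-Matrix": 1.0, "D2-Matrix": 1.0, "D1-VS": 1.0},
            density=density,
        ),
        Territory(region=cortex, type_weights={"Astro": 1.0, "Oligo": 1.0}, density=density),
    )
    # a modest caudal rise of D2-Matrix (rc is negative caudally, so its logit
    # slope is negative) offset by rostral-enriched VS types, leaving
    # D1-Matrix flat in percent terms; per-section jitter emulates tissue
    # heterogeneity beyond counting noise
    # D1-Matrix's tiny logit slope cancels the compositional drift induced by
    # the other types' trends, making its expected percentage exactly flat
    gradients = {
        "D2-Matrix": GradientSpec(slope=-0.03, animal_sd=0.15, section_sd=0.05),
        "D1-Matrix": GradientSpec(slope=-0.0025, animal_sd=0.15, section_sd=0.05),
        "D1-VS": GradientSpec(slope=0.03, animal_sd=0.15, section_sd=0.05),
        "D1-VS-RGS6": GradientSpec(slope=0.03, animal_sd=0.15, section_sd=0.05),
    }
    # first marker of D1-VS-RGS6 in the construction of make_reference
    jump_gene = f"gene{3 * 3 + 1:04d}"
    disc = (DiscontinuitySpec(gene=jump_gene, axis="x", boundary=350.0, jump=3.0,
                              slope=0.0, noise_sd=0.2, intercept=2.0),)
    return SimulationConfig(
        seed=seed,
        n_types=len(DEMO_TYPES),
        n_genes=120,
        n_marker_genes=3,
        marker_fold=10.0,
        type_names=tuple(DEMO_TYPES),
        territory_spec=territories,
        gradient_spec=gradients,
        discontinuity_spec=disc,
    )


def demo_discontinuity_config(seed: int = 0, density: float = 8e-3) -> SimulationConfig:
    """The bundled discontinuity demo: two VS bands flanking a 40-um gap.

    A medial band enriched in D1-VS-RGS6 and a lateral band enriched in D1-VS
    abut a cell-free strip centered at x = 350 um, where a TAC3-like jump in
    the first D1-VS-RGS6 marker gene is injected.  The default density is
    high enough that the pooled pair occupancy pins the Otsu boundary to the
    bin edge nearest the gap center.
    """
    medial = Rect(50.0, 330.0, 0.0, 1000.0)
    lateral = Rect(370.0, 650.0, 0.0, 1000.0)
    territories = (
        Territory(
            region=medial,
            type_weights={"D1-Matrix": 1.0, "D2-Matrix": 1.0, "D1-VS-RGS6": 2.0},
            density=density,
        ),
        Territory(
            region=lateral,
            type_weights={"D1-Matrix": 1.0, "D2-Matrix": 1.0, "D1-VS": 2.0},
            density=density,
        ),
    )
    jump_gene = f"gene{3 * 3 + 1:04d}"
    disc = (DiscontinuitySpec(gene=jump_gene, axis="x", boundary=350.0, jump=3.0,
                              slope=0.0, noise_sd=0.2, intercept=2.0),)
    return SimulationConfig(
        seed=seed,
        n_types=len(DEMO_TYPES),
        n_genes=120,
        n_marker_genes=3,
        marker_fold=10.0,
        type_names=tuple(DEMO_TYPES),
        territory_spec=territories,
        discontinuity_spec=disc,
    )
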