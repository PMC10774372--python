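"""Spatial graphs, co-localization enrichment, and compartment mapping.

The co-localization statistic is a permutation enrichment on a fixed
spatial neighborhood graph: observed type-pair edge counts are compared with
counts under random reassignment of the type labels, the score being
log2((obs + 1) / (mean_perm + 1)) with a two-sided permutation p-value.
Compartments are mapped from data alone by kernel density of an anchor cell
type (the differentiated-neuronal cells that form the nodules), thresholded
by Otsu's method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError, cKDTree
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label as sk_label
from sklearn.neighbors import NearestNeighbors


@dataclass
class SpatialGraph:
    """Undirected cell-adjacency graph with positions."""

    positions: np.ndarray            # n x 2
    edges: np.ndarray                # m x 2 (i < j), no self-loops
    method: str
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def edge_lengths(self) -> np.ndarray:
        d = self.positions[self.edges[:, 0]] - self.positions[self.edges[:, 1]]
        return np.sqrt((d**2).sum(axis=1))


def _knn_edges(positions: np.ndarray, k: int) -> np.ndarray:
    k_eff = min(k, len(positions) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(positions)
    _, idx = nn.kneighbors(positions)
    src = np.repeat(np.arange(len(positions)), k_eff)
    dst = idx[:, 1:].ravel()
    return np.unique(np.sort(np.column_stack([src, dst]), axis=1), axis=0)


def build_spatial_graph(
    positions: np.ndarray,
    method: str = "delaunay",
    k: int = 6,
    max_edge_factor: float = 4.0,
) -> SpatialGraph:
    """Delaunay triangulation with long-edge pruning, or symmetrized kNN.

    Delaunay edges longer than ``max_edge_factor`` times the median
    nearest-neighbor distance are removed (convex-hull artifacts).
    Degenerate (e.g. collinear) inputs fall back to the kNN graph with a
    warning.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be an n x 2 array")

    if method == "knn":
        edges = _knn_edges(positions, k)
        return SpatialGraph(positions, edges, "knn", {"k": k})
    if method != "delaunay":
        raise ValueError(f"unknown method {method!r}")

    try:
        tri = Delaunay(positions)
    except QhullError:
        warnings.warn("degenerate point set; falling back to kNN graph", stacklevel=2)
        edges = _knn_edges(positions, k)
        return SpatialGraph(positions, edges, "knn", {"k": k, "fallback": True})

    pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = sorted((simplex[a], simplex[b]))
                pairs.add((i, j))
    edges = np.array(sorted(pairs), dtype=int)

    nn_dist = cKDTree(positions).query(positions, k=2)[0][:, 1]
    cutoff = max_edge_factor * np.median(nn_dist)
    lengths = np.sqrt(
        ((positions[edges[:, 0]] - positions[edges[:, 1]]) ** 2).sum(axis=1)
    )
    edges = edges[lengths <= cutoff]
    return SpatialGraph(
        positions, edges, "delaunay", {"max_edge_factor": max_edge_factor, "cutoff": cutoff}
    )


@dataclass
class EnrichmentMatrix:
    """Type-pair co-localization scores with permutation p-values."""

    score: pd.DataFrame
    pvalue: pd.DataFrame
    observed: pd.DataFrame
    expected: pd.DataFrame
    B: int
    seed: int


def _pair_counts(codes: np.ndarray, e0: np.ndarray, e1: np.ndarray, T: int) -> np.ndarray:
    """Symmetric unordered edge counts per type pair (diagonal counted once)."""
    a, b = codes[e0], codes[e1]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    flat = np.bincount(lo * T + hi, minlength=T * T)
    M = flat.reshape(T, T)
    return M + np.triu(M, 1).T


def colocalization_enrichment(
    graph: SpatialGraph, types: pd.Series | np.ndarray, B: int = 1000, seed: int = 0
) -> EnrichmentMatrix:
    """Permutation test of type adjacency on a fixed spatial graph.

    ``score = log2((obs + 1) / (mean_perm + 1))``; p-values are two-sided by
    doubling the smaller tail with the add-one correction, so p in (0, 1].
    """
    types = pd.Series(np.asarray(types))
    cats = sorted(types.unique())
    if len(cats) < 2:
        warnings.warn("single cell type: only the diagonal is defined", stacklevel=2)
    codes = types.map({c: i for i, c in enumerate(cats)}).to_numpy()
    T = len(cats)
    if len(codes) != graph.n_nodes:
        raise ValueError("types length must match the graph node count")

    e0, e1 = graph.edges[:, 0], graph.edges[:, 1]
    obs = _pair_counts(codes, e0, e1, T)

    rng = np.random.default_rng(seed)
    perm_counts = np.empty((B, T, T), dtype=np.int64)
    shuffled = codes.copy()
    for b in range(B):
        rng.shuffle(shuffled)
        perm_counts[b] = _pair_counts(shuffled, e0, e1, T)

    mean_perm = perm_counts.mean(axis=0)
    score = np.log2((obs + 1.0) / (mean_perm + 1.0))

    ge = (perm_counts >= obs).sum(axis=0)
    le = (perm_counts <= obs).sum(axis=0)
    p_two = np.minimum(1.0, 2.0 * np.minimum(ge + 1, le + 1) / (B + 1))

    present = np.isin(np.arange(T), codes)
    score[~np.outer(present, present)] = np.nan
    p_two[~np.outer(present, present)] = np.nan

    idx = pd.Index(cats, name="type")
    return EnrichmentMatrix(
        score=pd.DataFrame(score, index=idx, columns=idx),
        pvalue=pd.DataFrame(p_two, index=idx, columns=idx),
        observed=pd.DataFrame(obs, index=idx, columns=idx),
        expected=pd.DataFrame(mean_perm, index=idx, columns=idx),
        B=B,
        seed=seed,
    )


@dataclass
class CompartmentMap:
    """Data-driven nodule regions and per-cell compartment labels."""

    compartment: pd.Series           # per cell: nodular / internodular
    region_labels: np.ndarray        # labeled grid image of nodule regions
    grid_origin: tuple[float, float]
    grid_step: float
    polygons: list


def compartment_map(
    positions: np.ndarray,
    type_labels: pd.Series | np.ndarray,
    nodular_anchor_types: list[str],
    bandwidth: float = 75.0,
    grid_step: float = 2.0,
    field_extent: tuple[float, float, float, float] | None = None,
) -> CompartmentMap:
    """Map nodule regions from the density of anchor-type cells.

    A Gaussian kernel density (sigma = ``bandwidth``) of the anchor cells is
    evaluated on a ``grid_step``-spaced grid, thresholded by Otsu's method,
    and the connected super-threshold regions become nodules; cells inside a
    region are labeled nodular.  With no anchor cells present everything is
    internodular (with a warning).
    """
    positions = np.asarray(positions, dtype=float)
    type_labels = pd.Series(np.asarray(type_labels))
    anchor = type_labels.isin(nodular_anchor_types).to_numpy()

    if field_extent is None:
        pad = 2 * bandwidth
        x0, y0 = positions.min(axis=0) - pad
        x1, y1 = positions.max(axis=0) + pad
    else:
        x0, y0, x1, y1 = field_extent

    nx = int(np.ceil((x1 - x0) / grid_step)) + 1
    ny = int(np.ceil((y1 - y0) / grid_step)) + 1

    labels_img = np.zeros((ny, nx), dtype=int)
    polygons: list[Polygon] = []
    if not anchor.any():
        warnings.warn("no anchor-type cells; everything labeled internodular", stacklevel=2)
        comp = pd.Series("internodular", index=range(len(positions)), name="compartment")
        return CompartmentMap(comp, labels_img, (x0, y0), grid_step, polygons)

    gx = np.clip(((positions[anchor, 0] - x0) / grid_step).astype(int), 0, nx - 1)
    gy = np.clip(((positions[anchor, 1] - y0) / grid_step).astype(int), 0, ny - 1)
    density = np.zeros((ny, nx))
    np.add.at(density, (gy, gx), 1.0)
    density = ndimage.gaussian_filter(density, bandwidth / grid_step)

    thr = threshold_otsu(density) if density.max() > 0 else np.inf
    regions = density > thr
    labels_img = sk_label(regions)

    # drop specks smaller than a disc of radius bandwidth/2
    min_px = np.pi * (bandwidth / 2.0) ** 2 / grid_step**2
    sizes = np.bincount(labels_img.ravel())
    small = np.flatnonzero(sizes < min_px)
    if len(small):
        labels_img[np.isin(labels_img, small)] = 0

    for region_id in np.unique(labels_img):
        if region_id == 0:
            continue
        contours = find_contours((labels_img == region_id).astype(float), 0.5)
        for cont in contours:
            xy = np.column_stack([x0 + cont[:, 1] * grid_step, y0 + cont[:, 0] * grid_step])
            if len(xy) >= 4:
                poly = Polygon(xy)
                if poly.is_valid and poly.area > 0:
                    polygons.append(poly)

    cgx = np.clip(((positions[:, 0] - x0) / grid_step).astype(int), 0, nx - 1)
    cgy = np.clip(((positions[:, 1] - y0) / grid_step).astype(int), 0, ny - 1)
    nodular = labels_img[cgy, cgx] > 0
    comp = pd.Series(
        np.where(nodular, "nodular", "internodular"),
        index=type_labels.index,
        name="compartment",
    )
    return CompartmentMap(comp, labels_img, (x0, y0), grid_step, polygons)


def compartment_composition(
    type_labels: pd.Series | np.ndarray, compartments: pd.Series | np.ndarray
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-compartment type proportions and per-type nodular fractions.

    Composition rows sum to 1; a compartment with no cells yields an NA row.
    """
    type_labels = pd.Series(np.asarray(type_labels), name="type")
    compartments = pd.Series(np.asarray(compartments), name="compartment")
    tab = pd.crosstab(compartments, type_labels)
    for comp in ("internodular", "nodular"):
        if comp not in tab.index:
            tab.loc[comp] = np.nan
    tab = tab.sort_index()
    composition = tab.div(tab.sum(axis=1), axis=0)

    per_type = pd.crosstab(type_labels, compartments)
    if "nodular" not in per_type.columns:
        per_type["nodular"] = 0
    nodular_fraction = per_type["nodular"] / per_type.sum(axis=1)
    nodular_fraction.name = "nodular_fraction"
    return composition, nodular_fraction
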