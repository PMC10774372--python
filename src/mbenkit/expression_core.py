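"""Shared expression analysis: normalization, clustering, markers, scores.

Operates on AnnData matrices from either droplet-style snRNA counts or
spatially derived single cells.  Clustering is PCA -> kNN graph -> Louvain
modularity communities; cells are canonically reordered before graph
construction so the partition is invariant to input row order.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import anndata as ad
import igraph
import numpy as np
import pandas as pd
from scipy import linalg, sparse, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def normalize(counts: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    All-zero cells map to all-zero rows.
    """
    X = _dense(counts.X).astype(float)
    totals = X.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    norm = ad.AnnData(
        X=np.log1p(X * scale), obs=counts.obs.copy(), var=counts.var.copy()
    )
    norm.uns["scale_factor"] = target_sum
    return norm


@dataclass
class ClusterResult:
    """A partition of cells with per-cluster mean profiles."""

    labels: pd.Series                 # per-cell cluster label (str)
    means: pd.DataFrame               # clusters x genes mean normalized expression
    pcs: pd.DataFrame                 # cells x PCs embedding used for the graph
    params: dict = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.means.index)


def cluster_means(norm: ad.AnnData, labels: pd.Series) -> pd.DataFrame:
    X = _dense(norm.X)
    out = {}
    for lab in sorted(labels.unique()):
        out[lab] = X[(labels == lab).to_numpy()].mean(axis=0)
    return pd.DataFrame(out, index=norm.var_names).T


def embed_and_cluster(
    norm: ad.AnnData,
    n_pcs: int = 30,
    k: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterResult:
    """PCA embedding, kNN graph, Louvain modularity communities.

    Deterministic: cells are reordered by a lexicographic sort of their PC
    coordinates before graph construction, so permuting the input rows
    yields the identical partition (up to the fixed label names).
    """
    X = _dense(norm.X)
    n_cells, n_genes = X.shape
    if n_cells < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells, got {n_cells}")
    max_pcs = min(n_cells - 1, n_genes)
    if n_pcs > max_pcs:
        warnings.warn(f"reducing n_pcs from {n_pcs} to {max_pcs}", stacklevel=2)
        n_pcs = max_pcs

    # canonical row order BEFORE any arithmetic: permuted inputs then yield
    # bitwise-identical centering, PCA and graphs, hence the same partition
    order = np.lexsort(tuple(X[:, c] for c in range(n_genes - 1, -1, -1)))
    Xs = X[order]

    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    pcs_sorted = pca.fit_transform(Xs - Xs.mean(axis=0, keepdims=True))
    pcs = np.empty_like(pcs_sorted)
    pcs[order] = pcs_sorted

    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs_sorted)
    _, idx = nn.kneighbors(pcs_sorted)
    src = np.repeat(np.arange(len(idx)), k)
    dst = idx[:, 1:].ravel()
    pairs = np.unique(np.sort(np.column_stack([src, dst]), axis=1), axis=0)

    g = igraph.Graph(n=len(pcs_sorted), edges=[tuple(e) for e in pairs])
    # igraph delegates randomness to a Python Random instance; pin it so the
    # partition is a pure function of (data, seed)
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(resolution=resolution)
    labels_sorted = np.asarray(part.membership)

    labels = np.empty(n_cells, dtype=int)
    labels[order] = labels_sorted
    label_series = pd.Series(
        [f"c{l}" for l in labels], index=norm.obs_names, name="cluster"
    )
    return ClusterResult(
        labels=label_series,
        means=cluster_means(norm, label_series),
        pcs=pd.DataFrame(pcs, index=norm.obs_names, columns=[f"PC{i+1}" for i in range(n_pcs)]),
        params={"n_pcs": n_pcs, "k": k, "resolution": resolution, "seed": seed},
    )


def merge_similar_clusters(
    clusters: ClusterResult, norm: ad.AnnData, r_min: float = 0.95
) -> ClusterResult:
    """Merge clusters whose mean profiles correlate at r >= r_min.

    Merging acts on connected components of the similarity graph, so
    mutually similar groups collapse transitively.
    """
    ids = clusters.cluster_ids
    if len(ids) < 2:
        return clusters
    M = clusters.means.loc[ids].to_numpy()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(M)
    corr = np.nan_to_num(corr, nan=-1.0)
    adj = sparse.csr_matrix((corr >= r_min).astype(int))
    n_comp, comp = sparse.csgraph.connected_components(adj, directed=False)
    mapping = {ids[i]: f"m{comp[i]}" for i in range(len(ids))}
    labels = clusters.labels.map(mapping).rename("cluster")
    return ClusterResult(
        labels=labels,
        means=cluster_means(norm, labels),
        pcs=clusters.pcs,
        params={**clusters.params, "r_min": r_min, "merged_from": len(ids)},
    )


def find_markers(norm: ad.AnnData, labels: pd.Series, min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker test per cluster.

    log2FC is computed on cluster means of the normalized values with a
    pseudocount of 1; p-values are Benjamini-Hochberg adjusted within each
    cluster.  Zero-variance genes are reported with p = 1.  Clusters smaller
    than ``min_cells`` are skipped with a warning.
    """
    X = _dense(norm.X)
    genes = norm.var_names.to_numpy()
    tables = []
    for lab in sorted(labels.unique()):
        in_mask = (labels == lab).to_numpy()
        n1, n2 = int(in_mask.sum()), int((~in_mask).sum())
        if n1 < min_cells or n2 == 0:
            warnings.warn(f"cluster {lab} has fewer than {min_cells} cells; skipped", stacklevel=2)
            continue
        Xi, Xo = X[in_mask], X[~in_mask]
        mean_in, mean_out = Xi.mean(axis=0), Xo.mean(axis=0)
        lfc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        pvals = np.ones(len(genes))
        for j in range(len(genes)):
            col = X[:, j]
            if col.max() == col.min():
                continue
            pvals[j] = stats.ranksums(Xi[:, j], Xo[:, j]).pvalue
        qvals = multipletests(pvals, method="fdr_bh")[1]
        tab = pd.DataFrame(
            {"cluster": lab, "gene": genes, "log2fc": lfc, "pvalue": pvals, "qvalue": qvals}
        )
        tables.append(tab.sort_values("pvalue", kind="stable"))
    if not tables:
        return pd.DataFrame(columns=["cluster", "gene", "log2fc", "pvalue", "qvalue"])
    return pd.concat(tables, ignore_index=True)


def module_score(
    norm: ad.AnnData,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Bin-matched control signature score (Tirosh scheme).

    Mean expression of the set genes minus the mean of ``n_ctrl`` control
    genes drawn per set gene from the same average-expression bin.
    """
    rng = np.random.default_rng(seed)
    X = _dense(norm.X)
    genes = norm.var_names
    set_genes = sorted(set(gene_set) & set(genes))
    if not set_genes:
        raise ValueError("gene set shares no genes with the matrix")

    gene_means = X.mean(axis=0)
    order = np.argsort(gene_means, kind="stable")
    n_bins = min(n_bins, len(genes))
    bins = np.empty(len(genes), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b

    gene_pos = {g: i for i, g in enumerate(genes)}
    set_idx = np.array([gene_pos[g] for g in set_genes])
    ctrl_idx = []
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        take = min(n_ctrl, len(pool))
        ctrl_idx.append(rng.choice(pool, size=take, replace=False))
    ctrl_idx = np.concatenate(ctrl_idx)

    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=norm.obs_names, name="module_score")


def cell_cycle_phase(
    norm: ad.AnnData, s_set: list[str], g2m_set: list[str], seed: int = 0
) -> pd.DataFrame:
    """S / G2M / G1 phase call from the two cycle signature scores."""
    s_score = module_score(norm, s_set, seed=seed)
    g2m_score = module_score(norm, g2m_set, seed=seed + 1)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1",
        np.where(s_score.to_numpy() >= g2m_score.to_numpy(), "S", "G2M"),
    )
    return pd.DataFrame(
        {"s_score": s_score, "g2m_score": g2m_score, "phase": phase}, index=norm.obs_names
    )


def annotate_by_reference(
    norm: ad.AnnData, reference_centroids: pd.DataFrame, min_rho: float = 0.2
) -> pd.DataFrame:
    """Label each cell by its best Spearman match to reference centroids.

    ``reference_centroids``: rows = reference types, columns = genes.  Cells
    whose best correlation is below ``min_rho`` are labeled "unassigned".
    """
    shared = [g for g in norm.var_names if g in reference_centroids.columns]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes with the reference")
    X = _dense(norm[:, shared].X)
    R = reference_centroids[shared].to_numpy()

    xr = stats.rankdata(X, axis=1)
    rr = stats.rankdata(R, axis=1)

    def _standardize(M):
        M = M - M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, M / sd, 0.0)

    corr = _standardize(xr) @ _standardize(rr).T / len(shared)
    best = corr.argmax(axis=1)
    best_rho = corr[np.arange(len(X)), best]
    labels = reference_centroids.index.to_numpy()[best].astype(object)
    labels[best_rho < min_rho] = "unassigned"
    return pd.DataFrame(
        {"label": labels, "rho": best_rho}, index=norm.obs_names
    )


def batch_adjust(norm: ad.AnnData, batch_labels: pd.Series) -> ad.AnnData:
    """Per-batch, per-gene centering; batch gene means are ~0 afterwards."""
    X = _dense(norm.X).copy()
    batch_labels = pd.Series(np.asarray(batch_labels), index=norm.obs_names)
    for b in batch_labels.unique():
        mask = (batch_labels == b).to_numpy()
        X[mask] -= X[mask].mean(axis=0, keepdims=True)
    out = ad.AnnData(X=X, obs=norm.obs.copy(), var=norm.var.copy())
    out.uns = dict(norm.uns)
    return out


def tf_activity(norm: ad.AnnData, regulons: pd.DataFrame) -> pd.DataFrame:
    """Per-cell TF activity from a multivariate linear model.

    Each cell's log-expression vector over the regulon gene universe is
    regressed on the TF weight matrix (one column per TF plus an intercept);
    the t-values of the TF slopes are the activity scores.  Residual degrees
    of freedom are genes - TFs - 1.
    """
    required = {"tf", "target", "weight"}
    if not required.issubset(regulons.columns):
        raise ValueError("regulon table needs columns tf, target, weight")
    if not np.all(np.isfinite(regulons["weight"])):
        raise ValueError("regulon weights must be finite")

    counts = regulons.groupby("tf")["target"].nunique()
    tfs = sorted(counts[counts >= 3].index)
    if len(tfs) < 2:
        raise ValueError("need at least 2 TFs with at least 3 targets each")

    genes = [g for g in norm.var_names if g in set(regulons["target"])]
    W = pd.DataFrame(0.0, index=genes, columns=tfs)
    for row in regulons.itertuples():
        if row.tf in W.columns and row.target in W.index:
            W.loc[row.target, row.tf] = row.weight

    zero_cols = W.columns[(W == 0).all(axis=0)]
    if len(zero_cols):
        raise ValueError(f"rank-deficient design: all-zero weight column(s) {list(zero_cols)}")

    D = np.column_stack([np.ones(len(genes)), W.to_numpy()])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # drop collinear TF columns via pivoted QR, keep the independent set
        _, _, piv = linalg.qr(D, pivoting=True)
        keep = sorted(piv[:rank])
        if 0 not in keep:
            keep = [0] + keep[: rank - 1]
        dropped = [tfs[j - 1] for j in range(1, D.shape[1]) if j not in keep]
        warnings.warn(f"dropping collinear TF(s): {dropped}", stacklevel=2)
        tfs = [tfs[j - 1] for j in keep if j > 0]
        D = D[:, keep]

    Y = _dense(norm[:, genes].X).T  # genes x cells
    G, p = D.shape
    df = G - p
    if df <= 0:
        raise ValueError("more TFs than genes; cannot fit")
    DtD_inv = np.linalg.inv(D.T @ D)
    beta = DtD_inv @ D.T @ Y                      # p x cells
    resid = Y - D @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(DtD_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    return pd.DataFrame(tvals[1:].T, index=norm.obs_names, columns=tfs)


def gene_set_overlap_test(
    query_set: list[str], reference_sets: dict[str, list[str]], universe_size: int
) -> pd.DataFrame:
    """Chi-squared (or exact) 2x2 overlap tests of a query set vs references.

    The contingency table is in/out of the query crossed with in/out of each
    reference over a universe of ``universe_size`` genes; Fisher's exact test
    replaces the chi-squared when any expected cell count is below 5.
    """
    q = set(query_set)
    rows = []
    for name, ref in reference_sets.items():
        r = set(ref)
        a = len(q & r)
        b = len(q - r)
        c = len(r - q)
        d = universe_size - a - b - c
        if d < 0:
            raise ValueError("universe smaller than the union of the sets")
        table = np.array([[a, b], [c, d]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        if (expected < 5).any():
            stat, p = np.nan, stats.fisher_exact(table, alternative="two-sided")[1]
            method = "fisher"
        else:
            res = stats.chi2_contingency(table, correction=True)
            stat, p, method = res[0], res[1], "chi2"
        rows.append(
            {"reference": name, "overlap": a, "statistic": stat, "pvalue": p,
             "odds_ratio": odds, "method": method}
        )
    return pd.DataFrame(rows)
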