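"""Malignant vs non-malignant calling.

Two complementary signals: the patient-mixing rule (a cluster composed at
>= 95% of one patient's cells is called malignant, since tumor cells are
patient-private while normal cell types mix across patients) and a
copy-number proxy computed from expression — reference-centered log ratios
clipped and smoothed along genomic gene order, summarized per cell as a
burden score.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .expression_core import _dense


def call_malignant_clusters(cluster_patient_table: pd.DataFrame, purity: float = 0.95) -> pd.Series:
    """Label clusters malignant iff the max patient fraction >= purity.

    ``cluster_patient_table``: rows = clusters, columns = patients, entries =
    cell counts.  The purity boundary is inclusive.
    """
    table = cluster_patient_table.astype(float)
    totals = table.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every cluster needs at least one cell")
    frac = table.div(totals, axis=0).max(axis=1)
    return pd.Series(
        np.where(frac >= purity, "malignant", "normal"),
        index=table.index,
        name="malignancy",
    )


def cluster_patient_table(clusters: pd.Series, patients: pd.Series) -> pd.DataFrame:
    """Cluster x patient cell-count contingency table."""
    return pd.crosstab(clusters, patients)


def _natural_chrom_key(chrom: str):
    m = re.match(r"^chr(\d+|[XYM])$", str(chrom))
    if m and m.group(1).isdigit():
        return (0, int(m.group(1)))
    return (1, str(chrom))


@dataclass
class CNVProfile:
    """Smoothed, centered expression log-ratios along genomic order."""

    values: pd.DataFrame        # cells x genes (genomic order)
    chrom: pd.Series            # per-gene chromosome, genomic order
    window: int
    clip: float

    def block_score(self, genes: list[str]) -> pd.Series:
        """Mean smoothed ratio over a gene block, per cell."""
        present = [g for g in genes if g in self.values.columns]
        return self.values[present].mean(axis=1)


def infer_cnv_profiles(
    norm: ad.AnnData,
    gene_annotation: pd.DataFrame,
    reference_cell_ids: list[str],
    window: int = 101,
    clip: float = 1.0,
) -> CNVProfile:
    """Expression-based copy-number proxy against a normal reference.

    Per gene, the mean log-expression of the reference cells is subtracted;
    values are clipped to ``+/- clip`` and averaged over a ``window``-gene
    running window within each chromosome (the window shrinks at chromosome
    edges and for short chromosomes).  The smoothed values are re-centered
    on the reference (clipping skews the first centering on sparse counts),
    and finally each cell's median is subtracted.
    """
    if len(reference_cell_ids) < 20:
        raise ValueError("need at least 20 reference cells")
    ann = gene_annotation.set_index("gene") if "gene" in gene_annotation.columns else gene_annotation
    mappable = [g for g in norm.var_names if g in ann.index]
    if not mappable:
        raise ValueError("no genes mappable to the annotation")

    sub = ann.loc[mappable]
    pos_col = "pos" if "pos" in sub.columns else "start"
    order = sorted(
        range(len(mappable)),
        key=lambda i: (_natural_chrom_key(sub["chrom"].iloc[i]), sub[pos_col].iloc[i]),
    )
    genes = [mappable[i] for i in order]
    chroms = sub["chrom"].iloc[order].to_numpy()

    X = _dense(norm[:, genes].X)
    ref_idx = norm.obs_names.isin(reference_cell_ids)
    if ref_idx.sum() < 20:
        raise ValueError("fewer than 20 reference cells found in the matrix")
    centered = X - X[ref_idx].mean(axis=0, keepdims=True)
    centered = np.clip(centered, -clip, clip)

    smoothed = np.empty_like(centered)
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        w = window
        if len(cols) < window:
            w = len(cols)
            warnings.warn(
                f"chromosome {chrom} has {len(cols)} genes < window {window}; shrinking",
                stacklevel=2,
            )
        half = w // 2
        block = centered[:, cols]
        csum = np.cumsum(block, axis=1)
        csum = np.concatenate([np.zeros((block.shape[0], 1)), csum], axis=1)
        n = len(cols)
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        smoothed[:, cols] = (csum[:, hi] - csum[:, lo]) / (hi - lo)

    smoothed -= smoothed[ref_idx].mean(axis=0, keepdims=True)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    return CNVProfile(
        values=pd.DataFrame(smoothed, index=norm.obs_names, columns=genes),
        chrom=pd.Series(chroms, index=genes, name="chrom"),
        window=window,
        clip=clip,
    )


def cnv_burden(
    profile: CNVProfile, clusters: pd.Series | None = None
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Mean squared smoothed ratio per cell; optional per-cluster summary."""
    burden = pd.Series(
        (profile.values.to_numpy() ** 2).mean(axis=1),
        index=profile.values.index,
        name="cnv_burden",
    )
    summary = None
    if clusters is not None:
        means = burden.groupby(clusters).mean()
        summary = pd.DataFrame({"mean_burden": means})
        summary["rank"] = summary["mean_burden"].rank(ascending=False).astype(int)
        summary = summary.sort_values("rank")
    return burden, summary


def attach_variant_flags(adata: ad.AnnData, flags: pd.DataFrame) -> ad.AnnData:
    """Join an optional user-supplied per-cell variant flag table into obs."""
    out = adata.copy()
    out.obs = out.obs.join(flags, how="left")
    return out
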