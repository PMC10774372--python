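"""Readers and writers for the pipeline's on-disk formats.

Matrices travel as MatrixMarket + TSV sidecars (cells.tsv / genes.tsv),
spot tables as CSV, label masks as uint16 TIFF, gene sets as GMT, and gene
genomic annotation as BED-like TSV.  write -> read is the identity on valid
files.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse


def write_counts(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts as counts.mtx + cells.tsv + genes.tsv (cells as rows)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(np.asarray(adata.X))
    spio.mmwrite(outdir / "counts.mtx", X)
    adata.obs.rename_axis("cell_id").to_csv(outdir / "cells.tsv", sep="\t")
    adata.var.rename_axis("gene").to_csv(outdir / "genes.tsv", sep="\t")


def read_counts(outdir: str | Path) -> ad.AnnData:
    outdir = Path(outdir)
    X = spio.mmread(outdir / "counts.mtx").tocsr()
    obs = pd.read_csv(outdir / "cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(outdir / "genes.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    if X.shape != (len(obs), len(var)):
        raise ValueError("matrix shape does not match cells/genes sidecars")
    return ad.AnnData(X=X, obs=obs, var=var)


def write_spots(spots: pd.DataFrame, path: str | Path) -> None:
    spots.to_csv(path, index=False)


def read_spots(path: str | Path) -> pd.DataFrame:
    spots = pd.read_csv(path)
    missing = {"x", "y", "gene"} - set(spots.columns)
    if missing:
        raise ValueError(f"spot table {path} is missing columns: {sorted(missing)}")
    return spots


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gene_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("gene", "chrom", "pos", "start") if c in annotation.columns]
    annotation[cols].to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    missing = {"gene", "chrom"} - set(ann.columns)
    if missing:
        raise ValueError(f"gene annotation {path} is missing columns: {sorted(missing)}")
    if "pos" not in ann.columns and "start" not in ann.columns:
        raise ValueError(f"gene annotation {path} needs a 'pos' or 'start' column")
    return ann


def write_bulk(bulk: pd.DataFrame, meta: pd.DataFrame, prefix: str | Path) -> None:
    prefix = Path(prefix)
    bulk.rename_axis("gene").to_csv(prefix.with_suffix(".tsv"), sep="\t")
    meta.rename_axis("sample").to_csv(prefix.parent / (prefix.name + "_meta.tsv"), sep="\t")


def read_bulk(prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    prefix = Path(prefix)
    bulk = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col=0)
    meta = pd.read_csv(prefix.parent / (prefix.name + "_meta.tsv"), sep="\t", index_col=0)
    return bulk, meta
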