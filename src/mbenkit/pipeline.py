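"""Pipeline orchestration: configuration, stage execution, reporting.

``run_pipeline`` chains simulate -> cells -> cluster -> malignancy ->
trajectory -> spatial -> deconvolve as configured, writing versioned
outputs plus a JSON report of per-stage counts, parameters and the derived
sub-seeds.  All randomness flows from the global seed through
:func:`mbenkit._seeds.stage_seed`, so a config + seed pair reproduces every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from ._seeds import stage_seed
from .compartments import composition_statistics, deconvolve_bulk
from .expression_core import (
    ClusterResult,
    batch_adjust,
    cluster_means,
    embed_and_cluster,
    merge_similar_clusters,
    module_score,
    normalize,
)
from .malignancy import call_malignant_clusters, cluster_patient_table, cnv_burden, infer_cnv_profiles
from .spatial_cells import assign_spots_to_cells, qc_filter_cells
from .spatial_stats import build_spatial_graph, colocalization_enrichment, compartment_map
from .synthetic import (
    BulkConfig,
    ExpressionConfig,
    TissueConfig,
    cnv_panel,
    default_cnv_blocks,
    default_panel,
    generate_bulk_compartments,
    generate_cohort,
    generate_expression,
    generate_spots_and_masks,
    normalize_signatures,
    paired_design,
)

ALL_STAGES = ("simulate", "cells", "cluster", "malignancy", "trajectory", "spatial", "deconvolve")


@dataclass
class RunConfig:
    """Full pipeline configuration; unknown YAML keys are rejected."""

    seed: int = 0
    outdir: str = "run"
    patients: list = field(default_factory=lambda: ["P1", "P2", "P3"])
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    input_dir: str | None = None
    tissue: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    imaging: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    cnv: dict = field(default_factory=dict)
    spatial: dict = field(default_factory=dict)
    bulk: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg


def _tissue_config(cfg: RunConfig, seed: int) -> TissueConfig:
    known = {f.name for f in dataclasses.fields(TissueConfig)}
    unknown = set(cfg.tissue) - known
    if unknown:
        raise ValueError(f"unknown tissue config keys: {sorted(unknown)}")
    return TissueConfig(**{**cfg.tissue, "seed": seed})


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    stages = list(config.stages)

    state: dict = {}

    if "simulate" in stages:
        report["stages"]["simulate"] = _stage_simulate(config, out, state)
    if "cells" in stages:
        report["stages"]["cells"] = _stage_cells(config, out, state)
    if "cluster" in stages:
        report["stages"]["cluster"] = _stage_cluster(config, out, state)
    if "malignancy" in stages:
        report["stages"]["malignancy"] = _stage_malignancy(config, out, state)
    if "trajectory" in stages:
        report["stages"]["trajectory"] = _stage_trajectory(config, out, state)
    if "spatial" in stages:
        report["stages"]["spatial"] = _stage_spatial(config, out, state)
    if "deconvolve" in stages:
        report["stages"]["deconvolve"] = _stage_deconvolve(config, out, state)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> dict:
    seed = stage_seed(config.seed, "simulate")
    tcfg = _tissue_config(config, seed)
    tissues = generate_cohort(tcfg, patients=tuple(config.patients))
    panel = default_panel()

    ecfg_kwargs = dict(config.expression)
    ecfg = ExpressionConfig(**{**ecfg_kwargs, "seed": seed + 1})
    counts, truth = generate_expression(tissues, panel, ecfg)

    # dense genome-wide panel with a planted gain in the first patient
    gpanel = cnv_panel()
    gcfg = ExpressionConfig(
        **{**ecfg_kwargs, "seed": seed + 2, "cnv_blocks": default_cnv_blocks(config.patients[0])}
    )
    gcounts, gtruth = generate_expression(tissues, gpanel, gcfg)

    img_kwargs = dict(config.imaging)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    spots_by_patient = {}
    masks_by_patient = {}
    offset = 0
    for tissue in tissues:
        sub = counts[offset : offset + tissue.n_cells].copy()
        offset += tissue.n_cells
        spots, mask = generate_spots_and_masks(
            tissue, sub, seed=stage_seed(seed, f"imaging_{tissue.patient}"), **img_kwargs
        )
        mio.write_spots(spots, out / f"spots_{tissue.patient}.csv")
        mio.write_mask(mask, out / f"mask_{tissue.patient}.tif")
        tissue.cells.to_csv(truth_dir / f"tissue_{tissue.patient}.tsv", sep="\t", index=False)
        tissue.nodules.to_csv(truth_dir / f"nodules_{tissue.patient}.tsv", sep="\t", index=False)
        spots_by_patient[tissue.patient] = spots
        masks_by_patient[tissue.patient] = mask

    mio.write_counts(counts, out / "counts_spatial")
    mio.write_counts(gcounts, out / "counts_genomewide")
    mio.write_gene_annotation(gpanel, out / "gene_annotation.tsv")
    truth.latent_time.to_csv(truth_dir / "latent_time.tsv", sep="\t")

    # bulk compartment mixtures from the true state signatures
    bulk_cfg = BulkConfig(**{**config.bulk, "seed": seed + 3})
    design = paired_design(patients=tuple(config.patients))
    signatures = normalize_signatures(truth.state_means.T)
    bulk, props = generate_bulk_compartments(signatures, design, bulk_cfg)
    meta = design.copy()
    meta.index = bulk.columns
    mio.write_bulk(bulk, meta, out / "bulk")
    props.to_csv(truth_dir / "bulk_proportions.tsv", sep="\t")

    state.update(
        tissues=tissues, panel=panel, counts=counts, truth=truth,
        gcounts=gcounts, gtruth=gtruth, gpanel=gpanel,
        spots=spots_by_patient, masks=masks_by_patient,
        bulk=bulk, bulk_meta=meta, bulk_props=props, signatures=signatures,
    )
    return {
        "seed": seed,
        "n_cells": int(counts.n_obs),
        "n_genes_spatial": int(counts.n_vars),
        "n_genes_genomewide": int(gcounts.n_vars),
        "n_bulk_samples": int(bulk.shape[1]),
    }


def _stage_cells(config: RunConfig, out: Path, state: dict) -> dict:
    seed = stage_seed(config.seed, "cells")
    import anndata as ad

    if "spots" not in state:
        indir = Path(config.input_dir or config.outdir)
        state["spots"], state["masks"] = {}, {}
        for patient in config.patients:
            spath = indir / f"spots_{patient}.csv"
            mpath = indir / f"mask_{patient}.tif"
            for p in (spath, mpath):
                if not p.exists():
                    raise FileNotFoundError(f"cells stage input missing: {p}")
            state["spots"][patient] = mio.read_spots(spath)
            state["masks"][patient] = mio.read_mask(mpath)

    panel = state.get("panel")
    panel_genes = list(panel["gene"]) if panel is not None else None
    per_patient = []
    unassigned_total = 0
    reports = {}
    for patient in config.patients:
        adata, unassigned = assign_spots_to_cells(
            state["spots"][patient], state["masks"][patient], panel=panel_genes, patient=patient
        )
        adata.obs_names = [f"{patient}_{n}" for n in adata.obs_names]
        filtered, rep = qc_filter_cells(adata, **config.qc)
        per_patient.append(filtered)
        unassigned_total += unassigned
        reports[patient] = rep
    cells = ad.concat(per_patient, join="outer", merge="first")
    cells.obs_names_make_unique()
    state["cells"] = cells
    mio.write_counts(cells, out / "counts_cells")
    return {
        "seed": seed,
        "unassigned_spots": int(unassigned_total),
        "qc": reports,
        "n_cells": int(cells.n_obs),
    }


def _stage_cluster(config: RunConfig, out: Path, state: dict) -> dict:
    seed = stage_seed(config.seed, "cluster")
    if "cells" not in state:
        state["cells"] = mio.read_counts(Path(config.input_dir or config.outdir) / "counts_cells")
    cells = state["cells"]
    params = dict(config.cluster)
    r_min = params.pop("r_min", 0.95)

    norm = normalize(cells)
    adjusted = batch_adjust(norm, cells.obs["patient"]) if "patient" in cells.obs else norm
    clusters = embed_and_cluster(adjusted, seed=seed, **params)
    clusters = merge_similar_clusters(clusters, adjusted, r_min=r_min)
    clusters = ClusterResult(
        labels=clusters.labels,
        means=cluster_means(norm, clusters.labels),
        pcs=clusters.pcs,
        params=clusters.params,
    )
    state["norm"] = norm
    state["clusters"] = clusters
    clusters.labels.to_frame().to_csv(out / "clusters.tsv", sep="\t")
    clusters.means.to_csv(out / "cluster_means.tsv", sep="\t")
    return {
        "seed": seed,
        "n_clusters": len(clusters.cluster_ids),
        "params": {k: v for k, v in clusters.params.items()},
    }


def _stage_malignancy(config: RunConfig, out: Path, state: dict) -> dict:
    """Patient-mixing rule on genome-wide clusters, then CNV profiling.

    The 95% single-patient rule is defined on whole-transcriptome clusters
    before any batch merging, so this stage clusters the genome-wide matrix
    unadjusted; cells of normal (patient-mixed) clusters become the CNV
    reference.
    """
    seed = stage_seed(config.seed, "malignancy")
    if "gcounts" not in state:
        state["gcounts"] = mio.read_counts(
            Path(config.input_dir or config.outdir) / "counts_genomewide"
        )
        state["gpanel"] = mio.read_gene_annotation(
            Path(config.input_dir or config.outdir) / "gene_annotation.tsv"
        )
    gcounts = state["gcounts"]
    gnorm = normalize(gcounts)
    gclusters = merge_similar_clusters(embed_and_cluster(gnorm, seed=seed), gnorm)
    table = cluster_patient_table(gclusters.labels, gcounts.obs["patient"])
    calls = call_malignant_clusters(table)
    cell_malignant = gclusters.labels.map(calls) == "malignant"
    calls.to_frame().to_csv(out / "malignancy_calls.tsv", sep="\t")

    result = {"seed": seed, "n_clusters_genomewide": len(gclusters.cluster_ids),
              "n_malignant_clusters": int((calls == "malignant").sum())}
    ref_ids = cell_malignant.index[~cell_malignant].tolist()
    cnv_kwargs = dict(config.cnv)
    if len(ref_ids) >= 20:
        profile = infer_cnv_profiles(gnorm, state["gpanel"], ref_ids, **cnv_kwargs)
        burden, _ = cnv_burden(profile)
        burden.to_csv(out / "cnv_burden.tsv", sep="\t")
        state["cnv_profile"] = profile
        result["n_reference_cells"] = int(len(ref_ids))
    else:
        warnings.warn("too few normal reference cells for CNV profiling", stacklevel=2)
    state["malignancy_calls"] = calls
    state["cell_malignant_sim"] = cell_malignant  # indexed by simulated cell id
    return result


def _map_cells_to_simulated(cell_ids, state) -> list[str]:
    """Spatial cell ids 'P1_cell_<label>' -> simulated ids 'P1_c<label-1>'."""
    out = []
    for cid in cell_ids:
        patient, _, label = cid.rpartition("_cell_")
        if label.isdigit():
            out.append(f"{patient}_c{int(label) - 1:05d}")
    return out


def _stage_trajectory(config: RunConfig, out: Path, state: dict) -> dict:
    from .trajectory import lineage_graph, pseudotime, select_root

    seed = stage_seed(config.seed, "trajectory")
    clusters = state["clusters"]
    norm = state["norm"]

    panel = state["panel"]
    prolif_genes = panel.loc[
        panel["marker_state"] == "proliferating_early_cgnp", "gene"
    ].tolist()
    score = module_score(norm, prolif_genes, seed=seed)
    cluster_score = score.groupby(clusters.labels).mean()

    cell_mal = state.get("cell_malignant_sim")
    if cell_mal is not None:
        sim_ids = _map_cells_to_simulated(clusters.labels.index, state)
        flags = pd.Series(
            cell_mal.reindex(sim_ids).fillna(False).to_numpy(), index=clusters.labels.index
        )
        mal_frac = flags.groupby(clusters.labels).mean()
        malignant = mal_frac[mal_frac >= 0.5].index
        keep = clusters.labels.isin(malignant)
        cluster_score = cluster_score[cluster_score.index.isin(malignant)]
    else:
        keep = pd.Series(True, index=clusters.labels.index)

    centroids = clusters.pcs[keep.to_numpy()].groupby(clusters.labels[keep]).mean()
    centroids = centroids.loc[[c for c in centroids.index if c in cluster_score.index]]
    if len(centroids) < 2:
        warnings.warn("fewer than 2 malignant clusters; skipping trajectory", stacklevel=2)
        return {"seed": seed, "skipped": True}
    root = select_root(cluster_score.loc[centroids.index])
    lineages = lineage_graph(centroids, root)
    pt = pseudotime(clusters.pcs[keep.to_numpy()], lineages)
    pt.to_csv(out / "pseudotime.tsv", sep="\t")
    with open(out / "lineages.json", "w") as fh:
        json.dump({"root": lineages.root, "lineages": lineages.lineages}, fh, indent=2)
    state["lineages"] = lineages
    state["pseudotime"] = pt
    return {"seed": seed, "root": root, "lineages": lineages.lineages}


def _stage_spatial(config: RunConfig, out: Path, state: dict) -> dict:
    seed = stage_seed(config.seed, "spatial")
    cells = state["cells"]
    clusters = state["clusters"]
    params = dict(config.spatial)
    B = params.pop("B", 1000)
    bandwidth = params.pop("bandwidth", 75.0)

    panel = state["panel"]
    diff_genes = panel.loc[panel["marker_state"] == "differentiated_neuronal", "gene"].tolist()
    diff_score = module_score(state["norm"], diff_genes, seed=seed)
    anchor_cluster = diff_score.groupby(clusters.labels).mean().idxmax()

    results = {}
    comp_frames = []
    for patient in config.patients:
        mask = (cells.obs["patient"] == patient).to_numpy()
        if mask.sum() < 10:
            continue
        pos = cells.obs.loc[mask, ["x", "y"]].to_numpy(dtype=float)
        types = clusters.labels[mask]
        graph = build_spatial_graph(pos, **params)
        enrich = colocalization_enrichment(graph, types, B=B, seed=seed)
        enrich.score.to_csv(out / f"enrichment_{patient}.tsv", sep="\t")
        enrich.pvalue.to_csv(out / f"enrichment_p_{patient}.tsv", sep="\t")
        cmap = compartment_map(pos, types, [anchor_cluster], bandwidth=bandwidth)
        comp = cmap.compartment.copy()
        comp.index = cells.obs_names[mask]
        comp_frames.append(comp)
        with open(out / f"nodules_{patient}.wkt", "w") as fh:
            for poly in cmap.polygons:
                fh.write(poly.wkt + "\n")
        results[patient] = {
            "n_edges": int(len(graph.edges)),
            "n_nodular": int((cmap.compartment == "nodular").sum()),
        }
    if comp_frames:
        compartments = pd.concat(comp_frames)
        compartments.to_frame().to_csv(out / "compartments.tsv", sep="\t")
        state["compartments"] = compartments
    return {"seed": seed, "anchor_cluster": str(anchor_cluster), "per_patient": results}


def _stage_deconvolve(config: RunConfig, out: Path, state: dict) -> dict:
    seed = stage_seed(config.seed, "deconvolve")
    if "bulk" not in state:
        state["bulk"], state["bulk_meta"] = mio.read_bulk(
            Path(config.input_dir or config.outdir) / "bulk"
        )
    bulk, meta = state["bulk"], state["bulk_meta"]

    # signatures: per-cluster mean linear expression of the spatial cells
    clusters = state["clusters"]
    norm = state["norm"]
    linear_means = np.expm1(cluster_means(norm, clusters.labels))
    signatures = linear_means.T  # genes x clusters
    result = deconvolve_bulk(bulk, signatures)
    result.proportions.to_csv(out / "deconvolution.tsv", sep="\t")
    stats_table = composition_statistics(result.proportions, meta["compartment"])
    stats_table.to_csv(out / "deconvolution_stats.tsv", sep="\t", index=False)
    state["deconvolution"] = result
    return {
        "seed": seed,
        "n_samples": int(result.proportions.shape[0]),
        "n_states": int(result.proportions.shape[1]),
    }
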