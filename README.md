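# mbenkit

Analysis toolkit for **bicompartmental tumors** — tumors such as
medulloblastoma with extensive nodularity (MBEN) whose histology splits
into *nodular* regions of post-mitotic, neuronally differentiated tumor
cells and an *internodular* compartment of proliferating precursor-like
cells, stroma and immune cells, with astrocytic-like tumor cells at the
nodule rims. The package re-implements, as a tested pipeline on fully
ground-truthed synthetic data, the computational stages such a study needs:

- **Spatial single-cell construction** — difference-of-Gaussians spot
  detection (`σ`, `1.6σ` band-pass, local maxima above a per-acquisition
  threshold), watershed nucleus segmentation, spot-to-nucleus assignment,
  and the transcript-count / nucleus-size QC filters (cells with < 5 or
  > 100 transcripts or nuclei < 90 or > 2000 px are removed).
- **Expression core** — total-count normalization, PCA → kNN → Louvain
  clustering (deterministic and invariant to cell order), merging of
  clusters with correlated mean profiles (r ≥ 0.95), one-vs-rest Wilcoxon
  markers with BH correction, bin-matched control module scores (Tirosh
  scheme), S/G2M phase calls, Spearman reference annotation, per-batch
  centering, per-cell multivariate-linear-model TF activity (t-values of
  the slopes), and chi-squared / Fisher gene-set overlap tests.
- **Malignancy** — the patient-mixing rule (a cluster ≥ 95% from one
  patient is malignant, mixed clusters are normal) and expression-based
  CNV inference: reference-centered log-expression, clipped to ±1,
  smoothed over a 101-gene genomic window per chromosome, median-centered
  per cell, summarized as a per-cell burden score.
- **Trajectory** — minimum-spanning-tree lineages over cluster centroids
  in PC space rooted at the most proliferative cluster; pseudotime is the
  arc length of each cell's orthogonal projection onto its nearest
  piecewise-linear root-to-leaf path.
- **Compartments** — nodular vs internodular differential expression with
  patient fixed effects and empirical-Bayes variance moderation at the
  |log2FC| ≥ 0.5, adjusted p ≤ 0.05 limits; single-sample rank-weighted
  KS signature enrichment (ssGSEA-style, τ = 0.25); non-negative least
  squares deconvolution of bulk profiles into state proportions; t-test /
  Spearman composition statistics.
- **Spatial statistics** — Delaunay (long-edge-pruned) or kNN cell graphs;
  permutation co-localization enrichment
  `score = log2((obs + 1) / (mean_perm + 1))` with two-sided permutation
  p-values; data-driven compartment mapping by kernel density of an
  anchor cell type with Otsu thresholding; composition summaries.
- **Synthetic data** — the generator that makes all of this testable:
  circular nodules in a 2-D field, six cell states placed by
  compartment-weighted rejection sampling with a hard-core minimum
  spacing, negative-binomial counts with state markers, smooth lineage
  time programs, per-patient batch and tumor programs, planted CNV
  blocks, rendered spot tables / nucleus masks / images, and bulk
  compartment mixtures — each with complete ground truth.

## Worked example

```bash
python examples/05_trajectory.py
```

prints, for the default 5000-cell tissue:

```
root cluster: m5 (proliferating_early_cgnp)
  lineage: m5[proliferating_early_cgnp] -> m4[early_cgnp] -> m1[migrating_cgnp] -> m0[differentiated_neuronal]
  lineage: m5[proliferating_early_cgnp] -> m3[astrocytic_like]
Kendall tau(latent time, pseudotime) = 0.829 over 4261 lineage cells (1.0 = identical ordering)
```

The first lineage is the granule-precursor differentiation axis
(proliferating → early → migrating → differentiated); the astrocytic-like
cluster branches off the early arm, as planted. Kendall τ compares the
inferred arc-length pseudotime with the generator's latent differentiation
time over all lineage cells: 0.83 means the ordering is recovered nearly
monotonically. The other scripts in `examples/` exercise one capability
each and print the quantity they verify; `examples/08_full_pipeline.py`
runs everything end to end from a config (also available as the `mbenkit`
command: `mbenkit run --config cfg.yaml --seed 11 --out run/`).

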