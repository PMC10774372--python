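# Methods

This note documents the models, parameters and numerical choices behind
`mbenkit`, and what the synthetic benchmarks do and do not establish.

## The synthetic tissue and count model

**Geometry.** A tissue is a rectangle (default 2000 × 2000 µm) containing
`n_nodules` discs (default 3; radius ~ N(300, 30²) µm, resampled until the
disc fits the field). Six cell states are drawn from a fixed composition
(proliferating early CGNP-like 0.15, early CGNP-like 0.20, migrating 0.20,
neuronally differentiated 0.30, astrocytic-like 0.05, stromal/immune 0.10)
and placed by rejection sampling: a uniform proposal is accepted with
probability `w[state][region] / max(w[state])`, where the region is *rim*
(within `rim_width`/2 = 30 µm of a disc boundary), *nodular* (inside a
disc) or *internodular*. The default weights encode the architecture the
analysis should recover — early/proliferating/stromal internodular,
differentiated nodular, migrating everywhere, astrocytic-like on the rim.
No quantitative propensities are published for this architecture, so the
weights are config-exposed defaults, not claims. A hard-core constraint
(`min_cell_spacing` = 8 µm, grid-hash checked) keeps nuclei separable;
placement fails explicitly after 500·n attempts. The ground-truth
compartment label is purely geometric: nodular iff inside any disc.

**Counts.** Gene counts are negative binomial with mean
`baseline × effect × batch × tumor × CNV` and dispersion θ = 2 (θ → ∞
recovers Poisson; sampled as Gamma–Poisson). The 120-gene spatial panel
has 15 markers per state plus 30 housekeeping genes; plain markers are
state-gated at fold 8. Ten genes per lineage program double as *gradient*
genes whose effect follows smooth functions of a latent time t ∈ [0, 1]
(early: σ((0.40 − t)/0.15); migrating: Gaussian bump at t = 0.5, width
0.15; differentiated: σ((t − 0.60)/0.15); peak fold 12). Latent times are
drawn per state from overlapping ranges (0–0.25, 0.10–0.40, 0.35–0.70,
0.65–1.0), so pseudotime is recoverable both between and within states;
these settings give Kendall τ ≈ 0.82–0.83 across seeds and leave
clustering ARI ≈ 0.93–0.95. Astrocytic-like cells carry half the early
program (they branch off the early arm) plus their own markers and have
no latent time. Batch factors are per-patient per-gene lognormal(0, 0.2);
malignant cells additionally carry a per-patient lognormal(0, 0.5) tumor
program, making tumor cells patient-private — the property the
patient-mixing malignancy rule needs — while normal stroma stays shared.
The genome-wide panel (2000 genes, 5 chromosomes × 400) hosts a planted
CNV block (default: 300 contiguous chr1 genes × 1.5 in one patient's
malignant cells).

**Imaging.** Nuclei are non-overlapping discs on a pixel grid (default
6 px radius at 2 px/µm, i.e. ≈113 px² areas inside the 90–2000 px QC
window; real nuclear morphology is out of scope, but touching-disc
fixtures still exercise the watershed). Each cell's counts are scattered
uniformly over its painted disc pixels, which makes spot-to-nucleus
assignment exactly invertible at zero background; background spots are
homogeneous Poisson over unlabeled pixels. Spot images place the full
amplitude at the spot's pixel and convolve with a Gaussian PSF
(σ = 0.93 px), plus white noise.

**Bulk.** Microdissected bulks are `signatures · proportions` with
per-sample lognormal noise and optional patient factors; signatures are
column-normalized so noiseless mixtures are exactly recoverable.
Default compositions make internodular samples precursor/stroma-rich and
nodular samples differentiated-rich.

**What passing does not show.** The generator has no segmentation errors,
no optical crowding beyond PSF overlap, no doublets or ambient RNA, no
spatial gradients within a state other than the lineage programs, discs
instead of irregular nodules, and mild, purely multiplicative batch
structure. Results quantify correctness of the implementations under the
stated model, not expected performance on real tissue.

## Analysis stages

**Spot detection.** DoG band-pass at (σ, 1.6σ); local maxima with a 2-px
exclusion radius above an absolute threshold (default 0.005). Thresholds
are acquisition-specific in practice (instrument range 0.004–0.0086); the
benchmark fixture uses 0.006 at amplitude 0.04, SNR 5, where the noise
floor of the DoG response sits ≈4.7 noise-σ below threshold.

**Clustering.** Total-count normalization to 10 000 and log1p; PCA (30
components, full SVD); symmetrized kNN graph (k = 20) in PC space;
igraph multilevel Louvain at resolution 1.0. Two determinism measures:
cells are canonically reordered by a lexicographic sort of the raw
matrix rows before any arithmetic (so permuted inputs give bitwise
identical results), and igraph's RNG is pinned to `random.Random(seed)`.
Clusters whose mean profiles correlate at r ≥ 0.95 are merged by
connected components (transitively), mirroring how over-split partitions
are consolidated in practice; modularity at resolution 1 over-splits
dense clouds (resolution limit), which the merge step absorbs.

**Malignancy.** The 95% rule is applied to clusters of the genome-wide
matrix *without* batch adjustment — tumor patient-specificity is the
signal, and adjustment would dilute it; the boundary is inclusive. CNV:
genes ordered by (chromosome, position) with natural chromosome keys;
per-gene reference-mean subtraction; clip ±1; truncated-window running
mean (window 101, shrunk at chromosome edges/short chromosomes, with a
warning); a second reference-centering pass (clipping the sparse, skewed
log counts biases the first pass); per-cell median subtraction. Burden is
the per-cell mean squared smoothed ratio.

**Trajectory.** MST over cluster-centroid Euclidean distances in PC
space (ties broken by processing clusters in sorted-id order); lineages
are root-to-leaf paths, rooted by default at the cluster with the highest
proliferation module score. Pseudotime is arc length to the orthogonal
projection onto the nearest piecewise-linear path, clamped to segments;
equidistant cells join the lower-index lineage. Principal-curve
refinement of the paths is a noted extension, not implemented.

**Compartment DE.** Per-gene OLS of log2 expression on compartment +
patient fixed effects; the compartment coefficient is the log2FC.
Residual variances are empirical-Bayes moderated (scaled
inverse-chi-square prior fitted by matching the moments of log s² to the
chi-square log-moments; posterior df = d₀ + df). Moderation is the
default because unmoderated OLS at a paired 6 + 6 design has 5 residual
df and cannot reach useful sensitivity at σ = 0.3; `moderate=False`
restores plain OLS. Confounded designs (compartment aliased by patient)
are refused. Significance uses BH q ≤ 0.05 and |log2FC| ≥ 0.5.

**Signature enrichment.** Single-sample weighted-KS statistic: genes
ranked by descending expression; a set gene at position *pos* contributes
weight `(N − pos + 1)^τ` (τ = 0.25; τ = 0 reduces to the classic KS form,
where a set occupying the top ranks scores exactly +1); the score is the
signed maximum deviation of the hit-minus-miss running sum. The kernel
density variant of sample-wise enrichment is deliberately not reproduced.

**Deconvolution.** Gene space = intersection; bulk columns and signature
columns normalized to unit sum (hence invariance to per-sample
rescaling); per-sample NNLS; proportions renormalized to the simplex.
Unweighted NNLS — no cross-subject variance weighting; with
column-normalized signatures the recovered weights are the mixing
proportions directly.

**Co-localization.** Fixed spatial graph (Delaunay with edges longer
than 4× the median nearest-neighbor distance pruned — removes convex
hull artifacts; or symmetrized kNN, which is also the fallback for
degenerate point sets). Observed unordered type-pair edge counts are
compared with B label permutations: score `log2((obs+1)/(mean_perm+1))`,
p two-sided by doubling the smaller tail with add-one correction (so
p ∈ (0, 1], exact discreteness preserved, uniform under the null).

**Compartment mapping.** 2-D histogram of anchor-type cells (default:
the differentiated-neuronal cluster, which forms the nodules) at 2 µm
grid, Gaussian-smoothed at bandwidth 75 µm, Otsu-thresholded; regions
smaller than a disc of radius bandwidth/2 are dropped; region contours
are exported as polygons. Per-cell accuracy ≈ 0.97 and region IoU ≈ 0.9
on the default geometry. The nodular fraction of the rim-dwelling
astrocytic-like state is boundary-sensitive by construction (the state
is planted on the boundary), so only compartment-restricted states are
held to tight recovery tolerances.

## Pipeline and reproducibility

`run_pipeline` derives one sub-seed per stage from the global seed
(CRC32 of the stage name XOR seed, kept below 2³¹), so toggling stages
never perturbs other stages' streams. Outputs carry no timestamps; two
runs with the same config + seed produce byte-identical files (verified
by hashing in the test suite). The smoke configuration is 3 patients ×
2000 cells (1200 × 1200 µm fields), which completes in about half a
minute; unit benchmarks use 5000-cell single-patient tissues and a
2 × 1000-cell genome-wide cohort.

## Known limitations

- Watershed segmentation is a deliberately simple stand-in for learned
  segmenters; it only sees disc-like fixtures here.
- Batch adjustment is per-batch gene centering, not an integration
  method; it removes location shifts only.
- The malignancy rule needs multiple patients and patient-private tumor
  profiles; single-patient cohorts cannot separate malignant from normal
  by mixing alone.
- CNV inference reports smoothed relative expression, not called copy
  states; no HMM segmentation or subclone inference.
- Pseudotime uses piecewise-linear paths; strongly curved manifolds
  would need principal-curve refitting.
- Optional per-cell variant flags can be joined as metadata
  (`malignancy.attach_variant_flags`) but variant calling itself is out
  of scope.
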