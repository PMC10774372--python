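"""Negative-binomial expression generator with lineage, batch and CNV effects.

Per-cell, per-gene counts are drawn from a negative binomial whose mean is

    baseline * state/time effect * patient batch factor * CNV fold-change

State identity is carried by state-gated marker genes; the granule-precursor
lineage additionally expresses smooth time-dependent programs (early-high,
migrating mid-bump, differentiated-late) over dedicated gradient genes so a
latent differentiation time t in [0, 1] is recoverable by pseudotime methods.
Copy-number gains/losses are planted as contiguous genomic blocks whose genes
get a multiplicative fold-change in the malignant cells of selected patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .tissue import LINEAGE_STATES, MALIGNANT_STATES, STATES, Tissue

_STATE_PREFIX = {
    "proliferating_early_cgnp": "PRO",
    "early_cgnp": "ERL",
    "migrating_cgnp": "MIG",
    "differentiated_neuronal": "DIF",
    "astrocytic_like": "AST",
    "stromal_immune": "STR",
}

#: latent-time range sampled per lineage state (overlapping on purpose)
_T_RANGE = {
    "proliferating_early_cgnp": (0.00, 0.25),
    "early_cgnp": (0.10, 0.40),
    "migrating_cgnp": (0.35, 0.70),
    "differentiated_neuronal": (0.65, 1.00),
}


@dataclass
class CnvBlock:
    """A planted contiguous copy-number block."""

    patient: str
    chrom: str
    gene_start: int  # index of first affected gene on the chromosome
    n_genes: int
    fold: float

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("CNV fold-change must be positive")


@dataclass
class ExpressionConfig:
    """Tunable parameters of the count model."""

    baseline_mean: float = 0.2       # counts per gene per cell, pre-effects
    marker_fold: float = 8.0         # state-gated marker elevation
    gradient_fold: float = 12.0      # peak elevation of lineage time programs
    dispersion: float = 2.0          # NB size; np.inf -> Poisson
    batch_sd: float = 0.2            # lognormal sigma of per-patient gene factors
    tumor_patient_sd: float = 0.5    # per-patient tumor-program sigma (malignant cells only)
    astro_early_level: float = 0.5   # fraction of the early program in astro cells
    cnv_blocks: list = field(default_factory=list)
    seed: int = 0


@dataclass
class ExpressionTruth:
    """Ground truth emitted alongside simulated counts."""

    latent_time: pd.Series            # NaN outside the lineage states
    batch_factors: pd.DataFrame       # patients x genes, multiplicative
    cnv_blocks: list
    state_means: pd.DataFrame         # states x genes, expected mean at batch=1
    dispersion: float


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def program_early(t: np.ndarray) -> np.ndarray:
    return _sigmoid((0.40 - t) / 0.15)


def program_migrating(t: np.ndarray) -> np.ndarray:
    return np.exp(-((t - 0.5) ** 2) / (2 * 0.15**2))


def program_differentiated(t: np.ndarray) -> np.ndarray:
    return _sigmoid((t - 0.60) / 0.15)


def default_panel(
    n_markers_per_state: int = 15,
    n_housekeeping: int = 30,
    n_gradient_per_program: int = 10,
    n_chromosomes: int = 6,
) -> pd.DataFrame:
    """Build the spatial gene panel with genomic annotation.

    Each state gets ``n_markers_per_state`` genes, of which the last
    ``n_gradient_per_program`` of the early/migrating/differentiated states
    double as lineage-gradient genes (their expression follows the smooth
    time program rather than a hard state gate).  Genes are spread
    round-robin over ``n_chromosomes`` synthetic chromosomes.
    """
    rows = []
    for state in STATES:
        prefix = _STATE_PREFIX[state]
        for i in range(n_markers_per_state):
            gradient = None
            if i >= n_markers_per_state - n_gradient_per_program:
                if state in ("proliferating_early_cgnp", "early_cgnp"):
                    gradient = "early"
                elif state == "migrating_cgnp":
                    gradient = "migrating"
                elif state == "differentiated_neuronal":
                    gradient = "differentiated"
            rows.append((f"{prefix}{i + 1:02d}", state, gradient))
    for i in range(n_housekeeping):
        rows.append((f"HK{i + 1:02d}", None, None))
    panel = pd.DataFrame(rows, columns=["gene", "marker_state", "gradient"])
    panel["chrom"] = [f"chr{(i % n_chromosomes) + 1}" for i in range(len(panel))]
    panel["pos"] = [1000 * (i // n_chromosomes + 1) for i in range(len(panel))]
    return panel


def cnv_panel(n_genes: int = 2000, n_chromosomes: int = 5, n_markers_per_state: int = 15,
              block_chrom: str = "chr1", block_start: int = 50, block_len: int = 300) -> pd.DataFrame:
    """Build a dense genome-wide panel suitable for expression-CNV inference.

    Genes are laid out contiguously chromosome by chromosome.  State markers
    (needed so the matrix also supports clustering and malignancy calling)
    are placed outside the CNV block region.
    """
    per_chrom = n_genes // n_chromosomes
    genes, chroms, pos = [], [], []
    for c in range(n_chromosomes):
        for i in range(per_chrom):
            genes.append(f"G{c * per_chrom + i:04d}")
            chroms.append(f"chr{c + 1}")
            pos.append(1000 * (i + 1))
    panel = pd.DataFrame({"gene": genes, "chrom": chroms, "pos": pos})
    panel["marker_state"] = None
    panel["gradient"] = None

    block_mask = (panel["chrom"] == block_chrom) & (
        panel.groupby("chrom").cumcount().between(block_start, block_start + block_len - 1)
    )
    free = np.flatnonzero(~block_mask.to_numpy())
    idx = 0
    for state in STATES:
        for _ in range(n_markers_per_state):
            panel.loc[free[idx], "marker_state"] = state
            idx += 7  # scatter markers along the genome
    return panel


def default_cnv_blocks(patient: str = "P1", fold: float = 1.5) -> list[CnvBlock]:
    """The default planted gain: 300 genes on chr1 in one patient."""
    return [CnvBlock(patient=patient, chrom="chr1", gene_start=50, n_genes=300, fold=fold)]


def _expected_means(panel: pd.DataFrame, cfg: ExpressionConfig) -> pd.DataFrame:
    """State x gene expected means at the state's mid latent time (batch=1)."""
    t_mid = {s: np.mean(_T_RANGE[s]) for s in LINEAGE_STATES}
    rows = {}
    for state in STATES:
        t = np.array([t_mid.get(state, np.nan)])
        rows[state] = _gene_means_for(panel, state, t, cfg)[0]
    return pd.DataFrame(rows, index=panel["gene"]).T


def _gene_means_for(panel: pd.DataFrame, state: str, t: np.ndarray, cfg: ExpressionConfig) -> np.ndarray:
    """Mean matrix (len(t) x genes) for cells of one state with latent times t."""
    n = len(t)
    g = len(panel)
    mult = np.ones((n, g))
    marker = panel["marker_state"].to_numpy()
    gradient = panel["gradient"].to_numpy()

    plain = (marker == state) & pd.isna(gradient)
    mult[:, plain] = cfg.marker_fold

    prog_val = {
        "early": program_early(np.nan_to_num(t, nan=0.0)),
        "migrating": program_migrating(np.nan_to_num(t, nan=0.0)),
        "differentiated": program_differentiated(np.nan_to_num(t, nan=0.0)),
    }
    if state in LINEAGE_STATES:
        for prog, val in prog_val.items():
            cols = gradient == prog
            mult[:, cols] = 1.0 + (cfg.gradient_fold - 1.0) * val[:, None]
    elif state == "astrocytic_like":
        cols = gradient == "early"
        level = cfg.astro_early_level * program_early(np.array([0.3]))[0]
        mult[:, cols] = 1.0 + (cfg.gradient_fold - 1.0) * level
    return cfg.baseline_mean * mult


def generate_expression(
    tissue: Tissue,
    panel: pd.DataFrame,
    config: ExpressionConfig | None = None,
    seed: int | None = None,
) -> tuple[ad.AnnData, ExpressionTruth]:
    """Draw a cells x genes count matrix for a tissue (or tissue list).

    Accepts a single :class:`Tissue` or a list of them (a multi-patient
    cohort).  Returns the counts as an :class:`anndata.AnnData` with cell
    metadata in ``obs`` and gene annotation in ``var``, plus the full
    :class:`ExpressionTruth`.
    """
    config = config or ExpressionConfig()
    tissues = tissue if isinstance(tissue, (list, tuple)) else [tissue]
    cells = pd.concat([t.cells for t in tissues], ignore_index=True)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    missing = panel["gene"].isna() | (panel["gene"] == "")
    if missing.any():
        raise ValueError("panel contains unnamed genes")
    covered = set(panel["marker_state"].dropna())
    if not covered.issuperset(STATES):
        raise ValueError(f"marker panel must cover all six states; missing {set(STATES) - covered}")

    genes = panel["gene"].to_numpy()
    n_cells, n_genes = len(cells), len(genes)

    # latent time per cell
    t = np.full(n_cells, np.nan)
    for state, (lo, hi) in _T_RANGE.items():
        mask = (cells["state"] == state).to_numpy()
        t[mask] = rng.uniform(lo, hi, mask.sum())

    # per-patient batch factors
    patients = sorted(cells["patient"].unique())
    batch = pd.DataFrame(
        rng.lognormal(0.0, config.batch_sd, size=(len(patients), n_genes)),
        index=patients,
        columns=genes,
    )

    mean = np.empty((n_cells, n_genes))
    for state in STATES:
        mask = (cells["state"] == state).to_numpy()
        if mask.any():
            mean[mask] = _gene_means_for(panel, state, t[mask], config)

    mean *= batch.loc[cells["patient"]].to_numpy()

    # patient-private tumor program: malignant cells are transcriptomically
    # patient-specific (normal cell types are shared across patients)
    malignant = cells["state"].isin(MALIGNANT_STATES).to_numpy()
    if config.tumor_patient_sd > 0:
        tumor = pd.DataFrame(
            rng.lognormal(0.0, config.tumor_patient_sd, size=(len(patients), n_genes)),
            index=patients,
            columns=genes,
        )
        mean[malignant] *= tumor.loc[cells["patient"][malignant]].to_numpy()

    # planted CNV blocks: malignant cells of the named patient only
    chrom_rank = panel.groupby("chrom").cumcount().to_numpy()
    for block in config.cnv_blocks:
        gmask = (panel["chrom"] == block.chrom).to_numpy() & (
            (chrom_rank >= block.gene_start) & (chrom_rank < block.gene_start + block.n_genes)
        )
        if not gmask.any():
            raise ValueError(f"CNV block on {block.chrom} matches no panel genes")
        cmask = malignant & (cells["patient"] == block.patient).to_numpy()
        mean[np.ix_(cmask, gmask)] *= block.fold

    if not np.all(mean > 0):
        raise ValueError("non-positive expression means")

    if np.isfinite(config.dispersion):
        lam = rng.gamma(config.dispersion, mean / config.dispersion)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int32)

    obs = cells.copy()
    obs["latent_time"] = t
    obs["malignant_truth"] = malignant
    obs.index = obs.pop("cell_id")
    var = panel.set_index("gene")
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.obs["total_counts"] = counts.sum(axis=1)

    truth = ExpressionTruth(
        latent_time=pd.Series(t, index=adata.obs_names, name="latent_time"),
        batch_factors=batch,
        cnv_blocks=list(config.cnv_blocks),
        state_means=_expected_means(panel, config),
        dispersion=config.dispersion,
    )
    return adata, truth
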