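"""Bulk compartment mixtures for deconvolution benchmarks.

Each microdissected bulk sample is a non-negative mixture of per-state
expression signatures, multiplied by lognormal measurement noise and an
optional per-patient batch factor.  True mixing proportions are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tissue import STATES

# Default compartment composition: internodular bulks rich in proliferating /
# early precursor and stromal states, nodular bulks dominated by
# differentiated cells — the architecture the deconvolution should recover.
_DEFAULT_COMPOSITION = {
    "internodular": {
        "proliferating_early_cgnp": 0.28,
        "early_cgnp": 0.27,
        "migrating_cgnp": 0.20,
        "differentiated_neuronal": 0.05,
        "astrocytic_like": 0.05,
        "stromal_immune": 0.15,
    },
    "nodular": {
        "proliferating_early_cgnp": 0.03,
        "early_cgnp": 0.04,
        "migrating_cgnp": 0.18,
        "differentiated_neuronal": 0.60,
        "astrocytic_like": 0.10,
        "stromal_immune": 0.05,
    },
}


@dataclass
class BulkConfig:
    compartment_proportions: dict = field(
        default_factory=lambda: {c: dict(p) for c, p in _DEFAULT_COMPOSITION.items()}
    )
    proportion_jitter: float = 0.02   # Dirichlet-like per-sample wobble
    noise_sd: float = 0.1             # lognormal sigma, per gene per sample
    batch_sd: float = 0.0             # lognormal sigma of per-patient factors
    seed: int = 0


def normalize_signatures(signatures: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize a genes x states signature matrix to unit column sum."""
    colsum = signatures.sum(axis=0)
    if (colsum <= 0).any():
        raise ValueError("signature columns must have positive sums")
    return signatures / colsum


def generate_bulk_compartments(
    state_signatures: pd.DataFrame,
    design: pd.DataFrame,
    config: BulkConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate bulk profiles for a sample design.

    Parameters
    ----------
    state_signatures
        genes x states matrix; will be column-normalized.
    design
        One row per bulk sample with columns ``patient`` and ``compartment``.

    Returns
    -------
    (bulk, proportions)
        ``bulk``: genes x samples linear-scale matrix.
        ``proportions``: samples x states true mixing weights (rows sum to 1).
    """
    config = config or BulkConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if not {"patient", "compartment"}.issubset(design.columns):
        raise ValueError("design needs 'patient' and 'compartment' columns")

    sig = normalize_signatures(state_signatures)
    states = [s for s in STATES if s in sig.columns] or list(sig.columns)
    sig = sig[states]

    sample_ids = [
        f"{row.patient}_{row.compartment}_{i}" for i, row in enumerate(design.itertuples())
    ]
    patients = sorted(design["patient"].unique())
    batch = {
        p: rng.lognormal(0.0, config.batch_sd, size=len(sig)) if config.batch_sd > 0
        else np.ones(len(sig))
        for p in patients
    }

    props = np.empty((len(design), len(states)))
    bulk = np.empty((len(sig), len(design)))
    for i, row in enumerate(design.itertuples()):
        base = np.array([config.compartment_proportions[row.compartment][s] for s in states])
        if config.proportion_jitter > 0:
            base = np.clip(base + rng.normal(0, config.proportion_jitter, len(base)), 1e-4, None)
        p = base / base.sum()
        props[i] = p
        profile = sig.to_numpy() @ p
        if config.noise_sd > 0:
            profile = profile * rng.lognormal(0.0, config.noise_sd, size=len(profile))
        bulk[:, i] = profile * batch[row.patient]

    bulk_df = pd.DataFrame(bulk, index=sig.index, columns=sample_ids)
    props_df = pd.DataFrame(props, index=sample_ids, columns=states)
    return bulk_df, props_df


def paired_design(patients: tuple[str, ...] = ("P1", "P2", "P3"), replicates: int = 2) -> pd.DataFrame:
    """A paired nodular/internodular design, ``replicates`` pairs per patient."""
    rows = [
        {"patient": p, "compartment": c}
        for p in patients
        for _ in range(replicates)
        for c in ("internodular", "nodular")
    ]
    return pd.DataFrame(rows)
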