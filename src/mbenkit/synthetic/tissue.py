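"""Synthetic bicompartmental tissue generator.

Emulates the spatial architecture of a nodular/internodular tumor: circular
nodules of post-mitotic differentiated cells embedded in an internodular
background of proliferating and early precursor-like cells plus stroma, with
astrocytic-like cells concentrated in an annulus at the nodule rim.  Cells
are placed by rejection sampling with per-state compartment weights and a
hard-core minimum spacing, and every cell carries its ground-truth state and
compartment label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical cell-state names, ordered along the granule-precursor lineage
#: (first four), then the rim-associated astrocytic-like malignant state and
#: the non-malignant stromal/immune background.
STATES = (
    "proliferating_early_cgnp",
    "early_cgnp",
    "migrating_cgnp",
    "differentiated_neuronal",
    "astrocytic_like",
    "stromal_immune",
)

#: States that are malignant (share the tumor lineage or branch off it).
MALIGNANT_STATES = STATES[:5]

#: States with a defined latent differentiation time along the lineage.
LINEAGE_STATES = STATES[:4]

REGIONS = ("internodular", "nodular", "rim")

_DEFAULT_PROPORTIONS = {
    "proliferating_early_cgnp": 0.15,
    "early_cgnp": 0.20,
    "migrating_cgnp": 0.20,
    "differentiated_neuronal": 0.30,
    "astrocytic_like": 0.05,
    "stromal_immune": 0.10,
}

# Placement weights per state over {internodular, nodular, rim}, encoding the
# histology being emulated: early/proliferating/stromal internodular,
# differentiated nodular, migrating in both compartments, astrocytic-like at
# the rim.  Exact propensities are unknown; these defaults are config-exposed.
_DEFAULT_PROPENSITY = {
    "proliferating_early_cgnp": {"internodular": 1.0, "nodular": 0.02, "rim": 0.10},
    "early_cgnp": {"internodular": 1.0, "nodular": 0.02, "rim": 0.10},
    "migrating_cgnp": {"internodular": 1.0, "nodular": 1.0, "rim": 1.0},
    "differentiated_neuronal": {"internodular": 0.05, "nodular": 1.0, "rim": 0.60},
    "astrocytic_like": {"internodular": 0.05, "nodular": 0.05, "rim": 1.0},
    "stromal_immune": {"internodular": 1.0, "nodular": 0.05, "rim": 0.20},
}


class PackingError(RuntimeError):
    """Raised when cells cannot be placed at the requested density/spacing."""


@dataclass
class TissueConfig:
    """Parameters of the synthetic tissue (distances in micrometres)."""

    field_width: float = 2000.0
    field_height: float = 2000.0
    n_nodules: int = 3
    nodule_radius_mean: float = 300.0
    nodule_radius_sd: float = 30.0
    n_cells: int = 5000
    state_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    spatial_propensity: dict = field(
        default_factory=lambda: {s: dict(w) for s, w in _DEFAULT_PROPENSITY.items()}
    )
    rim_width: float = 60.0
    min_cell_spacing: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.state_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state proportions sum to {total}, expected 1")
        if set(self.state_proportions) != set(STATES):
            raise ValueError("state_proportions must cover exactly the six states")
        if self.rim_width <= 0:
            raise ValueError("rim_width must be positive")
        if self.min_cell_spacing < 0:
            raise ValueError("min_cell_spacing must be non-negative")
        for s, w in self.spatial_propensity.items():
            if max(w.values()) <= 0:
                raise ValueError(f"state {s} has no positive placement weight")


@dataclass
class Tissue:
    """A realized tissue: per-cell table plus nodule geometry.

    ``cells`` columns: cell_id, x, y, state, patient, compartment.
    ``nodules`` columns: x, y, radius.
    """

    cells: pd.DataFrame
    nodules: pd.DataFrame
    config: TissueConfig
    patient: str = "P1"

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _sample_nodules(cfg: TissueConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for _ in range(cfg.n_nodules):
        for _attempt in range(1000):
            r = rng.normal(cfg.nodule_radius_mean, cfg.nodule_radius_sd)
            if r <= 0:
                continue
            if 2 * r >= min(cfg.field_width, cfg.field_height):
                continue
            cx = rng.uniform(r, cfg.field_width - r)
            cy = rng.uniform(r, cfg.field_height - r)
            rows.append((cx, cy, r))
            break
        else:
            raise ValueError("nodule radius incompatible with field size")
    return pd.DataFrame(rows, columns=["x", "y", "radius"])


def classify_region(
    x: np.ndarray, y: np.ndarray, nodules: pd.DataFrame, rim_width: float
) -> np.ndarray:
    """Region of each point: rim annulus takes precedence over disc interior."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    region = np.zeros(x.shape, dtype=int)  # 0 internodular, 1 nodular, 2 rim
    for _, nod in nodules.iterrows():
        d = np.hypot(x - nod.x, y - nod.y)
        inside = d < nod.radius
        in_rim = np.abs(d - nod.radius) <= rim_width / 2.0
        region[inside & (region == 0)] = 1
        region[in_rim] = 2
    return np.asarray(REGIONS)[region]


def compartment_of(x: np.ndarray, y: np.ndarray, nodules: pd.DataFrame) -> np.ndarray:
    """Ground-truth compartment: nodular iff inside any nodule disc."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = np.zeros(x.shape, dtype=bool)
    for _, nod in nodules.iterrows():
        inside |= np.hypot(x - nod.x, y - nod.y) < nod.radius
    return np.where(inside, "nodular", "internodular")


class _SpacingGrid:
    """Hash grid for the hard-core minimum-spacing check."""

    def __init__(self, spacing: float):
        self.spacing = spacing
        self.cell = max(spacing, 1e-9)
        self.grid: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def ok(self, x: float, y: float) -> bool:
        if self.spacing <= 0:
            return True
        gx, gy = int(x // self.cell), int(y // self.cell)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for px, py in self.grid.get((gx + dx, gy + dy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < self.spacing**2:
                        return False
        return True

    def add(self, x: float, y: float) -> None:
        self.grid.setdefault((int(x // self.cell), int(y // self.cell)), []).append((x, y))


def generate_tissue(config: TissueConfig, patient: str = "P1") -> Tissue:
    """Place cells in the field by state-weighted rejection sampling.

    Raises
    ------
    PackingError
        If cells cannot be placed within a bounded number of attempts
        (infeasible ``n_cells`` / ``min_cell_spacing`` combination).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nodules = _sample_nodules(config, rng)

    states = list(config.state_proportions)
    probs = np.array([config.state_proportions[s] for s in states])
    cell_states = rng.choice(states, size=config.n_cells, p=probs)

    grid = _SpacingGrid(config.min_cell_spacing)
    xs = np.empty(config.n_cells)
    ys = np.empty(config.n_cells)
    ncx = nodules["x"].to_numpy()
    ncy = nodules["y"].to_numpy()
    nr = nodules["radius"].to_numpy()
    half_rim = config.rim_width / 2.0

    def _region(x: float, y: float) -> str:
        if len(nr) == 0:
            return "internodular"
        d = np.hypot(x - ncx, y - ncy)
        if np.any(np.abs(d - nr) <= half_rim):
            return "rim"
        if np.any(d < nr):
            return "nodular"
        return "internodular"

    max_attempts = 500 * max(config.n_cells, 1)
    attempts = 0
    # batch the uniform proposals to keep the python loop cheap
    batch = max(1024, config.n_cells)
    prop_x = prop_y = prop_u = None
    bi = batch
    for i, state in enumerate(cell_states):
        w = config.spatial_propensity[state]
        wmax = max(w.values())
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise PackingError(
                    f"placed {i}/{config.n_cells} cells after {max_attempts} attempts; "
                    "reduce n_cells or min_cell_spacing"
                )
            if bi >= batch:
                prop_x = rng.uniform(0, config.field_width, batch)
                prop_y = rng.uniform(0, config.field_height, batch)
                prop_u = rng.uniform(0, 1, batch)
                bi = 0
            x, y, u = prop_x[bi], prop_y[bi], prop_u[bi]
            bi += 1
            if u * wmax > w[_region(x, y)]:
                continue
            if not grid.ok(x, y):
                continue
            grid.add(x, y)
            xs[i], ys[i] = x, y
            break

    cells = pd.DataFrame(
        {
            "cell_id": [f"{patient}_c{i:05d}" for i in range(config.n_cells)],
            "x": xs,
            "y": ys,
            "state": cell_states,
            "patient": patient,
            "compartment": compartment_of(xs, ys, nodules),
        }
    )
    return Tissue(cells=cells, nodules=nodules, config=config, patient=patient)


def generate_cohort(config: TissueConfig, patients: tuple[str, ...] = ("P1", "P2", "P3")) -> list[Tissue]:
    """One independent tissue per patient, with derived per-patient seeds."""
    tissues = []
    for i, pat in enumerate(patients):
        cfg = replace(config, seed=config.seed + 1009 * (i + 1))
        tissues.append(generate_tissue(cfg, patient=pat))
    return tissues
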