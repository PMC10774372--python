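"""Render transcript spot tables, nucleus label masks and raw images.

Nuclei are non-overlapping discs on an integer pixel grid (1 px = 1 µm by
default).  Each cell's count-matrix row is scattered uniformly over the
painted pixels of its nucleus disc, which guarantees that with zero
background the spot-to-nucleus assignment recovers the count matrix exactly.
Background spots follow a homogeneous Poisson process over unlabeled pixels.
Spot images are rendered with a Gaussian point-spread function so
difference-of-Gaussians detection is exercised end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .tissue import Tissue


class NucleusOverlapError(RuntimeError):
    """Nucleus discs would overlap at the requested radius."""


def generate_spots_and_masks(
    tissue: Tissue,
    counts,
    nucleus_radius: float = 6.0,
    background_rate: float = 0.0,
    image_shape: tuple[int, int] | None = None,
    scale: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Scatter a tissue's transcripts into a spot table plus label mask.

    Parameters
    ----------
    counts
        AnnData of the tissue's cells (rows must match ``tissue.cells``).
    nucleus_radius
        Disc radius in pixels.
    background_rate
        Expected background spots per unlabeled pixel.
    scale
        Pixels per micrometre.
    Returns
    -------
    (spots, mask)
        ``spots``: DataFrame with columns x, y (pixel floats), gene.
        ``mask``: uint16 label image, 0 = background, label k = k-th cell + 1.
    """
    rng = np.random.default_rng(seed)
    cells = tissue.cells
    if counts.n_obs != len(cells):
        raise ValueError("counts and tissue cell tables disagree in length")
    if len(cells) >= 2**16:
        raise ValueError("too many cells for a uint16 label mask")

    offset = 0.0
    if image_shape is None:
        # pad so edge nuclei fit; all emitted coordinates carry the offset
        offset = float(np.ceil(nucleus_radius) + 1)
        image_shape = (
            int(np.ceil(tissue.config.field_height * scale + 2 * offset)),
            int(np.ceil(tissue.config.field_width * scale + 2 * offset)),
        )
    h, w = image_shape

    cx = cells["x"].to_numpy() * scale + offset
    cy = cells["y"].to_numpy() * scale + offset
    if np.any(cx - nucleus_radius < 0) or np.any(cx + nucleus_radius >= w) or np.any(
        cy - nucleus_radius < 0
    ) or np.any(cy + nucleus_radius >= h):
        raise ValueError("nuclei do not fit inside the image")
    if len(cells) > 1:
        pts = np.column_stack([cx, cy])
        nn_dist = cKDTree(pts).query(pts, k=2)[0][:, 1]
        if np.min(nn_dist) < 2 * nucleus_radius:
            raise NucleusOverlapError("nucleus discs overlap; reduce nucleus_radius")

    mask = np.zeros((h, w), dtype=np.uint16)
    pixel_lists = []
    r_int = int(np.ceil(nucleus_radius))
    for i in range(len(cells)):
        x0, y0 = cx[i], cy[i]
        yy, xx = np.mgrid[
            int(y0) - r_int : int(y0) + r_int + 1, int(x0) - r_int : int(x0) + r_int + 1
        ]
        inside = (xx + 0.5 - x0) ** 2 + (yy + 0.5 - y0) ** 2 <= nucleus_radius**2
        py, px = yy[inside], xx[inside]
        mask[py, px] = i + 1
        pixel_lists.append((px, py))

    X = np.asarray(counts.X)
    gene_names = counts.var_names.to_numpy()
    xs, ys, gs = [], [], []
    for i, (px, py) in enumerate(pixel_lists):
        row = X[i]
        total = int(row.sum())
        if total == 0:
            continue
        pick = rng.integers(0, len(px), size=total)
        sub = rng.uniform(0.0, 1.0, size=(total, 2))
        xs.append(px[pick] + sub[:, 0])
        ys.append(py[pick] + sub[:, 1])
        gs.append(np.repeat(gene_names, row))

    # background spots over unlabeled pixels
    free_y, free_x = np.nonzero(mask == 0)
    if background_rate > 0 and len(free_x) > 0:
        n_bg = rng.poisson(background_rate * len(free_x))
        if n_bg > 0:
            pick = rng.integers(0, len(free_x), size=n_bg)
            sub = rng.uniform(0.0, 1.0, size=(n_bg, 2))
            xs.append(free_x[pick] + sub[:, 0])
            ys.append(free_y[pick] + sub[:, 1])
            gs.append(rng.choice(gene_names, size=n_bg))

    if xs:
        spots = pd.DataFrame(
            {
                "x": np.concatenate(xs),
                "y": np.concatenate(ys),
                "gene": np.concatenate(gs),
            }
        )
    else:
        spots = pd.DataFrame({"x": [], "y": [], "gene": []})
    return spots, mask


def render_spot_image(
    spots: pd.DataFrame,
    image_shape: tuple[int, int],
    psf_sigma: float = 0.93,
    amplitude: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render spots as Gaussian blobs of peak ``amplitude`` plus white noise."""
    rng = np.random.default_rng(seed)
    img = np.zeros(image_shape, dtype=float)
    px = np.floor(spots["x"].to_numpy()).astype(int)
    py = np.floor(spots["y"].to_numpy()).astype(int)
    np.add.at(img, (py, px), amplitude * 2 * np.pi * psf_sigma**2)
    img = ndimage.gaussian_filter(img, psf_sigma)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, image_shape)
    return img


def render_dapi_image(
    mask: np.ndarray, intensity: float = 1.0, blur_sigma: float = 1.0,
    noise_sd: float = 0.0, seed: int = 0,
) -> np.ndarray:
    """A DAPI-like image: nucleus footprints at ``intensity``, lightly blurred."""
    rng = np.random.default_rng(seed)
    img = (mask > 0).astype(float) * intensity
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    return img
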