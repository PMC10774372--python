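"""Spatial single-cell construction from spot tables and nucleus masks.

The stage that turns smFISH-style raw material into QC-filtered cells:
difference-of-Gaussians spot detection, watershed nucleus segmentation,
spot-to-nucleus assignment, and the transcript-count / nucleus-size filters.
Default filter bounds follow common practice for targeted panels: cells with
fewer than 5 or more than 100 transcripts, or nuclei smaller than 90 or
larger than 2000 px, are removed (removal is strict; boundary cells are
kept).
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

DOG_RATIO = 1.6


def detect_spots(image: np.ndarray, sigma: float = 0.93, threshold: float = 0.005) -> pd.DataFrame:
    """Detect diffraction-limited spots by difference-of-Gaussians.

    The image is band-pass filtered with Gaussians at ``sigma`` and
    ``1.6 * sigma``; local maxima of the response above ``threshold`` are
    returned as a spot table (columns x, y in pixel coordinates).  No
    subpixel refinement is performed.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    dog = ndimage.gaussian_filter(image, sigma) - ndimage.gaussian_filter(image, DOG_RATIO * sigma)
    peaks = peak_local_max(
        dog, min_distance=2, threshold_abs=threshold, exclude_border=False
    )
    return pd.DataFrame({"x": peaks[:, 1].astype(float), "y": peaks[:, 0].astype(float)})


def segment_nuclei(
    dapi_image: np.ndarray, intensity_threshold: float = 0.5, min_area: int = 4
) -> np.ndarray:
    """Segment nuclei by threshold, distance transform and watershed.

    Touching nuclei are split at the watershed between distance-transform
    maxima; regions below ``min_area`` pixels are discarded.  Returns a
    label image (0 = background).
    """
    img = np.asarray(dapi_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    binary = img > intensity_threshold
    if not binary.any():
        return np.zeros(img.shape, dtype=np.uint16)

    distance = ndimage.distance_transform_edt(binary)
    peak_idx = peak_local_max(distance, min_distance=3, labels=binary, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peak_idx, start=1):
        markers[r, c] = i
    labels = watershed(-distance, markers, mask=binary)

    # drop too-small regions
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_area)
    if len(small):
        labels[np.isin(labels, small)] = 0
    return labels.astype(np.uint16 if labels.max() < 2**16 else np.int32)


def mask_metadata(mask: np.ndarray) -> pd.DataFrame:
    """Per-nucleus area (px) and centroid from a label mask."""
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if len(labels) == 0:
        return pd.DataFrame(columns=["label", "area_px", "x", "y"])
    areas = ndimage.sum_labels(np.ones_like(mask, dtype=float), mask, labels)
    centroids = ndimage.center_of_mass(np.ones_like(mask, dtype=float), mask, labels)
    cy, cx = np.array(centroids).T
    return pd.DataFrame({"label": labels, "area_px": areas.astype(int), "x": cx, "y": cy})


def assign_spots_to_cells(
    spots: pd.DataFrame,
    mask: np.ndarray,
    panel: list[str] | None = None,
    patient: str | None = None,
) -> tuple[ad.AnnData, int]:
    """Count spots per (nucleus, gene); spots over background are dropped.

    A spot at continuous position (x, y) is resolved to pixel
    ``(floor(x), floor(y))``; the mask label at that pixel receives the
    count.  Label 0 spots are tallied as unassigned.  Returns the cell x
    gene AnnData (all mask nuclei appear, including zero-count ones) plus
    the unassigned-spot count.
    """
    required = {"x", "y", "gene"}
    missing = required - set(spots.columns)
    if missing:
        raise ValueError(f"spot table is missing columns: {sorted(missing)}")

    genes = sorted(spots["gene"].unique()) if panel is None else list(panel)
    unknown = set(spots["gene"]) - set(genes)
    if unknown:
        raise ValueError(f"spot genes not in panel: {sorted(unknown)}")

    px = np.floor(spots["x"].to_numpy(dtype=float)).astype(int)
    py = np.floor(spots["y"].to_numpy(dtype=float)).astype(int)
    h, w = mask.shape
    if len(px) and (px.min() < 0 or px.max() >= w or py.min() < 0 or py.max() >= h):
        raise ValueError("spots fall outside the mask bounds")

    meta = mask_metadata(mask)
    labels = meta["label"].to_numpy()
    label_index = {lab: i for i, lab in enumerate(labels)}
    gene_index = {g: j for j, g in enumerate(genes)}

    spot_labels = mask[py, px] if len(px) else np.array([], dtype=int)
    unassigned = int((spot_labels == 0).sum())

    X = np.zeros((len(labels), len(genes)), dtype=np.int32)
    keep = spot_labels > 0
    rows = np.array([label_index[l] for l in spot_labels[keep]], dtype=int)
    cols = spots["gene"].to_numpy()[keep]
    cols = np.array([gene_index[g] for g in cols], dtype=int)
    np.add.at(X, (rows, cols), 1)

    obs = pd.DataFrame(
        {
            "x": meta["x"].to_numpy(),
            "y": meta["y"].to_numpy(),
            "area_px": meta["area_px"].to_numpy(),
            "total_counts": X.sum(axis=1),
        },
        index=pd.Index([f"cell_{lab}" for lab in labels], name="cell_id"),
    )
    if patient is not None:
        obs["patient"] = patient
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    return adata, unassigned


def qc_filter_cells(
    counts: ad.AnnData,
    min_transcripts: int = 5,
    max_transcripts: int = 100,
    min_area: int = 90,
    max_area: int = 2000,
) -> tuple[ad.AnnData, dict]:
    """Apply the transcript-count and nucleus-size filters (bounds inclusive).

    Cells strictly below/above the transcript bounds or the nucleus-area
    bounds are removed; a report of removals per criterion is returned.
    """
    for col in ("total_counts", "area_px"):
        if col not in counts.obs:
            raise ValueError(f"metadata column '{col}' required for QC filtering")
    total = counts.obs["total_counts"].to_numpy()
    area = counts.obs["area_px"].to_numpy()

    low_t = total < min_transcripts
    high_t = total > max_transcripts
    low_a = area < min_area
    high_a = area > max_area
    keep = ~(low_t | high_t | low_a | high_a)

    report = {
        "n_input": int(counts.n_obs),
        "removed_low_transcripts": int(low_t.sum()),
        "removed_high_transcripts": int(high_t.sum()),
        "removed_small_nuclei": int(low_a.sum()),
        "removed_large_nuclei": int(high_a.sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_kept"] == 0:
        warnings.warn("QC filtering removed every cell", stacklevel=2)
    return counts[keep].copy(), report
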