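"""From transcript spots and a nucleus mask to QC-filtered single cells.

Simulates a small tissue, renders its transcripts as a spot table plus a
nucleus label mask, detects one gene's spots from a rendered image, assigns
all spots to nuclei, and applies the transcript-count / nucleus-size QC
filters (< 5 or > 100 transcripts, < 90 or > 2000 px are removed).
"""

import numpy as np

from mbenkit.spatial_cells import assign_spots_to_cells, detect_spots, qc_filter_cells
from mbenkit.synthetic import (
    ExpressionConfig, TissueConfig, default_panel,
    generate_expression, generate_spots_and_masks, generate_tissue,
    render_spot_image,
)

tissue = generate_tissue(TissueConfig(
    n_cells=400, field_width=600, field_height=600,
    nodule_radius_mean=100, nodule_radius_sd=10, seed=4))
panel = default_panel()
counts, _ = generate_expression(tissue, panel, ExpressionConfig(seed=5))
spots, mask = generate_spots_and_masks(tissue, counts, seed=6)
print(f"{len(spots)} transcript spots over {mask.max()} nuclei")

# difference-of-Gaussians detection on a rendered single-gene image
one_gene = spots[spots.gene == "DIF01"]
img = render_spot_image(one_gene, mask.shape, psf_sigma=0.93, amplitude=0.04,
                        noise_sd=0.008, seed=7)
found = detect_spots(img, sigma=0.93, threshold=0.006)
print(f"DIF01: {len(one_gene)} rendered spots, {len(found)} detected "
      f"(spots closer than ~2 px inside a nucleus merge into one peak)")

cells, unassigned = assign_spots_to_cells(spots, mask, panel=list(panel.gene))
filtered, report = qc_filter_cells(cells)
print(f"assigned {int(np.asarray(cells.X).sum())} spots ({unassigned} background)")
print(f"QC: kept {report['n_kept']}/{report['n_input']} cells "
      f"(removed {report['removed_low_transcripts']} low / "
      f"{report['removed_high_transcripts']} high transcripts, "
      f"{report['removed_small_nuclei']} small / "
      f"{report['removed_large_nuclei']} large nuclei)")
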