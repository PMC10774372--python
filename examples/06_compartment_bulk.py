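"""Compartment differential expression and bulk deconvolution.

Simulates paired nodular/internodular bulk mixtures of the six state
signatures, recovers the state proportions by non-negative least squares,
and tests per-state proportion differences between compartments.
"""

import numpy as np

from mbenkit.compartments import composition_statistics, deconvolve_bulk
from mbenkit.synthetic import (
    BulkConfig, ExpressionConfig, TissueConfig, default_panel,
    generate_bulk_compartments, generate_expression, generate_tissue,
    normalize_signatures, paired_design,
)

tissue = generate_tissue(TissueConfig(n_cells=800, seed=3))
counts, truth = generate_expression(tissue, default_panel(), ExpressionConfig(seed=4))
signatures = normalize_signatures(truth.state_means.T)

design = paired_design(patients=("P1", "P2", "P3"), replicates=2)
bulk, true_props = generate_bulk_compartments(
    signatures, design, BulkConfig(noise_sd=0.1, seed=5))
result = deconvolve_bulk(bulk, signatures)
mae = np.abs(result.proportions.to_numpy() - true_props.to_numpy()).mean()
print(f"{bulk.shape[1]} bulk samples deconvolved; "
      f"mean absolute proportion error = {mae:.4f}")

import pandas as pd

compartment = pd.Series(design["compartment"].to_numpy(), index=bulk.columns)
stats_table = composition_statistics(result.proportions, compartment)
print("\nper-state two-sided t-tests, nodular vs internodular proportions:")
print(stats_table.round(4).to_string(index=False))
# negative t: higher in nodular samples (e.g. differentiated neurons);
# positive t: higher internodular (early precursors, stroma)
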