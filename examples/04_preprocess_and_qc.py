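"""Preprocess raw two-channel traces and inspect the QC quantities.

Shows the stage-by-stage bookkeeping for one cell: bleach-slope estimation
from the population, divisive bleach correction, reporter/nuclear ratio,
GP detrending above 3 h and z-scoring.
"""

import numpy as np

from ouosc import (
    SyntheticDatasetConfig,
    estimate_bleach_slope,
    make_embryo_dataset,
    preprocess_dataset,
)

dataset = make_embryo_dataset(SyntheticDatasetConfig(n_cells=8, seed=4))
venus_slope = estimate_bleach_slope(dataset.venus)
h2b_slope = estimate_bleach_slope(dataset.h2b)
print(f"Estimated photobleaching: venus {venus_slope*100:.2f}%/h, h2b {h2b_slope*100:.2f}%/h")
print(f"(injected: venus {0.2:.2f}%/h, h2b {2.0:.2f}%/h)")

preprocessed, slopes = preprocess_dataset(dataset.venus, dataset.h2b)
p = preprocessed[0]
print(f"\nCell {p.cell_id}:")
print(f"  detrended mean = {p.detrended.values.mean():.2e}, sd = {p.detrended.values.std():.6f}")
recon = p.reconstruct_ratio()
print(f"  ratio reconstruction max error = {np.max(np.abs(recon - p.ratio.values)):.2e}")
print(
    "\nThe detrended signal is exactly z-scored (mean 0, sd 1) and the affine"
    " bookkeeping (trend + offset + scale) reconstructs the ratio losslessly,"
    " so amplitude information is never destroyed — only set aside."
)
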