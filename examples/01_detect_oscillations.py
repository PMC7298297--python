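"""Classify a mock embryo's cells as oscillatory or aperiodic at 3% FDR.

Builds a synthetic two-channel imaging experiment (80% of reporter traces
carry a 1.5 h ultradian rhythm, the rest are aperiodic noise), runs the
full preprocessing + GP-classification pipeline, and prints the per-cell
calls next to the ground truth.
"""

from ouosc import ExperimentConfig, SyntheticDatasetConfig, make_embryo_dataset, run_pipeline

dataset = make_embryo_dataset(
    SyntheticDatasetConfig(n_cells=20, frac_oscillatory=0.8, seed=7)
)
result = run_pipeline(ExperimentConfig(n_sims=200, seed=1), dataset=dataset)

print(f"{'cell':>8} {'truth':>12} {'call':>16} {'LLR':>8} {'q':>7} {'period (h)':>11}")
for (_, row), truth in zip(result.fits_table.iterrows(), dataset.labels):
    print(
        f"{row.cell_id:>8} {truth:>12} {row.label:>16} "
        f"{row.llr:8.2f} {row.q_value:7.3f} {row.period_h:11.2f}"
    )

print(
    f"\nRecovered oscillatory fraction: {result.classification.proportion_oscillatory:.2f}"
    f" (truth 0.80)."
)
print(
    "A large positive LLR means the quasi-periodic covariance model explains the"
    " trace far better than the aperiodic one; cells with q <= 0.03 are called"
    " oscillatory at a 3% false discovery rate."
)
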