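"""Contrast the noise spectra of slow- and fast-decorrelating populations.

Simulates two aperiodic populations differing only in lengthscale
(control-like alpha = 2 /h versus mutant-like alpha = 15 /h), then compares
aggregate-spectrum coherence and single-cell high-frequency content.
"""

import numpy as np

from ouosc import (
    OUParams,
    TimeGrid,
    aggregate_spectrum,
    coherence,
    high_freq_contribution,
    periodogram,
    sample_ou_trace,
)

grid = TimeGrid(t0=0.0, dt=0.1, n=120)  # 6-min sampling over 12 h

for label, alpha in (("control-like", 2.0), ("mutant-like", 15.0)):
    spectra, hf = [], []
    for i in range(100):
        tr = sample_ou_trace(OUParams(alpha_ou=alpha), grid, seed=1000 + i)
        spectra.append(periodogram(tr))
        hf.append(high_freq_contribution(periodogram(tr, normalization="psd")))
    coh = coherence(aggregate_spectrum(spectra))
    print(
        f"{label:>13} (alpha={alpha:>5.1f}/h): coherence = {coh:5.2f}% of power, "
        f"high-frequency content = {np.mean(hf):5.1f}% of spectral area"
    )

print(
    "\nFaster-decorrelating noise (larger alpha) spreads spectral mass above the"
    " 1.5 cycles/h cutoff and away from any dominant band, so high-frequency"
    " content rises while coherence falls."
)
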