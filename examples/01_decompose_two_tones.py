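"""Decompose a two-tone signal and watch EMD separate the components.

EMD acts as an adaptive filter bank: the fastest oscillation comes out as
IMF1, slower ones follow.  A 32 Hz + 4 Hz mixture at 128 Hz should split
cleanly into its two tones.
"""

import numpy as np

from emdeeg import decompose, make_tone

fs = 128.0
epoch = make_tone([32.0, 4.0], [1.0, 1.0], fs=fs, duration=5.0)
t = np.arange(len(epoch)) / fs
hi = np.sin(2 * np.pi * 32 * t)
lo = np.sin(2 * np.pi * 4 * t)

dec = decompose(epoch)
interior = slice(64, 576)  # central 80%, away from Hilbert/spline edges
print(f"extracted {dec.n_imfs} IMFs from {len(epoch)} samples")
print(f"corr(IMF1, 32 Hz tone) = {np.corrcoef(dec.imfs[0][interior], hi[interior])[0, 1]:.4f}")
print(f"corr(IMF2,  4 Hz tone) = {np.corrcoef(dec.imfs[1][interior], lo[interior])[0, 1]:.4f}")
err = np.linalg.norm(dec.reconstruct() - epoch.samples) / np.linalg.norm(epoch.samples)
print(f"relative reconstruction error = {err:.2e}")
# correlations near 1 mean each IMF isolated one tone; the reconstruction
# error near machine precision shows the decomposition is exact.
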