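"""The classical comparison features on signals with known answers.

Fractal dimension of a straight line is 1; sample entropy of a periodic
sequence is 0; DWT differential entropy assigns a 24 Hz tone to the Beta
band and a 40 Hz tone to the Gamma band.
"""

import numpy as np

from emdeeg import (
    dwt_differential_entropy,
    fractal_dimension_boxcount,
    sample_entropy,
)

print(f"FD(line)      = {fractal_dimension_boxcount(np.linspace(0, 1, 1024)):.3f}  (theory 1.0)")
rng = np.random.default_rng(0)
print(f"FD(noise)     = {fractal_dimension_boxcount(rng.standard_normal(1024)):.3f}  (rough, -> 2)")
print(f"SampEn([1,2]*64) = {sample_entropy(np.tile([1.0, 2.0], 64)):.3f}  (periodic -> 0)")
print(f"SampEn(noise) = {sample_entropy(rng.standard_normal(128)):.3f}")

t = np.arange(640) / 128.0
for f in (24, 40):
    tone = np.sin(2 * np.pi * f * t) + 0.01 * rng.standard_normal(640)
    beta = dwt_differential_entropy(tone, 128.0, "Beta")
    gamma = dwt_differential_entropy(tone, 128.0, "Gamma")
    band = "Beta" if beta > gamma else "Gamma"
    print(f"{f} Hz tone: DE_Beta = {beta:.2f}, DE_Gamma = {gamma:.2f} -> {band}")
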