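"""Analytic signal, instantaneous amplitude and unwrapped phase of an IMF.

The Hilbert transform turns a real band-limited oscillation x(n) into the
complex analytic signal z(n) = x(n) + j y(n) = A(n) exp(j phi(n)).  For a
narrowband IMF, A(n) tracks the instantaneous amplitude and the increments
of the unwrapped phase phi(n) approximate the instantaneous angular
frequency per sample.  The phase is the four-quadrant angle, unwrapped
cumulatively so no consecutive difference exceeds pi in magnitude — without
unwrapping, differences near the branch cut at +/-pi would swamp any
frequency information.

The transform is taken over the whole epoch at once; the edge distortion
inherent to the finite-length Hilbert transform is left in place, so
quantitative statements should be made on interior samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .exceptions import DegenerateSignalError, InvalidInputError

__all__ = ["AnalyticSeries", "analytic_signal"]


@dataclass(frozen=True)
class AnalyticSeries:
    """Real/imaginary parts, envelope amplitude and unwrapped phase (radians)."""

    real_part: np.ndarray
    imag_part: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray

    def __len__(self) -> int:
        return self.real_part.size

    def phase_increments(self) -> np.ndarray:
        """First differences of the unwrapped phase (radians/sample)."""
        return np.diff(self.phase)


def analytic_signal(imf) -> AnalyticSeries:
    """Hilbert-transform an IMF into its analytic representation.

    Parameters
    ----------
    imf
        1-d real array of >= 8 finite samples, approximately zero-mean.

    Raises
    ------
    DegenerateSignalError
        If the input is identically zero (phase undefined).
    """
    x = np.asarray(imf, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise InvalidInputError("analytic_signal needs a 1-d sequence of >= 8 samples")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("input contains non-finite values")
    if np.all(x == 0):
        raise DegenerateSignalError("all-zero signal has undefined phase")
    z = hilbert(x)
    y = np.imag(z)
    amplitude = np.abs(z)
    phase = np.unwrap(np.angle(z))
    return AnalyticSeries(real_part=x, imag_part=y, amplitude=amplitude, phase=phase)
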