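"""Empirical mode decomposition (EMD) by envelope-mean sifting.

EMD decomposes a signal into intrinsic mode functions (IMFs) — oscillatory
components whose extrema and zero-crossing counts differ by at most one and
whose upper/lower envelope mean is (approximately) zero.  The sifting loop
repeatedly subtracts the mean of the cubic-spline envelopes through the
local maxima and minima until the candidate satisfies the IMF conditions,
then peels the IMF off and continues on the remainder.  The decomposition
is exact by construction: the IMFs plus the final residual sum back to the
input sample-for-sample.

The stopping rules are configurable through :class:`SiftConfig`.  Sifting
of one IMF stops when the Cauchy-type ratio
``SD = sum((h_old - h_new)**2) / sum(h_old**2)`` drops below
``sd_threshold`` (default 0.2), when the two-condition IMF test passes, or
after ``max_sift_iterations``.  The outer loop stops when the residual has
fewer than three extrema, is monotone, or ``max_imfs`` have been extracted.
Spline envelopes are stabilised at the ends by mirroring the two extrema
nearest each boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import InvalidInputError, NotEnoughExtremaError

__all__ = [
    "Epoch",
    "SiftConfig",
    "IMFDecomposition",
    "find_extrema",
    "envelope_mean",
    "is_imf",
    "sift_once",
    "decompose",
    "count_zero_crossings",
]

MIN_EPOCH_LENGTH = 8


@dataclass(frozen=True)
class Epoch:
    """A single channel's fixed-rate sample sequence.

    Parameters
    ----------
    samples
        Real-valued signal (microvolts or arbitrary units).
    sampling_rate
        Samples per second, > 0.
    channel_label
        Optional 10-20 system electrode name.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_label: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < MIN_EPOCH_LENGTH:
            raise InvalidInputError(
                f"epoch needs >= {MIN_EPOCH_LENGTH} samples in one dimension, "
                f"got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("epoch contains non-finite samples")
        if not self.sampling_rate > 0:
            raise InvalidInputError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class SiftConfig:
    """Stopping rules and boundary treatment for the sifting loop."""

    sd_threshold: float = 0.2
    max_sift_iterations: int = 100
    max_imfs: int = 5
    boundary_mode: str = "mirror_extrema"
    zero_mean_tol: float = 0.05

    def __post_init__(self) -> None:
        if not self.sd_threshold > 0:
            raise InvalidInputError("sd_threshold must be > 0")
        if self.max_sift_iterations < 1 or self.max_imfs < 1:
            raise InvalidInputError("iteration/IMF caps must be >= 1")
        if self.boundary_mode != "mirror_extrema":
            raise InvalidInputError(f"unknown boundary_mode {self.boundary_mode!r}")


@dataclass
class IMFDecomposition:
    """Ordered IMFs plus residual for one epoch; fastest oscillation first."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.source_length == 0:
            self.source_length = self.residual.size

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs and the residual (equals the source signal)."""
        total = self.residual.copy()
        for imf in self.imfs:
            total += imf
        return total


def _validate_series(samples, min_len: int = 3) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < min_len:
        raise InvalidInputError(f"need a 1-d sequence of >= {min_len} samples")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("sequence contains non-finite values")
    return x


def find_extrema(samples):
    """Locate interior local maxima and minima, one per plateau.

    Flat runs of equal values that stand above (below) both neighbours
    contribute exactly one maximum (minimum) at the floor-midpoint index of
    the run.  Runs touching either end of the sequence are not extrema.

    Returns
    -------
    (max_idx, max_val, min_idx, min_val)
        Strictly increasing integer index arrays and the values there.
    """
    x = _validate_series(samples)
    # compress runs of equal consecutive values
    change = np.flatnonzero(np.diff(x) != 0)
    run_starts = np.concatenate(([0], change + 1))
    run_ends = np.concatenate((change, [x.size - 1]))  # inclusive
    max_idx, min_idx = [], []
    for k in range(1, run_starts.size - 1):
        v = x[run_starts[k]]
        left = x[run_ends[k - 1]]
        right = x[run_starts[k + 1]]
        mid = (run_starts[k] + run_ends[k]) // 2
        if v > left and v > right:
            max_idx.append(mid)
        elif v < left and v < right:
            min_idx.append(mid)
    max_idx = np.asarray(max_idx, dtype=int)
    min_idx = np.asarray(min_idx, dtype=int)
    return max_idx, x[max_idx], min_idx, x[min_idx]


def count_zero_crossings(samples) -> int:
    """Sign changes of the nonzero samples; exact zeros are skipped."""
    x = np.asarray(samples, dtype=float)
    signs = np.sign(x[x != 0])
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs) != 0))


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int):
    """Mirror up to two extrema nearest each boundary across it."""
    left_k = min(2, idx.size)
    right_k = min(2, idx.size)
    left_idx = -idx[:left_k][::-1]
    left_val = val[:left_k][::-1]
    right_idx = 2 * (n - 1) - idx[-right_k:][::-1]
    right_val = val[-right_k:][::-1]
    ext_idx = np.concatenate((left_idx, idx, right_idx))
    ext_val = np.concatenate((left_val, val, right_val))
    keep = np.concatenate(([True], np.diff(ext_idx) > 0))
    return ext_idx[keep], ext_val[keep]


def envelope_mean(samples, boundary_mode: str = "mirror_extrema"):
    """Mean of the cubic-spline upper and lower envelopes, m(t).

    Extrema are mirrored across each boundary before fitting so that the
    splines do not swing wildly at the ends.  Raises
    :class:`NotEnoughExtremaError` when the signal has no interior maxima
    or minima to interpolate (a residual-like signal).
    """
    if boundary_mode != "mirror_extrema":
        raise InvalidInputError(f"unknown boundary_mode {boundary_mode!r}")
    x = _validate_series(samples)
    max_idx, max_val, min_idx, min_val = find_extrema(x)
    if max_idx.size < 1 or min_idx.size < 1:
        raise NotEnoughExtremaError(
            f"need interior maxima and minima, found {max_idx.size} maxima "
            f"and {min_idx.size} minima"
        )
    n = x.size
    t = np.arange(n)
    up_i, up_v = _mirror_extend(max_idx, max_val, n)
    lo_i, lo_v = _mirror_extend(min_idx, min_val, n)
    if up_i.size < 2 or lo_i.size < 2:
        raise NotEnoughExtremaError("fewer than 2 envelope knots after extension")
    e_max = CubicSpline(up_i, up_v)(t)
    e_min = CubicSpline(lo_i, lo_v)(t)
    return 0.5 * (e_max + e_min)


def is_imf(samples, zero_mean_tol: float = 0.05) -> bool:
    """Two-condition admissibility test for an intrinsic mode function.

    True iff the counts of extrema and zero crossings differ by at most one
    and the envelope mean is everywhere small relative to the signal peak
    (``max |m| <= zero_mean_tol * max |x|``).  Signals whose envelopes
    cannot be built are not IMFs.
    """
    x = _validate_series(samples)
    max_idx, _, min_idx, _ = find_extrema(x)
    n_ext = max_idx.size + min_idx.size
    n_zc = count_zero_crossings(x)
    if abs(n_ext - n_zc) > 1:
        return False
    try:
        m = envelope_mean(x)
    except NotEnoughExtremaError:
        return False
    peak = np.max(np.abs(x))
    if peak == 0:
        return False
    return bool(np.max(np.abs(m)) <= zero_mean_tol * peak)


def sift_once(h_old, boundary_mode: str = "mirror_extrema"):
    """One sifting step: subtract the envelope mean, h_new = h_old - m."""
    h = _validate_series(h_old)
    return h - envelope_mean(h, boundary_mode)


def _is_terminal_residual(x: np.ndarray) -> bool:
    diffs = np.diff(x)
    if np.all(diffs >= 0) or np.all(diffs <= 0):
        return True
    max_idx, _, min_idx, _ = find_extrema(x)
    return max_idx.size + min_idx.size < 3


def decompose(epoch, config: SiftConfig | None = None) -> IMFDecomposition:
    """Decompose an epoch into IMFs and a residual.

    Parameters
    ----------
    epoch
        An :class:`Epoch` or a plain 1-d array of >= 8 finite samples.
    config
        Sifting configuration; defaults to :class:`SiftConfig`.

    Returns
    -------
    IMFDecomposition
        IMFs ordered fastest-oscillating first; ``sum(imfs) + residual``
        reproduces the input to floating-point accuracy.
    """
    if config is None:
        config = SiftConfig()
    x = epoch.samples if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    if x.ndim != 1 or x.size < MIN_EPOCH_LENGTH:
        raise InvalidInputError(f"epoch must hold >= {MIN_EPOCH_LENGTH} samples")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("epoch contains non-finite samples")

    residual = x.astype(float).copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < config.max_imfs and not _is_terminal_residual(residual):
        h = residual.copy()
        for _ in range(config.max_sift_iterations):
            try:
                m = envelope_mean(h, config.boundary_mode)
            except NotEnoughExtremaError:
                break
            h_new = h - m
            denom = float(np.sum(h * h))
            sd = float(np.sum(m * m)) / denom if denom > 0 else 0.0
            h = h_new
            if sd <= config.sd_threshold or is_imf(h, config.zero_mean_tol):
                break
        imfs.append(h)
        residual = residual - h
    return IMFDecomposition(imfs=imfs, residual=residual, source_length=x.size)
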