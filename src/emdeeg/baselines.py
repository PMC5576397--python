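"""Classical comparison features: fractal dimension, SampEn, DWT entropy.

These are the time-domain and time-frequency features the EMD pipeline is
benchmarked against:

* Box-counting fractal dimension of the signal's graph, normalised to the
  unit square, with dyadic box sizes 2^-1 .. 2^-6 and a least-squares fit
  of log N(eps) against log(1/eps).
* Sample entropy SampEn(m, r, N) with the standard physiological settings
  m = 2, r = 0.2 * sd, Chebyshev distance, self-matches excluded; on
  segments longer than the window N = 128, SampEn is averaged over
  non-overlapping windows.
* Differential entropy of the Beta (16-32 Hz) and Gamma (32-64 Hz) DWT
  subbands using a db4 wavelet: at 128 Hz sampling, detail level 1 covers
  32-64 Hz and level 2 covers 16-32 Hz.  The entropy uses the Gaussian
  closed form (1/2) log(2 pi e sigma^2) of the band's detail
  coefficients.  Note that 4-45 Hz band-limited recordings only populate
  the lower third of the nominal Gamma band; the band is identified by
  filter level, not by its nominal range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .exceptions import DegenerateSignalError, InvalidInputError

__all__ = [
    "BaselineConfig",
    "fractal_dimension_boxcount",
    "sample_entropy",
    "dwt_differential_entropy",
    "baseline_feature_table",
    "SAMPEN_INF",
]

#: Sentinel for SampEn when no (m+1)-template matches exist (A = 0).
SAMPEN_INF = float("inf")

_BAND_LEVEL = {"Beta": 2, "Gamma": 1}  # db4 detail levels at fs = 128 Hz


@dataclass(frozen=True)
class BaselineConfig:
    sampen_m: int = 2
    sampen_r: float = 0.2
    sampen_window: int = 128
    fd_box_scales: tuple[float, ...] = tuple(2.0 ** -k for k in range(1, 7))
    dwt_wavelet: str = "db4"
    bands: tuple[str, ...] = ("Beta", "Gamma")

    def __post_init__(self) -> None:
        if self.sampen_m < 1:
            raise InvalidInputError("sampen_m must be >= 1")
        if not 0 < self.sampen_r < 1:
            raise InvalidInputError("sampen_r is a fraction of sd in (0, 1)")
        if len(self.fd_box_scales) < 2:
            raise InvalidInputError("need >= 2 box scales")


def fractal_dimension_boxcount(series, scales=None) -> float:
    """Box-counting dimension of the curve's graph in the unit square.

    The series is mapped onto [0, 1] x [0, 1]; for each box size eps, the
    x-axis is cut into columns of width eps and the boxes covering the
    curve in each column are counted from the column's value range.  The
    dimension is the least-squares slope of log N vs log(1/eps).  A
    constant series is a horizontal line, dimension 1.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 64:
        raise InvalidInputError("fractal dimension needs >= 64 samples")
    if scales is None:
        scales = BaselineConfig().fd_box_scales
    scales = np.asarray(sorted(scales, reverse=True), dtype=float)
    if scales.size < 3:
        raise InvalidInputError("need >= 3 box scales for a stable slope")
    rng = np.ptp(x)
    if rng == 0:
        return 1.0
    ynorm = (x - x.min()) / rng
    tnorm = np.linspace(0.0, 1.0, x.size)
    counts = []
    for eps in scales:
        n_cols = int(round(1.0 / eps))
        col = np.minimum((tnorm / eps).astype(int), n_cols - 1)
        total = 0
        for c in range(n_cols):
            inside = col == c
            if not inside.any():
                continue
            lo = ynorm[inside].min()
            hi = ynorm[inside].max()
            # clamp the top edge (y = 1) into the last box row
            hi_idx = min(int(hi / eps), n_cols - 1)
            lo_idx = min(int(lo / eps), n_cols - 1)
            total += hi_idx - lo_idx + 1
        counts.append(total)
    slope, _ = np.polyfit(np.log(1.0 / scales), np.log(counts), 1)
    return float(slope)


def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Chebyshev template-match counts (B for length m, A for m+1)."""
    n = x.size
    # conventional SampEn compares the same number of templates (n - m) for
    # both lengths so that A/B is a proper conditional probability
    n_t = n - m
    templ_m = np.lib.stride_tricks.sliding_window_view(x, m)[:n_t]
    templ_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    b = 0
    a = 0
    for i in range(n_t - 1):
        d_m = np.max(np.abs(templ_m[i + 1 :] - templ_m[i]), axis=1)
        b += int(np.count_nonzero(d_m <= r))
        d_m1 = np.max(np.abs(templ_m1[i + 1 :] - templ_m1[i]), axis=1)
        a += int(np.count_nonzero(d_m1 <= r))
    return a, b


def sample_entropy(series, m: int = 2, r_frac: float = 0.2) -> float:
    """SampEn(m, r) with Chebyshev distance and self-matches excluded.

    r = r_frac * sd(series).  Returns -log(A/B) where B counts m-length
    template matches and A counts (m+1)-length matches over the same
    template set.  When no (m+1)-match exists the entropy is unbounded and
    the +inf sentinel is returned.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2 * (m + 1):
        raise InvalidInputError(f"sample entropy needs >= {2 * (m + 1)} samples")
    sd = x.std()
    if sd == 0:
        raise DegenerateSignalError("zero-variance series has undefined SampEn")
    a, b = _sampen_counts(x, m, r_frac * sd)
    if b == 0 or a == 0:
        return SAMPEN_INF
    return float(-math.log(a / b))


def windowed_sample_entropy(
    series, m: int = 2, r_frac: float = 0.2, window: int = 128
) -> float:
    """Mean SampEn over non-overlapping windows (finite windows only)."""
    x = np.asarray(series, dtype=float)
    n_win = x.size // window
    if n_win == 0:
        raise InvalidInputError(f"series shorter than one {window}-sample window")
    vals = []
    for k in range(n_win):
        try:
            v = sample_entropy(x[k * window : (k + 1) * window], m, r_frac)
        except DegenerateSignalError:
            continue
        if math.isfinite(v):
            vals.append(v)
    return float(np.mean(vals)) if vals else SAMPEN_INF


def dwt_differential_entropy(
    series, fs: float = 128.0, band: str = "Beta", wavelet: str = "db4"
) -> float:
    """Differential entropy of a db4-DWT subband, Gaussian closed form.

    DE = (1/2) log(2 pi e sigma^2) where sigma^2 is the variance of the
    band's detail coefficients.  Requires fs = 128 Hz so the dyadic detail
    levels line up with the nominal Beta/Gamma bands.
    """
    x = np.asarray(series, dtype=float)
    if band not in _BAND_LEVEL:
        raise InvalidInputError(f"band must be one of {sorted(_BAND_LEVEL)}")
    if fs != 128.0:
        raise InvalidInputError("band-to-level mapping assumes fs = 128 Hz")
    level = _BAND_LEVEL[band]
    if x.size < 2**level * 8:
        raise InvalidInputError("series too short for the requested band level")
    coeffs = pywt.wavedec(x, wavelet, level=level)
    detail = coeffs[1]  # detail at the deepest level of this decomposition
    var = float(np.var(detail))
    if var <= 0:
        raise DegenerateSignalError("zero-variance subband has DE of -inf")
    return 0.5 * math.log(2.0 * math.pi * math.e * var)


def baseline_feature_table(
    dataset,
    method: str,
    window_sec: float = 5.0,
    channels=None,
    config: BaselineConfig | None = None,
) -> pd.DataFrame:
    """Per-segment baseline features in the same table layout as the EMD features.

    ``method`` is one of ``fd``, ``sampen``, ``dwt-de-beta``, ``dwt-de-gamma``.
    One feature per channel per segment; column names keep the
    ``"<channel>|imf0|<method>"`` pattern so the evaluation code treats the
    table uniformly.
    """
    from .io import binarize_rating, segment_trial

    if config is None:
        config = BaselineConfig()
    methods = {"fd", "sampen", "dwt-de-beta", "dwt-de-gamma"}
    if method not in methods:
        raise InvalidInputError(f"method must be one of {sorted(methods)}")
    labels = list(channels) if channels is not None else list(dataset.channel_labels)

    def one(sig: np.ndarray) -> float:
        if method == "fd":
            return fractal_dimension_boxcount(sig, config.fd_box_scales)
        if method == "sampen":
            v = windowed_sample_entropy(
                sig, config.sampen_m, config.sampen_r, config.sampen_window
            )
            return v if math.isfinite(v) else 10.0  # flagged ceiling for no-match
        band = "Beta" if method.endswith("beta") else "Gamma"
        return dwt_differential_entropy(sig, dataset.sampling_rate, band,
                                        config.dwt_wavelet)

    rows, meta = [], []
    ch_index = [list(dataset.channel_labels).index(c) for c in labels]
    for trial_idx, trial in enumerate(dataset.trials):
        for seg_idx, seg in enumerate(
            segment_trial(trial.signal, window_sec, dataset.sampling_rate)
        ):
            rows.append([one(seg[i]) for i in ch_index])
            meta.append(
                {
                    "subject": dataset.subject_id,
                    "trial": trial_idx,
                    "segment": seg_idx,
                    "valence_rating": trial.valence_rating,
                    "arousal_rating": trial.arousal_rating,
                    "valence_label": binarize_rating(trial.valence_rating),
                    "arousal_label": binarize_rating(trial.arousal_rating),
                }
            )
    cols = [f"{c}|imf0|{method}" for c in labels]
    return pd.concat(
        [pd.DataFrame(rows, columns=cols), pd.DataFrame(meta)], axis=1
    )
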