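"""Per-IMF features: first differences in time and phase, normalized energy.

Each IMF of an EEG segment is summarised by three scalars spanning the
time, frequency and energy domains:

* ``D_t`` — mean absolute first difference of the IMF samples, the
  intensity of change in the time domain.
* ``D_p`` — mean absolute first difference of the IMF's unwrapped analytic
  phase (radians/sample); for a narrowband component this is the mean
  instantaneous angular frequency per sample.
* ``log(E_norm)`` — natural log of the IMF's energy divided by the raw
  segment's energy, the weight of the oscillation component.

Both difference features use the magnitude of the increments: a signed mean
telescopes to (last - first)/(N - 1) and carries no intensity information.

``extract_features`` assembles one flat vector per multichannel segment,
ordered channel-major, then IMF level ascending, then (D_t, D_p,
log_E_norm) — a deterministic layout that downstream tables and
classifiers rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emd import SiftConfig, decompose
from .exceptions import DegenerateSignalError, InvalidInputError, MissingChannelError
from .phase import analytic_signal

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "first_difference",
    "phase_first_difference",
    "normalized_energy",
    "log_normalized_energy",
    "extract_features",
    "feature_table",
]

log = logging.getLogger(__name__)

FEATURE_NAMES = ("D_t", "D_p", "log_E_norm")

#: Energy-ratio floor used when an IMF level is absent from a decomposition;
#: log(1e-12) ~ -27.6 is far outside the physiological range and flags the fill.
ENERGY_FLOOR = 1e-12


@dataclass(frozen=True)
class FeatureVector:
    """Flat feature values keyed by (channel_label, imf_level, feature_name)."""

    values: np.ndarray
    index: tuple[tuple[str, int, str], ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.index):
            raise InvalidInputError("values and index lengths differ")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(
            self.index, names=["channel", "imf_level", "feature"]
        )
        return pd.Series(self.values, index=idx)


def first_difference(series) -> float:
    """Mean absolute first difference, D_t = mean |x(n+1) - x(n)|."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidInputError("first_difference needs >= 2 samples")
    return float(np.mean(np.abs(np.diff(x))))


def phase_first_difference(phase) -> float:
    """Mean absolute first difference of an unwrapped phase, radians/sample."""
    p = np.asarray(phase, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise InvalidInputError("phase_first_difference needs >= 2 samples")
    return float(np.mean(np.abs(np.diff(p))))


def normalized_energy(imf, source) -> float:
    """IMF energy over raw-segment energy, sum(imf^2)/sum(source^2)."""
    a = np.asarray(imf, dtype=float)
    s = np.asarray(source, dtype=float)
    if a.shape != s.shape:
        raise InvalidInputError("imf and source must share a shape")
    denom = float(np.sum(s * s))
    if denom <= 0:
        raise DegenerateSignalError("source signal has zero energy")
    return float(np.sum(a * a)) / denom


def log_normalized_energy(e_norm: float) -> float:
    """Natural log of the normalized energy, floored at 1e-12."""
    if e_norm <= 0:
        log.warning("non-positive E_norm %g clamped to %g", e_norm, ENERGY_FLOOR)
        e_norm = ENERGY_FLOOR
    return float(np.log(e_norm))


def _feature_triple(imf: np.ndarray, source: np.ndarray) -> tuple[float, float, float]:
    d_t = first_difference(imf)
    d_p = phase_first_difference(analytic_signal(imf).phase)
    e = log_normalized_energy(normalized_energy(imf, source))
    return d_t, d_p, e


def extract_features(
    signals,
    channel_labels,
    channels=None,
    imf_levels=(1, 2, 3, 4, 5),
    config: SiftConfig | None = None,
) -> FeatureVector:
    """Feature vector for one multichannel segment.

    Parameters
    ----------
    signals
        2-d array, channels x samples.
    channel_labels
        Label for each row of ``signals``.
    channels
        Subset of labels to use, in the dataset's channel order; ``None``
        keeps all channels.
    imf_levels
        1-based IMF levels to summarise.  Levels beyond what the
        decomposition yields are filled with ``(0, 0, log(1e-12))``.
    config
        Sifting configuration; ``max_imfs`` is raised to cover the deepest
        requested level if needed.
    """
    sig = np.atleast_2d(np.asarray(signals, dtype=float))
    channel_labels = list(channel_labels)
    if sig.shape[0] != len(channel_labels):
        raise InvalidInputError(
            f"{sig.shape[0]} signal rows but {len(channel_labels)} labels"
        )
    if sig.shape[1] < 8:
        raise InvalidInputError("segment must hold >= 8 samples")
    imf_levels = sorted(int(v) for v in imf_levels)
    if imf_levels and imf_levels[0] < 1:
        raise InvalidInputError("IMF levels are 1-based")
    if config is None:
        config = SiftConfig(max_imfs=max(imf_levels))
    elif config.max_imfs < max(imf_levels):
        config = SiftConfig(
            sd_threshold=config.sd_threshold,
            max_sift_iterations=config.max_sift_iterations,
            max_imfs=max(imf_levels),
            boundary_mode=config.boundary_mode,
            zero_mean_tol=config.zero_mean_tol,
        )

    if channels is None:
        selected = channel_labels
    else:
        selected = list(channels)
        missing = [c for c in selected if c not in channel_labels]
        if missing:
            raise MissingChannelError(f"channels not in recording: {missing}")
        # keep dataset order regardless of the order the caller listed them
        selected = [c for c in channel_labels if c in set(selected)]

    values: list[float] = []
    index: list[tuple[str, int, str]] = []
    for label in selected:
        raw = sig[channel_labels.index(label)]
        dec = decompose(raw, config)
        for level in imf_levels:
            if level <= dec.n_imfs:
                d_t, d_p, e = _feature_triple(dec.imfs[level - 1], raw)
            else:
                log.debug("channel %s lacks IMF level %d; filling", label, level)
                d_t, d_p, e = 0.0, 0.0, float(np.log(ENERGY_FLOOR))
            for name, val in zip(FEATURE_NAMES, (d_t, d_p, e)):
                values.append(val)
                index.append((label, level, name))
    return FeatureVector(values=np.asarray(values), index=tuple(index))


def feature_table(
    dataset,
    window_sec: float = 5.0,
    channels=None,
    imf_levels=(1, 2, 3, 4, 5),
    config: SiftConfig | None = None,
) -> pd.DataFrame:
    """Segment every trial of a :class:`~emdeeg.io.TrialDataset` and extract features.

    Returns a DataFrame with one row per 5-s segment: the flattened feature
    columns (named ``"<channel>|imf<level>|<feature>"``) plus bookkeeping
    columns ``subject``, ``trial``, ``segment``, ``valence_rating``,
    ``arousal_rating``, ``valence_label``, ``arousal_label``.
    """
    from .io import binarize_rating, segment_trial  # deferred: io imports nothing back

    rows = []
    meta = []
    col_names: list[str] | None = None
    for trial_idx, trial in enumerate(dataset.trials):
        segments = segment_trial(trial.signal, window_sec, dataset.sampling_rate)
        for seg_idx, seg in enumerate(segments):
            fv = extract_features(
                seg, dataset.channel_labels, channels, imf_levels, config
            )
            if col_names is None:
                col_names = [f"{c}|imf{l}|{f}" for c, l, f in fv.index]
            rows.append(fv.values)
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
    if not rows:
        raise InvalidInputError("dataset produced no segments")
    table = pd.DataFrame(np.vstack(rows), columns=col_names)
    return pd.concat([table, pd.DataFrame(meta)], axis=1)
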