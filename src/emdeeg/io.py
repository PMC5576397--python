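"""Dataset containers and readers: DEAP-layout files and delimited recordings.

The unit of analysis is a :class:`TrialDataset`: one subject's trials, each
a channels x samples array at a fixed sampling rate with self-assessed
valence and arousal ratings on the 1-9 scale.  Ratings binarize at 5
(low < 5 <= high), trials segment into non-overlapping fixed-length
windows anchored at the trial start, and leftover tail samples are dropped.

Two on-disk layouts are supported:

* The DEAP preprocessed per-subject layout — ``data`` of shape
  (40 trials, 40 channels, 8064 samples at 128 Hz) and ``labels`` of shape
  (40, 4).  Only the first 32 rows (the EEG electrodes, Geneva order) are
  kept and the 3-s pretrial baseline (384 samples) is dropped, leaving
  60-s trials of 7680 samples.  Readable from ``.npz``/``.npy`` archives
  or the original pickled ``.dat`` files.
* A generic plain-text layout — one delimited file per trial (rows =
  samples, columns = channels, header = channel labels) next to a
  ``ratings.csv`` sidecar (trial, valence, arousal) and a one-line
  ``meta.csv`` holding the sampling rate.  Writing then reading a dataset
  through this layout is lossless for float64 samples.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, InvalidInputError

__all__ = [
    "DEAP_CHANNELS",
    "Trial",
    "TrialDataset",
    "binarize_rating",
    "segment_trial",
    "read_deap_subject",
    "write_dataset",
    "read_dataset",
]

log = logging.getLogger(__name__)

#: The 32 EEG electrodes of the DEAP preprocessed layout, in file order
#: (Geneva ordering, international 10-20 names).
DEAP_CHANNELS = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Column order of the DEAP label array as documented by the dataset
#: distributors (the in-paper prose lists the rating scales in a different
#: order; the file layout is authoritative and remappable via ``label_order``).
DEAP_LABEL_ORDER = ("valence", "arousal", "dominance", "liking")


@dataclass(frozen=True)
class Trial:
    """One trial: channels x samples signal plus its two affective ratings."""

    signal: np.ndarray
    valence_rating: float
    arousal_rating: float

    def __post_init__(self) -> None:
        sig = np.atleast_2d(np.asarray(self.signal, dtype=float))
        object.__setattr__(self, "signal", sig)
        for r in (self.valence_rating, self.arousal_rating):
            if not 1.0 <= r <= 9.0:
                raise InvalidInputError(f"rating {r} outside [1, 9]")


@dataclass(frozen=True)
class TrialDataset:
    """One subject's trials, channel labels and sampling rate."""

    subject_id: str
    trials: tuple[Trial, ...]
    channel_labels: tuple[str, ...]
    sampling_rate: float = 128.0

    def __post_init__(self) -> None:
        trials = tuple(self.trials)
        object.__setattr__(self, "trials", trials)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        n_ch = len(self.channel_labels)
        for t in trials:
            if t.signal.shape[0] != n_ch:
                raise InvalidInputError(
                    f"trial has {t.signal.shape[0]} channels, expected {n_ch}"
                )
        if not self.sampling_rate > 0:
            raise InvalidInputError("sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def binarize_rating(rating: float) -> str:
    """Binary affect label: ``"low"`` iff rating < 5, ``"high"`` iff >= 5."""
    if not 1.0 <= rating <= 9.0:
        raise InvalidInputError(f"rating {rating} outside [1, 9]")
    return "high" if rating >= 5.0 else "low"


def segment_trial(signal, window_sec: float, fs: float) -> list[np.ndarray]:
    """Cut a channels x samples trial into non-overlapping windows.

    Windows are anchored at the trial start; a tail shorter than one window
    is dropped.  A window longer than the trial yields an empty list.
    """
    sig = np.atleast_2d(np.asarray(signal, dtype=float))
    win = int(round(window_sec * fs))
    if win <= 0:
        raise InvalidInputError("window must span at least one sample")
    n = sig.shape[1]
    if win > n:
        log.warning("window of %d samples exceeds trial length %d", win, n)
        return []
    return [sig[:, k * win : (k + 1) * win] for k in range(n // win)]


def _load_deap_arrays(path: Path):
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as archive:
            if "data" not in archive or "labels" not in archive:
                raise FormatError(f"{path} lacks 'data'/'labels' arrays")
            return archive["data"], archive["labels"]
    if path.suffix == ".dat":
        with open(path, "rb") as fh:
            payload = pickle.load(fh, encoding="latin1")
        try:
            return np.asarray(payload["data"]), np.asarray(payload["labels"])
        except (TypeError, KeyError) as exc:
            raise FormatError(f"{path} is not a DEAP pickled dict") from exc
    raise FormatError(f"unsupported DEAP file type {path.suffix!r}")


def read_deap_subject(
    path,
    subject_id: str | None = None,
    label_order=DEAP_LABEL_ORDER,
    drop_baseline: bool = True,
) -> TrialDataset:
    """Read one subject in the DEAP preprocessed layout.

    Parameters
    ----------
    path
        ``.npz`` (arrays ``data``, ``labels``) or pickled ``.dat`` file.
    label_order
        Names of the four label columns, by default the documented
        (valence, arousal, dominance, liking); override if a derived file
        reordered them.
    drop_baseline
        Drop the 3-s (384-sample) pretrial baseline when trials arrive at
        8064 samples; 7680-sample trials are accepted as already trimmed.
    """
    path = Path(path)
    data, labels = _load_deap_arrays(path)
    if data.ndim != 3 or data.shape[0] != 40 or data.shape[1] < 32:
        raise FormatError(
            f"expected data shaped (40, >=32 channels, samples), found {data.shape}"
        )
    if labels.shape != (40, 4):
        raise FormatError(f"expected labels shaped (40, 4), found {labels.shape}")
    if "valence" not in label_order or "arousal" not in label_order:
        raise InvalidInputError("label_order must name 'valence' and 'arousal'")
    v_col = list(label_order).index("valence")
    a_col = list(label_order).index("arousal")

    n_samp = data.shape[2]
    if drop_baseline and n_samp == 8064:
        data = data[:, :, 384:]
    elif n_samp not in (8064, 7680):
        raise FormatError(
            f"expected 8064 (63 s) or 7680 (60 s) samples per trial, found {n_samp}"
        )
    trials = tuple(
        Trial(
            signal=data[i, :32, :],
            valence_rating=float(labels[i, v_col]),
            arousal_rating=float(labels[i, a_col]),
        )
        for i in range(40)
    )
    return TrialDataset(
        subject_id=subject_id or path.stem,
        trials=trials,
        channel_labels=DEAP_CHANNELS,
        sampling_rate=128.0,
    )


def write_dataset(dataset: TrialDataset, directory) -> Path:
    """Write a dataset to the plain-text layout (one CSV per trial + sidecars)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, trial in enumerate(dataset.trials):
        frame = pd.DataFrame(trial.signal.T, columns=list(dataset.channel_labels))
        # %.17g round-trips float64 exactly
        frame.to_csv(directory / f"trial_{i:03d}.csv", index=False, float_format="%.17g")
    ratings = pd.DataFrame(
        {
            "trial": range(dataset.n_trials),
            "valence": [t.valence_rating for t in dataset.trials],
            "arousal": [t.arousal_rating for t in dataset.trials],
        }
    )
    ratings.to_csv(directory / "ratings.csv", index=False, float_format="%.17g")
    pd.DataFrame(
        {"subject_id": [dataset.subject_id], "sampling_rate": [dataset.sampling_rate]}
    ).to_csv(directory / "meta.csv", index=False, float_format="%.17g")
    return directory


def read_dataset(directory) -> TrialDataset:
    """Read a dataset written by :func:`write_dataset` (lossless round trip)."""
    directory = Path(directory)
    meta_path = directory / "meta.csv"
    ratings_path = directory / "ratings.csv"
    if not meta_path.exists() or not ratings_path.exists():
        raise FormatError(f"{directory} lacks meta.csv/ratings.csv sidecars")
    meta = pd.read_csv(meta_path)
    ratings = pd.read_csv(
        ratings_path, float_precision="round_trip"
    ).sort_values("trial")
    trial_files = sorted(directory.glob("trial_*.csv"))
    if len(trial_files) != len(ratings):
        raise FormatError(
            f"{len(trial_files)} trial files but {len(ratings)} rating rows"
        )
    channel_labels: tuple[str, ...] | None = None
    trials = []
    for path, (_, row) in zip(trial_files, ratings.iterrows()):
        # the exact-round-trip parser keeps write->read lossless for float64
        frame = pd.read_csv(path, float_precision="round_trip")
        if channel_labels is None:
            channel_labels = tuple(frame.columns)
        elif tuple(frame.columns) != channel_labels:
            raise FormatError(f"{path} channel header differs from first trial")
        trials.append(
            Trial(
                signal=frame.to_numpy(dtype=float).T,
                valence_rating=float(row["valence"]),
                arousal_rating=float(row["arousal"]),
            )
        )
    return TrialDataset(
        subject_id=str(meta["subject_id"].iloc[0]),
        trials=tuple(trials),
        channel_labels=channel_labels or (),
        sampling_rate=float(meta["sampling_rate"].iloc[0]),
    )
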