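"""Electrode ranking by two-class Fisher distance.

For one feature on one channel, the Fisher distance between the high and
low affect classes is the classical separability ratio

    J = (mu_1 - mu_2)^2 / (sigma_1^2 + sigma_2^2)

with unbiased sample variances — squared between-class scatter over summed
within-class scatter.  Channels whose feature distributions separate the
classes well score high; ranking them identifies the informative
electrodes.  Degenerate (near-zero) within-class variance is floored at
1e-12 so rankings stay total; such scores are flagged with a warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = ["PAPER8_CHANNELS", "fisher_distance", "rank_channels"]

log = logging.getLogger(__name__)

#: The eight-electrode preset used for channel-reduced classification
#: (prefrontal, lateral frontal, temporal and lateral parietal sites).
PAPER8_CHANNELS = ("Fp1", "Fp2", "F7", "F8", "T7", "T8", "P7", "P8")

_VAR_FLOOR = 1e-12


def fisher_distance(class_a, class_b) -> float:
    """Two-class Fisher criterion (mean_a - mean_b)^2 / (var_a + var_b)."""
    a = np.asarray(class_a, dtype=float)
    b = np.asarray(class_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each class needs >= 2 samples")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidInputError("class values must be finite")
    num = (a.mean() - b.mean()) ** 2
    denom = a.var(ddof=1) + b.var(ddof=1)
    if denom < _VAR_FLOOR:
        log.warning(
            "within-class variance %g below floor; Fisher score capped", denom
        )
        denom = _VAR_FLOOR
    return float(num / denom)


def rank_channels(
    table: pd.DataFrame,
    feature_name: str,
    dimension: str = "valence",
    imf_level: int = 1,
) -> pd.DataFrame:
    """Rank channels by Fisher distance of one feature at one IMF level.

    Parameters
    ----------
    table
        Feature table from :func:`emdeeg.features.feature_table`: columns
        ``"<channel>|imf<level>|<feature>"`` plus ``<dimension>_label``.
    feature_name
        One of ``D_t``, ``D_p``, ``log_E_norm``.
    dimension
        ``valence`` or ``arousal``.

    Returns
    -------
    DataFrame with columns (channel, feature, score, rank), sorted by
    descending score; ties keep the table's channel order.
    """
    label_col = f"{dimension}_label"
    if label_col not in table.columns:
        raise InvalidInputError(f"table lacks column {label_col!r}")
    labels = table[label_col].to_numpy()
    high = labels == "high"
    low = labels == "low"
    if high.sum() < 2 or low.sum() < 2:
        raise InvalidInputError("both classes need >= 2 samples for Fisher ranking")

    suffix = f"|imf{imf_level}|{feature_name}"
    cols = [c for c in table.columns if c.endswith(suffix)]
    if not cols:
        raise InvalidInputError(
            f"no columns for feature {feature_name!r} at IMF level {imf_level}"
        )
    records = []
    for col in cols:
        values = table[col].to_numpy(dtype=float)
        records.append(
            {
                "channel": col.split("|", 1)[0],
                "feature": feature_name,
                "score": fisher_distance(values[high], values[low]),
            }
        )
    ranked = pd.DataFrame(records)
    # stable sort: ties keep the dataset channel order
    ranked = ranked.sort_values("score", ascending=False, kind="stable")
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked.reset_index(drop=True)


def aggregate_ranks(per_subject_rankings: list[pd.DataFrame], top_k: int = 8) -> pd.DataFrame:
    """Average each channel's rank across subjects and return the top-k.

    This mirrors the cross-subject electrode-selection workflow: channels
    that rank consistently high across subjects are preferred.
    """
    if not per_subject_rankings:
        raise InvalidInputError("need at least one subject ranking")
    merged = pd.concat(
        [r[["channel", "rank"]] for r in per_subject_rankings], ignore_index=True
    )
    mean_rank = (
        merged.groupby("channel", sort=False)["rank"].mean().rename("mean_rank")
    )
    out = mean_rank.sort_values(kind="stable").reset_index()
    return out.head(top_k)
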