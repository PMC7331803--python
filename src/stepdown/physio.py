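"""Electrodermal and perceived-fear summaries, and fear-group classification.

The electrodermal signal is summarized as its arithmetic mean over the
entire condition, in microsiemens, with no preprocessing (no filtering or
phasic decomposition); the arousal response is the within-participant
difference ``delta_EDA = mean(high) - mean(low)``.

Perceived fear is rated 1-10 (half-point resolution) after each height
block.  Because fear ratings habituate with exposure, only the ratings
after the *first* block of each condition enter the between-condition
comparison; a participant is classified fearful iff that first-block
rating strictly increased with threat (``delta_fear > 0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import EDATrace

__all__ = [
    "ConditionSummary",
    "eda_condition_mean",
    "delta_eda",
    "classify_fear_group",
    "summarize_participant",
]

FEARFUL = "fearful"
NON_FEARFUL = "non-fearful"


@dataclass(frozen=True)
class ConditionSummary:
    """Per-participant physiological and fear summary."""

    participant_id: str
    eda_low_uS: float
    eda_high_uS: float
    delta_eda_uS: float
    fear_first_low: float
    fear_first_high: float
    delta_fear: float
    fear_group: str


def eda_condition_mean(trace: EDATrace | np.ndarray) -> float:
    """Mean electrodermal level (uS) over the entire condition."""
    signal = trace.signal if isinstance(trace, EDATrace) else np.asarray(trace)
    if signal.size == 0:
        raise ValueError("empty EDA trace")
    return float(np.mean(signal))


def delta_eda(high: EDATrace | np.ndarray, low: EDATrace | np.ndarray) -> float:
    """Arousal response: high-threat minus low-threat condition mean (uS)."""
    return eda_condition_mean(high) - eda_condition_mean(low)


def classify_fear_group(first_low: float, first_high: float) -> str:
    """Fear-group label from the two first-block ratings.

    Strictly increased rating under threat -> ``'fearful'``; equal or
    decreased -> ``'non-fearful'``.
    """
    for r in (first_low, first_high):
        if r is None or not np.isfinite(r):
            raise ValueError("missing first-block fear rating")
    return FEARFUL if (first_high - first_low) > 0 else NON_FEARFUL


def summarize_participant(
    participant_id: str,
    eda_low: EDATrace | np.ndarray,
    eda_high: EDATrace | np.ndarray,
    fear_ratings_low: list[float],
    fear_ratings_high: list[float],
) -> ConditionSummary:
    """Bundle the condition means, deltas, and fear classification."""
    if not fear_ratings_low or not fear_ratings_high:
        raise ValueError("missing first-block fear rating")
    m_low = eda_condition_mean(eda_low)
    m_high = eda_condition_mean(eda_high)
    f_low, f_high = float(fear_ratings_low[0]), float(fear_ratings_high[0])
    return ConditionSummary(
        participant_id=participant_id,
        eda_low_uS=m_low,
        eda_high_uS=m_high,
        delta_eda_uS=m_high - m_low,
        fear_first_low=f_low,
        fear_first_high=f_high,
        delta_fear=f_high - f_low,
        fear_group=classify_fear_group(f_low, f_high),
    )
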