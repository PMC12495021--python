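"""Firing-rate summaries across stimuli and cross-stimulus activity correlations."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ParameterError
from .spike_trains import SpikeTrainSet

logger = logging.getLogger(__name__)


def rate_table(sessions: dict[int, SpikeTrainSet]) -> pd.DataFrame:
    """Channels x stimuli table of mean firing rates (count / duration)."""
    if not sessions:
        raise ParameterError("sessions must not be empty")
    channel_sets = {tuple(s.channel_ids) for s in sessions.values()}
    if len(channel_sets) != 1:
        raise ParameterError("all sessions must share the same channel set")
    cols = {}
    for stim in sorted(sessions):
        s = sessions[stim]
        if s.duration_s <= 0:
            raise ParameterError(f"stimulus {stim}: zero-duration session")
        cols[stim] = s.rates_hz()
    return pd.DataFrame(cols)


def top_active(table: pd.DataFrame, stimulus: int, k: int = 5) -> list[int]:
    """Top-k channels by rate under one stimulus, descending; ties by label."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if stimulus not in table.columns:
        raise ParameterError(f"unknown stimulus {stimulus}")
    if k > len(table):
        logger.warning("k=%d exceeds channel count %d; returning full ranking", k, len(table))
        k = len(table)
    col = table[stimulus]
    order = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
    return [int(ch) for ch, _ in order[:k]]


def stimulus_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between the per-channel rate vectors of each
    stimulus pair (unit diagonal, symmetric).

    Activity patterns that correlate strongly indicate stimuli driving
    similar population responses.  Zero-variance columns yield NaN
    correlations with a logged warning.
    """
    if len(table) < 2:
        raise ParameterError("need at least 2 channels")
    flat = table.std(ddof=0) == 0
    if flat.any():
        logger.warning(
            "zero-variance rate vectors for stimuli %s; correlations undefined",
            list(table.columns[flat]),
        )
    corr = table.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr
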