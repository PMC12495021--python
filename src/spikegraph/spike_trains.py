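"""Spike-train containers, text I/O, trial extraction, and channel screening.

The in-memory containers mirror how multielectrode recordings are usually
handled: a set of per-channel spike-time sequences on a common session clock,
plus a stimulus schedule listing the trial intervals during which each
stimulus was presented.  Analyses downstream operate per stimulus on the
concatenation of that stimulus's trial intervals: spikes are remapped onto a
gapless time axis and treated as one continuous recording.

File formats are plain CSV:

* spike table: header ``channel,time_s``, one row per spike;
* schedule: header ``stimulus_id,trial_index,start_s,end_s``;
* adjacency: square 0/1 matrix, header row and index column carry channel
  labels, rows are sources and columns are targets.

Times are seconds, written with six fractional digits so that
millisecond-scale influence kernels survive a write/read round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ScheduleError

logger = logging.getLogger(__name__)

_TIME_FMT = "%.6f"


@dataclass
class SpikeTrainSet:
    """Ordered spike times for N channels on a common clock.

    Parameters
    ----------
    channel_ids
        Channel labels in display order.  Original labels are preserved even
        after channels are dropped, so a 29-channel set may be labelled
        1..32 with gaps.
    spikes
        Mapping channel id -> strictly increasing float array of spike times
        in seconds, all within ``[0, duration_s)``.
    duration_s
        Total recording duration in seconds.
    """

    channel_ids: list[int]
    spikes: dict[int, np.ndarray]
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ParameterError("channel ids must be unique")
        if set(self.channel_ids) != set(self.spikes):
            raise ParameterError("channel_ids and spikes keys must agree")
        for ch in self.channel_ids:
            t = np.asarray(self.spikes[ch], dtype=float)
            self.spikes[ch] = t
            if t.size:
                if np.any(np.diff(t) <= 0):
                    raise ParameterError(f"channel {ch}: spike times not strictly increasing")
                if t[0] < 0 or t[-1] >= self.duration_s:
                    raise ParameterError(f"channel {ch}: spike times outside [0, duration)")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def counts(self) -> pd.Series:
        return pd.Series({ch: self.spikes[ch].size for ch in self.channel_ids})

    def rates_hz(self) -> pd.Series:
        """Mean firing rate (spike count / duration) per channel."""
        return self.counts() / self.duration_s


@dataclass
class StimulusSchedule:
    """Table of trial intervals: (stimulus_id, trial_index, start_s, end_s).

    Intervals are half-open ``[start_s, end_s)`` on the session clock and
    must be pairwise disjoint within one session.
    """

    entries: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("stimulus_id", "trial_index", "start_s", "end_s")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.entries.columns]
        if missing:
            raise ScheduleError(f"schedule missing columns: {missing}")
        e = self.entries
        if (e["start_s"] >= e["end_s"]).any():
            raise ScheduleError("schedule has intervals with start_s >= end_s")
        srt = e.sort_values("start_s")
        if (srt["start_s"].to_numpy()[1:] < srt["end_s"].to_numpy()[:-1]).any():
            raise ScheduleError("schedule intervals overlap")

    @property
    def stimulus_ids(self) -> list[int]:
        return sorted(self.entries["stimulus_id"].unique().tolist())

    def intervals_for(self, stimulus_id: int) -> pd.DataFrame:
        sel = self.entries[self.entries["stimulus_id"] == stimulus_id]
        return sel.sort_values("start_s").reset_index(drop=True)


# ---------------------------------------------------------------------------
# text I/O


def read_spike_table(path: str | Path, duration_s: float | None = None) -> SpikeTrainSet:
    """Read a ``channel,time_s`` CSV into a :class:`SpikeTrainSet`.

    Unsorted channels are sorted with a logged warning; duplicate
    (channel, time) rows are collapsed with a logged warning.  If
    ``duration_s`` is not given it is the maximum time rounded up to the
    next integer second (and at least 1 s).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no records") from None
    for col in ("channel", "time_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df.empty:
        raise FormatError(f"{path}: no records")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    if times.isna().any():
        line = int(times.isna().idxmax()) + 2  # header + 1-based
        raise FormatError(f"{path}: non-numeric time_s at line {line}")
    if (times < 0).any():
        line = int((times < 0).idxmax()) + 2
        raise FormatError(f"{path}: negative time_s at line {line}")
    channels = pd.to_numeric(df["channel"], errors="coerce")
    if channels.isna().any() or (channels != channels.astype(int)).any():
        raise FormatError(f"{path}: channel column must hold integers")

    if duration_s is None:
        duration_s = max(1.0, float(np.ceil(times.max() + 1e-9)))

    spikes: dict[int, np.ndarray] = {}
    for ch, grp in df.assign(time_s=times, channel=channels.astype(int)).groupby("channel"):
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            logger.warning("channel %d: spike times out of order; sorting", ch)
            t = np.sort(t)
        uniq = np.unique(t)
        if uniq.size != t.size:
            logger.warning("channel %d: %d duplicate spike times collapsed", ch, t.size - uniq.size)
            t = uniq
        spikes[int(ch)] = t
    ids = sorted(spikes)
    return SpikeTrainSet(channel_ids=ids, spikes=spikes, duration_s=float(duration_s))


def write_spike_table(spikes: SpikeTrainSet, path: str | Path) -> None:
    rows = []
    for ch in spikes.channel_ids:
        for t in spikes.spikes[ch]:
            rows.append((ch, _TIME_FMT % t))
    pd.DataFrame(rows, columns=["channel", "time_s"]).to_csv(path, index=False)


def read_schedule(path: str | Path) -> StimulusSchedule:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no records") from None
    return StimulusSchedule(entries=df)


def write_schedule(schedule: StimulusSchedule, path: str | Path) -> None:
    out = schedule.entries.copy()
    for col in ("start_s", "end_s"):
        out[col] = out[col].map(lambda v: _TIME_FMT % v)
    out.to_csv(path, index=False)


def read_adjacency(path: str | Path) -> pd.DataFrame:
    """Read the square 0/1 adjacency CSV (rows = sources, columns = targets)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(int)
    df.columns = df.columns.astype(int)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: adjacency row and column labels differ")
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise FormatError(f"{path}: adjacency entries must be 0/1")
    return df.astype(int)


def write_adjacency(adj: pd.DataFrame, path: str | Path) -> None:
    adj.to_csv(path)


# ---------------------------------------------------------------------------
# preprocessing


def extract_stimulus_segments(
    spikes: SpikeTrainSet, schedule: StimulusSchedule, stimulus_id: int
) -> SpikeTrainSet:
    """Concatenate one stimulus's trial intervals onto a gapless time axis.

    A spike at absolute time ``t`` inside the k-th interval (sorted by
    start) maps to ``(t - start_k) + sum of earlier interval lengths``.  The
    output duration is the sum of interval lengths; spikes outside the
    intervals are discarded.  No boundary marker is inserted: inter-spike
    intervals spanning a trial boundary are retained as-is, matching the
    convention of treating the selected intervals as one continuous record.
    Use :func:`segment_boundaries` to censor them in the inference stage
    instead.
    """
    iv = schedule.intervals_for(stimulus_id)
    if iv.empty:
        raise ScheduleError(f"schedule has no intervals for stimulus {stimulus_id}")
    starts = iv["start_s"].to_numpy(dtype=float)
    ends = iv["end_s"].to_numpy(dtype=float)
    if (starts[1:] < ends[:-1]).any():
        raise ScheduleError(f"overlapping intervals for stimulus {stimulus_id}")
    lengths = ends - starts
    offsets = np.concatenate([[0.0], np.cumsum(lengths)[:-1]])
    duration = float(lengths.sum())

    out: dict[int, np.ndarray] = {}
    for ch in spikes.channel_ids:
        t = spikes.spikes[ch]
        pieces = []
        for s, e, off in zip(starts, ends, offsets):
            lo, hi = np.searchsorted(t, [s, e])
            pieces.append(t[lo:hi] - s + off)
        out[ch] = np.concatenate(pieces) if pieces else np.empty(0)
    return SpikeTrainSet(channel_ids=list(spikes.channel_ids), spikes=out, duration_s=duration)


def segment_boundaries(schedule: StimulusSchedule, stimulus_id: int) -> np.ndarray:
    """Concatenated-axis times at which one trial ends and the next begins."""
    iv = schedule.intervals_for(stimulus_id)
    lengths = (iv["end_s"] - iv["start_s"]).to_numpy(dtype=float)
    return np.cumsum(lengths)[:-1]


def flag_outlier_channels(
    rates: pd.DataFrame, ceiling_hz: float = 20.0, floor_hz: float = 0.0
) -> set[int]:
    """Screen channels by firing rate across stimuli.

    A channel is flagged when its rate exceeds ``ceiling_hz`` under any
    stimulus, or stays below ``floor_hz`` under every stimulus.  The default
    20 Hz ceiling is the upper end of the "medium" cortical firing-rate band;
    channels beyond it dominate the recording and are excluded from the
    connectivity analysis.
    """
    if ceiling_hz <= floor_hz:
        raise ParameterError("ceiling_hz must exceed floor_hz")
    if (rates.to_numpy() < 0).any():
        raise ParameterError("rates must be non-negative")
    high = rates.gt(ceiling_hz).any(axis=1)
    low = rates.lt(floor_hz).all(axis=1)
    return set(rates.index[high | low].astype(int))


def drop_channels(spikes: SpikeTrainSet, ids: Iterable[int]) -> SpikeTrainSet:
    """Remove channels, keeping the original labels of the remainder."""
    ids = set(ids)
    unknown = ids - set(spikes.channel_ids)
    if unknown:
        raise ParameterError(f"unknown channel ids: {sorted(unknown)}")
    keep = [ch for ch in spikes.channel_ids if ch not in ids]
    if not keep:
        raise ParameterError("no channels remain")
    return SpikeTrainSet(
        channel_ids=keep,
        spikes={ch: spikes.spikes[ch] for ch in keep},
        duration_s=spikes.duration_s,
    )
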