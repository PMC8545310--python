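"""Behavior-change detection on per-region per-topic daily counts.

A day is flagged when its message count deviates from a baseline by at
least the relative threshold (30% in the default configuration, applied
to both increases and decreases). The baseline is the trailing mean of
the previous ``window`` days (default 7) or, in the literal day-over-day
mode, the previous day's count; days whose baseline falls below a
minimum floor are skipped to suppress small-count false alarms.
Consecutive flags for one (region, topic) merge into a single event whose
onset is the first flagged day; events are attributed to their dominant
subtopic and summarised with top-k keywords and a +/-15-day emotion
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DailyCountSeries",
    "DetectorConfig",
    "ChangeFlag",
    "EventRecord",
    "InsufficientHistoryError",
    "aggregate_daily",
    "detect_change",
    "detect_events",
    "attribute_event",
    "emotion_window",
]


class InsufficientHistoryError(ValueError):
    """Series shorter than the baseline window + 1."""


@dataclass
class DailyCountSeries:
    """Zero-filled daily message counts for one (region, topic)."""

    region: str
    topic: str
    counts: pd.Series  # DatetimeIndex (daily, UTC calendar days) -> int

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if not self.counts.index.is_monotonic_increasing:
            raise ValueError("dates must be increasing")


@dataclass
class DetectorConfig:
    """Threshold rule settings; ``mode`` selects the baseline."""

    threshold: float = 0.30
    window: int = 7
    min_baseline: float = 5.0
    mode: str = "trailing-mean"  # or "day-over-day"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.mode not in ("trailing-mean", "day-over-day"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class ChangeFlag:
    date: pd.Timestamp
    relative_change: float
    direction: str  # "increase" | "decrease"


@dataclass
class EventRecord:
    region: str
    topic: str
    onset: pd.Timestamp
    direction: str
    relative_change: float
    dominant_subtopic: Optional[str] = None
    subtopic_counts: Dict[str, int] = field(default_factory=dict)
    subtopic_tie: bool = False
    keywords: List[str] = field(default_factory=list)
    emotion_window: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "topic": self.topic,
            "onset": str(self.onset.date()),
            "direction": self.direction,
            "relative_change": self.relative_change,
            "dominant_subtopic": self.dominant_subtopic,
            "subtopic_counts": self.subtopic_counts,
            "subtopic_tie": self.subtopic_tie,
            "keywords": self.keywords,
        }


def aggregate_daily(messages: pd.DataFrame) -> List[DailyCountSeries]:
    """Group labelled messages into daily count series.

    ``messages`` needs columns region, topic, created_at (parseable
    timestamps; a message belongs to the UTC calendar day of its
    timestamp). Unparseable timestamps are rejected per message and
    logged via a warning. Missing days inside the global date range are
    present with count 0, and the total across all series equals the
    number of accepted messages.
    """
    if messages.empty:
        return []
    ts = pd.to_datetime(messages["created_at"], errors="coerce", utc=True)
    bad = ts.isna()
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} messages with "
                      "unparseable timestamps")
    df = messages.loc[~bad, ["region", "topic"]].copy()
    df["date"] = ts[~bad].dt.floor("D").dt.tz_localize(None)
    if df.empty:
        return []
    full = pd.date_range(df["date"].min(), df["date"].max(), freq="D")
    out = []
    for (region, topic), grp in df.groupby(["region", "topic"], sort=True):
        counts = grp.groupby("date").size().reindex(full, fill_value=0)
        out.append(DailyCountSeries(str(region), str(topic), counts))
    return out


def detect_change(series: DailyCountSeries,
                  cfg: Optional[DetectorConfig] = None) -> List[ChangeFlag]:
    """Flag days whose count deviates from baseline by >= threshold.

    Baseline b_t is the mean of the ``window`` preceding days
    (trailing-mean mode) or the previous day's count (day-over-day).
    Days with b_t below ``min_baseline`` are skipped. A flag records the
    signed relative change (c_t - b_t)/b_t and its direction.
    """
    cfg = cfg or DetectorConfig()
    c = series.counts.to_numpy(dtype=float)
    w = cfg.window if cfg.mode == "trailing-mean" else 1
    if len(c) <= w:
        raise InsufficientHistoryError(
            f"series of length {len(c)} needs more than {w} days")
    flags = []
    for t in range(w, len(c)):
        b = c[t - w:t].mean() if cfg.mode == "trailing-mean" else c[t - 1]
        if b < cfg.min_baseline or b == 0:
            continue
        rel = (c[t] - b) / b
        if abs(rel) >= cfg.threshold:
            flags.append(ChangeFlag(
                date=series.counts.index[t],
                relative_change=float(rel),
                direction="increase" if rel > 0 else "decrease",
            ))
    return flags


def detect_events(series_list: Sequence[DailyCountSeries],
                  cfg: Optional[DetectorConfig] = None) -> List[EventRecord]:
    """Run the detector over every series and merge consecutive-day flags
    of one (region, topic) into single events (onset = first flagged
    day). Series too short for the baseline window are skipped."""
    cfg = cfg or DetectorConfig()
    events = []
    for s in series_list:
        try:
            flags = detect_change(s, cfg)
        except InsufficientHistoryError:
            continue
        run: List[ChangeFlag] = []
        for f in flags:
            if run and (f.date - run[-1].date).days == 1 \
                    and f.direction == run[0].direction:
                run.append(f)
            else:
                if run:
                    events.append(_event_from_run(s, run))
                run = [f]
        if run:
            events.append(_event_from_run(s, run))
    return events


def _event_from_run(s: DailyCountSeries, run: List[ChangeFlag]
                    ) -> EventRecord:
    return EventRecord(
        region=s.region, topic=s.topic, onset=run[0].date,
        direction=run[0].direction,
        relative_change=max((f.relative_change for f in run), key=abs),
    )


def attribute_event(event: EventRecord, messages: pd.DataFrame,
                    lookback_days: int = 3, top_k: int = 25,
                    stopwords: Optional[Set[str]] = None) -> EventRecord:
    """Fill in the dominant subtopic and keywords from the messages of
    the flagged window (onset +/- ``lookback_days``).

    ``messages`` needs columns created_at, subtopic and tokens (list).
    The dominant subtopic is the mode of assignments; a tie picks the
    lexicographically first and sets ``subtopic_tie``. Keywords are the
    ``top_k`` most frequent non-stopword tokens.
    """
    ts = pd.to_datetime(messages["created_at"], utc=True, format="ISO8601").dt.floor("D") \
        .dt.tz_localize(None)
    lo = event.onset - pd.Timedelta(days=lookback_days)
    hi = event.onset + pd.Timedelta(days=lookback_days)
    win = messages.loc[(ts >= lo) & (ts <= hi)]
    if win.empty:
        raise ValueError("no messages in the flagged window")
    counts = win["subtopic"].value_counts()
    top = counts.max()
    tied = sorted(counts.index[counts == top])
    event.dominant_subtopic = tied[0]
    event.subtopic_tie = len(tied) > 1
    event.subtopic_counts = {str(k): int(v) for k, v in counts.items()}
    stop = stopwords or set()
    freq: Dict[str, int] = {}
    for toks in win["tokens"]:
        for t in toks:
            if t not in stop:
                freq[t] = freq.get(t, 0) + 1
    event.keywords = [t for t, _ in sorted(freq.items(),
                                           key=lambda kv: (-kv[1], kv[0]))
                      ][:top_k]
    return event


def emotion_window(event: EventRecord, messages: pd.DataFrame,
                   half_window: int = 15) -> pd.DataFrame:
    """Per-emotion daily counts over [onset - h, onset + h], each emotion
    series divided by its own maximum for comparability (an all-zero
    emotion stays all zero). ``messages`` needs created_at and emotion
    columns; a window truncated by the data span warns."""
    ts = pd.to_datetime(messages["created_at"], utc=True, format="ISO8601").dt.floor("D") \
        .dt.tz_localize(None)
    lo = event.onset - pd.Timedelta(days=half_window)
    hi = event.onset + pd.Timedelta(days=half_window)
    if len(ts) and (lo < ts.min() or hi > ts.max()):
        warnings.warn("emotion window truncated to the available data span")
    win = messages.loc[(ts >= lo) & (ts <= hi)].copy()
    win_ts = ts[(ts >= lo) & (ts <= hi)]
    idx = pd.date_range(lo, hi, freq="D")
    emotions = sorted(messages["emotion"].unique())
    table = pd.DataFrame(0.0, index=idx, columns=emotions)
    if not win.empty:
        grouped = win.groupby([win_ts, "emotion"]).size()
        for (d, e), v in grouped.items():
            table.loc[d, e] = float(v)
    for e in emotions:
        m = table[e].max()
        if m > 0:
            table[e] = table[e] / m
    event.emotion_window = table
    return table
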