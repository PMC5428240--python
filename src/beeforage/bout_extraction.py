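"""RFID event streams -> foraging bouts -> per-bee activity metrics.

A nest-entrance RFID reader logs when each tagged bee leaves ("out") and
re-enters ("in") the nest.  A foraging bout is an out read paired with
the next in read for the same bee; candidate bouts shorter than a
minimum duration (entrance-platform loitering and re-reads) are
discarded.  Bees completing more than five bouts are classified as
foragers; activity is summarised as days foraged, mean bouts per day
and mean bout duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OUT = "out"
IN = "in"

#: bouts shorter than this (minutes) are treated as entrance loitering
DEFAULT_MIN_DURATION_MIN = 2.0

#: a bee is a forager once it completes more than this many bouts
FORAGER_BOUT_THRESHOLD = 5


@dataclass(frozen=True)
class TagEvent:
    bee_id: str
    timestamp: pd.Timestamp
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (OUT, IN):
            raise ValueError(f"direction must be 'out' or 'in', got {self.direction!r}")


@dataclass(frozen=True)
class Bout:
    """One foraging trip, delimited by an out read and the next in read."""

    bee_id: str
    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    @property
    def day(self):
        """Calendar date of the bout start (bouts do not span nights)."""
        return self.start.date()


def events_from_frame(df: pd.DataFrame) -> list[TagEvent]:
    """Parse an events table (bee_id, timestamp, direction) with validation."""
    events = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ts = pd.Timestamp(row.timestamp)
            if pd.isna(ts):
                raise ValueError("missing timestamp")
            events.append(TagEvent(str(row.bee_id), ts, str(row.direction)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"events line {lineno}: {exc}") from exc
    return events


def read_events(path) -> list[TagEvent]:
    return events_from_frame(pd.read_csv(path, dtype={"bee_id": str}))


def clean_events(raw: list[TagEvent]) -> list[TagEvent]:
    """Sort per bee, drop exact duplicates, resolve same-direction runs.

    Two consecutive reads in the same direction imply a missed read; the
    intervening incomplete trip is unrecoverable and is discarded: for a
    run of "out" reads only the last is kept (the earlier departures have
    no recorded return), for a run of "in" reads only the first (the
    later entries have no recorded departure).  A leading "in" with no
    prior "out" is likewise dropped.  Already-alternating streams pass
    through unchanged.
    """
    dedup = sorted(set(raw), key=lambda e: (e.bee_id, e.timestamp, e.direction))
    cleaned: list[TagEvent] = []
    for bee_id in sorted({e.bee_id for e in dedup}):
        stream = [e for e in dedup if e.bee_id == bee_id]
        kept: list[TagEvent] = []
        for ev in stream:
            if ev.direction == OUT:
                if kept and kept[-1].direction == OUT:
                    logger.warning(
                        "bee %s: consecutive 'out' reads at %s and %s; "
                        "discarding incomplete trip", bee_id, kept[-1].timestamp, ev.timestamp)
                    kept[-1] = ev
                else:
                    kept.append(ev)
            else:  # IN
                if not kept or kept[-1].direction == IN:
                    logger.warning(
                        "bee %s: 'in' read at %s with no open trip; discarded",
                        bee_id, ev.timestamp)
                    continue
                kept.append(ev)
        cleaned.extend(kept)
    return cleaned


def extract_bouts(events: list[TagEvent],
                  min_duration: float = DEFAULT_MIN_DURATION_MIN) -> list[Bout]:
    """Pair each out read with the next in read for the same bee.

    Candidates shorter than ``min_duration`` minutes are dropped.  A
    terminal unmatched out (the bee never returned) is a censored
    departure, not a bout.  Expects a cleaned (alternating) stream.
    """
    bouts: list[Bout] = []
    open_out: dict[str, TagEvent] = {}
    for ev in sorted(events, key=lambda e: (e.bee_id, e.timestamp)):
        if ev.direction == OUT:
            open_out[ev.bee_id] = ev
        else:
            start = open_out.pop(ev.bee_id, None)
            if start is None:
                continue
            bout = Bout(ev.bee_id, start.timestamp, ev.timestamp)
            if bout.duration_min >= min_duration:
                bouts.append(bout)
    return bouts


def bouts_to_frame(bouts: list[Bout]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"bee_id": b.bee_id, "start": b.start.isoformat(), "end": b.end.isoformat(),
          "duration_min": b.duration_min, "day": b.day.isoformat()} for b in bouts],
        columns=["bee_id", "start", "end", "duration_min", "day"],
    )


def frame_to_bouts(df: pd.DataFrame) -> list[Bout]:
    return [Bout(str(r.bee_id), pd.Timestamp(r.start), pd.Timestamp(r.end))
            for r in df.itertuples(index=False)]


def read_bouts(path) -> list[Bout]:
    return frame_to_bouts(pd.read_csv(path, dtype={"bee_id": str}))


def _consecutive(dates: set) -> bool:
    days = sorted(dates)
    return all((b - a).days == 1 for a, b in zip(days, days[1:]))


def summarize_activity(bouts: list[Bout], bees: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-bee activity metrics.

    Parameters
    ----------
    bouts
        Extracted bouts.
    bees
        Optional bee table with a ``bee_id`` column; bees absent from the
        bout list get a zero-bout row (activity metrics missing,
        ``is_forager`` False) so non-returning bees stay visible.

    Returns a DataFrame with columns bee_id, n_bouts, days_foraged,
    mean_bouts_per_day, mean_bout_duration, is_forager, consecutive_days.
    """
    ids: list[str] = sorted({b.bee_id for b in bouts})
    if bees is not None:
        ids = sorted(set(ids) | set(bees["bee_id"].astype(str)))
    rows = []
    by_bee: dict[str, list[Bout]] = {i: [] for i in ids}
    for b in bouts:
        by_bee[b.bee_id].append(b)
    for bee_id in ids:
        bb = by_bee[bee_id]
        n = len(bb)
        if n == 0:
            rows.append({"bee_id": bee_id, "n_bouts": 0, "days_foraged": 0,
                         "mean_bouts_per_day": np.nan, "mean_bout_duration": np.nan,
                         "is_forager": False, "consecutive_days": False})
            continue
        dates = {b.day for b in bb}
        rows.append({
            "bee_id": bee_id,
            "n_bouts": n,
            "days_foraged": len(dates),
            "mean_bouts_per_day": n / len(dates),
            "mean_bout_duration": float(np.mean([b.duration_min for b in bb])),
            "is_forager": n > FORAGER_BOUT_THRESHOLD,
            "consecutive_days": _consecutive(dates),
        })
    return pd.DataFrame(rows, columns=[
        "bee_id", "n_bouts", "days_foraged", "mean_bouts_per_day",
        "mean_bout_duration", "is_forager", "consecutive_days"])
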