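"""Nectar and pollen collection rates from weighing-station observations.

Observers weighed tagged bees walking over a balance at the nest
entrance as they left or returned, and graded any pollen load carried
(small/medium/large/very large, coded 1-4).  Observation timestamps are
matched to RFID bouts; a bout observed both ways is classified as a
pollen bout (incoming pollen load present) or a nectar bout, and per-bee
collection rates are computed for bees with at least three observed
bouts of the resource:

    nectar rate  = (mean incoming mass - mean outgoing mass) / mean trip duration   [mg/min]
    pollen rate  = mean pollen score / mean trip duration                           [score/min]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bout_extraction import Bout

logger = logging.getLogger(__name__)

POLLEN_SCORES = {"small": 1, "medium": 2, "large": 3, "very_large": 4}
NO_POLLEN = "none"

#: maximum gap (minutes) between an observation and a bout boundary
DEFAULT_MATCH_TOLERANCE_MIN = 2.0

#: rates require at least this many observed bouts of the resource
MIN_OBSERVED_BOUTS = 3


@dataclass(frozen=True)
class ObservationRecord:
    bee_id: str
    timestamp: pd.Timestamp
    direction: str            # "out" or "in"
    mass_mg: float
    pollen_load: str = NO_POLLEN

    def __post_init__(self) -> None:
        if self.mass_mg <= 0:
            raise ValueError(f"mass must be positive, got {self.mass_mg}")
        if self.pollen_load != NO_POLLEN and self.pollen_load not in POLLEN_SCORES:
            raise ValueError(f"unknown pollen load {self.pollen_load!r}")
        if self.pollen_load != NO_POLLEN and self.direction != "in":
            raise ValueError("pollen load can only be recorded on incoming records")


@dataclass
class ObservedBout:
    """A bout annotated with its matched weighing-station records."""

    bout: Bout
    outgoing: ObservationRecord | None = None
    incoming: ObservationRecord | None = None

    @property
    def observed(self) -> bool:
        return self.outgoing is not None and self.incoming is not None

    @property
    def resource(self) -> str | None:
        """'pollen' or 'nectar' for a classifiable bout, else None."""
        if self.incoming is None:
            return None
        return "pollen" if self.incoming.pollen_load != NO_POLLEN else "nectar"


def records_from_frame(df: pd.DataFrame) -> list[ObservationRecord]:
    recs = []
    for row in df.itertuples(index=False):
        load = row.pollen_load if isinstance(row.pollen_load, str) else NO_POLLEN
        recs.append(ObservationRecord(str(row.bee_id), pd.Timestamp(row.timestamp),
                                      str(row.direction), float(row.mass_mg), load))
    return recs


def read_observations(path) -> list[ObservationRecord]:
    return records_from_frame(pd.read_csv(path, dtype={"bee_id": str}))


def match_observations(records: list[ObservationRecord], bouts: list[Bout],
                       tolerance: float = DEFAULT_MATCH_TOLERANCE_MIN) -> list[ObservedBout]:
    """Attach weighing records to the bouts they time-align with.

    An outgoing record attaches to the nearest bout start within
    ``tolerance`` minutes (incoming records to bout ends); ties go to the
    earlier bout, and a slot already filled by a closer record is not
    overwritten.  Records matching no bout are logged and dropped.
    """
    annotated = [ObservedBout(b) for b in bouts]
    by_bee: dict[str, list[ObservedBout]] = {}
    for ob in annotated:
        by_bee.setdefault(ob.bout.bee_id, []).append(ob)
    for obs in by_bee.values():
        obs.sort(key=lambda ob: ob.bout.start)

    for rec in sorted(records, key=lambda r: (r.bee_id, r.timestamp)):
        best: tuple[float, int] | None = None  # (gap_min, bout position)
        cands = by_bee.get(rec.bee_id, [])
        for pos, ob in enumerate(cands):
            boundary = ob.bout.start if rec.direction == "out" else ob.bout.end
            taken = ob.outgoing if rec.direction == "out" else ob.incoming
            if taken is not None:
                continue
            gap = abs((rec.timestamp - boundary).total_seconds()) / 60.0
            if gap <= tolerance and (best is None or gap < best[0] - 1e-12):
                best = (gap, pos)
        if best is None:
            logger.warning("bee %s: %s record at %s matches no bout within %.1f min; dropped",
                           rec.bee_id, rec.direction, rec.timestamp, tolerance)
            continue
        target = cands[best[1]]
        if rec.direction == "out":
            target.outgoing = rec
        else:
            target.incoming = rec
    return annotated


def classify_bout_resource(ob: ObservedBout) -> str:
    """'pollen' if the incoming record carries a pollen load, else 'nectar'."""
    if ob.incoming is None:
        raise ValueError("cannot classify a bout without an incoming record")
    return ob.resource


def nectar_rate(observed_nectar_bouts: list[ObservedBout]) -> float | None:
    """Milligrams of nectar gained per minute outside the nest.

    Mean incoming mass minus mean outgoing mass, divided by the mean
    duration of the observed bouts.  Requires at least three fully
    observed pollen-free bouts; may be negative (reported as-is).
    """
    obs = [ob for ob in observed_nectar_bouts if ob.observed]
    if len(obs) < MIN_OBSERVED_BOUTS:
        return None
    mean_in = np.mean([ob.incoming.mass_mg for ob in obs])
    mean_out = np.mean([ob.outgoing.mass_mg for ob in obs])
    mean_dur = np.mean([ob.bout.duration_min for ob in obs])
    return float((mean_in - mean_out) / mean_dur)


def pollen_rate(observed_pollen_bouts: list[ObservedBout]) -> float | None:
    """Mean pollen-load score (1-4) per minute outside the nest."""
    obs = [ob for ob in observed_pollen_bouts if ob.incoming is not None]
    if len(obs) < MIN_OBSERVED_BOUTS:
        return None
    mean_score = np.mean([POLLEN_SCORES[ob.incoming.pollen_load] for ob in obs])
    mean_dur = np.mean([ob.bout.duration_min for ob in obs])
    return float(mean_score / mean_dur)


def experience_score(bee_id: str, bouts: list[Bout]) -> int:
    """Total RFID-recorded bouts completed by the bee."""
    return sum(1 for b in bouts if b.bee_id == bee_id)


def compute_efficiency(records: list[ObservationRecord], bouts: list[Bout],
                       tolerance: float = DEFAULT_MATCH_TOLERANCE_MIN) -> pd.DataFrame:
    """Per-bee efficiency table from raw observations and bouts.

    Columns: bee_id, n_nectar_bouts_observed, n_pollen_bouts_observed,
    nectar_rate, pollen_rate, negative_nectar_flag, experience.
    Rates are missing (NaN) below the three-bout minimum.
    """
    annotated = match_observations(records, bouts, tolerance=tolerance)
    by_bee: dict[str, list[ObservedBout]] = {}
    for ob in annotated:
        by_bee.setdefault(ob.bout.bee_id, []).append(ob)
    rows = []
    for bee_id in sorted(by_bee):
        obs = by_bee[bee_id]
        nectar = [ob for ob in obs if ob.observed and ob.resource == "nectar"]
        pollen = [ob for ob in obs if ob.observed and ob.resource == "pollen"]
        nrate = nectar_rate(nectar)
        prate = pollen_rate(pollen)
        if nrate is not None and nrate < 0:
            logger.warning("bee %s: negative nectar rate %.3f mg/min", bee_id, nrate)
        rows.append({
            "bee_id": bee_id,
            "n_nectar_bouts_observed": len(nectar),
            "n_pollen_bouts_observed": len(pollen),
            "nectar_rate": np.nan if nrate is None else nrate,
            "pollen_rate": np.nan if prate is None else prate,
            "negative_nectar_flag": bool(nrate is not None and nrate < 0),
            "experience": experience_score(bee_id, bouts),
        })
    return pd.DataFrame(rows, columns=[
        "bee_id", "n_nectar_bouts_observed", "n_pollen_bouts_observed",
        "nectar_rate", "pollen_rate", "negative_nectar_flag", "experience"])
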