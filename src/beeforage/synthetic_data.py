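"""Simulated bee cohorts with the statistical structure the analysis assumes.

The generator emulates a split-colony study: bees from five colonies
are tested in a laboratory colour-learning assay (100 sequential
blue/yellow flower choices driven by a latent first-order decay curve),
then released to forage freely while a nest-entrance RFID reader logs
every departure and return, and a weighing station intermittently
records masses and pollen loads.

Default parameters reproduce the study conditions: 5 colonies of 15-21
tested bees, a positive LPI effect (+0.06 per LPI unit) on log days
foraged, colony-age effects of -0.52 and +0.06 on square-root bouts per
day and square-root bout duration, about 58% of tagged bees becoming
foragers, consecutive foraging days for 92% of foragers, and a 9.4%
observed-bout fraction at the weighing station.

Everything is a pure function of (config, seed): the same seed
reproduces byte-identical output tables.
"""

from __future__ import annotations

import ast
import logging
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .bout_extraction import IN, OUT, Bout, TagEvent
from .foraging_efficiency import NO_POLLEN, ObservationRecord
from .learning_performance import BLUE, YELLOW, Choice, ChoiceSequence, score_cohort

logger = logging.getLogger(__name__)

POLLEN_CLASSES = ("small", "medium", "large", "very_large")

#: start of the simulated field season (timestamps count from here)
EPOCH = pd.Timestamp("2016-07-01 00:00:00")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator; defaults are the study conditions."""

    # cohort structure
    n_colonies: int = 5
    bees_per_colony: tuple[int, int] = (15, 21)
    seed: int = 0

    # latent learning parameters: y0 ~ 10*Beta(a,b); A = (10-y0)*Beta(a,b)
    # (keeps per-bin error counts in [0,10] by construction); t log-normal
    y0_beta: tuple[float, float] = (1.0, 9.0)
    amp_beta: tuple[float, float] = (5.0, 2.0)
    t_log_mean: float = math.log(20.0)
    t_log_sd: float = 0.5
    n_choices: int = 100
    pre_probe_max: int = 10           # blue visits before the first yellow probe

    # covariates
    worker_age_range: tuple[float, float] = (3.0, 10.0)    # days at testing
    worker_mass_mean: float = 180.0                        # mg
    worker_mass_sd: float = 25.0
    colony_age_range: tuple[float, float] = (7.0, 12.0)    # days at transfer

    # foraging activity
    forager_prob: float = 0.58        # fraction of tagged bees that forage at all
    activity_intercept: float = 1.7   # baseline log days foraged
    lpi_effect: float = 0.06          # per-LPI-unit effect on log days foraged
    consecutive_fraction: float = 0.92
    bouts_sqrt_intercept: float = 8.48
    colony_age_effect_bouts: float = -0.52   # per day, sqrt(bouts/day) scale
    bouts_sqrt_bee_sd: float = 0.8
    duration_sqrt_intercept: float = 6.36
    colony_age_effect_duration: float = 0.06  # per day, sqrt(minutes) scale
    duration_sqrt_bee_sd: float = 1.5
    duration_log_sd: float = 0.4      # within-bee log-normal spread of durations
    sqrt_floor: float = 0.5           # floor for derived sqrt-scale means
    final_departure_prob: float = 0.5  # foragers whose last departure is unmatched

    # weighing-station observation
    observation_fraction: float = 0.094
    pollen_prob: float = 0.45         # probability an observed bout carries pollen
    outgoing_mass_mean: float = 180.0  # mg
    outgoing_mass_sd: float = 15.0
    nectar_load_mean: float = 50.0    # mg
    nectar_load_sd: float = 15.0
    mass_noise_sd: float = 2.0        # balance repeatability, mg
    pollen_load_probs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    obs_jitter_s: float = 30.0        # |observation time - bout boundary|

    def __post_init__(self) -> None:
        for name in ("forager_prob", "consecutive_fraction", "observation_fraction",
                     "pollen_prob", "final_departure_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("t_log_sd", "worker_mass_sd", "outgoing_mass_sd",
                     "nectar_load_sd", "mass_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.bees_per_colony[0] < 1 or self.bees_per_colony[1] < self.bees_per_colony[0]:
            raise ValueError(f"invalid bees_per_colony range {self.bees_per_colony}")
        if abs(sum(self.pollen_load_probs) - 1.0) > 1e-9 or len(self.pollen_load_probs) != 4:
            raise ValueError("pollen_load_probs must be 4 probabilities summing to 1")
        if self.n_choices < 10:
            raise ValueError("n_choices must be >= 10")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Read a flat ``key = value`` text file (values are Python literals)."""
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path} line {lineno}: expected 'key = value'")
                key, raw = (s.strip() for s in line.split("=", 1))
                if key not in valid:
                    raise ValueError(f"{path} line {lineno}: unknown key {key!r}")
                kwargs[key] = ast.literal_eval(raw)
        return cls(**kwargs)


@dataclass
class SimulatedBee:
    bee_id: str
    colony_id: str
    y0_true: float
    A_true: float
    t_true: float
    worker_age: float
    worker_mass: float
    colony_age: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.y0_true <= 10.0 and 0.0 <= self.y0_true + self.A_true <= 10.0):
            raise ValueError(
                f"bee {self.bee_id}: latent (y0={self.y0_true}, A={self.A_true}) "
                "must keep error counts in [0, 10]")
        if self.t_true <= 0:
            raise ValueError(f"bee {self.bee_id}: t_true must be > 0")


def simulate_choice_sequence(bee: SimulatedBee, n_choices: int,
                             rng: np.random.Generator,
                             pre_probe_max: int = 10) -> ChoiceSequence:
    """One bee's assay record, aligned to start at its first yellow probe.

    A short run of blue (innately preferred) visits precedes the first
    yellow probe; the aligned choice at index x (1-based, counted from
    the probe) is blue with probability
    ``clamp((y0_true + A_true * exp(-x/t_true)) / 10, 0, 1)``.
    """
    if n_choices < 10:
        raise ValueError("n_choices must be >= 10")
    n_pre = int(rng.integers(0, pre_probe_max + 1))
    choices = [Choice(BLUE) for _ in range(n_pre)]
    choices.append(Choice(YELLOW, probed=True))
    x = np.arange(1, n_choices + 1)
    p_err = np.clip((bee.y0_true + bee.A_true * np.exp(-x / bee.t_true)) / 10.0, 0.0, 1.0)
    blue = rng.random(n_choices) < p_err
    choices.extend(Choice(BLUE if b else YELLOW, probed=not b) for b in blue)
    return ChoiceSequence(bee_id=bee.bee_id, choices=choices)


def simulate_bees(config: SimulationConfig, rng: np.random.Generator) -> list[SimulatedBee]:
    bees = []
    for c in range(config.n_colonies):
        colony_id = f"C{c + 1}"
        lo, hi = config.bees_per_colony
        n = int(rng.integers(lo, hi + 1))
        for b in range(n):
            y0 = 10.0 * rng.beta(*config.y0_beta)
            A = (10.0 - y0) * rng.beta(*config.amp_beta)
            t = float(rng.lognormal(config.t_log_mean, config.t_log_sd))
            bees.append(SimulatedBee(
                bee_id=f"{colony_id}-{b + 1:03d}",
                colony_id=colony_id,
                y0_true=y0, A_true=A, t_true=t,
                worker_age=float(np.round(rng.uniform(*config.worker_age_range), 1)),
                worker_mass=float(np.round(
                    max(rng.normal(config.worker_mass_mean, config.worker_mass_sd), 60.0), 1)),
                colony_age=float(np.round(rng.uniform(*config.colony_age_range), 1)),
            ))
    return bees


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, list[ChoiceSequence]]:
    """Bee covariate table plus one choice sequence per bee.

    Deterministic under ``config.seed``; bee counts per colony are drawn
    uniformly from ``config.bees_per_colony``.
    """
    rng = np.random.default_rng(config.seed)
    bees = simulate_bees(config, rng)
    sequences = [simulate_choice_sequence(bee, config.n_choices, rng,
                                          pre_probe_max=config.pre_probe_max)
                 for bee in bees]
    table = pd.DataFrame([{
        "bee_id": b.bee_id, "colony_id": b.colony_id,
        "worker_age": b.worker_age, "worker_mass": b.worker_mass,
        "colony_age": b.colony_age,
        "y0_true": b.y0_true, "A_true": b.A_true, "t_true": b.t_true,
    } for b in bees])
    return table, sequences


# ---------------------------------------------------------------------------
# RFID event log

#: daily flight window: bouts are scheduled between these hours
_DAY_START_H, _DAY_END_H = 6.0, 21.0


def _sample_days(d: int, consecutive: bool, rng: np.random.Generator) -> np.ndarray:
    first = int(rng.integers(0, 10))
    if consecutive or d == 1:
        return first + np.arange(d)
    span = max(2 * d, d + 2)
    offsets = np.sort(rng.choice(span, size=d, replace=False))
    return first + offsets


def _floor_clip(value: float, floor: float, what: str, bee_id: str) -> float:
    if value < floor:
        logger.warning("bee %s: derived %s mean %.3f below floor %.3f; clipped",
                       bee_id, what, value, floor)
        return floor
    return value


def simulate_rfid_log(bees: pd.DataFrame, config: SimulationConfig,
                      rng: np.random.Generator) -> list[TagEvent]:
    """Nest-entrance reader log for a cohort of bees carrying LPI values.

    ``bees`` needs columns bee_id, colony_age and lpi (NaN LPI bees are
    treated as unfittable but still foraging, with the cohort-median
    LPI).  Days foraged are Poisson on the log link
    (intercept + lpi_effect * LPI); bouts per day and bout durations
    have square-root-scale means linear in colony age.  Non-foragers
    leave once and never return.
    """
    events: list[TagEvent] = []
    lpi_fill = float(np.nanmedian(bees["lpi"])) if bees["lpi"].notna().any() else 0.0
    for row in bees.itertuples(index=False):
        lpi = row.lpi if not pd.isna(row.lpi) else lpi_fill
        if rng.random() >= config.forager_prob:
            # never forages: leaves the nest once and does not return
            ts = EPOCH + pd.Timedelta(days=int(rng.integers(0, 10)),
                                      seconds=int(rng.uniform(8, 12) * 3600))
            events.append(TagEvent(row.bee_id, ts, OUT))
            continue

        d = max(1, int(rng.poisson(math.exp(
            config.activity_intercept + config.lpi_effect * lpi))))
        days = _sample_days(d, rng.random() < config.consecutive_fraction, rng)

        m_bouts = _floor_clip(
            config.bouts_sqrt_intercept + config.colony_age_effect_bouts * row.colony_age
            + rng.normal(0.0, config.bouts_sqrt_bee_sd),
            config.sqrt_floor, "sqrt bouts/day", row.bee_id)
        m_dur = _floor_clip(
            config.duration_sqrt_intercept + config.colony_age_effect_duration * row.colony_age
            + rng.normal(0.0, config.duration_sqrt_bee_sd),
            config.sqrt_floor, "sqrt duration", row.bee_id)
        mu_bouts = m_bouts ** 2
        med_dur = m_dur ** 2

        bee_events: list[TagEvent] = []
        for day in days:
            n_bouts = max(1, int(rng.poisson(mu_bouts)))
            t_min = _DAY_START_H * 60.0 + rng.uniform(0.0, 60.0)
            for j in range(n_bouts):
                dur = med_dur * math.exp(rng.normal(0.0, config.duration_log_sd))
                dur = max(dur, 3.0)
                if t_min + dur > _DAY_END_H * 60.0:
                    if j > 0:
                        break
                    # every sampled day gets at least one bout: truncate it
                    dur = max(_DAY_END_H * 60.0 - t_min, 3.0)
                start = EPOCH + pd.Timedelta(days=int(day), seconds=round(t_min * 60.0))
                end = start + pd.Timedelta(seconds=round(dur * 60.0))
                bee_events.append(TagEvent(row.bee_id, start, OUT))
                bee_events.append(TagEvent(row.bee_id, end, IN))
                t_min += dur + rng.uniform(2.0, 10.0)  # time inside the nest
        if bee_events and rng.random() < config.final_departure_prob:
            # final departure from which the bee never returns
            last = bee_events[-1].timestamp
            bee_events.append(TagEvent(
                row.bee_id, last + pd.Timedelta(seconds=round(rng.uniform(5, 15) * 60)), OUT))
        events.extend(bee_events)
    return events


def simulate_observations(bouts: list[Bout], config: SimulationConfig,
                          rng: np.random.Generator) -> list[ObservationRecord]:
    """Weighing-station records for a sampled fraction of bouts.

    Each observed bout yields an outgoing record (bee body mass) and an
    incoming one (body mass + nectar load, or a pollen-load category for
    pollen bouts); timestamps jitter around the bout boundaries within
    the matching tolerance.
    """
    records: list[ObservationRecord] = []
    base_mass: dict[str, float] = {}
    for bout in bouts:
        if rng.random() >= config.observation_fraction:
            continue
        if bout.bee_id not in base_mass:
            base_mass[bout.bee_id] = max(
                rng.normal(config.outgoing_mass_mean, config.outgoing_mass_sd), 60.0)
        m_out = base_mass[bout.bee_id] + rng.normal(0.0, config.mass_noise_sd)
        is_pollen = rng.random() < config.pollen_prob
        if is_pollen:
            load = POLLEN_CLASSES[int(rng.choice(4, p=config.pollen_load_probs))]
            gain = 12.0 * (POLLEN_CLASSES.index(load) + 1) + rng.normal(0.0, 3.0)
        else:
            load = NO_POLLEN
            gain = max(rng.normal(config.nectar_load_mean, config.nectar_load_sd), 2.0)
        m_in = m_out + gain + rng.normal(0.0, config.mass_noise_sd)
        jit = config.obs_jitter_s
        records.append(ObservationRecord(
            bout.bee_id, bout.start + pd.Timedelta(seconds=round(rng.uniform(-jit, jit))),
            "out", round(max(m_out, 1.0), 1)))
        records.append(ObservationRecord(
            bout.bee_id, bout.end + pd.Timedelta(seconds=round(rng.uniform(-jit, jit))),
            "in", round(max(m_in, 1.0), 1), load))
    records.sort(key=lambda r: (r.timestamp, r.bee_id, r.direction))
    return records


# ---------------------------------------------------------------------------
# full study bundle

@dataclass
class StudyData:
    """Everything one simulated field season produces."""

    config: SimulationConfig
    bees: pd.DataFrame                    # covariates (+ latent truth)
    sequences: list[ChoiceSequence]
    scores: pd.DataFrame                  # fitted learning curves + LPI
    events: list[TagEvent]
    observations: list[ObservationRecord]


def simulate_study(config: SimulationConfig) -> StudyData:
    """Simulate a full study: assay, curve fits, RFID season, observations.

    Learning curves are fitted to the simulated choice sequences (so LPI
    carries realistic estimation noise) before LPI drives the activity
    simulation.
    """
    from .bout_extraction import clean_events, extract_bouts

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    bees, sequences = simulate_cohort(config)
    scores = score_cohort(sequences)
    merged = bees.merge(scores[["bee_id", "lpi"]], on="bee_id", how="left")
    events = simulate_rfid_log(merged, config, rng)
    bouts = extract_bouts(clean_events(events))
    observations = simulate_observations(bouts, config, rng)
    return StudyData(config=config, bees=bees, sequences=sequences,
                     scores=scores, events=events, observations=observations)


def write_study(study: StudyData, outdir) -> None:
    """Write bees/choices/events/observations CSVs to a directory."""
    from pathlib import Path

    from .learning_performance import choices_to_frame

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.bees.drop(columns=["y0_true", "A_true", "t_true"]).to_csv(
        out / "bees.csv", index=False)
    choices_to_frame(study.sequences).to_csv(out / "choices.csv", index=False)
    pd.DataFrame(
        [{"bee_id": e.bee_id, "timestamp": e.timestamp.isoformat(), "direction": e.direction}
         for e in study.events]).to_csv(out / "events.csv", index=False)
    pd.DataFrame(
        [{"bee_id": r.bee_id, "timestamp": r.timestamp.isoformat(), "direction": r.direction,
          "mass_mg": r.mass_mg, "pollen_load": r.pollen_load}
         for r in study.observations]).to_csv(out / "observations.csv", index=False)
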