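"""Per-bee learning curves and the Learning Performance Index (LPI).

In the visual learning assay a bee makes 100 sequential choices between
blue (unrewarding, innately preferred) and yellow (sucrose-rewarding)
artificial flowers.  Choices are aligned to the first yellow flower the
bee actually feeds from ("probes"); errors (blue choices) are counted in
consecutive blocks of 10 aligned choices and a first-order decay curve

    y = y0 + A * exp(-x / t)

is fitted, where ``x`` is the number of choices made after the first
yellow probe and ``y`` the number of errors per block.  ``y0`` is the
saturation error level, ``A`` the curve amplitude and ``t`` the decay
constant (learning speed).  The LPI sums the curve-predicted errors at
5, 50 and 100 choices, each clamped to [0, 10], so the score lies in
[0, 30]; low LPI means a fast learner.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

BLUE = "B"
YELLOW = "Y"

#: choice counts at which the fitted curve is evaluated for the LPI
LPI_EVAL_POINTS = (5.0, 50.0, 100.0)

#: per-block error ceiling (block size of the standard binning)
DEFAULT_BIN_SIZE = 10


class UnfittableSequence(Exception):
    """Raised when a choice sequence cannot support a curve fit.

    Mirrors the study's exclusion of bees whose choice data make curve
    fitting impossible (no yellow probe, too few aligned choices, or
    optimiser failure).
    """


@dataclass(frozen=True)
class Choice:
    colour: str          # "B" or "Y"
    probed: bool = False  # bee fed from the flower

    def __post_init__(self) -> None:
        if self.colour not in (BLUE, YELLOW):
            raise ValueError(f"colour must be {BLUE!r} or {YELLOW!r}, got {self.colour!r}")


@dataclass
class ChoiceSequence:
    """One bee's ordered flower choices in the learning assay."""

    bee_id: str
    choices: list[Choice]

    @property
    def first_probe_index(self) -> int | None:
        """Index of the first yellow flower the bee feeds from, or None."""
        for i, c in enumerate(self.choices):
            if c.colour == YELLOW and c.probed:
                return i
        return None

    def aligned(self) -> list[Choice]:
        """Choices made after the first yellow probe (the probe excluded)."""
        idx = self.first_probe_index
        if idx is None:
            raise UnfittableSequence(f"bee {self.bee_id}: no yellow probe in sequence")
        return self.choices[idx + 1:]


@dataclass
class BinnedErrors:
    """Error counts per block of aligned choices.

    ``x_mid`` of block *i* (1-based) is ``bin_size*i - bin_size/2``,
    i.e. 5, 15, ..., 95 for the standard block of 10.
    """

    bee_id: str
    x_mid: np.ndarray
    errors: np.ndarray
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        self.x_mid = np.asarray(self.x_mid, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if len(self.x_mid) != len(self.errors):
            raise ValueError("x_mid and errors must have equal length")
        if np.any(np.diff(self.x_mid) <= 0):
            raise ValueError("x_mid must be strictly increasing")
        if np.any((self.errors < 0) | (self.errors > self.bin_size)):
            raise ValueError(f"errors must lie in [0, {self.bin_size}]")


@dataclass
class LearningCurveFit:
    """Fitted decay-curve parameters and derived LPI for one bee."""

    bee_id: str
    y0: float = math.nan
    A: float = math.nan
    t: float = math.nan
    converged: bool = False
    residual_ss: float = math.nan
    lpi: float = math.nan
    reason: str = ""  # empty if fitted; otherwise why the bee is unfittable

    @property
    def fitted(self) -> bool:
        return self.converged and not self.reason


def decay_curve(x, y0, A, t):
    """First-order decay ``y0 + A * exp(-x / t)``."""
    return y0 + A * np.exp(-np.asarray(x, dtype=float) / t)


def align_and_bin(seq: ChoiceSequence, bin_size: int = DEFAULT_BIN_SIZE) -> BinnedErrors:
    """Align a choice sequence to the first yellow probe and bin the errors.

    Drops choices before (and including) the first yellow probe, partitions
    the rest into consecutive full blocks of ``bin_size`` and counts blue
    choices per block; a trailing partial block is dropped.

    Raises
    ------
    UnfittableSequence
        If the sequence has no yellow probe, or fewer than 3 full blocks
        remain (three points cannot constrain three parameters).
    """
    aligned = seq.aligned()
    n_bins = len(aligned) // bin_size
    if n_bins < 3:
        raise UnfittableSequence(
            f"bee {seq.bee_id}: only {n_bins} full bins of {bin_size} aligned "
            "choices (need >= 3)"
        )
    errors = np.array(
        [
            sum(1 for c in aligned[i * bin_size:(i + 1) * bin_size] if c.colour == BLUE)
            for i in range(n_bins)
        ],
        dtype=float,
    )
    x_mid = bin_size * np.arange(1, n_bins + 1) - bin_size / 2.0
    return BinnedErrors(bee_id=seq.bee_id, x_mid=x_mid, errors=errors, bin_size=bin_size)


def _t_upper(x_mid: np.ndarray) -> float:
    # generous: 10x the span of the data; beyond this the curve is linear
    return 10.0 * float(x_mid[-1] + x_mid[0])


def fit_learning_curve(bins: BinnedErrors) -> LearningCurveFit:
    """Least-squares fit of the decay curve to one bee's binned errors.

    Bounds: y0 in [0, bin_size], A in [-bin_size, bin_size], t > 0.
    Constant data short-circuit to (y0 = c, A = 0, t = NaN) — the
    smallest-|A| member of the degenerate solution family.  Multi-start
    over t0 in {5, 20, 80}; if no start converges the bee is returned
    unfittable rather than raising, so cohort scoring can proceed.
    """
    x, y = bins.x_mid, bins.errors
    if len(x) < 3:
        return LearningCurveFit(bins.bee_id, reason="fewer than 3 bins")
    ymax = float(bins.bin_size)

    if np.ptp(y) == 0.0:  # constant data: flat curve, t unidentifiable
        y0 = float(y[0])
        fit = LearningCurveFit(bins.bee_id, y0=y0, A=0.0, t=math.nan,
                               converged=True, residual_ss=0.0)
        fit.lpi = compute_lpi(fit)
        return fit

    y0_init = float(np.clip(np.mean(y[-2:]), 0.0, ymax))
    a_init = float(np.clip(y[0] - y0_init, -ymax, ymax))
    t_hi = _t_upper(x)
    best = None
    for t0 in (5.0, 20.0, 80.0):
        try:
            popt, _ = curve_fit(
                decay_curve, x, y,
                p0=(y0_init, a_init, t0),
                bounds=([0.0, -ymax, 1e-6], [ymax, ymax, t_hi]),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((decay_curve(x, *popt) - y) ** 2))
        if best is None or rss < best[1] - 1e-12:
            best = (popt, rss)
    if best is None:
        return LearningCurveFit(bins.bee_id, reason="optimizer failed to converge")
    (y0, A, t), rss = best
    fit = LearningCurveFit(bins.bee_id, y0=float(y0), A=float(A), t=float(t),
                           converged=True, residual_ss=rss)
    fit.lpi = compute_lpi(fit)
    return fit


def compute_lpi(fit: LearningCurveFit,
                eval_points: tuple[float, ...] = LPI_EVAL_POINTS,
                ceiling: float = 10.0) -> float:
    """Sum of curve-predicted errors at the evaluation choices.

    Each prediction is clamped to [0, ceiling] before summing, which is
    what bounds the index to [0, 30] for the standard three points.
    A flat fit (A = 0, t undefined) evaluates to y0 everywhere.
    """
    if not fit.converged:
        raise UnfittableSequence(f"bee {fit.bee_id}: cannot score an unfitted curve")
    if fit.A == 0.0 and math.isnan(fit.t):
        preds = np.full(len(eval_points), fit.y0)
    else:
        preds = decay_curve(np.asarray(eval_points), fit.y0, fit.A, fit.t)
    return float(np.sum(np.clip(preds, 0.0, ceiling)))


def score_cohort(sequences: list[ChoiceSequence],
                 bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Fit every bee's learning curve; unfittable bees keep a reason code.

    Returns a DataFrame with one row per bee
    (bee_id, y0, A, t, converged, residual_ss, lpi, reason).
    """
    ids = [s.bee_id for s in sequences]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate bee_id(s): {dupes}")
    rows = []
    for seq in sequences:
        try:
            fit = fit_learning_curve(align_and_bin(seq, bin_size=bin_size))
        except UnfittableSequence as exc:
            fit = LearningCurveFit(seq.bee_id, reason=str(exc))
        rows.append(vars(fit).copy())
    out = pd.DataFrame(
        rows, columns=["bee_id", "y0", "A", "t", "converged", "residual_ss", "lpi", "reason"]
    )
    n_fit = int(out["converged"].sum())
    logger.info("score_cohort: %d fitted, %d unfittable", n_fit, len(out) - n_fit)
    return out


# ---------------------------------------------------------------------------
# choices.csv I/O

def choices_to_frame(sequences: list[ChoiceSequence]) -> pd.DataFrame:
    rows = [
        {"bee_id": s.bee_id, "visit_index": i, "colour": c.colour, "probed": int(c.probed)}
        for s in sequences
        for i, c in enumerate(s.choices)
    ]
    return pd.DataFrame(rows, columns=["bee_id", "visit_index", "colour", "probed"])


def frame_to_choices(df: pd.DataFrame) -> list[ChoiceSequence]:
    seqs = []
    for bee_id, grp in df.groupby("bee_id", sort=True):
        grp = grp.sort_values("visit_index")
        seqs.append(ChoiceSequence(
            bee_id=str(bee_id),
            choices=[Choice(colour=r.colour, probed=bool(r.probed))
                     for r in grp.itertuples()],
        ))
    return seqs


def read_choices(path) -> list[ChoiceSequence]:
    return frame_to_choices(pd.read_csv(path, dtype={"bee_id": str}))


def write_scores(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
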