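"""Transmigration ratios, population retention and condition contrasts.

Works from frame-indexed compartment counts of a neutrophil population in
one field of view: cells crawling on the luminal endothelial surface,
cells that have crossed the monolayer (transmigrated; any sub-endothelial
location counts, including cells that subsequently fell off into the
bottom channel and left the field of view, tallied separately as "lost").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bbbkit.migration import COMPARTMENTS, Trajectory

__all__ = [
    "CountTable",
    "TransmigrationResult",
    "RetentionFit",
    "ContrastResult",
    "counts_from_tracks",
    "transmigration_ratio",
    "population_retention",
    "condition_contrast",
]


@dataclass
class CountTable:
    """Frame-indexed compartment counts of one field of view.

    Columns are disjoint: every cell is luminal, transmigrated (still in
    view below the monolayer) or lost (fell off into the bottom channel),
    so ``luminal + transmigrated + lost`` is the total population.
    """

    frame: np.ndarray
    t: np.ndarray  # seconds
    luminal: np.ndarray
    transmigrated: np.ndarray
    lost: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.luminal = np.asarray(self.luminal, dtype=int)
        self.transmigrated = np.asarray(self.transmigrated, dtype=int)
        if self.lost is None:
            self.lost = np.zeros_like(self.luminal)
        else:
            self.lost = np.asarray(self.lost, dtype=int)
        lens = {len(a) for a in (self.frame, self.t, self.luminal,
                                 self.transmigrated, self.lost)}
        if len(lens) != 1:
            raise ValueError("all columns must have equal length")
        if np.any(np.diff(self.frame) <= 0):
            raise ValueError("frames must be strictly increasing")
        for name in ("luminal", "transmigrated", "lost"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} counts must be non-negative")

    @property
    def total(self) -> np.ndarray:
        return self.luminal + self.transmigrated + self.lost

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.frame, "t_s": self.t, "luminal": self.luminal,
            "transmigrated": self.transmigrated, "lost": self.lost,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        lost = df["lost"].to_numpy() if "lost" in df else None
        return cls(df["frame"].to_numpy(), df["t_s"].to_numpy(),
                   df["luminal"].to_numpy(), df["transmigrated"].to_numpy(),
                   lost)


@dataclass
class TransmigrationResult:
    """Steady-state transmigration ratio of one recording.

    ``ratio`` is the mean per-frame ratio (percent of the population that
    has crossed the endothelium) over the steady-state window;
    ``final_frame_ratio`` is the last sampled frame's ratio, reported
    alongside because either convention appears in practice.
    """

    ratio: float
    per_frame_ratio: np.ndarray
    steady_state_start: float
    n_frames_used: int
    final_frame_ratio: float


@dataclass
class RetentionFit:
    """Linear fit of the normalized field-of-view population over time.

    ``slope`` is in fraction of the initial population per minute.
    ``degenerate`` marks a perfectly constant population, where r² is
    undefined and reported as 0.
    """

    slope: float
    intercept: float
    r2: float
    degenerate: bool = False


@dataclass
class ContrastResult:
    """Percent change of condition b relative to condition a.

    Positive values mean b is lower than a ("reduced by X%"); the SD is
    propagated from replicate scatter by the delta method.
    """

    percent_reduction: float
    sd: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def counts_from_tracks(tracks: Sequence[Trajectory]) -> CountTable:
    """Tally per-frame compartment labels of a track collection.

    All tracks must share the same frame times. Unknown labels raise
    (validated at Trajectory construction).
    """
    if not tracks:
        raise ValueError("no trajectories given")
    t = tracks[0].t
    n_frames = len(t)
    counts = {name: np.zeros(n_frames, dtype=int) for name in COMPARTMENTS}
    for tr in tracks:
        if len(tr) != n_frames or abs(tr.dt - tracks[0].dt) > 1e-6 * tracks[0].dt:
            raise ValueError("all tracks must share the same frame grid")
        for name in COMPARTMENTS:
            counts[name] += tr.compartment == name
    return CountTable(
        frame=np.arange(n_frames), t=t,
        luminal=counts["luminal"], transmigrated=counts["transmigrated"],
        lost=counts["lost"],
    )


def transmigration_ratio(
    table: CountTable,
    steady_state_start: float = 900.0,
    steady_state_end: float | None = None,
    include_lost: bool = True,
) -> TransmigrationResult:
    """Steady-state transmigration ratio in percent.

    The per-frame ratio is transmigrated (plus lost, by default — those
    cells crossed the endothelium before falling out of view) divided by
    the total population. The result is the mean of per-frame ratios over
    frames at or after ``steady_state_start`` seconds (default 900 s,
    i.e. the window after the ~15-min establishment of the diapedesis
    response), which is robust to slow population drift.

    Set ``include_lost=False`` for a field-of-view-only ratio
    (transmigrated / (luminal + transmigrated)).
    """
    total = table.total
    if np.any(total == 0):
        raise ValueError("zero population at some frame")
    if include_lost:
        per_frame = (table.transmigrated + table.lost) / total
    else:
        in_fov = table.luminal + table.transmigrated
        if np.any(in_fov == 0):
            raise ValueError("zero in-FOV population at some frame")
        per_frame = table.transmigrated / in_fov
    window = table.t >= steady_state_start
    if steady_state_end is not None:
        window &= table.t <= steady_state_end
    if window.sum() < 2:
        raise ValueError("steady-state window must contain at least 2 frames")
    return TransmigrationResult(
        ratio=float(100.0 * per_frame[window].mean()),
        per_frame_ratio=100.0 * per_frame,
        steady_state_start=steady_state_start,
        n_frames_used=int(window.sum()),
        final_frame_ratio=float(100.0 * per_frame[-1]),
    )


def population_retention(table: CountTable) -> RetentionFit:
    """OLS fit of the normalized in-view population against time.

    The field-of-view population is luminal + transmigrated (lost cells
    left the recording). Counts are normalized to the first frame and
    regressed on time in minutes, so the slope is the fraction of the
    initial population gained/lost per minute.
    """
    if len(table.frame) < 2:
        raise ValueError("need at least 2 frames to fit retention")
    pop = (table.luminal + table.transmigrated).astype(float)
    if pop[0] <= 0:
        raise ValueError("frame-0 population must be positive")
    norm = pop / pop[0]
    t_min = table.t / 60.0
    if np.allclose(norm, norm[0]):
        return RetentionFit(slope=0.0, intercept=float(norm[0]), r2=0.0,
                            degenerate=True)
    res = stats.linregress(t_min, norm)
    return RetentionFit(slope=float(res.slope), intercept=float(res.intercept),
                        r2=float(res.rvalue ** 2))


def condition_contrast(
    a: Sequence[float] | TransmigrationResult,
    b: Sequence[float] | TransmigrationResult,
) -> ContrastResult:
    """Percent reduction of condition b relative to condition a.

    Arguments are replicate steady-state ratios (or single
    :class:`TransmigrationResult` objects). Returns
    100·(mean_a − mean_b)/mean_a; negative when b exceeds a. The SD is the
    delta-method propagation of the replicate SDs (0 when either side has
    a single replicate).
    """
    ra = _as_ratios(a)
    rb = _as_ratios(b)
    mean_a, mean_b = float(np.mean(ra)), float(np.mean(rb))
    if mean_a == 0:
        raise ValueError("reference condition has zero mean ratio")
    sd_a = float(np.std(ra, ddof=1)) if len(ra) > 1 else 0.0
    sd_b = float(np.std(rb, ddof=1)) if len(rb) > 1 else 0.0
    # delta method on f(a, b) = 100·(1 − b/a)
    sd = math.hypot(100.0 * mean_b / mean_a**2 * sd_a, 100.0 / mean_a * sd_b)
    return ContrastResult(
        percent_reduction=100.0 * (mean_a - mean_b) / mean_a,
        sd=sd, mean_a=mean_a, mean_b=mean_b, n_a=len(ra), n_b=len(rb),
    )


def _as_ratios(x: Sequence[float] | TransmigrationResult) -> np.ndarray:
    if isinstance(x, TransmigrationResult):
        return np.array([x.ratio], dtype=float)
    arr = np.asarray(
        [v.ratio if isinstance(v, TransmigrationResult) else v for v in x],
        dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one replicate per condition")
    return arr
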