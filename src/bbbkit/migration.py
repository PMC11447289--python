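"""Mean squared displacement analysis and persistent-random-walk fitting.

Crawling leukocytes are well described by a persistent random walk (PRW):
directionally correlated motion whose velocity autocorrelation decays
exponentially with a persistence time ``P``. The population mean squared
displacement then follows the Fürth equation

    <d²>(τ) = n · S² · P · [τ − P · (1 − exp(−τ/P))]

with crawling speed ``S``, persistence time ``P`` and dimensionality
``n = 2`` for in-plane crawling. The model interpolates between ballistic
motion <d²> = S²τ² at lags τ ≪ P and diffusive motion <d²> = n·S²·P·τ at
lags τ ≫ P.

This module computes time-averaged MSD curves from centroid trajectories
(overlapping displacement pairs, pooled across cells) and fits the Fürth
model by weighted nonlinear least squares, reporting S in μm/min and P in
seconds as is conventional for neutrophil crawling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Trajectory",
    "MSDCurve",
    "PRWFit",
    "PopulationSummary",
    "furth_msd",
    "compute_msd",
    "fit_prw",
    "per_cell_fits",
]

#: compartment labels a trajectory may carry per frame
COMPARTMENTS = ("luminal", "transmigrated", "lost")


@dataclass
class Trajectory:
    """One cell's time-stamped 2-D centroid path.

    Parameters
    ----------
    cell_id : identifier for the cell.
    t : frame times in seconds, strictly increasing, uniformly spaced.
    x, y : centroid coordinates in μm.
    compartment : per-frame label, one of ``luminal``, ``transmigrated``,
        ``lost``. Defaults to all-luminal.
    boundary_flag : True if the track touched the field-of-view boundary
        (reflected tracks are excluded from MSD fits by default).
    """

    cell_id: int | str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    compartment: np.ndarray | None = None
    boundary_flag: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if len(self.x) != len(self.t) or len(self.y) != len(self.t):
            raise ValueError("t, x, y must have equal length")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.x))
                and np.all(np.isfinite(self.y))):
            raise ValueError("trajectory coordinates must be finite")
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            raise ValueError("frame times must be strictly increasing")
        dt = dts[0]
        if np.any(np.abs(dts - dt) > 1e-6 * dt):
            raise ValueError("frame interval must be uniform within 1e-6·dt")
        if self.compartment is None:
            self.compartment = np.full(len(self.t), "luminal", dtype="<U13")
        else:
            self.compartment = np.asarray(self.compartment)
            if len(self.compartment) != len(self.t):
                raise ValueError("compartment labels must match frame count")
            bad = set(np.unique(self.compartment)) - set(COMPARTMENTS)
            if bad:
                raise ValueError(f"unknown compartment label(s): {sorted(bad)}")

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class MSDCurve:
    """Pooled time-averaged MSD versus lag time.

    ``msd[k]`` is the mean squared displacement at lag ``lag[k]`` seconds,
    averaged over all overlapping frame pairs of all contributing tracks;
    ``n_pairs[k]`` counts those pairs (used as fit weights). The zero lag is
    omitted (MSD(0) ≡ 0 by convention).
    """

    lag: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    dt: float
    n_tracks: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(self.msd < 0):
            raise ValueError("msd values must be non-negative")
        if np.any(np.diff(self.n_pairs) > 0):
            raise ValueError("n_pairs must be non-increasing in lag")


@dataclass
class PRWFit:
    """Fitted persistent-random-walk parameters.

    S is in μm/min, P in seconds; ``n`` is the dimensionality (2 for
    in-plane crawling). ``p_at_bound`` marks a persistence estimate pinned
    at a fit bound — the persistence is then not identifiable from the
    available lag range (e.g. purely ballistic data).
    """

    S: float
    P: float
    n: int
    residual_rms: float
    k_max_used: int
    n_tracks: int
    converged: bool
    p_at_bound: bool = False


@dataclass
class PopulationSummary:
    """Mean ± SD of per-cell fitted parameters, excluding failed fits."""

    mean_S: float
    sd_S: float
    mean_P: float
    sd_P: float
    n_fit: int
    n_failed: int


def furth_msd(lag: np.ndarray | float, S: float, P: float, n: int = 2) -> np.ndarray:
    """Fürth MSD model, <d²>(τ) = n·S²·P·[τ − P(1 − e^(−τ/P))].

    ``S`` in μm/s, ``P`` and ``lag`` in seconds; result in μm².
    """
    tau = np.asarray(lag, dtype=float)
    return n * S * S * P * (tau - P * (1.0 - np.exp(-tau / P)))


def _accumulate_msd(x: np.ndarray, y: np.ndarray, k_max: int,
                    sums: np.ndarray, counts: np.ndarray) -> None:
    # time-averaged MSD over all overlapping pairs, lags 1..k_max
    for k in range(1, min(k_max, len(x) - 1) + 1):
        dx = x[k:] - x[:-k]
        dy = y[k:] - y[:-k]
        sums[k - 1] += float(np.sum(dx * dx + dy * dy))
        counts[k - 1] += len(dx)


def compute_msd(
    tracks: Sequence[Trajectory],
    max_lag_fraction: float = 0.25,
    min_track_length: int = 100,
    include_boundary: bool = False,
    luminal_only: bool = False,
) -> MSDCurve:
    """Pooled time-averaged MSD curve from a collection of trajectories.

    All overlapping displacement pairs within each track contribute, and
    tracks are pooled weighted by pair count. Lags are capped at
    ``floor(max_lag_fraction × shortest track length)`` frame intervals to
    limit the strongly correlated, poorly sampled long lags.

    Parameters
    ----------
    tracks : trajectories sharing one frame interval.
    max_lag_fraction : fraction of the shortest usable track length that
        sets the maximum lag (default 0.25).
    min_track_length : tracks with fewer frames are excluded and counted in
        ``n_excluded`` (default 100, matching the tracking protocol's
        minimum of 100 data points per track).
    include_boundary : include tracks that touched the FOV boundary
        (excluded by default because reflection distorts displacements).
    luminal_only : restrict each track to its leading luminal segment
        before computing displacements.

    Raises
    ------
    ValueError : empty input, mixed frame intervals, or no usable track.
    """
    if not tracks:
        raise ValueError("no trajectories given")
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")

    dt = tracks[0].dt
    usable: list[tuple[np.ndarray, np.ndarray]] = []
    n_excluded = 0
    for tr in tracks:
        if abs(tr.dt - dt) > 1e-6 * dt:
            raise ValueError("all tracks must share the same frame interval")
        if tr.boundary_flag and not include_boundary:
            n_excluded += 1
            continue
        x, y = tr.x, tr.y
        if luminal_only:
            lum = tr.compartment == "luminal"
            stop = len(lum) if lum.all() else int(np.argmin(lum))
            x, y = x[:stop], y[:stop]
        if len(x) < min_track_length:
            n_excluded += 1
            continue
        usable.append((x, y))
    if not usable:
        raise ValueError(
            f"no usable tracks (all {len(tracks)} excluded by length/boundary filters)")

    shortest = min(len(x) for x, _ in usable)
    k_max = max(1, min(math.floor(max_lag_fraction * shortest), shortest - 1))
    sums = np.zeros(k_max)
    counts = np.zeros(k_max, dtype=int)
    for x, y in usable:
        _accumulate_msd(x, y, k_max, sums, counts)
    return MSDCurve(
        lag=dt * np.arange(1, k_max + 1),
        msd=sums / counts,
        n_pairs=counts,
        dt=dt,
        n_tracks=len(usable),
        n_excluded=n_excluded,
    )


def _initial_guess(curve: MSDCurve) -> tuple[float, float]:
    """(S0 in μm/s, P0 in s) from the short-lag ballistic regime and the
    lag where the log-log slope of the MSD crosses 1.5."""
    s0 = math.sqrt(max(curve.msd[0], 1e-300)) / curve.lag[0]
    p0 = 5.0 * curve.dt
    pos = curve.msd > 0
    if pos.sum() >= 3:
        loglag = np.log(curve.lag[pos])
        logmsd = np.log(curve.msd[pos])
        slope = np.gradient(logmsd, loglag)
        below = np.nonzero(slope <= 1.5)[0]
        if below.size:
            p0 = float(curve.lag[pos][below[0]])
    return s0, p0


def fit_prw(
    curve: MSDCurve,
    n: int = 2,
    weighted: bool = True,
) -> PRWFit:
    """Fit the Fürth PRW model to an MSD curve by nonlinear least squares.

    Residuals are relative errors (model − msd)/msd, weighted by the square
    root of the pair count at each lag; the variance model is
    Var(msd_k) ∝ msd_k²/n_pairs_k, the standard heteroscedasticity of
    time-averaged MSD estimates (their scatter grows with the MSD itself,
    so absolute residuals would let the noisy long lags swamp the
    short-lag ballistic regime that identifies S and P separately). Set
    ``weighted=False`` for unweighted relative residuals. Speed is bounded in
    (0, 10·S₀] and persistence in (dt/10, 10·τ_max]; a persistence estimate
    at a bound is flagged ``p_at_bound`` (non-identifiable) and reported as
    not converged for summary purposes.
    """
    if len(curve.lag) < 4:
        raise ValueError("need at least 4 lag points to fit the PRW model")
    if not np.all(np.isfinite(curve.msd)):
        raise ValueError("msd values must be finite")

    s0, p0 = _initial_guess(curve)
    s_hi = 10.0 * max(s0, 1e-12)
    p_lo, p_hi = curve.dt / 10.0, 10.0 * float(curve.lag[-1])
    p0 = min(max(p0, p_lo * 1.01), p_hi * 0.99)
    w = np.sqrt(curve.n_pairs) if weighted else np.ones_like(curve.msd)
    scale = np.where(curve.msd > 0, curve.msd, 1.0)

    def resid(theta: np.ndarray) -> np.ndarray:
        return w * (furth_msd(curve.lag, theta[0], theta[1], n) - curve.msd) / scale

    sol = least_squares(
        resid,
        x0=[max(s0, 1e-12), p0],
        bounds=([1e-12, p_lo], [s_hi, p_hi]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    s_hat, p_hat = float(sol.x[0]), float(sol.x[1])
    at_bound = p_hat >= p_hi * (1 - 1e-6) or p_hat <= p_lo * (1 + 1e-6)
    model = furth_msd(curve.lag, s_hat, p_hat, n)
    rms = float(np.sqrt(np.mean((model - curve.msd) ** 2)))
    return PRWFit(
        S=s_hat * 60.0,  # μm/s → μm/min
        P=p_hat,
        n=n,
        residual_rms=rms,
        k_max_used=len(curve.lag),
        n_tracks=curve.n_tracks,
        converged=bool(sol.success) and not at_bound,
        p_at_bound=at_bound,
    )


def per_cell_fits(
    tracks: Sequence[Trajectory],
    max_lag_fraction: float = 0.25,
    min_track_length: int = 100,
    include_boundary: bool = False,
    n: int = 2,
    weighted: bool = True,
) -> tuple[list[PRWFit], PopulationSummary]:
    """One PRW fit per track plus a population summary (mean ± SD).

    Non-converged or bound-flagged fits are excluded from the summary but
    counted in ``n_failed``. If every fit fails the summary is empty (NaN
    means, ``n_fit = 0``) rather than raising.
    """
    fits: list[PRWFit] = []
    n_failed = 0
    for tr in tracks:
        try:
            curve = compute_msd(
                [tr],
                max_lag_fraction=max_lag_fraction,
                min_track_length=min_track_length,
                include_boundary=include_boundary,
            )
            fit = fit_prw(curve, n=n, weighted=weighted)
        except ValueError:
            n_failed += 1
            continue
        fits.append(fit)
        if not fit.converged:
            n_failed += 1
    good = [f for f in fits if f.converged]
    if good:
        s = np.array([f.S for f in good])
        p = np.array([f.P for f in good])
        summary = PopulationSummary(
            mean_S=float(s.mean()), sd_S=float(s.std(ddof=1)) if len(s) > 1 else 0.0,
            mean_P=float(p.mean()), sd_P=float(p.std(ddof=1)) if len(p) > 1 else 0.0,
            n_fit=len(good), n_failed=n_failed,
        )
    else:
        summary = PopulationSummary(
            mean_S=float("nan"), sd_S=float("nan"),
            mean_P=float("nan"), sd_P=float("nan"),
            n_fit=0, n_failed=n_failed,
        )
    return fits, summary
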