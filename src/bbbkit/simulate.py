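"""Seeded synthetic-data generators with known ground truth.

Every analysis surface of the package has a matched generator here, so the
full pipeline (trajectories → MSD → PRW fit; compartment labels → counts →
transmigration ratio; assay readouts → permeability; images → fold-change
and z-profiles) can be exercised and validated by parameter recovery
without any microscopy or plate-reader data.

Trajectory model
----------------
Cell velocity follows a stationary Ornstein–Uhlenbeck process per
component, autocovariance (S²/2)·e^(−t/P) (so E|v|² = S² in 2-D), which is
the generative process whose population MSD is exactly the Fürth
persistent-random-walk curve. Position and velocity are advanced jointly
with the exact Gaussian transition of the integrated OU process, so the
sampled positions follow the continuous-time law with no time-step bias;
the velocity marginal reduces to v ← v·e^(−dt/P) + √(1−e^(−2dt/P))·(S/√2)·ξ.

Diapedesis is a two-state (plus absorbing loss) jump process: a Bernoulli
"responder" subpopulation transmigrates with an exponential hazard, after
which independent hazards govern falling out of view and (optionally)
reverse migration. With no reverse migration the transmigrated fraction
plateaus at responder_fraction × (1 − e^(−λt)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from bbbkit.migration import Trajectory
from bbbkit.permeability import PermeabilityRecord
from bbbkit.trafficking import CountTable

__all__ = [
    "TrackSimConfig",
    "AssaySimConfig",
    "ImageSimConfig",
    "ou_velocity_series",
    "simulate_tracks",
    "simulate_count_table",
    "simulate_assay",
    "simulate_images",
    "simulate_image_batch",
]


@dataclass
class TrackSimConfig:
    """Truth parameters for one simulated trafficking recording.

    Defaults mirror the recording protocol the analysis expects: one frame
    every 4 s for 450 frames (30 min), a ~333 μm square field of view
    (2048 px at 6.5-μm camera pixels under 40×), and hazard rates in 1/min.
    ``true_speed`` is in μm/min, ``true_persistence`` in seconds.
    """

    n_cells: int = 12
    true_speed: float = 15.0
    true_persistence: float = 30.0
    dt: float = 4.0
    n_frames: int = 450
    fov_size: tuple[float, float] = (333.0, 333.0)
    responder_fraction: float = 0.0
    diapedesis_hazard: float = 0.3
    falloff_hazard: float = 0.0
    reverse_hazard: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.true_speed, self.true_persistence,
                                       self.dt))):
            raise ValueError("speed, persistence and dt must be finite")
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.true_speed < 0:
            raise ValueError("true_speed must be non-negative")
        if self.true_persistence <= 0:
            raise ValueError(
                "persistence must be positive (P = 0 has no PRW limit; "
                "use a dedicated Brownian generator instead)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        for name in ("diapedesis_hazard", "falloff_hazard", "reverse_hazard"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if min(self.fov_size) <= 0:
            raise ValueError("fov_size must be positive")


@dataclass
class AssaySimConfig:
    """Truth parameters for a simulated sampling permeability assay.

    ``true_Pe`` and ``membrane_Pm`` in cm/min; the bottom compartment is
    one well-mixed volume ``bottom_volume`` (ml) whose concentration is
    read after ``duration`` minutes. Defaults: 150 μg/ml loading, 1-h
    incubation, 50-μl effective bottom/sample volume, 0.01 cm² membrane.
    """

    true_Pe: float = 0.6e-3
    membrane_Pm: float = 2.0e-2
    Ci: float = 150.0
    top_volume: float = 0.1
    bottom_volume: float = 0.05
    sample_volume: float = 0.05
    duration: float = 60.0
    area: float = 0.01
    noise_cv: float = 0.05
    n_devices: int = 11
    transport_model: str = "sink_linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_Pe <= 0:
            raise ValueError("true_Pe must be positive")
        if self.membrane_Pm <= self.true_Pe:
            raise ValueError(
                "membrane_Pm must exceed true_Pe (series resistances imply "
                "P_S < P_M)")
        for name in ("Ci", "top_volume", "bottom_volume", "sample_volume",
                     "duration", "area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_devices < 1:
            raise ValueError("n_devices must be at least 1")
        if self.transport_model not in ("sink_linear", "two_compartment_ode"):
            raise ValueError("unknown transport_model")

    @property
    def true_Ps(self) -> float:
        """System permeability implied by the series resistances, cm/min."""
        return 1.0 / (1.0 / self.true_Pe + 1.0 / self.membrane_Pm)


@dataclass
class ImageSimConfig:
    """Truth parameters for simulated fluorescence images or z-stacks.

    2-D shape → flat image of mean ``baseline_intensity × fold_change``
    plus Gaussian noise. 3-D shape (z, y, x) → each protein layer adds a
    Gaussian z-profile of width ``layer_widths`` centered at its offset
    (μm) from the membrane plane at z = 0; ``membrane_index`` locates that
    plane within the stack at ``z_spacing`` μm per slice (0.2 by default,
    the confocal stepping the profiles assume).
    """

    shape: tuple[int, ...] = (64, 64)
    baseline_intensity: float = 1000.0
    fold_change: float = 1.0
    layer_centers: Sequence[float] = ()
    layer_widths: Sequence[float] | float = 0.4
    membrane_index: int | None = None
    z_spacing: float = 0.2
    noise_sigma: float = 0.0
    roi_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) not in (2, 3) or min(self.shape) < 1:
            raise ValueError("shape must be 2-D (y, x) or 3-D (z, y, x)")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")
        if self.z_spacing <= 0:
            raise ValueError("z_spacing must be positive")
        if self.roi_mask is not None and not np.asarray(self.roi_mask).any():
            raise ValueError("roi_mask must select at least one pixel")


def _ou_step_moments(s_um_s: float, p: float, dt: float):
    """Exact one-step covariance structure of (velocity, position increment)
    for the integrated OU process, per component.

    Velocity relaxation rate λ = 1/P, stationary velocity variance S²/2.
    Returns (a, sd_v, cov_xv/var_v ratio term handled by caller) pieces:
    a = e^(−λdt), var_v_step, var_x_step, cov_xv_step.
    """
    lam = 1.0 / p
    a = math.exp(-lam * dt)
    sv2 = 0.5 * s_um_s * s_um_s  # per-component stationary velocity variance
    var_v = sv2 * (1.0 - a * a)
    var_x = (sv2 / lam**2) * (2.0 * lam * dt - 3.0 + 4.0 * a - a * a)
    cov_xv = (sv2 / lam) * (1.0 - a) ** 2
    return a, var_v, var_x, cov_xv


def ou_velocity_series(
    speed: float, persistence: float, dt: float, n_steps: int, seed: int = 0,
) -> np.ndarray:
    """Sample the stationary 2-D OU velocity process at the frame grid.

    ``speed`` in μm/min, ``persistence`` in s; returns an (n_steps, 2)
    array in μm/s with E|v|² = (speed/60)². Diagnostic counterpart of the
    velocity law driving :func:`simulate_tracks`.
    """
    rng = np.random.default_rng(seed)
    s_um_s = speed / 60.0
    a, var_v, _, _ = _ou_step_moments(s_um_s, persistence, dt)
    sd_v = math.sqrt(var_v)
    v = np.empty((n_steps, 2))
    v[0] = rng.normal(0.0, math.sqrt(0.5) * s_um_s, size=2)
    for k in range(1, n_steps):
        v[k] = v[k - 1] * a + sd_v * rng.standard_normal(2)
    return v


def _simulate_compartments(cfg: TrackSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-cell, per-frame compartment codes (0 luminal, 1 transmigrated,
    2 lost) of the diapedesis jump process."""
    dt_min = cfg.dt / 60.0
    p_dia = 1.0 - math.exp(-cfg.diapedesis_hazard * dt_min)
    exit_hazard = cfg.falloff_hazard + cfg.reverse_hazard
    p_exit = 1.0 - math.exp(-exit_hazard * dt_min)
    p_fall = cfg.falloff_hazard / exit_hazard if exit_hazard > 0 else 0.0

    responder = rng.random(cfg.n_cells) < cfg.responder_fraction
    state = np.zeros(cfg.n_cells, dtype=np.int8)
    codes = np.zeros((cfg.n_cells, cfg.n_frames), dtype=np.int8)
    for k in range(1, cfg.n_frames):
        u = rng.random(cfg.n_cells)
        lum = state == 0
        trans = state == 1
        state[lum & responder & (u < p_dia)] = 1
        exiting = trans & (u < p_exit)
        if np.any(exiting):
            v = rng.random(cfg.n_cells)
            state[exiting & (v < p_fall)] = 2
            state[exiting & (v >= p_fall)] = 0
        codes[:, k] = state
    return codes


def simulate_tracks(cfg: TrackSimConfig) -> list[Trajectory]:
    """Simulate OU persistent-random-walk trajectories with diapedesis.

    Cells start uniformly in the field of view with stationary velocities
    and are advanced with the exact integrated-OU transition, so the
    population MSD matches the Fürth curve for the configured (S, P) at
    every sampled lag. Positions are reflected at the FOV boundary (with
    the velocity component flipped) and such tracks carry
    ``boundary_flag=True`` so fits can exclude them. Compartment labels
    evolve per the configured hazards; positions are simulated for the full
    recording regardless of compartment, matching tracking of cells for as
    many frames as possible. Bit-reproducible for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    s_um_s = cfg.true_speed / 60.0
    n, m = cfg.n_cells, cfg.n_frames
    lx, ly = cfg.fov_size

    codes = _simulate_compartments(cfg, rng)

    pos = np.empty((n, m, 2))
    pos[:, 0, 0] = rng.uniform(0, lx, n)
    pos[:, 0, 1] = rng.uniform(0, ly, n)
    if s_um_s == 0.0:
        pos[:] = pos[:, :1, :]
        flags = np.zeros(n, dtype=bool)
    else:
        a, var_v, var_x, cov_xv = _ou_step_moments(s_um_s, cfg.true_persistence,
                                                   cfg.dt)
        sd_v = math.sqrt(var_v)
        # condition position noise on velocity noise (joint Gaussian)
        beta = cov_xv / var_v
        sd_x_cond = math.sqrt(max(var_x - cov_xv**2 / var_v, 0.0))
        lam = 1.0 / cfg.true_persistence
        vel = rng.normal(0.0, math.sqrt(0.5) * s_um_s, size=(n, 2))
        flags = np.zeros(n, dtype=bool)
        bounds = np.array([lx, ly])
        for k in range(1, m):
            z1 = rng.standard_normal((n, 2))
            z2 = rng.standard_normal((n, 2))
            xi_v = sd_v * z1
            xi_x = beta * xi_v + sd_x_cond * z2
            new_pos = pos[:, k - 1, :] + vel * (1.0 - a) / lam + xi_x
            vel = vel * a + xi_v
            # reflect into [0, L] and flip the velocity component
            for c in range(2):
                low = new_pos[:, c] < 0
                high = new_pos[:, c] > bounds[c]
                while low.any() or high.any():
                    flags |= low | high
                    new_pos[low, c] = -new_pos[low, c]
                    new_pos[high, c] = 2 * bounds[c] - new_pos[high, c]
                    vel[low | high, c] *= -1.0
                    low = new_pos[:, c] < 0
                    high = new_pos[:, c] > bounds[c]
            pos[:, k, :] = new_pos

    t = cfg.dt * np.arange(m)
    names = np.array(["luminal", "transmigrated", "lost"])
    return [
        Trajectory(
            cell_id=i,
            t=t,
            x=pos[i, :, 0],
            y=pos[i, :, 1],
            compartment=names[codes[i]],
            boundary_flag=bool(flags[i]),
        )
        for i in range(n)
    ]


def simulate_count_table(cfg: TrackSimConfig, cadence: int = 1) -> CountTable:
    """Simulate a frame-sampled compartment count table.

    Counts the diapedesis jump process of ``cfg.n_cells`` cells at frames
    {0, cadence, 2·cadence, …} (cadence 30 mirrors the manual counting
    protocol of tabulating every 30th frame). Conservation holds exactly:
    luminal + transmigrated + lost = n_cells at every sampled frame.
    """
    if cadence < 1:
        raise ValueError("cadence must be at least 1")
    if cadence > cfg.n_frames - 1:
        raise ValueError("cadence exceeds the recording length")
    rng = np.random.default_rng(cfg.seed)
    codes = _simulate_compartments(cfg, rng)
    frames = np.arange(0, cfg.n_frames, cadence)
    sampled = codes[:, frames]
    return CountTable(
        frame=frames,
        t=frames * cfg.dt,
        luminal=(sampled == 0).sum(axis=0),
        transmigrated=(sampled == 1).sum(axis=0),
        lost=(sampled == 2).sum(axis=0),
    )


def simulate_assay(cfg: AssaySimConfig) -> list[PermeabilityRecord]:
    """Simulate per-device tracer concentrations of the sampling assay.

    ``sink_linear`` keeps the top concentration fixed and accumulates
    C_t = C_i·P_S·A·t / V_b; ``two_compartment_ode`` solves the mass-
    conserving exchange dC_b/dt = P_S·A·(C_top − C_b)/V_b, whose solution
    is the exponential equilibration of the two compartments. Plate-reader
    scatter is multiplicative lognormal with the configured CV (mean-one,
    so the concentration is unbiased). Records carry the membrane
    permeability so the endothelial coefficient can be recovered.
    """
    rng = np.random.default_rng(cfg.seed)
    ps = cfg.true_Ps
    if cfg.transport_model == "sink_linear":
        ct_clean = cfg.Ci * ps * cfg.area * cfg.duration / cfg.bottom_volume
    else:
        # closed form of the linear two-compartment system
        k = ps * cfg.area * (1.0 / cfg.top_volume + 1.0 / cfg.bottom_volume)
        c_eq = cfg.Ci * cfg.top_volume / (cfg.top_volume + cfg.bottom_volume)
        ct_clean = c_eq * (1.0 - math.exp(-k * cfg.duration))
    if ct_clean >= cfg.Ci:
        raise ValueError("simulated C_t reached the loading concentration; "
                         "check volumes and duration")
    records = []
    for _ in range(cfg.n_devices):
        if cfg.noise_cv > 0:
            sigma = math.sqrt(math.log1p(cfg.noise_cv**2))
            ct = ct_clean * rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma)
        else:
            ct = ct_clean
        records.append(PermeabilityRecord(
            Ct=min(ct, cfg.Ci * (1.0 - 1e-12)),
            V=cfg.bottom_volume,
            Ci=cfg.Ci,
            t=cfg.duration,
            A=cfg.area,
            Pm=cfg.membrane_Pm,
        ))
    return records


def _stack_profile(cfg: ImageSimConfig) -> np.ndarray:
    nz = cfg.shape[0]
    mem = cfg.membrane_index if cfg.membrane_index is not None else nz // 2
    if not 0 <= mem < nz:
        raise ValueError("membrane_index out of range")
    z = (np.arange(nz) - mem) * cfg.z_spacing
    widths = (np.full(len(cfg.layer_centers), cfg.layer_widths)
              if np.isscalar(cfg.layer_widths) else np.asarray(cfg.layer_widths))
    prof = np.zeros(nz)
    for c, w in zip(cfg.layer_centers, widths):
        prof += np.exp(-0.5 * ((z - c) / w) ** 2)
    return prof


def simulate_images(cfg: ImageSimConfig) -> np.ndarray:
    """Simulate a fluorescence image (2-D) or z-stack (3-D).

    2-D: flat field of mean ``baseline_intensity × fold_change`` plus
    additive Gaussian noise of ``noise_sigma``. 3-D: each configured
    protein layer contributes a Gaussian z-profile (amplitude
    ``baseline_intensity × fold_change``) centered at its offset from the
    membrane plane. Intensities are clipped at zero.
    """
    rng = np.random.default_rng(cfg.seed)
    amplitude = cfg.baseline_intensity * cfg.fold_change
    if len(cfg.shape) == 2:
        img = np.full(cfg.shape, amplitude)
    else:
        prof = _stack_profile(cfg)
        img = amplitude * prof[:, None, None] * np.ones(cfg.shape)
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, size=cfg.shape)
    return np.clip(img, 0.0, None)


def simulate_image_batch(
    cfg: ImageSimConfig, n_control: int, n_treated: int,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """One experiment batch: control images at fold 1 and treated images
    at the configured fold-change, with independent noise per image.

    Sub-seeds are derived from ``cfg.seed`` so the batch is reproducible.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(n_control + n_treated)
    controls, treated = [], []
    for i in range(n_control):
        sub = ImageSimConfig(**{**cfg.__dict__, "fold_change": 1.0,
                                "seed": ss[i].generate_state(1)[0] % (2**31)})
        controls.append(simulate_images(sub))
    for i in range(n_treated):
        sub = ImageSimConfig(**{**cfg.__dict__,
                                "seed": ss[n_control + i].generate_state(1)[0] % (2**31)})
        treated.append(simulate_images(sub))
    return controls, treated
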