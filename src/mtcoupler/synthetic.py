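"""Ground-truthed synthetic data for every analysis stage.

Generators emulating the four kinds of raw data the analyses consume:

* kymographs of fluorescent spots on a (possibly shortening) microtubule,
  with a Poisson + Gaussian camera model;
* stepwise photobleaching time traces;
* quadrant-photodetector (QPD) traces of an optically trapped bead --
  Ornstein-Uhlenbeck thermal fluctuations plus programmed
  ramp-and-plateau stall events ending in detachment (snap-back) or
  rescue (gradual return);
* residence-time tables per valence (delegating to the Gillespie
  simulator in :mod:`mtcoupler.kinetics`).

Every generator takes an integer seed and is reproducible bit-for-bit.
Each returns its ground truth alongside the data so that recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.special import erf

from .kinetics import KineticParams, ResidenceTimeSet, simulate_residence

__all__ = [
    "CameraNoise",
    "SpotModel",
    "KymoGroundTruth",
    "gen_kymograph",
    "gen_bleach_trace",
    "StallSegment",
    "TrapGroundTruth",
    "gen_qpd_trace",
    "gen_residence_dataset",
]

#: Boltzmann constant in pN nm / K.
KB_PN_NM = 1.380649e-2


class StabilityError(ValueError):
    """Integration step too coarse for the requested Euler-Maruyama update."""


# --------------------------------------------------------------------------
# kymographs


@dataclass(frozen=True)
class CameraNoise:
    """Camera model: Poisson shot noise on (signal + background), then
    multiplicative gain and additive Gaussian read noise, in counts."""

    background: float = 0.0  # photons / pixel
    read_sd: float = 0.0  # counts RMS
    gain: float = 1.0  # counts / photon
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.background < 0 or self.read_sd < 0 or self.gain <= 0:
            raise ValueError("noise parameters must be non-negative (gain > 0)")


@dataclass(frozen=True)
class SpotModel:
    """One fluorescent particle on the kymograph.

    ``peak_photons`` is the expected photon count in the brightest pixel;
    for a background-free spot the peak signal-to-noise ratio is therefore
    ``sqrt(peak_photons)`` (shot-noise limited).
    """

    position_px: float
    sigma_px: float = 1.3
    peak_photons: float = 25.0
    diffusion_nm2_s: float = 0.0
    tip_tracking: bool = False
    landing_frame: int = 0
    detach_frame: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_px < 0.5:
            raise ValueError(f"spot sigma {self.sigma_px} px is sub-resolution (< 0.5 px)")
        if self.peak_photons <= 0 or self.diffusion_nm2_s < 0:
            raise ValueError("peak_photons must be > 0 and diffusion >= 0")


@dataclass
class KymoGroundTruth:
    """True per-frame state behind one synthetic kymograph.

    Spot position and intensity are NaN outside [landing_frame, detach_frame].
    Tip position is monotone non-increasing while the microtubule shortens.
    """

    spot_position_px: np.ndarray
    spot_peak_photons: np.ndarray
    tip_position_px: np.ndarray
    landing_frame: int
    detach_frame: int
    tip_velocity_nm_s: float
    px_size_nm: float
    frame_dt_s: float


def _apply_camera(rng: np.random.Generator, photons: np.ndarray, noise: CameraNoise) -> np.ndarray:
    lam = photons + noise.background
    counts = rng.poisson(lam).astype(float) if noise.poisson else lam
    counts *= noise.gain
    if noise.read_sd > 0:
        counts += rng.normal(0.0, noise.read_sd, counts.shape)
    return counts


def gen_kymograph(
    frames: int,
    n_px: int = 64,
    px_size_nm: float = 160.0,
    frame_dt_s: float = 1.1,
    spot: SpotModel | None = None,
    tip_velocity_nm_s: float = 0.0,
    tip_start_px: float | None = None,
    mt_peak_photons: float = 50.0,
    noise: CameraNoise = CameraNoise(),
    detach_on_tip_pass: bool = True,
    seed: int = 0,
):
    """Generate a two-channel synthetic kymograph with ground truth.

    Returns ``(spot_kymo, mt_kymo, truth)`` where the kymographs are
    :class:`mtcoupler.kymograph.Kymograph` objects (rows = frames).  The
    spot channel carries one Gaussian particle (optionally diffusing or
    tracking the shortening tip); the microtubule channel carries an
    erf-edged filament whose tip retracts at ``tip_velocity_nm_s``
    (positive = shortening).
    """
    from .kymograph import Kymograph  # local import to avoid a cycle

    if frames < 10:
        raise ValueError(f"frames must be >= 10, got {frames}")
    if spot is None:
        spot = SpotModel(position_px=n_px / 2)
    rng = np.random.default_rng(seed)
    t_idx = np.arange(frames)

    if tip_start_px is None:
        tip_start_px = n_px - 4.0
    tip = tip_start_px - tip_velocity_nm_s * frame_dt_s * t_idx / px_size_nm

    landing = int(spot.landing_frame)
    detach = frames - 1 if spot.detach_frame is None else int(spot.detach_frame)
    detach = min(detach, frames - 1)
    if not 0 <= landing <= detach:
        raise ValueError("need 0 <= landing_frame <= detach_frame < frames")

    pos = np.full(frames, np.nan)
    if spot.tip_tracking:
        pos[landing : detach + 1] = tip[landing : detach + 1]
    else:
        step_sd_px = np.sqrt(2.0 * spot.diffusion_nm2_s * frame_dt_s) / px_size_nm
        steps = rng.normal(0.0, step_sd_px, detach - landing) if step_sd_px > 0 else np.zeros(detach - landing)
        walk = spot.position_px + np.concatenate([[0.0], np.cumsum(steps)])
        pos[landing : detach + 1] = np.clip(walk, 1.0, n_px - 2.0)
        if detach_on_tip_pass:
            gone = np.where(tip[landing : detach + 1] < pos[landing : detach + 1])[0]
            if gone.size:
                detach = landing + max(int(gone[0]) - 1, 0)
                pos[detach + 1 :] = np.nan

    x = np.arange(n_px, dtype=float)
    peak = np.where(np.isfinite(pos), spot.peak_photons, 0.0)
    safe_pos = np.where(np.isfinite(pos), pos, 0.0)
    spot_photons = peak[:, None] * np.exp(
        -((x[None, :] - safe_pos[:, None]) ** 2) / (2.0 * spot.sigma_px**2)
    )
    mt_photons = mt_peak_photons * 0.5 * (
        1.0 + erf((tip[:, None] - x[None, :]) / (spot.sigma_px * np.sqrt(2.0)))
    )

    spot_kymo = Kymograph(
        matrix=_apply_camera(rng, spot_photons, noise),
        px_size_nm=px_size_nm,
        frame_dt_s=frame_dt_s,
        channel="spot",
    )
    mt_kymo = Kymograph(
        matrix=_apply_camera(rng, mt_photons, noise),
        px_size_nm=px_size_nm,
        frame_dt_s=frame_dt_s,
        channel="microtubule",
    )
    truth = KymoGroundTruth(
        spot_position_px=pos,
        spot_peak_photons=peak,
        tip_position_px=tip,
        landing_frame=landing,
        detach_frame=detach,
        tip_velocity_nm_s=tip_velocity_nm_s,
        px_size_nm=px_size_nm,
        frame_dt_s=frame_dt_s,
    )
    return spot_kymo, mt_kymo, truth


# --------------------------------------------------------------------------
# photobleaching traces


def gen_bleach_trace(
    n_fluor: int,
    unit: float = 100.0,
    bleach_rate: float = 0.1,
    noise_sd: float = 0.0,
    dt: float = 0.1,
    n_samples: int | None = None,
    seed: int = 0,
):
    """Stepwise photobleaching trace of ``n_fluor`` independent fluorophores.

    Intensity is ``unit * (surviving fluorophores) + N(0, noise_sd)``.
    Each fluorophore bleaches after an Exp(``bleach_rate``) lifetime;
    two lifetimes falling inside one frame produce the occasional
    simultaneous double step seen in real traces.

    Returns ``(trace, step_times)`` with ``trace`` a
    :class:`mtcoupler.photobleach.BleachTrace` and ``step_times`` the sorted
    true bleach instants in seconds.
    """
    from .photobleach import BleachTrace

    if n_fluor < 1:
        raise ValueError(f"n_fluor must be >= 1, got {n_fluor}")
    if bleach_rate <= 0 or dt <= 0 or noise_sd < 0:
        raise ValueError("bleach_rate and dt must be > 0, noise_sd >= 0")
    rng = np.random.default_rng(seed)
    step_times = np.sort(rng.exponential(1.0 / bleach_rate, n_fluor))
    if n_samples is None:
        n_samples = int(np.ceil(step_times[-1] / dt)) + max(10, int(1.0 / (bleach_rate * dt)))
    time = np.arange(n_samples) * dt
    counts = (time[:, None] < step_times[None, :]).sum(axis=1)
    intensity = unit * counts.astype(float)
    if noise_sd > 0:
        intensity += rng.normal(0.0, noise_sd, n_samples)
    return BleachTrace(time=time, intensity=intensity), step_times


# --------------------------------------------------------------------------
# optical-trap (QPD) traces


@dataclass(frozen=True)
class StallSegment:
    """One programmed stall: ramp to a plateau, hold, then release.

    ``outcome`` is ``"detachment"`` (instantaneous snap-back to the trap
    centre) or ``"rescue"`` (gradual return at ``return_speed_nm_s``,
    i.e. the regrowing microtubule carries the bead back).
    ``link_stiffness_pn_nm`` stiffens the bead while engaged: fluctuations
    are those of an OU process at ``kappa_trap + link_stiffness``.
    """

    t_start_s: float
    plateau_nm: float
    duration_s: float
    outcome: str = "detachment"
    ramp_speed_nm_s: float = 100.0
    return_speed_nm_s: float = 20.0
    link_stiffness_pn_nm: float = 0.2

    def __post_init__(self) -> None:
        if self.outcome not in ("detachment", "rescue"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.plateau_nm <= 0 or self.duration_s < 0:
            raise ValueError("plateau_nm must be > 0 and duration_s >= 0")


@dataclass(frozen=True)
class TrapGroundTruth:
    """Physical parameters behind one synthetic trap recording."""

    kappa_pn_nm: float
    gamma_pn_s_nm: float = 7.5e-6  # Stokes drag of a 1-um bead in water at ~30 C
    conversion_nm_v: float = 200.0
    temperature_k: float = 303.0
    stalls: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kappa_pn_nm <= 0 or self.gamma_pn_s_nm <= 0:
            raise ValueError("kappa and gamma must be > 0")


def _ou_fluctuations(
    rng: np.random.Generator,
    kappa: np.ndarray,
    gamma: float,
    kbt: float,
    dt: float,
    scheme: str,
) -> np.ndarray:
    """AR(1) recursion for OU fluctuations with piecewise-constant stiffness.

    ``scheme="exact"`` uses the distribution-exact discretization
    ``a = exp(-kappa dt / gamma)``; ``scheme="euler"`` uses the
    Euler-Maruyama update and raises :class:`StabilityError` when
    ``kappa * dt / gamma >= 0.1``.
    """
    n = kappa.size
    u = np.empty(n)
    # runs of constant stiffness
    edges = np.flatnonzero(np.diff(kappa)) + 1
    starts = np.concatenate([[0], edges])
    stops = np.concatenate([edges, [n]])
    prev = 0.0
    first = True
    for s, e in zip(starts, stops):
        k = kappa[s]
        theta = k * dt / gamma
        if scheme == "euler":
            if theta >= 0.1:
                raise StabilityError(
                    f"Euler-Maruyama unstable: kappa*dt/gamma = {theta:.3f} >= 0.1"
                )
            a = 1.0 - theta
            drive_sd = np.sqrt(2.0 * kbt * dt / gamma)
        elif scheme == "exact":
            a = np.exp(-theta)
            drive_sd = np.sqrt(kbt / k * (1.0 - a * a))
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        w = rng.normal(0.0, drive_sd, e - s)
        if first:
            # start in the stationary distribution of the first segment
            prev = rng.normal(0.0, np.sqrt(kbt / k))
            first = False
        seg, _ = lfilter([1.0], [1.0, -a], w, zi=np.array([a * prev]))
        u[s:e] = seg
        prev = seg[-1]
    return u


def gen_qpd_trace(
    truth: TrapGroundTruth,
    duration_s: float,
    rate_hz: float,
    seed: int = 0,
    scheme: str = "exact",
):
    """Synthetic calibrated QPD recording of a trapped bead.

    The along-microtubule channel is an Ornstein-Uhlenbeck process
    ``dx = -(kappa/gamma) x dt + sqrt(2 kBT/gamma) dW`` around a
    deterministic ramp-and-plateau trajectory for each programmed stall;
    the across channel is a stall-free OU process.  Returns a
    :class:`mtcoupler.force.QPDTrace` (displacements in nm).
    """
    from .force import QPDTrace

    if rate_hz < 1000:
        raise ValueError(f"sampling rate must be >= 1 kHz, got {rate_hz}")
    n = int(round(duration_s * rate_hz))
    if n > 10**8:
        raise ValueError("duration * rate exceeds 1e8 samples")
    dt = 1.0 / rate_hz
    time = np.arange(n) * dt
    kbt = KB_PN_NM * truth.temperature_k

    mean = np.zeros(n)
    kappa = np.full(n, truth.kappa_pn_nm)
    for seg in truth.stalls:
        t0 = seg.t_start_s
        t_ramp = seg.plateau_nm / seg.ramp_speed_nm_s
        t1 = t0 + t_ramp  # plateau reached
        t2 = t1 + seg.duration_s  # stall ends
        if seg.outcome == "rescue":
            t3 = t2 + seg.plateau_nm / seg.return_speed_nm_s
            tp = [t0, t1, t2, t3]
            xp = [0.0, seg.plateau_nm, seg.plateau_nm, 0.0]
            engaged_end = t3
        else:  # detachment: snap back within one sample
            tp = [t0, t1, t2, t2 + dt]
            xp = [0.0, seg.plateau_nm, seg.plateau_nm, 0.0]
            engaged_end = t2
        m = (time >= t0) & (time <= tp[-1])
        mean[m] = np.interp(time[m], tp, xp)
        kappa[(time >= t0) & (time < engaged_end)] = (
            truth.kappa_pn_nm + seg.link_stiffness_pn_nm
        )

    rng = np.random.default_rng(seed)
    x = mean + _ou_fluctuations(rng, kappa, truth.gamma_pn_s_nm, kbt, dt, scheme)
    y = _ou_fluctuations(
        rng, np.full(n, truth.kappa_pn_nm), truth.gamma_pn_s_nm, kbt, dt, scheme
    )
    return QPDTrace(time_s=time, x=x, y=y, rate_hz=rate_hz, axis_angle_rad=0.0)


# --------------------------------------------------------------------------
# residence-time tables


def gen_residence_dataset(
    k_on: float,
    k_off: float,
    valences: Sequence[int],
    n_per_valence: int,
    seed: int = 0,
) -> list[ResidenceTimeSet]:
    """Gillespie residence-time tables for several valences (one seed stream)."""
    child_seeds = np.random.SeedSequence(seed).generate_state(len(valences)) & 0x7FFFFFFF
    return [
        simulate_residence(
            KineticParams(valence=int(v), k_off=k_off, k_on=k_on),
            n_per_valence,
            seed=int(s),
        )
        for v, s in zip(valences, child_seeds)
    ]
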