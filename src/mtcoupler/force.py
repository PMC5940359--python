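"""Optical-trap force-trace analysis.

A bead held in a harmonic optical trap (stiffness ``kappa``, pN/nm) reports
force through its displacement from the trap centre, recorded by a quadrant
photodetector (QPD).  This module covers the full chain: voltage-to-nm
conversion from a calibration sweep, trap stiffness from the Lorentzian
power spectral density of a free trapped bead (with Faxen's wall correction
for the drag near the coverslip), rotation of the detector axes onto the
microtubule axis, downsampling and Chung-Kennedy smoothing of pull
segments, detection of depolymerization-driven stall plateaus, stall force
``F = kappa * (stall level - free level)`` with an optional nonlinearity
correction, classification of stall outcomes (detachment snap-back versus
gradual rescue return), link stiffness ``k_B T / var`` from in-stall
fluctuations, and rescue-fraction statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import welch

from .photobleach import chung_kennedy_filter

__all__ = [
    "QPDTrace",
    "TrapCalibration",
    "StallEvent",
    "qpd_conversion",
    "trap_stiffness_psd",
    "rotate_to_mt_axes",
    "preprocess_pull_segment",
    "detect_stall",
    "stall_force",
    "classify_outcome",
    "link_stiffness",
    "rescue_fraction",
    "analyze_force_trace",
]

#: Boltzmann constant in pN nm / K.
KB_PN_NM = 1.380649e-2


def kbt(temperature_k: float = 303.0) -> float:
    """Thermal energy in pN nm (default 303 K, i.e. 30 C)."""
    return KB_PN_NM * temperature_k


class CalibrationError(RuntimeError):
    """Power-spectrum fit failed or gave an out-of-band corner frequency."""


@dataclass
class QPDTrace:
    """Calibrated bead displacement versus time along the detector axes."""

    time_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate_hz: float
    axis_angle_rad: float | None = None
    conversion_nm_v: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.time_s.shape == self.x.shape == self.y.shape):
            raise ValueError("time, x and y must have equal length")
        if self.rate_hz <= 0:
            raise ValueError("rate must be > 0")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time_s, "x_nm": self.x, "y_nm": self.y}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, rate_hz: float, axis_angle_rad: float | None = None) -> "QPDTrace":
        df = pd.read_csv(path)
        return cls(
            time_s=df["time_s"].to_numpy(float),
            x=df["x_nm"].to_numpy(float),
            y=df["y_nm"].to_numpy(float),
            rate_hz=rate_hz,
            axis_angle_rad=axis_angle_rad,
        )


@dataclass(frozen=True)
class TrapCalibration:
    """Trap stiffness and the quantities behind it."""

    kappa_pn_nm: float
    corner_frequency_hz: float
    conversion_nm_v: float | None = None
    bead_diameter_nm: float = 1000.0
    height_nm: float = 150.0
    temperature_k: float = 303.0

    def __post_init__(self) -> None:
        if self.kappa_pn_nm <= 0 or self.corner_frequency_hz <= 0:
            raise ValueError("kappa and corner frequency must be > 0")


@dataclass
class StallEvent:
    """One depolymerization-driven stall plateau."""

    t_start_s: float
    t_end_s: float
    stall_level_nm: float
    free_level_nm: float
    force_pn: float | None = None
    outcome: str | None = None  # "detachment" | "rescue" | "indeterminate"
    link_stiffness_pn_nm: float | None = None

    def __post_init__(self) -> None:
        if self.t_end_s <= self.t_start_s:
            raise ValueError("t_end must be > t_start")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


def qpd_conversion(
    displacement_nm: np.ndarray, voltage_v: np.ndarray, fit_range_nm: float = 200.0
) -> float:
    """nm/V conversion factor from a calibration sweep.

    Fits a straight line to the central ``+-fit_range_nm`` of the
    voltage-displacement curve; the sweep must span at least that range on
    both sides.  Returns 1/slope in nm per volt.
    """
    d = np.asarray(displacement_nm, dtype=float)
    v = np.asarray(voltage_v, dtype=float)
    if d.max() < fit_range_nm or d.min() > -fit_range_nm:
        raise ValueError(f"sweep must span at least +-{fit_range_nm} nm")
    core = np.abs(d) <= fit_range_nm
    slope_v_per_nm = np.polyfit(d[core], v[core], 1)[0]
    if slope_v_per_nm == 0:
        raise ValueError("flat voltage response; conversion is not invertible")
    return 1.0 / slope_v_per_nm


def faxen_drag_factor(bead_diameter_nm: float, height_nm: float) -> float:
    """Faxen's law correction to the Stokes drag of a sphere near a wall.

    ``height_nm`` is the gap between the bead surface and the coverslip;
    the factor tends to 1 as the gap grows.
    """
    r = bead_diameter_nm / 2.0
    z = r + height_nm  # centre height above the wall
    q = r / z
    denom = 1 - (9 / 16) * q + (1 / 8) * q**3 - (45 / 256) * q**4 - (1 / 16) * q**5
    return 1.0 / denom


def stokes_drag(bead_diameter_nm: float, viscosity_pa_s: float = 0.8e-3) -> float:
    """Bulk Stokes drag of a sphere, in pN s / nm (water at ~30 C by default)."""
    radius_m = bead_diameter_nm * 1e-9 / 2.0
    gamma_si = 6.0 * np.pi * viscosity_pa_s * radius_m  # N s / m
    return gamma_si * 1e3  # 1 N s/m = 1e3 pN s/nm


def trap_stiffness_psd(
    trace: QPDTrace,
    bead_diameter_nm: float = 1000.0,
    height_nm: float = 150.0,
    temperature_k: float = 303.0,
    viscosity_pa_s: float = 0.8e-3,
    f_band_hz: tuple[float, float] = (5.0, 2000.0),
    nperseg: int | None = None,
) -> TrapCalibration:
    """Trap stiffness from the Lorentzian power spectrum of a free bead.

    The one-sided spectrum of an overdamped trapped bead is the Lorentzian
    ``S(f) = k_B T / (pi^2 gamma (f_c^2 + f^2))``.  Finite sampling folds
    high frequencies back into the band, so the fit uses the aliased
    (discrete-time) form ``S(f) = c / (1 - 2 a cos(2 pi f / f_s) + a^2)``
    with ``a = exp(-2 pi f_c / f_s)``, least-squares with relative weights
    over ``f_band_hz``.  The stiffness is ``kappa = 2 pi gamma f_c`` with
    ``gamma`` the Stokes drag times Faxen's wall-correction factor at the
    given height above the coverslip.
    """
    from scipy.optimize import curve_fit

    x = trace.x - trace.x.mean()
    if x.size / trace.rate_hz < 10.0:
        raise ValueError("need >= 10 s of stall-free signal for calibration")
    if nperseg is None:
        nperseg = max(int(x.size // 64), 256)
    fs = trace.rate_hz
    f, s = welch(x, fs=fs, nperseg=nperseg)
    band = (f >= f_band_hz[0]) & (f <= f_band_hz[1]) & (s > 0)
    if band.sum() < 10:
        raise CalibrationError("too few spectral points in the fit band")

    def aliased_lorentzian(freq, c, fc):
        a = np.exp(-2.0 * np.pi * fc / fs)
        return c / (1.0 - 2.0 * a * np.cos(2.0 * np.pi * freq / fs) + a * a)

    try:
        popt, _ = curve_fit(
            aliased_lorentzian, f[band], s[band],
            p0=[float(s[band].max()) * 1e-2, float(np.sqrt(f_band_hz[0] * f_band_hz[1]))],
            sigma=s[band], maxfev=5000,
        )
    except RuntimeError as exc:
        raise CalibrationError(f"power-spectrum fit did not converge: {exc}") from exc
    fc = float(abs(popt[1]))
    if not f_band_hz[0] < fc < f_band_hz[1]:
        raise CalibrationError(f"corner frequency {fc:.1f} Hz outside the fit band")
    gamma = stokes_drag(bead_diameter_nm, viscosity_pa_s) * faxen_drag_factor(
        bead_diameter_nm, height_nm
    )
    kappa = 2.0 * np.pi * gamma * fc
    return TrapCalibration(
        kappa_pn_nm=float(kappa),
        corner_frequency_hz=fc,
        bead_diameter_nm=bead_diameter_nm,
        height_nm=height_nm,
        temperature_k=temperature_k,
    )


def rotate_to_mt_axes(trace: QPDTrace) -> QPDTrace:
    """Rotate detector axes so x runs along and y across the microtubule.

    A plain 2-D rotation by ``axis_angle_rad``; per-sample vector norms are
    preserved to machine precision.
    """
    if trace.axis_angle_rad is None:
        raise ValueError("trace has no axis_angle_rad set")
    c, s = np.cos(trace.axis_angle_rad), np.sin(trace.axis_angle_rad)
    along = c * trace.x + s * trace.y
    across = -s * trace.x + c * trace.y
    return replace(trace, x=along, y=across, axis_angle_rad=0.0)


def preprocess_pull_segment(
    trace: QPDTrace,
    target_rate_hz: float = 1000.0,
    window: int = 8,
    p: float = 2.0,
) -> QPDTrace:
    """Block-average decimation to ``target_rate_hz`` plus Chung-Kennedy smoothing.

    Decimation preserves the mean exactly; smoothing is applied to the
    along-axis channel only (y is decimated but left unsmoothed).
    """
    if target_rate_hz > trace.rate_hz:
        raise ValueError("target rate must not exceed the native rate")
    factor = int(round(trace.rate_hz / target_rate_hz))
    n = (trace.x.size // factor) * factor
    x = trace.x[:n].reshape(-1, factor).mean(axis=1)
    y = trace.y[:n].reshape(-1, factor).mean(axis=1)
    t = trace.time_s[:n].reshape(-1, factor).mean(axis=1)
    x = chung_kennedy_filter(x, window, p)
    return replace(trace, time_s=t, x=x, y=y, rate_hz=trace.rate_hz / factor)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    w = max(int(w), 1)
    kernel = np.ones(w) / w
    pad = np.pad(x, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def detect_stall(
    trace: QPDTrace,
    baseline_window_s: tuple[float, float] = (0.0, 1.0),
    threshold_sd: float = 5.0,
    min_duration_s: float = 0.2,
    slope_threshold_nm_s: float = 10.0,
    slope_window_s: float = 0.05,
) -> StallEvent | None:
    """Find the stall plateau in a smoothed along-axis pull signal.

    The free-bead level and its SD come from the baseline window.  The stall
    is the longest contiguous run where the displacement exceeds the free
    level by ``threshold_sd`` baseline SDs while the local slope magnitude
    stays below ``slope_threshold_nm_s``, lasting at least
    ``min_duration_s``.  Returns None when nothing qualifies (e.g. the bead
    detached before stalling, or a stall-free trace).
    """
    t, x = trace.time_s, trace.x
    base = (t >= baseline_window_s[0]) & (t < baseline_window_s[1])
    if base.sum() < 10:
        raise ValueError("baseline window contains too few samples")
    free_level = float(x[base].mean())
    sd = float(x[base].std())

    lag = max(int(slope_window_s * trace.rate_hz), 1)
    smooth = _moving_average(x, lag)
    # central difference over one full window: robust to sample-scale noise
    padded = np.pad(smooth, lag, mode="edge")
    slope = (padded[2 * lag :] - padded[: -2 * lag]) * trace.rate_hz / (2.0 * lag)
    ok = (x - free_level > threshold_sd * sd) & (np.abs(slope) < slope_threshold_nm_s)

    # longest contiguous qualifying run
    best = None
    i = 0
    n = ok.size
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        if best is None or (j - i) > (best[1] - best[0]):
            best = (i, j)
        i = j + 1
    if best is None:
        return None
    i, j = best
    # the slope filter clips the ramp->plateau transitions; refine the bounds
    # by expanding to where the signal first reaches the plateau level
    level = float(x[i : j + 1].mean())
    sd_plateau = float(x[i : j + 1].std())
    enter = level - 2.5 * sd_plateau
    while i > 0 and smooth[i - 1] >= enter:
        i -= 1
    while j + 1 < n and smooth[j + 1] >= enter:
        j += 1
    if (t[j] - t[i]) < min_duration_s:
        return None
    return StallEvent(
        t_start_s=float(t[i]),
        t_end_s=float(t[j]),
        stall_level_nm=float(x[i : j + 1].mean()),
        free_level_nm=free_level,
    )


def stall_force(
    event: StallEvent,
    calibration: TrapCalibration,
    correction: Callable[[float], float] | tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Stall force in pN: (stall level - free level) x trap stiffness x c(level).

    ``correction`` is an optional multiplicative factor accounting for the
    nonlinear rise of trap force far from the centre, either a callable
    c(displacement_nm) or a (displacement_nm, factor) table interpolated
    linearly; by default c = 1.  Displacements beyond a table's domain raise.
    """
    dx = event.stall_level_nm - event.free_level_nm
    c = 1.0
    if correction is not None:
        if callable(correction):
            c = float(correction(event.stall_level_nm))
        else:
            xs, cs = np.asarray(correction[0], float), np.asarray(correction[1], float)
            if not xs.min() <= event.stall_level_nm <= xs.max():
                raise ValueError(
                    f"stall level {event.stall_level_nm:.1f} nm outside the correction domain"
                )
            c = float(np.interp(event.stall_level_nm, xs, cs))
    return dx * calibration.kappa_pn_nm * c


def classify_outcome(
    trace: QPDTrace,
    event: StallEvent,
    baseline_sd_nm: float,
    velocity_threshold_nm_s: float = 1000.0,
    return_tolerance_sd: float = 2.0,
) -> str:
    """Label the end of a stall: ``"detachment"`` or ``"rescue"``.

    Detachment snaps the bead back to the trap centre essentially
    instantaneously; rescue returns it gradually with the regrowing
    microtubule.  The label is set by the mean return velocity from the
    stall level to within ``return_tolerance_sd`` baseline SDs of the free
    level.  If the trace ends before the bead returns the label is
    ``"indeterminate"``.
    """
    t, x = trace.time_s, trace.x
    after = t > event.t_end_s
    if not after.any():
        return "indeterminate"
    ta, xa = t[after], x[after]
    back = np.flatnonzero(xa - event.free_level_nm <= return_tolerance_sd * baseline_sd_nm)
    if back.size == 0:
        return "indeterminate"
    t_return = ta[back[0]]
    dt = t_return - event.t_end_s
    if dt <= 0:
        return "detachment"
    v = (event.stall_level_nm - event.free_level_nm) / dt
    return "detachment" if v >= velocity_threshold_nm_s else "rescue"


def link_stiffness(segment_nm: np.ndarray, temperature_k: float = 303.0) -> float:
    """Effective bead-microtubule link stiffness from in-stall fluctuations.

    ``k_B T / var(x)`` over the stall segment, in pN/nm.  This is the
    combined (effective) stiffness of trap plus link; no series/parallel
    decomposition is attempted.
    """
    seg = np.asarray(segment_nm, dtype=float)
    if seg.size < 100:
        raise ValueError(f"need >= 100 samples, got {seg.size}")
    var = float(seg.var())
    if var == 0:
        raise ValueError("zero variance segment")
    return kbt(temperature_k) / var


def rescue_fraction(
    events: Sequence[StallEvent], force_bin_edges_pn: np.ndarray | None = None
) -> dict:
    """Detachment/rescue counts and the rescue percentage, optionally by force bin.

    Returns ``{"n_detachment", "n_rescue", "percent_rescue"}`` plus a
    ``"by_force"`` DataFrame when bin edges are given.  Events without a
    detachment/rescue label raise.
    """
    if len(events) == 0:
        raise ValueError("no stall events supplied")
    outcomes = [e.outcome for e in events]
    if any(o not in ("detachment", "rescue") for o in outcomes):
        raise ValueError("all events must be labelled detachment or rescue")
    n_d = outcomes.count("detachment")
    n_r = outcomes.count("rescue")
    result = {
        "n_detachment": n_d,
        "n_rescue": n_r,
        "percent_rescue": 100.0 * n_r / (n_d + n_r),
    }
    if force_bin_edges_pn is not None:
        forces = np.array([e.force_pn for e in events], dtype=float)
        if np.any(np.isnan(forces)):
            raise ValueError("force-binned fractions need force_pn on every event")
        rows = []
        for lo, hi in zip(force_bin_edges_pn[:-1], force_bin_edges_pn[1:]):
            m = (forces >= lo) & (forces < hi)
            nr = sum(1 for k in np.flatnonzero(m) if outcomes[k] == "rescue")
            rows.append(
                {
                    "force_lo_pn": lo,
                    "force_hi_pn": hi,
                    "n_events": int(m.sum()),
                    "n_rescue": nr,
                    "percent_rescue": 100.0 * nr / m.sum() if m.any() else np.nan,
                }
            )
        result["by_force"] = pd.DataFrame(rows)
    return result


def analyze_force_trace(
    trace: QPDTrace,
    calibration: TrapCalibration,
    baseline_window_s: tuple[float, float] = (0.0, 1.0),
    target_rate_hz: float = 1000.0,
    correction=None,
    **detect_kwargs,
) -> StallEvent | None:
    """Full per-trace pipeline: rotate, downsample/smooth, detect, score.

    Returns the labelled :class:`StallEvent` with force and link stiffness,
    or None for traces where the bead detached before stalling (these are
    excluded from force statistics downstream).
    """
    if trace.axis_angle_rad not in (None, 0.0):
        trace = rotate_to_mt_axes(trace)
    smoothed = preprocess_pull_segment(trace, target_rate_hz)
    event = detect_stall(smoothed, baseline_window_s=baseline_window_s, **detect_kwargs)
    if event is None:
        return None
    base = (smoothed.time_s >= baseline_window_s[0]) & (smoothed.time_s < baseline_window_s[1])
    baseline_sd = float(smoothed.x[base].std())
    event.force_pn = stall_force(event, calibration, correction)
    event.outcome = classify_outcome(smoothed, event, baseline_sd)
    in_stall = (trace.time_s >= event.t_start_s) & (trace.time_s <= event.t_end_s)
    if in_stall.sum() >= 100:
        event.link_stiffness_pn_nm = link_stiffness(
            trace.x[in_stall], calibration.temperature_k
        )
    return event
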