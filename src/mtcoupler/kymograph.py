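"""Kymograph construction and single-particle tracing.

A kymograph is a time (rows) x position (columns) intensity image built by
resampling a movie along a line drawn on the microtubule.  Each row is
fitted with a Gaussian; the peak gives the sub-pixel spot position and the
area under the curve the spot intensity.  Chaining per-row fits yields a
track whose first and last successful frames define landing and detachment,
hence the residence time.  Tracks are compared against the position of the
shortening microtubule end to classify tip-tracking.

Conventions: 0-based pixel indices, positions measured at pixel centres,
row 0 is the first frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit

__all__ = [
    "Kymograph",
    "SpotTrack",
    "TipTrack",
    "GaussianFit",
    "build_kymograph",
    "fit_line_gaussian",
    "trace_spot",
    "trace_tip",
    "residence_time",
    "classify_tip_tracking",
    "tip_velocity",
]


@dataclass
class Kymograph:
    """Time x position intensity matrix with pixel and frame calibration."""

    matrix: np.ndarray
    px_size_nm: float
    frame_dt_s: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 2:
            raise ValueError("kymograph must be 2-D with >= 2 rows")
        if self.px_size_nm <= 0 or self.frame_dt_s <= 0:
            raise ValueError("px_size_nm and frame_dt_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_px(self) -> int:
        return self.matrix.shape[1]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix).to_csv(path, index=False, header=False)

    @classmethod
    def from_csv(cls, path, px_size_nm: float, frame_dt_s: float, channel: str = "") -> "Kymograph":
        return cls(
            matrix=pd.read_csv(path, header=None).to_numpy(float),
            px_size_nm=px_size_nm,
            frame_dt_s=frame_dt_s,
            channel=channel,
        )


@dataclass
class SpotTrack:
    """Per-frame sub-pixel position and intensity of one traced particle."""

    frames: np.ndarray
    positions_px: np.ndarray
    intensities_au: np.ndarray
    landing_frame: int
    detach_frame: int
    left_censored: bool = False

    def __post_init__(self) -> None:
        if self.landing_frame > self.detach_frame:
            raise ValueError("landing_frame must be <= detach_frame")
        if np.any(np.asarray(self.intensities_au) < 0):
            raise ValueError("intensities must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "position_px": self.positions_px,
                "intensity_au": self.intensities_au,
            }
        )


@dataclass
class TipTrack:
    """Position of the microtubule end over a contiguous frame range."""

    frames: np.ndarray
    positions_px: np.ndarray
    velocity_nm_s: float | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.size and np.any(np.diff(f) != 1):
            raise ValueError("tip track frames must be contiguous")


@dataclass(frozen=True)
class GaussianFit:
    center_px: float
    area_au: float
    sigma_px: float
    baseline_au: float
    success: bool


class EmptyTrackError(ValueError):
    """Seed point did not yield a single successful fit."""


def build_kymograph(
    stack: np.ndarray,
    line: np.ndarray,
    width: int = 5,
    px_size_nm: float = 160.0,
    frame_dt_s: float = 1.0,
    channel: str = "",
) -> Kymograph:
    """Reslice an image stack along a polyline, averaging perpendicular samples.

    ``line`` is an (n, 2) array of (x, y) pixel coordinates.  The polyline is
    resampled at 1-px spacing; at each sample, ``width`` values spaced 1 px
    along the local normal are bilinearly interpolated and averaged.  Row t
    of the result is that profile in frame t.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    line = np.asarray(line, dtype=float)
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    if (
        line[:, 0].min() < 0
        or line[:, 1].min() < 0
        or line[:, 0].max() > stack.shape[2] - 1
        or line[:, 1].max() > stack.shape[1] - 1
    ):
        raise ValueError("line extends outside the image bounds")

    # resample polyline at unit arc-length spacing
    seg = np.diff(line, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_samp = max(int(np.floor(s[-1])) + 1, 2)
    si = np.linspace(0.0, s[-1], n_samp)
    xs = np.interp(si, s, line[:, 0])
    ys = np.interp(si, s, line[:, 1])
    # local tangent -> unit normal
    tx = np.gradient(xs)
    ty = np.gradient(ys)
    norm = np.hypot(tx, ty)
    nx, ny = -ty / norm, tx / norm
    offsets = np.arange(width) - width // 2

    px = xs[None, :] + offsets[:, None] * nx[None, :]
    py = ys[None, :] + offsets[:, None] * ny[None, :]
    rows = np.empty((stack.shape[0], n_samp))
    for t in range(stack.shape[0]):
        samples = map_coordinates(stack[t], [py, px], order=1, mode="nearest")
        rows[t] = samples.mean(axis=0)
    return Kymograph(rows, px_size_nm=px_size_nm, frame_dt_s=frame_dt_s, channel=channel)


def _gauss(x, a, mu, sigma, b):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) + b


def fit_line_gaussian(
    profile: np.ndarray,
    init_center: float | None = None,
    sigma_init: float = 1.3,
    weight_poisson: bool = False,
    fix_sigma: bool = False,
    window: tuple[int, int] | None = None,
    min_significance: float = 4.0,
) -> GaussianFit:
    """Least-squares Gaussian fit ``A exp(-(x-mu)^2 / 2 sigma^2) + B`` to one row.

    The area under the curve, ``A sigma sqrt(2 pi)``, is the spot intensity.
    With ``weight_poisson`` the fit is inverse-variance weighted for
    shot-noise-limited data (iteratively reweighted with variance taken from
    the fitted model, floored at one count).  ``fix_sigma`` holds the width
    at ``sigma_init`` -- the PSF width is an instrument constant, and fixing
    it improves localization at low photon counts.  The fit is flagged
    unsuccessful rather than raising when it diverges, the amplitude is
    below ``min_significance`` residual SDs, or the width collapses below
    half a pixel (a noise spike, not a diffraction-limited spot).
    """
    y_full = np.asarray(profile, dtype=float)
    x_full = np.arange(y_full.size, dtype=float)
    if window is not None:
        lo, hi = max(window[0], 0), min(window[1], y_full.size)
        x, y = x_full[lo:hi], y_full[lo:hi]
    else:
        x, y = x_full, y_full
    if y.size < 7:
        raise ValueError("profile must contain >= 7 samples")
    if np.ptp(y) == 0:
        return GaussianFit(np.nan, np.nan, np.nan, float(y[0]), False)

    b0 = float(np.median(y))
    mu0 = float(x[np.argmax(y)]) if init_center is None else float(init_center)
    a0 = max(float(y.max() - b0), 1e-12)
    if fix_sigma:
        model_fn = lambda xx, a, mu, b: _gauss(xx, a, mu, sigma_init, b)  # noqa: E731
        p0 = [a0, mu0, b0]
        bounds = ([0.0, x[0] - 1.0, -np.inf], [np.inf, x[-1] + 1.0, np.inf])
    else:
        model_fn = _gauss
        p0 = [a0, mu0, sigma_init, b0]
        bounds = (
            [0.0, x[0] - 1.0, 0.3, -np.inf],
            [np.inf, x[-1] + 1.0, x.size, np.inf],
        )
    try:
        popt, pcov = curve_fit(model_fn, x, y, p0=p0, bounds=bounds, maxfev=2000)
        if weight_poisson:
            for _ in range(2):
                model = np.maximum(model_fn(x, *popt), 1.0)  # variance floor of 1 count
                popt, pcov = curve_fit(
                    model_fn, x, y, p0=popt, sigma=np.sqrt(model),
                    absolute_sigma=True, bounds=bounds, maxfev=2000,
                )
    except RuntimeError:
        return GaussianFit(np.nan, np.nan, np.nan, b0, False)
    if fix_sigma:
        a, mu, b = popt
        sigma = sigma_init
    else:
        a, mu, sigma, b = popt
    resid_sd = float(np.std(y - _gauss(x, a, mu, sigma, b)))
    amp_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    # a real diffraction-limited spot is statistically significant and about
    # one PSF wide; pure-noise fits collapse onto single-pixel spikes or
    # smear into broad background humps
    success = (
        bool(a > min_significance * resid_sd)
        and bool(a > min_significance * amp_se)
        and x[0] <= mu <= x[-1]
        and 0.5 <= sigma <= 2.5 * sigma_init
    )
    return GaussianFit(
        center_px=float(mu),
        area_au=float(a * sigma * np.sqrt(2.0 * np.pi)),
        sigma_px=float(sigma),
        baseline_au=float(b),
        success=success,
    )


def trace_spot(
    kymo: Kymograph,
    seed_point: tuple[int, float],
    search_window_px: int = 5,
    max_consecutive_failures: int = 3,
    sigma_init: float = 1.3,
    weight_poisson: bool = False,
    fix_sigma: bool = False,
) -> SpotTrack:
    """Trace one particle through a kymograph starting from a seed point.

    Rows are fitted one by one, each fit initialized at (and windowed around)
    the previous centre, extending forward then backward from the seed frame.
    A direction ends after ``max_consecutive_failures`` consecutive failed
    fits; landing and detachment are the first and last successful frames.
    A track already present in frame 0 is flagged left-censored (it was
    bound before observation started).
    """
    f0, x0 = int(seed_point[0]), float(seed_point[1])
    if not (0 <= f0 < kymo.n_frames and 0 <= x0 < kymo.n_px):
        raise ValueError("seed point outside the kymograph")
    w = int(search_window_px)

    def fit_at(frame: int, center: float) -> GaussianFit:
        lo = int(np.floor(center)) - w
        hi = int(np.ceil(center)) + w + 1
        fit = fit_line_gaussian(
            kymo.matrix[frame],
            init_center=center,
            sigma_init=sigma_init,
            weight_poisson=weight_poisson,
            fix_sigma=fix_sigma,
            window=(lo, hi),
        )
        if fit.success and abs(fit.center_px - center) > w:
            return GaussianFit(fit.center_px, fit.area_au, fit.sigma_px, fit.baseline_au, False)
        return fit

    seed_fit = fit_at(f0, x0)
    if not seed_fit.success:
        raise EmptyTrackError(f"no spot at seed point (frame {f0}, {x0:.1f} px)")

    results: dict[int, GaussianFit] = {f0: seed_fit}
    for direction in (+1, -1):
        center = seed_fit.center_px
        failures = 0
        frame = f0 + direction
        while 0 <= frame < kymo.n_frames and failures < max_consecutive_failures:
            fit = fit_at(frame, center)
            if fit.success:
                results[frame] = fit
                center = fit.center_px
                failures = 0
            else:
                failures += 1
            frame += direction

    frames = np.array(sorted(results))
    landing, detach = int(frames[0]), int(frames[-1])
    frames = frames[(frames >= landing) & (frames <= detach)]
    return SpotTrack(
        frames=frames,
        positions_px=np.array([results[f].center_px if f in results else np.nan for f in frames]),
        intensities_au=np.array([max(results[f].area_au, 0.0) if f in results else np.nan for f in frames]),
        landing_frame=landing,
        detach_frame=detach,
        left_censored=(landing == 0),
    )


def trace_tip(kymo: Kymograph, edge_sigma_px: float = 1.3) -> TipTrack:
    """Locate the microtubule end in each row of a microtubule-channel kymograph.

    Fits an erf edge ``A/2 (1 + erf((mu - x)/(sigma sqrt(2)))) + B`` per row.
    """
    from scipy.special import erf

    def edge(x, a, mu, sigma, b):
        return a * 0.5 * (1.0 + erf((mu - x) / (sigma * np.sqrt(2.0)))) + b

    x = np.arange(kymo.n_px, dtype=float)
    positions = np.full(kymo.n_frames, np.nan)
    prev_mu = None
    bounds = ([0.0, 0.0, 0.3, -np.inf], [np.inf, float(kymo.n_px - 1), 10.0, np.inf])
    for t in range(kymo.n_frames):
        y = kymo.matrix[t]
        if np.ptp(y) == 0:
            continue
        half = 0.5 * (y.max() + y.min())
        mu0 = prev_mu if prev_mu is not None else float(x[np.argmin(np.abs(y - half))])
        try:
            popt, _ = curve_fit(
                edge, x, y,
                p0=[float(y.max() - y.min()), mu0, edge_sigma_px, float(y.min())],
                bounds=bounds, maxfev=2000,
            )
        except RuntimeError:
            continue
        resid_sd = float(np.std(y - edge(x, *popt)))
        if popt[0] > 4.0 * resid_sd:  # a real edge, not a noise gradient
            positions[t] = popt[1]
            prev_mu = float(popt[1])
    ok = np.isfinite(positions)
    return TipTrack(frames=np.flatnonzero(ok), positions_px=positions[ok])


def residence_time(track: SpotTrack, frame_dt_s: float) -> tuple[float, bool]:
    """Residence time = (detach - landing) frames x frame interval, with censor flag."""
    return (track.detach_frame - track.landing_frame) * frame_dt_s, track.left_censored


def classify_tip_tracking(
    spot: SpotTrack,
    tip: TipTrack,
    tol_px: float = 2.0,
    min_run_frames: int = 5,
    min_tip_move_px: float = 3.0,
) -> bool:
    """True iff the spot stays within ``tol_px`` of the shortening end for a
    sustained run during which the tip actually moves.

    The run must span >= ``min_run_frames`` consecutive frames with
    |spot - tip| <= tol while the tip travels >= ``min_tip_move_px`` in total.
    """
    common, si, ti = np.intersect1d(spot.frames, tip.frames, return_indices=True)
    if common.size == 0:
        raise ValueError("spot and tip tracks share no frames")
    d = np.abs(spot.positions_px[si] - tip.positions_px[ti])
    close = (d <= tol_px) & np.isfinite(d)
    tip_pos = tip.positions_px[ti]
    # scan maximal runs of consecutive close frames
    i = 0
    while i < close.size:
        if not close[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < close.size
            and close[j + 1]
            and common[j + 1] == common[j] + 1
        ):
            j += 1
        if (j - i + 1) >= min_run_frames and abs(tip_pos[j] - tip_pos[i]) >= min_tip_move_px:
            return True
        i = j + 1
    return False


def tip_velocity(tip: TipTrack, px_size_nm: float, frame_dt_s: float) -> float:
    """Depolymerization speed in nm/s from a least-squares line through the tip.

    Sign convention: shortening (tip position decreasing) is positive.
    """
    if tip.frames.size < 5:
        raise ValueError("need >= 5 tip frames to fit a velocity")
    slope_px_per_frame = np.polyfit(tip.frames.astype(float), tip.positions_px, 1)[0]
    return float(-slope_px_per_frame * px_size_nm / frame_dt_s)
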