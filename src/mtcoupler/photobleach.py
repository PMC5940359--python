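"""Fluorophore counting from stepwise photobleaching traces.

Bleaching of a particle carrying ``n`` fluorophores produces a staircase of
``n`` downward intensity steps.  The pipeline is: smooth each trace with the
edge-preserving Chung-Kennedy filter, pool all smoothed intensities into a
histogram whose equally spaced peaks are the 0-, 1-, 2-, ... fluorophore
levels, read the common spacing off as the unitary (single-fluorophore)
intensity, and divide each particle's initial (pre-first-bleach) intensity
by that unit to count its fluorophores.  Ratios of counts between two
colour channels give per-particle stoichiometries; dividing a coated bead's
brightness by the unit gives its (real-valued) complex count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "BleachTrace",
    "UnitIntensity",
    "chung_kennedy_filter",
    "estimate_unit_intensity",
    "count_fluorophores",
    "stoichiometry",
    "bead_complex_count",
]


class EstimationError(RuntimeError):
    """No usable periodic level structure in the pooled intensity histogram."""


@dataclass
class BleachTrace:
    """One background-subtracted intensity-versus-time bleaching trace."""

    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "intensity_au": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "BleachTrace":
        df = pd.read_csv(path)
        return cls(time=df["time_s"].to_numpy(float), intensity=df["intensity_au"].to_numpy(float))


@dataclass(frozen=True)
class UnitIntensity:
    """Intensity of a single fluorophore, estimated from pooled level histograms."""

    value: float
    se: float
    n_traces: int

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("unit intensity must be > 0")


def chung_kennedy_filter(trace: np.ndarray, window: int = 8, p: float = 2.0) -> np.ndarray:
    """Edge-preserving nonlinear smoother of Chung & Kennedy.

    Each sample is replaced by a weighted combination of the mean of the
    ``window`` preceding samples (forward predictor) and the mean of the
    ``window`` following samples (backward predictor).  The weights are
    proportional to the mean squared prediction error of each predictor over
    its own test window, raised to the power ``-p``, so the predictor that
    straddles a step is switched off and step edges survive smoothing.
    Edges of the trace fall back on the one-sided predictor available there.
    """
    x = np.asarray(trace, dtype=float)
    w = int(window)
    if w < 2:
        raise ValueError("window must be >= 2")
    n = x.size
    if n <= 2 * w:
        raise ValueError(f"trace length {n} too short for window {w} (need > {2 * w})")

    csum = np.concatenate([[0.0], np.cumsum(x)])

    def mean_range(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        # mean of x[lo:hi] with hi > lo, vectorized
        return (csum[hi] - csum[lo]) / (hi - lo)

    idx = np.arange(n)
    # forward predictor: mean of up to w samples strictly before i
    f_lo = np.maximum(idx - w, 0)
    f_valid = idx >= 1
    fpred = np.where(f_valid, mean_range(f_lo, np.maximum(idx, 1)), 0.0)
    # backward predictor: mean of up to w samples strictly after i
    b_valid = idx <= n - 2
    b_lo = np.minimum(idx + 1, n - 1)
    b_hi = np.clip(idx + 1 + w, b_lo + 1, n)
    bpred = np.where(b_valid, mean_range(b_lo, b_hi), 0.0)

    err_f = np.where(f_valid, (x - fpred) ** 2, 0.0)
    err_b = np.where(b_valid, (x - bpred) ** 2, 0.0)
    # test windows: MSE of the forward predictor over the w samples up to i,
    # of the backward predictor over the w samples from i on
    cf = np.concatenate([[0.0], np.cumsum(err_f)])
    cb = np.concatenate([[0.0], np.cumsum(err_b)])
    mse_f = (cf[idx + 1] - cf[np.maximum(idx + 1 - w, 0)]) / np.minimum(idx + 1, w)
    mse_b = (cb[np.minimum(idx + w, n)] - cb[idx]) / np.minimum(n - idx, w)

    with np.errstate(divide="ignore"):
        wf = np.where(f_valid, mse_f, np.inf) ** -p
        wb = np.where(b_valid, mse_b, np.inf) ** -p
    out = np.empty(n)
    both_zero = np.isinf(wf) & np.isinf(wb)
    only_f = np.isinf(wf) & ~both_zero
    only_b = np.isinf(wb) & ~both_zero
    finite = ~(both_zero | only_f | only_b)
    total = wf[finite] + wb[finite]
    out[finite] = (wf[finite] * fpred[finite] + wb[finite] * bpred[finite]) / total
    out[only_f] = fpred[only_f]
    out[only_b] = bpred[only_b]
    # both predictors perfect (noise-free plateau): either one is exact
    out[both_zero] = np.where(f_valid[both_zero], fpred[both_zero], bpred[both_zero])
    return out


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def estimate_unit_intensity(
    traces: list[BleachTrace],
    bin_width: float | None = None,
    window: int = 8,
    p: float = 2.0,
    max_residual_frac: float = 0.25,
) -> UnitIntensity:
    """Unitary fluorophore intensity from pooled smoothed-intensity histograms.

    All traces are Chung-Kennedy smoothed and pooled; the histogram of the
    pooled samples shows peaks at 0, 1x, 2x, ... the single-fluorophore
    intensity.  Detected peaks are assigned integer levels by their spacing
    and the common spacing is fitted by least squares through the origin.
    Raises :class:`EstimationError` when no periodic peak structure exists
    (e.g. a single flat trace) or the level fit residual exceeds
    ``max_residual_frac`` of the spacing.
    """
    if len(traces) < 5:
        raise ValueError(f"need >= 5 traces, got {len(traces)}")
    pooled = np.concatenate([chung_kennedy_filter(t.intensity, window, p) for t in traces])
    if bin_width is None:
        # noise scale from first differences of the raw traces: within-level
        # jitter, uncontaminated by the level spacing itself
        noise_sd = np.median(
            [_robust_sd(np.diff(t.intensity)) / np.sqrt(2.0) for t in traces]
        )
        if noise_sd == 0:
            noise_sd = _robust_sd(pooled)
        if noise_sd == 0:
            raise EstimationError("pooled intensities are constant; no level structure")
        bin_width = 0.2 * noise_sd
    lo = min(pooled.min(), 0.0) - bin_width
    edges = np.arange(lo, pooled.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(pooled, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    min_height = max(counts.max() * 0.05, 3)
    peaks, _ = find_peaks(
        counts, height=min_height, prominence=min_height, distance=3
    )
    # refine each peak to the local centroid (sub-bin resolution)
    refined = []
    for pk in peaks:
        sl = slice(max(pk - 2, 0), pk + 3)
        refined.append(float(np.average(centers[sl], weights=counts[sl])))
    positions = np.asarray(refined)
    if positions.size < 2:
        raise EstimationError("fewer than two intensity levels found in the histogram")

    spacing0 = float(np.median(np.diff(np.sort(positions))))
    levels = np.round(positions / spacing0)
    keep = levels >= 0
    positions, levels = positions[keep], levels[keep]
    if np.count_nonzero(levels > 0) < 1:
        raise EstimationError("no non-zero intensity level found")
    # least squares through the origin: position ~= unit * level
    unit = float(np.sum(levels * positions) / np.sum(levels**2))
    resid = positions - unit * levels
    rms = float(np.sqrt(np.mean(resid**2)))
    if unit <= 0 or rms > max_residual_frac * unit:
        raise EstimationError(
            f"level positions not equally spaced (rms residual {rms:.3g} vs unit {unit:.3g})"
        )
    se = rms / np.sqrt(max(positions.size - 1, 1))
    return UnitIntensity(value=unit, se=se, n_traces=len(traces))


def _first_step_index(
    smoothed: np.ndarray, unit: float, window: int, min_drop_frac: float = 0.5
) -> int | None:
    """Index of the first bleach step: the first sustained drop exceeding
    ``min_drop_frac`` units below the running pre-step level."""
    n = smoothed.size
    hold = max(int(window), 2)
    for i in range(1, n):
        base = smoothed[:i].mean()
        seg = smoothed[i : i + hold]
        if seg.size >= max(hold // 2, 1) and np.all(seg < base - min_drop_frac * unit):
            return i
    return None


def count_fluorophores(
    trace: BleachTrace,
    unit: UnitIntensity,
    window: int = 8,
    p: float = 2.0,
    allow_no_step: bool = False,
) -> int:
    """Number of fluorophores on one particle: round(initial intensity / unit).

    The initial intensity is the mean of the raw samples before the first
    detected bleach step (a sustained drop of more than half a unit in the
    smoothed trace).  A simultaneous double bleach simply appears as a
    ~2-unit step and does not bias the count, which only uses the pre-step
    level.  Without a detectable step, the whole-trace mean is used only if
    ``allow_no_step`` is set.
    """
    if not unit.value > 0:
        raise ValueError("unit intensity must be > 0")
    smoothed = chung_kennedy_filter(trace.intensity, window, p)
    i0 = _first_step_index(smoothed, unit.value, window)
    if i0 is None:
        if not allow_no_step:
            raise ValueError("no bleach step detected; pass allow_no_step=True to use the trace mean")
        initial = float(trace.intensity.mean())
    else:
        initial = float(trace.intensity[:i0].mean())
    return int(round(initial / unit.value))


def stoichiometry(counts_a, counts_b) -> dict:
    """Per-particle count ratios a/b and the modal rounded ratio.

    Particles with ``b == 0`` are excluded with a warning and reported in
    the result.  Returns ``{"ratios", "rounded", "mode", "n_excluded"}``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("counts must be paired per particle")
    bad = b == 0
    if bad.any():
        warnings.warn(f"excluding {bad.sum()} particle(s) with zero denominator count")
    ratios = a[~bad] / b[~bad]
    if ratios.size == 0:
        raise ValueError("no particles with non-zero denominator")
    rounded = np.round(ratios).astype(int)
    mode = int(np.bincount(rounded[rounded >= 0]).argmax())
    return {
        "ratios": ratios,
        "rounded": rounded,
        "mode": mode,
        "n_excluded": int(bad.sum()),
    }


def bead_complex_count(bead_intensity: float, unit: UnitIntensity) -> float:
    """Real-valued complex count on a coated bead: brightness / unit intensity."""
    if bead_intensity < 0:
        raise ValueError(f"bead intensity must be >= 0, got {bead_intensity}")
    if not unit.value > 0:
        raise ValueError("unit intensity must be > 0")
    return bead_intensity / unit.value
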