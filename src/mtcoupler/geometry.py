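"""Bead-coating arithmetic.

How many multivalent modules sit on a coated bead, how far apart they are,
and how many can reach a microtubule touching the bead.  The spacing uses
the square-lattice mean ``sqrt(area / n)`` over the full sphere surface
``pi d^2``; the in-reach count uses the spherical-cap fraction ``h / 2r``
of modules within tether reach ``h`` of a plane touching the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BeadCoating",
    "module_spacing",
    "modules_in_reach",
    "modules_from_fraction",
]


@dataclass(frozen=True)
class BeadCoating:
    """A bead of given diameter carrying ``n_modules`` coupling modules."""

    bead_diameter_nm: float
    n_modules: float
    peg_biotin_fraction: float | None = None  # percent of biotinylated PEG

    def __post_init__(self) -> None:
        if self.bead_diameter_nm <= 0:
            raise ValueError("bead_diameter_nm must be > 0")
        if self.n_modules < 0:
            raise ValueError("n_modules must be >= 0")


def module_spacing(coating: BeadCoating) -> float:
    """Mean linear distance (nm) between adjacent modules on the bead surface.

    ``sqrt(pi d^2 / n)``: the side of the square each module occupies if the
    ``n`` modules tile the sphere's surface evenly.  50 modules on a 1-um
    bead sit ~250 nm apart.
    """
    if coating.n_modules < 1:
        raise ValueError("need at least one module for a spacing")
    area = np.pi * coating.bead_diameter_nm**2
    return float(np.sqrt(area / coating.n_modules))


def modules_in_reach(coating: BeadCoating, reach_nm: float = 60.0) -> float:
    """Expected number of modules within tether reach of a touching microtubule.

    Approximates the microtubule as a plane touching the bead: modules on
    the spherical cap of height ``reach_nm`` can reach it, a fraction
    ``2 pi r h / 4 pi r^2 = h / 2r`` of the surface.  Default reach is the
    ~60-nm length of one NDC80 tether.
    """
    radius = coating.bead_diameter_nm / 2.0
    if not 0 < reach_nm < radius:
        raise ValueError(f"reach must lie in (0, bead radius); got {reach_nm}")
    return coating.n_modules * reach_nm / (2.0 * radius)


def modules_from_fraction(
    fraction_percent: float,
    calibration_table: np.ndarray,
) -> float:
    """Module count at a given biotin-PEG fraction, interpolating a calibration.

    ``calibration_table`` holds >= 2 rows of (fraction %, module count);
    interpolation is linear in log-log space, matching the near power-law
    rise of coating density with biotin fraction.  Queries outside the table
    range raise.
    """
    table = np.asarray(calibration_table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] != 2:
        raise ValueError("calibration table needs >= 2 rows of (fraction, count)")
    if np.any(table <= 0):
        raise ValueError("fractions and counts must be positive for log-log interpolation")
    order = np.argsort(table[:, 0])
    frac, count = table[order, 0], table[order, 1]
    if not frac[0] <= fraction_percent <= frac[-1]:
        raise ValueError(
            f"fraction {fraction_percent} outside the calibrated range [{frac[0]}, {frac[-1]}]"
        )
    return float(np.exp(np.interp(np.log(fraction_percent), np.log(frac), np.log(count))))
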