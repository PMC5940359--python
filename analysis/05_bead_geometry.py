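#!/usr/bin/env python
"""Bead-coating geometry: module spacing and modules within tether reach.

Tabulates, for a 1-um bead, the mean distance between coupling modules and
the expected number of modules within the ~60-nm tether reach of a touching
microtubule, across the coating densities used experimentally, and
interpolates module counts from a biotin-PEG calibration table.

Writes results/geometry_table.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mtcoupler.geometry import (
    BeadCoating,
    module_spacing,
    modules_from_fraction,
    modules_in_reach,
)

OUT = Path(__file__).resolve().parent.parent / "results"
CALIBRATION = np.array([[0.01, 2.0], [0.03, 5.0], [0.1, 25.0], [1.0, 300.0], [10.0, 2000.0]])


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for n in (5, 10, 50, 100, 1000):
        c = BeadCoating(1000.0, n)
        rows.append({
            "n_modules": n,
            "spacing_nm": round(module_spacing(c), 1),
            "in_reach_60nm": round(modules_in_reach(c, 60.0), 2),
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "geometry_table.csv", index=False)
    print("1-um bead coating geometry (60-nm tether reach):")
    print(table.to_string(index=False))
    print("\nAt 10-50 modules the spacing is ~500-250 nm; beads carrying "
          "100-1000 modules present at least ~6 modules to a touching "
          "microtubule end, saturating the force coupling.")

    for frac in (0.01, 0.07, 0.3):
        n = modules_from_fraction(frac, CALIBRATION)
        print(f"{frac:5.2f}% biotin-PEG -> ~{n:.0f} modules per bead (log-log interpolation).")


if __name__ == "__main__":
    main()
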