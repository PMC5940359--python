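#!/usr/bin/env python
"""Fluorophore counting and two-colour stoichiometry from bleaching traces.

Generates stepwise photobleaching traces, estimates the single-fluorophore
intensity from the pooled level histogram, counts fluorophores per particle
from the pre-bleach intensity, and reads out the tether-per-platform
stoichiometry of two-colour particles built with three tethers per
platform.  Also converts a bright coated bead into a complex count.

Writes results/bleach_counts.csv and results/bleach_summary.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mtcoupler.photobleach import (
    bead_complex_count,
    count_fluorophores,
    estimate_unit_intensity,
    stoichiometry,
)
from mtcoupler.synthetic import gen_bleach_trace

UNIT = 100.0  # au per fluorophore
NOISE_SD = 15.0  # au, 0.15 x unit
SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    traces, truth = [], []
    for i in range(250):
        nf = int(rng.integers(1, 7))
        tr, _ = gen_bleach_trace(nf, unit=UNIT, noise_sd=NOISE_SD, dt=0.1, seed=50_000 + i)
        traces.append(tr)
        truth.append(nf)

    unit = estimate_unit_intensity(traces)
    counts = [count_fluorophores(t, unit, allow_no_step=True) for t in traces]
    exact = float(np.mean(np.asarray(counts) == np.asarray(truth)))
    pd.DataFrame({"true_n": truth, "counted_n": counts}).to_csv(
        OUT / "bleach_counts.csv", index=False
    )
    print(f"Unitary intensity from pooled histograms: {unit.value:.1f} au "
          f"(generating value {UNIT:.0f}); exact count recovery {100 * exact:.0f}% "
          f"over {len(traces)} particles at noise 0.15 x unit.")

    # two-colour particles: platforms carrying 3 tethers each, ~92% labelled
    platforms = rng.integers(1, 3, 100)
    tether_labels = np.maximum(rng.binomial(3 * platforms, 0.92), 1)
    st = stoichiometry(tether_labels, platforms)
    print(f"Two-colour stoichiometry: modal tether-per-platform ratio = {st['mode']} "
          f"(built with 3).")

    bead = bead_complex_count(1.0e5, unit)
    print(f"A bead of brightness 1e5 au carries ~{bead:.0f} complexes.")

    summary = {
        "seed": SEED,
        "unit_intensity_au": round(unit.value, 2),
        "unit_se_au": round(unit.se, 2),
        "exact_count_fraction": round(exact, 3),
        "stoichiometry_mode": st["mode"],
        "bead_complexes_at_1e5_au": round(bead, 1),
    }
    (OUT / "bleach_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
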