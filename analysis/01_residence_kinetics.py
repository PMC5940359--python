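#!/usr/bin/env python
"""Residence-time kinetics of mono- to tetravalent tether modules.

Simulates 1000 Gillespie residence times per valence at the fitted rates
(k_off = 0.62 1/s from the monovalent data, k_on = 2.6 1/s), compares the
sample means with the exact birth-death absorption times, re-fits k_on from
the synthetic data as a self-consistency check, and reports the avidity
numbers: the local concentration of one tether confined to its ~60-nm reach
and the implied bimolecular on-rate.

Writes results/residence_times.csv and results/kinetics_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from mtcoupler.kinetics import (
    KineticParams,
    fit_kon,
    local_concentration,
    bimolecular_kon,
    mean_residence_closed_form,
)
from mtcoupler.synthetic import gen_residence_dataset

K_OFF = 0.62  # 1/s, reciprocal of the monovalent mean residence time
K_ON = 2.6  # 1/s, per-site attachment rate
SPHERE_RADIUS_NM = 62.0  # confinement radius of one ~60-nm tether
SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    sets = gen_residence_dataset(K_ON, K_OFF, [1, 2, 3, 4], 1000, seed=SEED)
    pd.concat([s.to_frame() for s in sets]).to_csv(OUT / "residence_times.csv", index=False)

    rows = []
    for s in sets:
        exact = mean_residence_closed_form(KineticParams(s.valence, K_OFF, K_ON))
        rows.append(
            {
                "valence": s.valence,
                "mean_residence_s": round(s.mean(), 3),
                "closed_form_s": round(exact, 3),
                "median_residence_s": round(float(pd.Series(s.times).median()), 3),
            }
        )
    table = pd.DataFrame(rows)
    print("Residence time vs valence (n = 1000 each):")
    print(table.to_string(index=False))
    fold = table.mean_residence_s.iloc[-1] / table.mean_residence_s.iloc[0]
    print(f"\nMean residence grows {fold:.0f}-fold from valence 1 to 4 "
          "(super-exponential avidity of the multivalent tether).")

    fit = fit_kon([s for s in sets if s.valence >= 2], k_off=K_OFF)
    print(f"\nRe-fitted k_on from the synthetic data: {fit['k_on']:.2f} 1/s "
          f"(generating value {K_ON}).")

    conc = local_concentration(1, SPHERE_RADIUS_NM)
    k_bi = bimolecular_kon(K_ON, conc)
    print(f"One tether in a {SPHERE_RADIUS_NM:.0f}-nm sphere: {conc:.2f} uM local "
          f"concentration -> bimolecular on-rate {k_bi:.2f} 1/(uM s), in the "
          "published range for the free tether binding microtubules.")

    summary = {
        "seed": SEED,
        "k_off_per_s": K_OFF,
        "k_on_per_s": K_ON,
        "k_on_refit_per_s": round(fit["k_on"], 3),
        "local_concentration_uM": round(conc, 3),
        "bimolecular_kon_per_uM_s": round(k_bi, 3),
        "per_valence": rows,
    }
    (OUT / "kinetics_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
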