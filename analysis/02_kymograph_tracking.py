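#!/usr/bin/env python
"""Kymograph tracing: residence times and tip-tracking from synthetic movies.

Generates two-channel kymographs (spot + microtubule) with known ground
truth, traces the spots by per-line Gaussian fitting, and recovers (a) the
monovalent residence-time distribution through the full imaging chain and
(b) tip-tracking classification and depolymerization speeds for couplers
that do or do not follow the shortening end.

Writes results/kymo_tracks.csv and results/kymo_summary.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mtcoupler.kinetics import KineticParams, simulate_residence
from mtcoupler.kymograph import (
    EmptyTrackError,
    TipTrack,
    classify_tip_tracking,
    residence_time,
    tip_velocity,
    trace_spot,
    trace_tip,
)
from mtcoupler.synthetic import CameraNoise, SpotModel, gen_kymograph

K_OFF = 0.62
FRAME_DT = 0.2  # s
SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def residence_through_imaging(n=150):
    sim = simulate_residence(KineticParams(1, K_OFF), n, seed=SEED)
    taus, rows = [], []
    for i, true_tau in enumerate(sim.times):
        detach = 3 + int(round(true_tau / FRAME_DT))
        spot = SpotModel(position_px=30.0, peak_photons=120, landing_frame=3,
                         detach_frame=min(detach, 59))
        kymo, _, _ = gen_kymograph(60, frame_dt_s=FRAME_DT, spot=spot,
                                   noise=CameraNoise(background=2.0), seed=10_000 + i)
        try:
            track = trace_spot(kymo, (3, 30.0))
        except EmptyTrackError:
            continue
        tau, censored = residence_time(track, FRAME_DT)
        if not censored:
            taus.append(tau)
        rows.append({"kymo": i, "landing": track.landing_frame,
                     "detach": track.detach_frame, "residence_s": tau,
                     "censored": censored})
    return np.asarray(taus), pd.DataFrame(rows)


def tip_tracking_fractions(n_each=40):
    results = []
    for i in range(2 * n_each):
        tracking = i < n_each
        spot = SpotModel(position_px=40.0, tip_tracking=tracking, peak_photons=100)
        kymo, mt, truth = gen_kymograph(
            40, tip_velocity_nm_s=180.0, tip_start_px=58.0, spot=spot,
            noise=CameraNoise(background=2.0), seed=20_000 + i,
            detach_on_tip_pass=False,
        )
        tip = trace_tip(mt)
        try:
            track = trace_spot(kymo, (2, truth.spot_position_px[2]))
            label = classify_tip_tracking(track, tip)
        except (EmptyTrackError, ValueError):
            label = False
        results.append({"truth": tracking, "classified": label,
                        "tip_speed_nm_s": tip_velocity(tip, 160.0, 1.1)})
    return pd.DataFrame(results)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    taus, tracks = residence_through_imaging()
    tracks.to_csv(OUT / "kymo_tracks.csv", index=False)
    sem = taus.std() / np.sqrt(taus.size)
    print(f"Monovalent residence through the imaging chain: "
          f"{taus.mean():.2f} +- {sem:.2f} s (kinetic truth 1/k_off = {1 / K_OFF:.2f} s, "
          f"n = {taus.size} uncensored tracks).")

    tt = tip_tracking_fractions()
    frac_true = tt[tt.truth].classified.mean()
    frac_false = tt[~tt.truth].classified.mean()
    print(f"Tip-tracking classification: {100 * frac_true:.0f}% of true tip-trackers "
          f"called tracking, {100 * frac_false:.0f}% false-positive rate on static spots.")
    print(f"Recovered depolymerization speed {tt.tip_speed_nm_s.mean():.0f} nm/s "
          "(programmed 180 nm/s).")

    summary = {
        "seed": SEED,
        "mean_residence_s": round(float(taus.mean()), 3),
        "sem_residence_s": round(float(sem), 3),
        "kinetic_truth_s": round(1 / K_OFF, 3),
        "tip_tracking_sensitivity": round(float(frac_true), 3),
        "tip_tracking_false_positive": round(float(frac_false), 3),
        "tip_speed_nm_s": round(float(tt.tip_speed_nm_s.mean()), 1),
    }
    (OUT / "kymo_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
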