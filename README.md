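# mtcoupler

Quantitative machinery for studying **multivalent microtubule couplers** —
engineered modules carrying N copies of the kinetochore tether NDC80 — at
the single-molecule level. The package covers the four measurement chains
such a study needs, each exercisable end-to-end on synthetic data with
known ground truth:

1. **Residence-time kinetics.** The number of attached tethers of an
   N-valent module is a birth–death chain: with m sites bound, a free site
   attaches at rate (N − m)·k_on and a bound site detaches at rate
   m·k_off. The module's residence time is the first-passage time from
   m = 1 to absorption at m = 0. A Gillespie simulator and the exact
   closed-form mean (solving the linear system
   (λ_m + μ_m)T_m = 1 + λ_m T_{m+1} + μ_m T_{m−1}, T_0 = 0) let k_on be
   fitted from per-valence residence data; avidity bookkeeping converts
   the per-site rate into a bimolecular rate via the local concentration
   n/(N_A·(4/3)πr³) of tethers confined to their ~60-nm reach.
2. **Kymograph tracing.** Reslice image stacks into time × position
   kymographs, fit each line with a Gaussian (peak = sub-pixel position,
   A·σ·√(2π) = spot intensity), chain fits into tracks, read off landing
   and detachment (hence residence time, with left-censoring flags), and
   classify tip-tracking against the shortening microtubule end.
3. **Photobleaching stoichiometry.** Chung–Kennedy edge-preserving
   smoothing, single-fluorophore intensity from the equally spaced peaks
   of pooled intensity histograms, fluorophore counts from pre-bleach
   intensities, two-colour ratios, and bead-brightness → complex counts.
4. **Optical-trap force traces.** QPD volts→nm calibration, trap
   stiffness from the (aliased) Lorentzian power spectrum with Faxén's
   wall correction, axis rotation, 1-kHz smoothing, stall-plateau
   detection, stall force F = κ·Δx, detachment/rescue classification by
   return speed, link stiffness k_BT/⟨var⟩, and rescue-fraction
   statistics.

A `geometry` module handles bead-coating arithmetic (module spacing
√(πd²/n), modules within tether reach n·h/2r), and `synthetic` generates
every input type — Gillespie residence tables, two-channel kymographs with
a Poisson+Gaussian camera model, stepwise bleaching traces, and
Ornstein–Uhlenbeck trap recordings with programmed ramp-and-plateau stalls.

## Worked example

```python
from mtcoupler.kinetics import (KineticParams, simulate_residence,
                                mean_residence_closed_form, fit_kon,
                                local_concentration, bimolecular_kon)
from mtcoupler.synthetic import gen_residence_dataset

# monovalent module: mean residence = 1/k_off
rts = simulate_residence(KineticParams(valence=1, k_off=0.62), 10_000, seed=1)
print(round(1 / rts.mean(), 2))            # 0.62  (1/s)

# avidity: mean residence grows ~40-fold from valence 1 to 4
for n in (1, 2, 3, 4):
    print(n, round(mean_residence_closed_form(KineticParams(n, 0.62, 2.6)), 1))
# 1 1.6   2 5.0   3 17.8   4 69.9   (seconds)

# recover k_on from synthetic residence data, valences 2-4
sets = gen_residence_dataset(2.6, 0.62, [2, 3, 4], 1000, seed=1)
print(round(fit_kon(sets, k_off=0.62)["k_on"], 2))   # 2.57  (1/s)

# one tether confined to a 62-nm sphere
conc = local_concentration(1, 62.0)        # 1.66 uM -> prints as 1.7
print(round(bimolecular_kon(2.6, 1.7), 1))  # 1.5  (1/(uM s))
```

The monovalent simulator returns the detachment rate it was given (0.62/s);
the closed-form means show the avidity effect (1.6 s → 70 s from one to
four tethers at these rates); the fit recovers the generating attachment
rate within a few percent; and dividing the per-site rate by the local
concentration gives a bimolecular on-rate of 1.5 per µM·s, in the published
range for the free tether.

## Analysis scripts

Numbered drivers under `analysis/` run each measurement chain on synthetic
data and write tables to `results/`:

```
01_residence_kinetics.py        residence vs valence, k_on fit, avidity numbers
02_kymograph_tracking.py        residence through the imaging chain, tip-tracking
03_photobleach_stoichiometry.py unitary intensity, counts, 3:1 stoichiometry
04_force_traces.py              trap calibration, stalls, outcomes, stiffening
05_bead_geometry.py             module spacing and modules within reach
```

For example, `04_force_traces.py` calibrates the trap to within 1%
(PSD vs equipartition), recovers programmed stall forces with ~0.2% median
error, labels 100% of detachment/rescue outcomes correctly, and reports a
28% overall rescue fraction rising with stall force.

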