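# Methods

## Kinetic model

An N-valent module is a set of N identical, independent tether–microtubule
bonds on a common scaffold. The state is the number m of attached tethers;
transitions are attachment of any free site, rate λ_m = (N − m)·k_on, and
detachment of any bound site, rate μ_m = m·k_off. Residence time is the
first-passage time from m = 1 (the landing event) to m = 0. Assumptions:
rates are force-independent and site-independent (no cooperativity, no
geometry), and the landing rate itself is outside the model — every
realization starts with exactly one bound site.

The Gillespie simulator draws the waiting time from Exp(λ_m + μ_m) and the
event type with probability λ_m/(λ_m + μ_m); all runs advance in lock-step
on vectorized draws from one seeded `numpy` generator, so a seed fixes the
dataset bit-for-bit. The closed-form mean residence solves the standard
tridiagonal first-passage system
(λ_m + μ_m)T_m − λ_m T_{m+1} − μ_m T_{m−1} = 1 with T_0 = 0, λ_N = 0, and
serves as the simulator's independent oracle (it is also cross-checked in
the tests against −Q⁻¹·1 on the transient generator matrix).

`fit_kon` holds k_off fixed (it is identified by the monovalent mean,
1/k_off, which cannot depend on k_on) and minimizes the summed squared
difference of log mean residence between data and closed form over all
valences ≥ 2. Log means, rather than raw means, keep the steeply growing
higher valences from dominating the objective. Minimization is a grid
search (default 0.1–10 s⁻¹, step 0.05) with ties broken toward smaller
k_on, refined by bisection between the neighbouring grid points; the
objective is smooth and unimodal in practice, and the derivative-free
search is exactly reproducible. Left-censored observations (spots already
bound when observation starts) bias means downward and are excluded from
fitting by default (flag to include).

Avidity bookkeeping treats the module as a sphere within which its tethers
are confined: local concentration n/(N_A·(4/3)πr³), and bimolecular rate
k_on divided by that concentration. The default example radius is 62 nm —
the ~60-nm tether length with the printed two-significant-digit
concentration (1.7 µM) singling out 62 over 60 nm (which gives 1.8 µM).
The radius is always an explicit argument.

## Synthetic data

The generators define the study conditions; every one takes a seed and is
bit-reproducible.

**Kymographs.** Rows are frames (default 1.1 s) and columns pixels
(default 160 nm). The spot is a Gaussian of width σ = 1.3 px sampled at
pixel centres; the camera applies Poisson noise to signal + background,
then gain and additive Gaussian read noise. A spot's quoted SNR is
shot-noise-limited peak SNR: with a 25-photon peak and no background,
SNR = √25 = 5. The second channel carries the microtubule as an erf edge
whose tip retracts at the programmed velocity; the spot either stays put,
diffuses (Gaussian steps of variance 2DΔt), or rides the tip exactly. A
diffusing spot detaches when the tip passes it, mimicking shedding from a
shortening end. Not emulated: photobleaching of the tracked spot, drift,
neighbouring spots, or non-uniform illumination — so passing tests bound
estimator noise, not robustness to those artefacts.

**Bleaching traces.** Each of n fluorophores survives Exp(bleach_rate);
intensity is unit × survivors + Gaussian noise. Two lifetimes inside one
frame give the occasional simultaneous double step. No blinking or
reactivation.

**Trap recordings.** The bead coordinate is an Ornstein–Uhlenbeck process,
dx = −(κ/γ)x dt + √(2k_BT/γ) dW, with Stokes drag of a 1-µm bead in water
at 30 °C (γ ≈ 7.5·10⁻⁶ pN·s/nm) and κ in the experimental range
0.015–0.033 pN/nm. Updates use the distribution-exact AR(1) discretization
x_{i+1} = a·x_i + √(k_BT/κ·(1 − a²))·ξ with a = exp(−κΔt/γ): the naive
Euler–Maruyama update is unstable whenever κΔt/γ ≥ 0.1, which the physical
drag already violates at 10 kHz sampling, while the exact scheme is correct
at any step. (An explicit `scheme="euler"` path retains the stability
error for callers who want the naive integrator.) Stalls are deterministic
ramp-and-plateau excursions added to the mean: ramp at 100 nm/s (the bead
following the shortening tip), hold, then either an instantaneous return
(detachment) or a 20 nm/s ramp back (rescue; typical tubulin growth
speed). While engaged, fluctuations use κ + κ_link (default link stiffness
0.2 pN/nm), which is what dampens in-stall variance. No force-dependent
kinetics, protofilament mechanics, or bond rupture are modelled.

## Estimators and numerical choices

**Line fits.** Each kymograph row is fitted with A·exp(−(x−μ)²/2σ²) + B by
least squares (scipy `curve_fit`), optionally inverse-variance weighted
for shot-noise data (two reweighting passes with variance max(model, 1)) and
optionally with σ fixed at the instrument PSF width — both on by default in
the precision analyses, since at a 25-photon peak the weighted, fixed-width
fit reaches ~0.148 px RMSE against the ~0.144 px information bound
(σ/√N_photons with σ = 1.3 px, ≈81 photons). A fit counts as a detection
only if the amplitude exceeds 4 residual SDs *and* 4 amplitude standard
errors, with 0.5 px ≤ σ ≤ 2.5·σ_init: pure-noise fits otherwise collapse
onto single-pixel spikes or broad background humps and would extend tracks
past their true ends (a 2-SD amplitude rule alone passes 17–56% of
background rows). Tracking chains fits frame to frame (±5 px search window
around the previous centre), ends a direction after 3 consecutive failures,
and flags tracks present in frame 0 as left-censored; censored tracks enter
tip-tracking fractions but not mean residence times.

**Chung–Kennedy filter.** Forward/backward window means (default W = 8)
weighted by their mean squared prediction error over a W-sample test
window raised to −p (default p = 2); one-sided at the trace edges; exact
on noiseless plateaus and preserving edges to within one sample. Unitary
intensity: all smoothed traces are pooled into a histogram whose bin width
is 0.2× the within-level noise SD — estimated robustly from first
differences of the raw traces, since the spread of the pooled histogram
itself is dominated by the level spacing. Peaks (scipy `find_peaks` with
height and prominence at 5% of the maximum) are refined to local
centroids, assigned integer levels by their median spacing, and the unit
is the least-squares slope through the origin; an rms level residual above
0.25 units raises an estimation error. First-bleach detection: a drop of
more than half a unit below the running pre-step mean sustained for W
samples; the count is round(pre-step mean / unit), so a simultaneous
double bleach does not bias it.

**Trap analysis.** The volts→nm factor is the inverse slope of a line
through the central ±200 nm of the calibration sweep. Trap stiffness comes
from the Welch spectrum fitted with the *aliased* Lorentzian
c/(1 − 2a·cos(2πf/f_s) + a²), a = exp(−2πf_c/f_s), with relative (1/S)
weights over 5–2000 Hz: fitting the continuous Lorentzian to sampled data
biases f_c upward by ~15–20% at these corner frequencies. κ = 2πγf_c with
γ = Stokes drag × Faxén's wall correction
1/(1 − 9/16·q + 1/8·q³ − 45/256·q⁴ − 1/16·q⁵), q = r/(r + gap). Pull
segments are block-average decimated to 1 kHz (mean-preserving) and
Chung–Kennedy smoothed. Stall detection: baseline mean/SD from a
user-set window; candidate samples exceed the free level by 5 baseline
SDs with local slope below 10 nm/s (central difference over a 50-ms
moving average — differencing adjacent samples is far too noisy); the
longest qualifying run, refined outward to where the smoothed signal
first reaches 2.5 plateau-SDs below the plateau level (the slope filter
alone clips the transitions), must last ≥ 0.2 s. These thresholds detect
programmed 1.5-s stalls at ≥1.5 pN with zero false positives in 500
stall-free traces while keeping duration bias below 0.05 s. Outcome: mean
return speed from stall level to within 2 baseline SDs of the free level,
detachment above 1000 nm/s, rescue below, indeterminate if the trace ends
first (mirroring the exclusion of beads lost before stalling). Stall
force is Δlevel × κ × c(level) with c an optional user-supplied
nonlinearity correction (identity by default — no invented physics). Link
stiffness is literal k_BT/var over the stall, an *effective* trap+link
stiffness; no series/parallel decomposition is attempted because the
measurement alone cannot separate them. Temperature default 303 K
(k_BT = 4.18 pN·nm).

**Geometry.** Mean module spacing is the square-lattice value √(πd²/n)
over the whole sphere; it reproduces the quoted ~250 nm at 50 modules on a
1-µm bead, while the quoted ~775 nm at ~5 modules corresponds to no simple
convention we found (this formula gives 793 nm) and is treated as
approximate. Modules in reach use the spherical-cap fraction h/2r of a
plane-approximated microtubule at tether reach h (default 60 nm).
Coating-fraction→count interpolation is linear in log-log space, matching
the near power-law calibration.

## Problem sizes

Default analysis and test sizes: 10⁴ Gillespie runs per parameter set
(Monte-Carlo SEM ≈1% of the mean); 1000 runs per valence for k_on fitting
(recovery within a few percent); 100 kymographs × 100 frames for tracer
precision; 250 bleaching traces; 30 s at 10 kHz for trap calibration;
120–200 programmed stall events per outcome/force battery at 5 kHz. Each
driver under `analysis/` completes in well under a minute.

## Known limitations

Rates are force-independent, so the model cannot produce the experimentally
observed force–rescue correlation (the force-trace driver programs one in
at the generator level purely to exercise the binned statistics). The
tracer handles one spot per kymograph window — no multi-spot association
or drift correction. The unit-intensity estimator needs a populated zero
level (fully bleached traces). The spacing formula is a mean-field
estimate, not a stochastic placement model. Synthetic trap traces omit
low-frequency drift and laser pointing noise, so calibration accuracy on
real recordings will be worse than the ~1–3% seen here.
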