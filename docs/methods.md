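# Methods

## The model

The eye and its perfusion hardware are a lumped-parameter hydraulic circuit.
A source — a pump delivering flow F_S, or a raised fluid reservoir at
pressure P feeding through the system (flow-sensor) resistance R_S — charges
the system compliance C_S at pressure P_S.  Fluid enters the eye through the
cannula resistance R_C at pressure P_E, drains through the trabecular
resistance R_T toward the Goldmann resting pressure P̄_E (which absorbs
aqueous production, uveoscleral outflow and episcleral venous pressure), and
distends the globe wall.  The wall is a standard linear solid: compliance
C_W2 in series with the parallel pair (R_W, C_W1), with quasi-static series
compliance 1/C_W = 1/C_W1 + 1/C_W2 and C_W1 = C_W2 = 2 C_W by default.

Eliminating internal nodes yields a third-order linear ODE for P_S whose
characteristic coefficients are

    alpha = R_T R_W C_W1 C_W2
    beta  = R_C R_W C_W1 + R_C R_W C_W2 + R_C R_T C_W2
            + R_T R_W C_W1 + R_T R_W C_W2
    gamma = R_C C_S + R_T C_S + R_W C_W1 + R_W C_W2 + R_T C_W2

We do **not** integrate the scalar third-order form: for step inputs its
right-hand side contains derivatives of the input, which are impulsive.
Instead the simulator integrates the equivalent 3-state circuit form
(states: P_S and the pressures across C_W1 and C_W2), and a unit test
asserts that the state matrix's characteristic polynomial equals
(alpha·R_C·C_S, alpha + beta·C_S, gamma, 1) to machine precision, with the
R_S-including variant for the gravity scheme.

Default parameters describe an adult Brown-Norway rat eye cannulated with a
33g needle: P̄_E = 15 mmHg, R_T = 43 and R_W = 2.3 mmHg·min·µl⁻¹,
C_W = 0.09 and C_S = 0.05 µl·mmHg⁻¹, R_C = 0.36 mmHg·min·µl⁻¹, gravity
impedances R_S = 10 (CPg1) or 0.6 (CPg2) mmHg·min·µl⁻¹ and pump gain
K = 7 µl·min⁻¹·mmHg⁻¹ (CPp); CPpx is the low-gain pump (K = 0.3) with a
15-s moving-average smoothing of its feedback signal.

## Integration

The governing equations are advanced with classical fixed-step fourth-order
Runge-Kutta at the feedback update interval (0.1 s).  Because the system is
linear and inputs are held constant over each update, the RK4 step equals
the fourth-order Taylor one-step map, which is precomputed once.  Controller
modes that remain linear per update (CF, CPg, analog CPp, digital CPp with
the standard one-update measurement delay) are evaluated through a
diagonalized recurrence (`scipy.signal.lfilter` per eigenmode) — bit-for-bit
the same recursion as the explicit loop, at vectorized speed; CPpx and other
filtered/delayed digital variants use the explicit per-sample loop.  Digital
pump commands are computed from the pressure measured at the start of each
update interval, which realizes the "slightly delayed" digital regulation.
Gain sweeps that visit very stiff configurations (for example R_S = 0.01,
where |h·lambda| exceeds RK4's ≈2.78 stability bound at 0.1 s) refine the
step automatically.

Settling time is the last instant pressure or flow leaves the ±1% band
around the analytic plateau.  "1%" is measured against the step excursion
(plateau minus pre-step level) by default; the absolute-plateau convention
is available (`convention="absolute"`).  The absolute convention is
degenerate for flows that start at zero, and the excursion convention
reproduces the published constant-pressure settling times.  The simulated
constant-flow step settles in 46.7 min against a published 47.2: the
printed value lies midway between the circuit response and a
zero-initial-derivative scalar integration, which suggests the original
implementation handled the impulsive input-derivative terms by finite
differences.  We keep the circuit response, which is the physically correct
one.

## Noise

Noise records are zero-mean pressure fluctuations overlaid on the measured
system pressure: recorded P_S (and P_E) equal the model values plus the
record, gravity flow records inherit the noise through (P − P_S)/R_S, and
pump commands K(P_T − P_S) feed it back into the true dynamics.  This
overlay preserves the record's full spectrum in every trace; injecting the
same noise into the state instead lets the circuit's fast pole (−87 min⁻¹)
relax slow fluctuations between updates, high-pass filtering away exactly
the slow in vivo transients that matter.

* **Ex vivo**: Gaussian white noise at 10 Hz through a single-pole lowpass
  (bilinear transform, −3 dB at 0.4 Hz), rescaled to SD 0.04 mmHg — the
  statistic enucleated-eye records are validated against (filtering alone
  would leave SD ≈ 0.013; a flag disables the rescale).
* **Anesthetized surrogate**: filtered Gaussian base plus sporadic signed
  transients (Poisson 0.08 min⁻¹, lognormal magnitude with mean 1.2 mmHg,
  25-s decay), rescaled to the published overall SD of 0.23 mmHg.
* **Conscious surrogate**: slower base (0.1 Hz) plus strictly positive IOP
  bumps (Poisson 0.25 min⁻¹, mean 1.3 mmHg, 15-s decay), giving the
  positive skew characteristic of awake recordings; SD ≈ 0.4 mmHg.

Only the ex vivo recipe and two in vivo statistics (SD 0.23; positive skew)
are published; the surrogate event parameters were chosen once to mimic the
qualitative appearance of recorded rat IOP and are defaults, not claims
about rat physiology.  In particular the surrogates do not reproduce the
low-frequency structure of real recordings, so in vivo cohort durations are
checked as orderings and rough magnitudes, not as numeric targets; real
records loaded from CSV can be substituted anywhere.  Denser or
longer-lived bumps than the defaults create low-frequency mean wander that
biases fitted flow asymptotes in high-gain schemes by amounts the published
in vivo facility tables exclude.

## Steady-state criteria

* **Window**: steady when P_S varies by less than 10% of the input step
  size over a trailing 5-min window.  For constant-flow steps the step size
  is expressed in pressure units as (R_C + R_T)·ΔF.  Variation is max−min.
* **Ratio**: steady when the least-squares slope of F_S/P_S
  (nl·min⁻¹·mmHg⁻¹ versus minutes) over a trailing 5-min window stays below
  0.1 nl·min⁻²·mmHg⁻¹ (absolute value) for 1 min.
* **Fitting**: incoming pressure and flow are block-averaged to 1 s and
  refit at 1-s increments (starting 2 min after step onset) to
  PS* = A(1−e^(−t/τ)) + B and FS* = C·e^(−t/τ) + D with a shared τ.  Given
  τ the model is linear, so the fit profiles a weighted (flow ×100,
  the 1 mmHg : 0.01 µl·min⁻¹ scale ratio) sum of two conditional linear
  least-squares objectives over τ, warm-started from the previous fit.
  Steady state is declared when the fitted responses *and their fitted
  asymptotes* vary by less than 0.5 mmHg (pressure) and 0.05 µl·min⁻¹
  (flow) over a trailing 2-min window that lies more than 6τ̂ after onset
  and contains only genuine fit updates.  Monitoring the asymptotes is what
  prevents a fast fitted τ — the single exponential locks onto the
  compliance-charging mode of high-gain responses — from declaring steady
  state while the plateau estimate still drifts.

Raw data may be smoothed with a trailing moving average of width T before
the window/ratio criteria; windows are then evaluated only once the filter
is fully initialized, so the earliest possible detection is T plus the
window length after onset.  The window/ratio criteria can also run on the
*fitted response* — the series of current-fit predictions, with the first
fit backfilling predictions to onset — which is the mechanism that lets
experiments on conscious noise finish roughly an hour sooner than with the
best lowpass filter.

Steady-state values are means over the final criterion window (window,
ratio) or the fitted asymptotes mapped through the plateau relations
F_E = F_S, P_E = P_S − R_C·F_S (fitting and fitted responses).  Two
consequences worth knowing: (1) the window mean of *flow* in high-gain CP
schemes includes part of the initial pump transient, offsetting it well
above plateau — identically on every step, so the facility slope is
unaffected (noise-free recovery of 1/R_T is exact to <0.1%); (2) the ratio
criterion fires before the slow viscoelastic tail has fully decayed, so its
steady values carry a small convergence bias (facility low by ~1.3% for
constant flow, ±0.2–0.6% for CP schemes) — the same magnitude and pattern
visible in the published ex vivo facility table.

## Facility experiments

An experiment raises the input in equal steps (defaults: five steps of
0.1 µl·min⁻¹ for CF, 5 mmHg for CP), initiating each next step the instant
the criterion fires, and continuing from the simulated state at detection.
One noise record drives the whole experiment, consumed sequentially and
wrapping if exhausted.  Facility is the slope of the linear regression of
steady-state F_E on P_E (Pearson R reported); steps that reach the 90-min
timeout are flagged, excluded from the regression, and counted at the
timeout in the duration.  Cohort runs derive one child seed per record from
a single global seed.

The data-filter-width optimizer simulates one step per record per width and
selects the width minimizing mean + SD of settling time across records
("fastest with least variability"; runs that never detect count at the
timeout).  The mean+SD scalarization is our choice; the published account
does not state one.

With the stated ex vivo recipe the simulator reproduces the published
cohort statistics: mean experiment durations ≈ 121–123 (CF window), 60 (CF
ratio), 50 (CPg1 window), 26.8 (CPg2 window) and 25.4 min (CPp window), and
a CPg2 ratio-criterion facility of ≈ 23.3 nl·min⁻¹·mmHg⁻¹, across 12
regenerated 120-min records.  The published CPg2/CPp *ratio-criterion
durations* (31.0/30.6 min, flagged as detected at the earliest possible
time in the original report) are not reproduced: with the stated noise and
an absolute-value least-squares slope, the gain-amplified flow noise keeps
the slope statistic above threshold for several extra minutes per step
(~46 min totals).  Evidently the original slope statistic was insensitive
to flow noise in a way the printed rule does not capture.

## Problem sizes

Default test and acceptance runs use: 12 ex vivo records of 120 min for the
cohort statistics; 3 conscious surrogate records of 150 min for the
fitted-versus-filtered comparisons (4 CP schemes × window/ratio × both
responses); 6 fixed seeds for fit-recovery checks, asserted on the cohort
mean (the flow plateau, 0.116 µl·min⁻¹ against 0.067 µl·min⁻¹ of amplified
flow noise, is noise-floor-limited at ~5% per run); gain sweeps over
R_S ∈ [0.01, 100] and K ∈ [0.01, 10].  A full 4-scheme × 2-criterion ×
12-record ex vivo cohort simulates in a few seconds.

## Known limitations

* Linear eye: no pressure-dependent outflow resistance or compliance, no
  washout drift, no fluid inertia, and noise is additive on pressure (a
  volume-disturbance noise path would be damped differently).
* The single-exponential fitting function is matched to low-gain dynamics;
  for high-gain schemes it absorbs the fast system mode and relies on the
  asymptote-stability guard for accuracy.  A double-exponential model would
  fit those responses better and is not implemented.
* Surrogate in vivo noise matches summary statistics, not the spectra of
  real recordings; conclusions drawn from surrogate cohorts are orderings
  and robustness patterns, not absolute durations.
* The flow-based steady-state criterion used by some gravity-perfusion
  systems, and integral/derivative pump control, are out of scope.
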