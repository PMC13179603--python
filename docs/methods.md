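# Methods

## Scope and model overview

`dmscc` analyses dynamic microfluidic single-cell cultivations (dMSCC) of
budding yeast: colonies grown in perfused picoliter chambers whose glucose
supply alternates between excess (50 g/L) and limitation (10 mg/L) on a
fixed 30 s period.  The pipeline starts from segmented per-cell, per-frame
measurement tables (it performs no image processing) and quantifies four
population readouts per condition — specific growth rate, adaptation
duration, two ratiometric biosensor signals, and cell size — each
normalised to the constant-excess control of the same experiment.  A
calibrated agent-based generator stands in for real microscopy data, and a
chip model quantifies how faithfully the nominal square wave reaches a
given chamber.

The independent variable throughout is the excess fraction
`f = excess_s / period_s`, stepped by 2 s between conditions.

## Chip model

The nominal forcing is an ideal square wave, excess phase first in each
period (cells arrive from a 4 h excess pre-phase, so an excess-first
convention avoids a step discontinuity at the onset of the dynamics).
Two degradation mechanisms are modelled:

* **Lateral (across arrays).**  Moving the laminar flow boundary takes
  time, so each array step away from the chip centre delays the switch by
  `array_shift_step_s` (default 2 s) and transfers the same amount between
  the two phase durations (the left side lengthens the excess phase, the
  right side shortens it).  The outermost arrays never oscillate; they are
  the constant-condition controls.  The transfer rule is the minimal model
  consistent with an observed prolongation/shortening of pulses on
  peripheral arrays; no functional form is established experimentally.
* **Longitudinal (along an array).**  In-chamber concentration follows a
  first-order exchange model `dC/dt = k(n) (C_channel − C)` with
  `k(n) = k0 · decay^(n−1)`: exchange is fastest in the chamber nearest
  the inlet and decays geometrically as the upstream chambers' contents
  reduce the diffusion gradient.  This linear filter is the minimal
  mechanism that reproduces both smoothing along the array and mean
  conservation; no advection–diffusion PDE is solved.

**Pulse metrics.**  Effective phase durations are read from
threshold crossings at 50 % of the *achieved* amplitude (the threshold
definition is our choice; results are insensitive to it for traces with
definition ≳ 0.2), averaged over cycles.  "Definition" — achieved over
nominal amplitude — is our construction for quantifying pulse fidelity; it
is 1 for a perfect square wave and 0 for a fully smoothed trace, and NaN
durations are reported when the trace never crosses threshold.
Integration uses an exact exponential update per step (dt ≤ 0.5 s,
default 0.1 s) with the channel value taken at step midpoints, after a
burn-in of ~8 relaxation times so the periodic steady state is reached.

## Synthetic-data generator

The generator emulates what the analysis consumes, not microscopy itself.

* **Growth.**  Every cell in a chamber grows exponentially in area at the
  colony's current specific rate µ(t): `mu_excess` before onset (4 h),
  `mu_ini = mu_ini_fraction(f) · mu_adapted` during the adaptation window
  `t_adapt(f)`, and `mu_adapted = dose_response_mu(f) · mu_excess`
  afterwards.  The limitation control is held at limitation from
  inoculation and grows at `mu_limitation` throughout.  Because division
  splits area between mother and bud without loss, total colony area is
  *exactly* `A0 · exp(∫µ dt)` — noise-free runs are exact piecewise
  log-linear oracles for the estimators.
* **Division.**  A cell divides on reaching `division_area` (40 µm²,
  ~5 % lognormal per-division jitter to desynchronise the population),
  giving `bud_fraction` (0.35) of its area to the bud.  This produces the
  characteristic small-cell shoulder of budding populations.  The division
  threshold is scaled by `dose_response_size(f)`, relaxing linearly during
  the **last 10 %** of the adaptation window: cell size changes only once
  growth recovers, not at the oscillation onset.
* **Sensors.**  Per cell, four gray values are drawn so that
  uvGFP/GFP (QUEEN-2m, ATP) and CFP/RFP (GlyRNA, FBP) have condition means
  given by the dose-response maps, with multiplicative lognormal noise of
  CV 5 % per channel (mean exactly 1, so normalised window means are
  unbiased).  Ethanol Red carries a heritable 50/50 ATP subpopulation at
  0.7×/1.3× of the condition mean, inherited at division; PE2 carries a 3 %
  high-FBP-ratio outlier fraction.
* **Sampling.**  Phase-contrast frames every 8 min, fluorescence every
  32 min (missing channels elsewhere); cell identities are fresh per frame
  (segmentation-style output, no tracking).  One RNG stream per chamber is
  spawned from the experiment seed, so chamber results do not depend on
  chamber count.

**Calibration.**  Dose-response curves are shape-preserving monotone
cubics (PCHIP) through anchors expressed relative to the excess control:
all strains keep 50 % of the adapted rate at f = 0.1 and show a 40 %
higher GlyRNA ratio at constant limitation; CEN.PK113-7D/PE2 keep 90 % of
the maximal ATP signal at constant limitation and plateau near 90 % size
at short excess, while Ethanol Red keeps 70 % ATP and shrinks to 70 %
size; adaptation durations span 2.0–3.5 h, decreasing with f, with PE2
slowest.  The size map is deliberately non-monotone (above 1 at f = 0,
minimum near f = 0.1): all strains *enlarge* under constant limitation.
The Ethanol Red ATP map is kept monotone; a reported transient dip below
the constant-limitation level at very short excess is not modelled.
Absolute rates are not anchored by published values; defaults
(0.16–0.20 h⁻¹, ranking Ethanol Red > CEN.PK113-7D > PE2) are chosen so
that default seeding (1–3 cells of 16–32 µm²) can never exceed the
3600 µm² chamber capacity within 18 h, keeping the default study
conditions truncation-free.  All acceptance-level quantities are
control-normalised and therefore independent of the absolute scale.

**What the generator does not emulate:** second-scale intracellular
dynamics within one oscillation period, cell-cycle structure, lineage
tracking, mechanistic metabolism (storage carbohydrates, maintenance),
photobleaching/maturation, or segmentation errors.  Passing tests
therefore validate the *estimators and conventions* of the pipeline, not
biological predictions.

## Growth analysis

* Natural logarithm of total pooled colony area per frame; OLS slope over
  a closed–open time window `[t0, t1)` is the specific growth rate in h⁻¹.
* `mu_max`: maximum slope over all complete 3 h windows starting at or
  after onset, slid one frame at a time; earliest window wins ties.  An
  exhaustive window enumeration serves as the test oracle.
* `mu_ini`: single fixed 1 h window after onset (7–8 frames at 8 min
  cadence).
* Adaptation duration: intersection of the two regression lines,
  `t* = (b_ini − b_max)/(s_max − s_ini)`, reported relative to onset, and
  gated on `mu_ini < mu_max` and `mu_ini/mu_max < 0.9`.  Gate failures
  report duration 0 (flagged) so sweep tables stay rectangular; the gate
  also fails if the slopes agree within 1e-9 h⁻¹ or the intersection falls
  before onset (a negative duration is meaningless).  On noise-free
  piecewise data the estimator is exact to machine precision because the
  `mu_max` line extrapolates back through the construction breakpoint.
  With measurement noise the statistic has a heavy right tail near the
  gate boundary (the denominator `s_max − s_ini` can fluctuate toward 0);
  condition-level estimates should therefore be averaged over replicates,
  and sweep-level extremes need generous replication (see below).
* Normalisation divides by the excess-control `mu_max` of the same run;
  the time-weighted baseline is `f·µ_exc + (1−f)·µ_lim` from the two
  measured controls.
* Monod goodness-of-fit: `µ = µ_m S/(K_s + S)` fitted by nonlinear least
  squares against the duty-cycle-weighted mean concentration
  `S_eff = f·50 + (1−f)·0.01 g/L` (the covariate choice is ours and is
  logged as an assumption).  On the calibrated dose-response this fit is
  poor by construction near S → 0 — the model cannot represent growth
  retained at constant limitation — which is the point of reporting it.
* A count-based slope (`signal="count"`) is available as a diagnostic;
  area-based slopes are canonical.

## Population statistics

Per timepoint, the median and 25th/75th percentiles (linear interpolation
between order statistics) of all pooled cells; per condition, the
arithmetic mean of those medians over the closed 10–18 h window (6 h after
onset, avoiding the cell-number-limited early phase).  Fluorescence
metrics use only full-channel frames (32 min cadence); size uses every
8 min frame.  Records with non-positive gray values are skipped and
counted.  Normalisation divides window means by the excess control's.

Known emergent bias: under constant limitation the population barely
divides within 18 h, so cells accumulate just below the division threshold
and the median size overshoots the generator's nominal size factor (≈1.2×
observed vs 1.1× configured).  Dynamic conditions, whose populations turn
over, recover their configured size factors to within ~1 %.  No acceptance
quantity depends on the limitation-control size level, only on its sign
(> 1).

## Problem sizes and numerical choices

Default analyses use 10 chambers/condition, 1–3 founder cells per chamber,
18 h runs.  The packaged acceptance computations use 20 chambers × 5 seeds
for the growth dose–response point, 10 chambers × 2–3 seeds for sensor and
size targets, and, for the sweep-wide maximum adaptation duration, 16
replicate experiments of 10 chambers pooled per condition before a single
growth analysis (the pipeline's combine-into-one-file convention) — a
maximum over ~39 heavy-tailed per-condition estimates converges slowly,
and at this replication it estimates its population value (≈3.4 h) to
within ~0.2 h.
Tolerances: window masks use 1e-9 h slack on an exact 8-min grid (frame
times are computed as integer minutes divided by 60, so hour boundaries
are exact); the adaptation gate uses a 1e-9 slope tolerance; burn-in for
chamber traces is ~8/k seconds.  All randomness flows from a single
integer seed through `numpy` `SeedSequence` spawning.

## Limitations

* The generator's dose-response anchors are condition means; it does not
  attempt realistic cell-to-cell correlation structure beyond the explicit
  subpopulation labels.
* The chip model is phenomenological; it reproduces the two-axis
  degradation pattern (duration across arrays, definition along arrays)
  but is not a transport simulation.
* Growth is colony-level; single-cell growth-rate heterogeneity is not
  modelled and per-lineage rates are out of scope.
* The Monod R² values depend on the assumed effective-concentration
  covariate; only the qualitative lack of fit is asserted.
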