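# Methods

This note documents the models, parameter choices, and numerical decisions
behind `svsbalance`, in the order the pipeline runs them.

## Stimulus synthesis

**SVS waveform.** White Gaussian samples are drawn at the requested rate,
low-passed with an ideal frequency-domain cutoff at 30 Hz (every rFFT bin
above the band edge zeroed), re-zeroed in mean, and rescaled. An ideal
cutoff was chosen over an IIR design because it leaves no filter-order or
phase ambiguity and makes the spectral contract (< 1% of periodogram power
above 35 Hz) trivially auditable. "Amplitude" for a stochastic current is
not a standard notion; the default **peak convention** rescales so
max |sample| equals the target amplitude, matching the peak convention of
the sinusoidal probe, with an SD-based convention available via
`scaling="sd"`. Whether the original analog chain scaled noise by peak, SD,
or DAC range is not knowable from the outside; peak is the default because
it makes the familiarization probe (1500 µA peak) and the noise stimulus
directly comparable on one current axis.

**Sham.** A linear 1 s rise to the matched amplitude and a linear 1 s fall,
zero for the remainder of the 10 s window. "Gradual" admits many shapes;
linear is the simplest consistent choice and the one conventionally used in
non-invasive stimulation shams. The final sample is pinned to zero because
on a k/rate grid the 2 s ramp's zero otherwise lands one sample past the end
when the duration is exactly 2 s.

**Threshold procedures.** The perceptual observer is a deterministic step by
default (perceives iff level ≥ latent threshold); a logistic psychometric
observer with scale `response_noise_sd` is available for stochastic
simulations. The sinusoidal procedure presents the full level list
(50–1000 µA in 50 µA steps, then 1100 and 1200 µA) in seeded random order
and returns the lowest perceived level; the familiarization pulse precedes
the randomized levels and is not part of classification. The cutaneous
staircase ascends from 50 µA in 25 µA steps, twice, and returns the lowest
perceived level; it aborts at a configurable 2000 µA ceiling (no ceiling is
inherent to the procedure, but an unbounded staircase on a non-perceiving
observer would not terminate). Rest intervals between presentations are
protocol timing, not computation, and are not modeled.

**Technique comparison.** A two-tailed paired *t* on cutaneous − sinusoidal
stimulation amplitudes; the sign convention makes the statistic negative
when the sinusoidal technique yields larger amplitudes, which is the case
for the bundled 13-participant reference cohort (t(12) = −3.36).

## Kinematic measurement

The fixed preprocessing order is gap-fill → filter positions →
differentiate; every velocity-based measure consumes the output of that
chain (the order is recorded in `TrialMeasures.audit`). Marker gaps up to
0.1 s are linearly interpolated; longer gaps reject the trial with a reason.

**Filtering.** Zero-phase (forward–backward) Butterworth low-pass. A
4th-order net response is realized as two passes of a 2nd-order filter with
the per-pass cutoff pre-warped by `(√2 − 1)^(1/4)` ≈ 0.802 so the *net*
−3 dB point sits at the nominal 6 Hz — the standard dual-pass correction in
biomechanics. Positions are filtered and then differentiated (rather than
filtering velocities); with a linear filter and a linear difference operator
the order is immaterial for the result, but filtering positions first keeps
displacement-based measures (distances, step widths) on the same smoothed
signal.

**Differentiation.** Central differences in the interior, one-sided at the
endpoints (`numpy.gradient`): exact for affine trajectories and second-order
accurate otherwise.

**Foot contacts.** Local minima of the filtered mid-foot vertical velocity,
guarded by a minimum prominence of 0.05 m/s (well above sensor noise, well
below the ~0.3–0.4 m/s dip a swing arc produces) and a 0.4 s same-foot
refractory period (below any plausible stride time). Both guards are
configurable in `MeasurementParams`.

**Stride window.** Contacts from both feet are merged, alternation is
enforced, and the four consecutive contacts whose mean contacting-foot AP
position lies closest to the walkway midpoint (default 3.0 m of a ~6 m
path) are selected, excluding gait initiation and termination.

**Step width.** |ML distance| between the leading foot's mid-foot marker at
its contact and the trailing foot's mid-foot marker at its own preceding
contact; the mid-foot marker is used because it is the marker that defines
the contact event. Step-width variability is the sample SD (n − 1) of the
three widths in a trial, the common convention for gait variability.

**Base-of-support distances** use the absolute chest-to-reference
difference; frames where the chest passes the reference marker would simply
contribute near-zero distances rather than sign flips.

**Gait speed** interpolates the chest AP crossing times of the central 3 m
window edges linearly between frames, so the result is not quantized to the
frame period.

## Synthetic cohort generator

The generator emulates the crossed design (13 participants × 16 cells × 5
trials = 1040 trials) and is the package's test bed; it defines the
conditions under which the pipeline's claims are verified.

**Standing sway** is a stationary AR(1) velocity process — the exact
discretization of an Ornstein–Uhlenbeck process — with correlation time 1 s
and stationary RMS equal to the cell's target, integrated to positions.
This gives the headline measure (velocity RMS) a closed form for oracle
tests and looks qualitatively sway-like. Its integral is not mean-reverting,
so chest *position* drifts more over 5 s than real postural sway does; the
position-based distance measures are therefore only directionally
realistic, while the velocity-RMS measures are exact by construction.

**Walking** builds per-step foot placements (step length 0.70 m, 10 steps,
alternating sides starting right) and moves each foot through a stance
plateau plus a swing arc. The vertical arc is `h·sin⁴(πs)` (height
h = 5 cm): it is C²-continuous at the stance boundaries — so the 6 Hz
zero-phase filter produces no boundary ringing that could mimic a contact —
and its vertical velocity has a single smooth minimum at s = 2/3 of swing.
That instant is recorded as the ground-truth contact time: the generator
and the detector share one operational event definition, which is what the
±1-frame recovery tests verify. The foot's ML transition completes by
s = 0.6, so the foot's ML position at the contact instant equals the drawn
placement. ML placements are drawn per step as Normal(±w̄/2, σ_w/√2) with
w̄ = 0.10 m, so consecutive-placement differences (step widths) have SD
σ_w (default 0.015 m). The chest advances at the cell's target speed
(default 1.3 m/s) with a small within-stride oscillation and added OU sway;
gait speed is constant within a trial, so the generator does not emulate
gait initiation/termination transients (the stride-window logic is
exercised by the window-selection tests instead).

**Condition effects** are multiplicative factors on the cell targets:

| effect | factor | empirically anchored? |
| --- | --- | --- |
| balance challenge on standing AP sway | × 3.32 | yes (+232%) |
| balance challenge on standing ML sway | × 2.5 | direction only |
| SVS on challenged-standing ML sway | × 0.76 | yes (−24%) |
| balance challenge on walking ML trunk velocity | × 1.30 | yes (+30%) |
| balance challenge on walking AP oscillation | × 0.92 | yes (−8%) |
| balance challenge on step-width SD | × 1.31 | yes (+31%) |
| balance challenge on gait speed | × 0.85 | direction only |
| SVS on gait speed (both balance levels) | × 1.03 | yes (+3%) |
| SVS on step-width SD (both balance levels) | × 0.89 | yes (−11%) |

The two "direction only" factors are generator choices where no magnitude
is available. The walking ML factor is applied to trunk ML *velocity*: the
lateral oscillation amplitude is divided by the cell's speed factor so the
amplitude × cadence product scales exactly by the intended multiplier.
Walking AP trunk velocity RMS is dominated by the mean forward speed (RMS
of velocity, not of detrended velocity), so the AP factor scales only the
oscillatory component and the measured AP RMS largely tracks gait speed —
one known divergence from real data, where a 3% speed change need not
surface in AP RMS.

**Heterogeneity and noise.** Each participant gets a multiplicative
log-normal factor (σ = 0.15) applied to every baseline, which makes the
random-intercept ANOVA meaningful and induces realistic participant × cell
interaction on the raw scale. All marker coordinates receive additive white
noise of 0.15 mm RMS, the accuracy class of active-marker optical capture;
at 6 Hz bandwidth this contributes ≈ 1.4 mm/s to velocity RMS, small
against the 15–66 mm/s sway targets. (A coarser noise floor — e.g. 0.5 mm,
≈ 5 mm/s after differentiation — would add in quadrature to the weakest
cells and visibly bias cell-mean ratios, defeating the generator's purpose
of injecting known effect sizes.)

**Thresholds** for simulated participants are drawn from the reference
cohort's distributions (sinusoidal: mean 608, SD 162 µA; cutaneous: mean
312, SD 104 µA), truncated positive and snapped to the nearest legal grid
member of each procedure. Nearest-member snapping keeps the sampled mean on
the distribution mean; ceiling-style snapping (what a single staircase run
would produce) would bias it upward by half a grid step.

**Measure-level mode.** `simulate_measures` samples trial measures directly
from the same statistical model the kinematic synthesis targets (baseline ×
cell multiplier × participant factor × log-normal trial noise, with trial
CVs of 0.45 for RMS measures, 0.52 for a 3-step SD, 0.06 for speed —
matching the dispersion the kinematic generator produces). It exists so
that calibration questions needing hundreds or thousands of replicate
cohorts (type-I error, detection-rate curves) are answerable in seconds;
the fidelity of the kinematics → measures link is established separately by
the 500-trial cell-mean ratio recoveries through the full pipeline. With
`null=True` all condition multipliers are 1, which is the calibration null
of the ANOVA.

## Inference

**Analysis unit.** Trials are averaged to participant × cell means before
fitting. With 13 participants and 8 cells this yields 104 observations and
a residual with 104 − 1 − 7 − 12 = 84 degrees of freedom, so every
fixed-effect test is F(1, 84). Fitting individual trials instead would
multiply the error degrees of freedom and overstate precision for
within-cell replicates; per-trial fitting is possible by passing a
trial-level table, with correspondingly different df.

**Model.** On balanced cell means, the random-intercept mixed model is the
classical mixed ANOVA: participant enters as a block (fixed dummies absorb
the random intercepts exactly), and each fixed effect is tested against the
residual mean square. The implementation is an OLS fit with a type-II ANOVA
decomposition (statsmodels); on balanced data type I/II/III coincide, and
type II degrades gracefully under the mild imbalance created by outlier
removal. The participant variance component is recovered from the mean
squares as (MS_participant − MS_residual) / cells-per-participant, floored
at zero. The equivalence of these F tests with a hand-rolled
sums-of-squares decomposition is asserted to 1e-6 in the test suite.

**Post-hoc tests.** Tukey HSD among the four cell means of a significant
2×2 interaction, using the model MSE and residual df with Tukey–Kramer
standard errors; p-values from the studentized-range distribution with
k = 4. Interactions gate the post-hoc stage; Tukey tests on 2-level main
effects would duplicate the F tests and are omitted. The sham-vs-SVS
contrasts within each balance level are flagged as the planned reading of a
balance × stimulation interaction.

**Outliers.** Externally studentized residuals; |r| ≥ 4 flags the row
(configurable), and the model is refitted without flagged rows, both
reports retained so the analyst can compare. A threshold that flags more
than 10% of rows triggers a misconfiguration warning.

**Reporting.** p-values print with three decimals and as "< 0.0001" below
that; significance marks at α = 0.05.

## Problem sizes and determinism

Every stochastic component takes an explicit seed; identical seeds give
bit-identical waveforms, trials, manifests, and measures (asserted by
regression tests). The statistical verification sizes are: 200 trials for
stationary-RMS convergence (10% band), 500 trials per cell for
effect-multiplier ratio recovery (±0.06), 1000 replicate null cohorts for
type-I calibration ([0.035, 0.065] per effect), 200 effect-bearing cohorts
for the detection-rate pattern, and 100 noise-free walking trials for
contact recovery (100% within ±1 frame). The acceptance script defaults to
300 trials per cell and 500 null replicates; both sizes are comfortably
past the convergence knees of the corresponding estimates.

## Known limitations

- Integrated-OU chest position drifts over a 5 s standing trial; the
  base-of-support distance measures are directionally but not
  quantitatively realistic.
- Walking AP trunk velocity RMS tracks mean gait speed, so small speed
  effects surface in AP RMS more readily than in real data.
- The generator walks at constant speed; initiation/termination transients
  are not emulated, and the stride-window midpoint logic is validated on
  constructed contact sequences instead.
- Foot markers move rigidly with the mid-foot trajectory (no foot
  rotation), which is adequate for the measures computed here but not for
  joint-angle work.
- The observer model reduces perception to a (possibly logistic) threshold
  on amplitude; it does not model adaptation, lapses, or criterion drift.
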