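# Methods

## The transit-time problem

Carotid-femoral pulse wave velocity is a distance over a time delay:
`cfPWV = 0.8 · D / cfPTT`, where `D` is the straight-line body-surface
distance between the two recording sites and 0.8 corrects for the overlap of
the carotid and femoral path segments.  The delay must be read off two
pressure waveforms that (i) have arbitrary, uncalibrated amplitude (tonometry
measures shape, not pressure), (ii) were recorded sequentially, minutes
apart, synchronized only through a simultaneous ECG, and (iii) carry baseline
drift and broadband noise.  Every design choice below traces back to one of
those three facts.

## Tube-load model

The carotid-femoral arterial path is idealized as a uniform, lossless
transmission tube with transit time `T_d`, terminated by a three-element
Windkessel: characteristic impedance `Z_c` in series with a parallel
peripheral resistance `R` and compliance `C`.  Pressure on the tube is a
superposition of a forward wave and a wave reflected at the termination.
Only the products `τ_RC = R·C` and `τ_ZC = Z_c·C` are identifiable from a
pressure-to-pressure relation, so the model is parameterized by the triple
`(T_d, τ_RC, τ_ZC)`:

    Γ(ω) = τ_RC / (τ_RC + 2 τ_ZC + jω·2 τ_RC τ_ZC)
    H(ω) = (1 + Γ(ω)) / (e^{jωT_d} + Γ(ω) e^{−jωT_d})

`H(0) = 1` identically (the load passes mean pressure unchanged), `|Γ| ≤ 1`
with magnitude non-increasing in frequency, and `τ_RC = 0` gives a matched
(reflectionless) tube: `H = e^{−jωT_d}`, a pure delay.

### Fitting

Each R-R beat pair is treated as one period of a periodic signal.  Both
beats are min-max normalized (tonometric gain is arbitrary); the proximal
beat's spectrum is multiplied by `H(ω_k)` on the beat's harmonic grid and
compared with the distal beat.  Because the two normalizations need not
agree, a residual scalar gain and offset carry no information; they are
solved in closed form inside the objective before squaring, which makes the
noiseless forward-then-fit residual exactly zero at the true parameters.

The sum of squares is evaluated on the harmonics up to 30 Hz.  By Parseval's
theorem this equals the time-domain sum of squares of the band-limited
signals; arterial pressure has no usable content above ~30 Hz, so the cap
discards only out-of-band noise (and cuts the per-beat fit cost by roughly
a factor of four).  Setting `f_max=None` restores the full-band objective.

Minimization is a coarse multistart grid — `T_d ∈ {10, 20, …, 150} ms ×
τ_RC ∈ {0.3, 1, 2} s × τ_ZC ∈ {5, 20, 50} ms`, evaluated vectorized — whose
best point is refined by bounded trust-region least squares (analytic
Jacobian).  Ties in residual break toward the smallest `T_d`.  Default
bounds: `T_d ∈ [5, 300] ms`, `τ_RC ∈ [0, 3] s`, `τ_ZC ∈ [1, 100] ms`.  The
lower `τ_RC` bound is 0, not a small positive number, so a matched
termination is exactly representable: excluding it biases `T_d` by about
1 ms on pure-delay data, because the smallest reachable reflection
coefficient would then be ≈ 1/3 at DC.  A fit whose `T_d` lands on a bound
is flagged (`boundary_pinned_`).

`T_d` enters the model as a continuous phase, so recovery below the 1 ms
sample spacing is possible; reported transit times are the arithmetic mean
over beats.

### Single versus dual tube

The dual-tube estimator fits aorta→carotid and aorta→femoral tubes
independently and reports `cfPTT = |afPTT − acPTT|`; the single-tube
estimator fits one carotid→femoral tube directly.  On data generated by the
dual-tube forward model the dual fit is exact while the single tube is a
structural approximation: the femoral reflection's round trip references
the aortic entry plane, so the phase the single tube would need,
`Γ·e^{−jω(af+ac)}` inside a tube of delay `af − ac`, lies outside its
class.  The resulting single-tube overestimate is ≈ 0.7·acPTT (about 6 ms
at the default acPTT of 20 ms, i.e. ~0.4 m/s at 6 m/s) — visible in this
generator precisely because the generator *is* the dual-tube model; a
distributed arterial tree does not single out either topology this way.

## Comparator estimators

* **Intersecting tangent** (per beat): diastolic minimum searched in the
  first 40% of the beat (ties → earliest), first derivative by central
  differences after a 25 ms moving average (both configurable), maximum
  slope searched between the minimum and the beat maximum; the foot is the
  tangent/horizontal crossing.  Invariant to gain and offset by
  construction.
* **Waveform matching** (per beat): patch of half-width `t` (diastolic
  minimum to maximum slope) centred on the proximal diastolic minimum,
  min-max normalized, slid 0-300 ms in 1-sample steps over the distal beat;
  SSE-optimal shift, ties → smallest.  Patch indexing is circular within
  the beat — the patch of a distal wave whose foot sits early in the R-R
  window necessarily reaches before the beat onset, and the periodic-beat
  convention supplies exactly the preceding diastole.
* **Cross-correlation** (whole record): sequential records are first
  re-gated beat-by-beat onto the proximal R grid (cumulative R-R drift
  between sessions would otherwise masquerade as transit time — with a
  0.25 bpm session offset the drift reaches tens of milliseconds over a
  15 s window); then the middle 80% of the proximal record is correlated
  against the distal record shifted 0-300 ms, and the Pearson-maximizing
  shift wins, ties → smallest.

All three share the 0-300 ms search range at 1 kHz (cfPTT is
physiologically < 200 ms) with no sub-sample interpolation.

## Preprocessing

Baseline drift is removed by subtracting the approximation band of a
Daubechies-8 DWT whose depth puts that band below 0.5 Hz (level 7 at
128 Hz, level 10 at 1 kHz).  The record's end-to-end ramp is removed
before the periodized decomposition and the decomposition is allowed past
the advisory maximum depth; together these keep edge ringing of the drift
estimate small (a 0.2 Hz, 3 mmHg drift is suppressed > 20 dB on a 15 s
record while a 1.2 Hz passband tone changes < 5% RMS).  Signals acquired at
128 Hz are up-sampled to 1 kHz by linear interpolation.  R peaks come with
synthetic records, or from a Pan-Tompkins-style detector (5-15 Hz band-pass,
differentiate, square, 150 ms integration, adaptive threshold, 250 ms
refractory) for CSV input.  Sequential pairs whose mean heart rates differ
by more than 1 bpm are rejected.

## Synthetic generator

The aortic input is an analytic contour: raised-cosine systolic upstroke
(~100 ms), Gaussian dicrotic bump at 35% of the cycle, exponential
diastolic decay (time constant T/3), continuous across the period boundary
and mapped onto [DBP, SBP].  Carotid and femoral waves are produced beat by
beat through the tube transfer function with the subject's load parameters,
optionally damped by `e^{−αωT_d}` per harmonic (α = 0.05 by default) — a
deliberate departure from the lossless fit model.

Default loads are `(τ_RC, τ_ZC) = (0.2, 0.08)` s per tube, and cohort draws
use `τ_RC ~ U(0.1, 0.35)`, `τ_ZC ~ U(0.05, 0.1)`.  These were chosen on
pulsatile phenomenology: reflection magnitude ≈ 0.4-0.6 at the heart-rate
fundamental and femoral pulse amplification ≈ 1.3-1.5, as observed in vivo.
DC reflection realism is deliberately ignored because `H(0) = 1` makes the
generator blind to it.  Stronger low-frequency reflections (τ_ZC near
20 ms) drive the lossless tube into an unphysiological quarter-wave
resonance with ~10× femoral amplification.

Sequential acquisition is emulated with two sessions (carotid, femoral)
whose R-R sequences are independently jittered (sd 20 ms) and whose mean
heart rates differ by a seeded draw (sd 0.25 bpm) — so the 1 bpm rule is
exercised by construction; `mode="simultaneous"` shares one R-R sequence
across all three sites and stands in for numerically simulated data.
`degrade()` applies gain, sinusoidal drift, moving-average decimation to
128 Hz and seeded Gaussian noise at a stated SNR, defined on mean-removed
power (the DC level is gain-dependent and carries no information).

Random cohorts draw true cfPWV uniformly from 5-12 m/s and derive
`af_td = ac_td + 0.8·D/PWV`; the sweep mode varies one parameter (e.g.
`af_td`) in 1% steps over ±20%, giving 41 deterministic subjects.

What the generator does **not** emulate: distributed (multi-site)
reflections, vessel taper, nonlinear pressure-area behaviour, measured
pathology morphologies, probe-contact artifacts.  Passing tests therefore
demonstrate correctness of the algorithms and their stated invariants under
a controlled wave-propagation model, not clinical accuracy.

## Evaluation statistics

* **ICC(1,1)** — one-way random-effects, single measurement:
  `(MSB − MSW) / (MSB + (k−1)·MSW)`; > 0.75 is the conventional "good
  reliability" anchor.  Negative estimates are reported unclipped with a
  log note.
* **Bland-Altman** — mean difference, SD, ±1.96 SD limits, plus an OLS
  regression of difference on mean with a two-sided slope t-test for
  proportional bias.
* **Friedman** — within-row mid-ranks with the standard tie correction,
  chi-square reference with k−1 df; an exact permutation p is available for
  n ≤ 8 as a cross-check.  No multiple-testing correction is applied;
  α = 0.05.

Experiment drivers: *accuracy* compares estimates against generator truth
on clean simultaneous records; *repeatability* re-measures each subject's
fixed session with independent noise seeds (zero-noise repeats are
identical, making ICC = 1 an exact check); *robustness* measures
`|cfPWV(noisy) − cfPWV(noiseless)|` per SNR — the error baseline is the
same degraded record without added noise, so an SNR = ∞ condition is an
exact zero row.  Failed estimates (e.g. a non-positive transit time at
5 dB) are logged and excluded subject-wise.

## Problem sizes and numerical choices

Experiment records are 15 s (≈ 17 beats) for repeatability and
single-vs-dual comparisons and 10 s for the 50-subject × 20-repetition
robustness sweep; these are the package's default study sizes and keep a
full evaluation under ~10 minutes on one CPU.  The generator's own default
record length remains 30 s.  All randomness flows from a single root seed
through `numpy.random.SeedSequence` spawning; reported PTTs are rounded to
0.1 ms only at the CLI surface, never internally.  Known degenerate inputs
and their handling: flat beats (error), beats shorter than 0.25 s
(discarded with a warning at segmentation, rejected at construction),
zero-variance correlation windows (error), identical proximal/distal beats
(fit pins `T_d` at its lower bound and flags it).
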