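# Methods

## Cell models

Two human atrial myocyte models are implemented from their published
equation sets: the Courtemanche et al. (1998) model (21 states; time in
ms, concentrations in mM, currents in pA) and the Maleckar et al. (2009)
modification of the Nygren et al. (1998) model (29 states including a
bulk/cleft/diadic compartment structure and explicit Ca²⁺ buffer
occupancies; native time unit seconds, integrated here on a millisecond
clock).  Two stabilising changes are applied, matching common practice for
long paced protocols: intracellular Na⁺ and K⁺ are held at their default
initial values (11.17 and 139.00 mM) in the Courtemanche model, removing
its well-known slow concentration drift, and the acetylcholine-activated
K⁺ current of the Maleckar model is set to zero.  Stimuli are inward
currents of 2,000 pA for 2 ms (Courtemanche) and 750 pA for 6 ms
(Maleckar; as a density this is 750/C_m pA/pF, which is why cell
capacitance strongly shapes the Maleckar upstroke).

Because the reference CellML exports are not bundled, transcription
correctness is validated against published steady-state physiology rather
than trace-by-trace: at a 1,000 ms cycle length the Courtemanche
implementation settles at a resting potential of −80.7 mV, APD₉₀ ≈ 300 ms,
dV/dt_max ≈ 216 mV/ms, peak ≈ +24 mV and a Ca²⁺ transient of ≈ 0.11–0.74 µM,
all within the ranges reported for the original model; the Maleckar
implementation rests near −78 mV with the more triangular, shorter action
potential characteristic of the Nygren family.  The G_Kur verification
experiment (below) provides an additional mechanism-level check on both.

### Integration

The production integrator is an adaptive step-size scheme compiled with
numba that switches per step:

* below −55 mV with |dV/dt| < 0.5 mV/ms (diastole), Hodgkin–Huxley gates
  are advanced by exact exponential (Rush–Larsen) updates with rates
  frozen at the step midpoint, and the remaining states by the explicit
  midpoint rule.  This removes the stiffness of the fast Na⁺-gate rates at
  the resting potential (τ_m ≈ 0.01 ms), which otherwise caps explicit
  steps at ~0.03 ms through a 700 ms diastole;
* elsewhere (upstroke, plateau, rapid repolarization) an embedded
  Cash–Karp 4(5) pair is used, which is far cheaper per unit accuracy when
  the gates are active.

Error control uses rtol = atol = 10⁻⁶ with the step capped at 0.5 ms; the
error estimate is the embedded fourth-order solution (Runge–Kutta branch)
or an embedded first-order rates-at-t solution (Rush–Larsen branch).
State values are clamped to a wide physical bracket inside the rate
functions so that rejected trial stages cannot overflow.  A BDF-type
reference path (scipy LSODA at identical tolerances) and a pure Cash–Karp
path are retained; the test suite checks that the hybrid integrator
reproduces the reference APD₉₀ to < 0.5 ms and that tightening the
tolerances tenfold moves the final-beat APD₉₀ by < 0.5 ms.  A 40-beat
Courtemanche run takes ≈ 1 s on one CPU.

Runs start cold from the published initial state; no pre-pacing beyond
the protocol's own beats is applied.  In the S1–S2 protocol the S2
stimulus is delivered at `last S1 onset + APD₉₀(last S1) + 10 ms + DI`,
with APD₉₀ measured online (activation = maximum dV/dt; level referenced
to the beat's own amplitude) while the final S1 beat is integrated in
25 ms chunks; anchoring at the stimulus onset makes DI the recovery time
after 90% repolarization plus a 10 ms guard.

## Input spaces

The design table assigns each input a central value (the model default),
a half-range fraction (0.50; 0.25 for G_K1 and C_m; 0.10 for [Na⁺]ₒ,
[K⁺]ₒ, [Ca²⁺]ₒ) and a sensitivity-analysis variance on the normalized
scale (0.02 / 0.04 / 0.1 respectively).  Ranges are always computed as
`central × (1 ± fraction)`; the handful of printed endpoints that
contradict their own percentage column are recorded verbatim in
`design.PRINTED_RANGE_AUDIT` for audit rather than used.  The Courtemanche
SR release rate constant is taken as its published default 30 ms⁻¹
(the printed central value 0.30 carries a decimal slip; every other row
matches the published default exactly).

Stage 1 uses all 20 (Courtemanche) or 22 (Maleckar) inputs.  Stage 2
keeps the subsets that dominate action-potential shape and duration —
G_K1, G_to, the G_Kur multiplier, G_CaL, G_bCa, I_NaK^max, I_NaCa^max and
I_pCa^max for Courtemanche; G_K1, G_t, G_Kur, G_CaL, G_bCa, I_NaK^max and
C_m for Maleckar — plus the diastolic interval DI ∈ [50, 450] ms of a
final S2 beat, expressed internally as central 250 ms with fraction 0.8.
DI is a protocol input (it maps to the pacing protocol, not the model),
and carries the default 0.02 variance class in the sensitivity measure.
Designs are Latin hypercubes optimized by the maximin criterion over a
seedable pool of candidate draws (default 50).

## Biomarkers and the plausibility filter

Eleven outputs are taken from the final analyzed beat (the 40th S1 beat
in Stage 1; the S2 beat in Stage 2).  The activation is the time of
maximum dV/dt after the stimulus; RestV_m is the mean voltage over a
10 ms window ending 100 ms before the activation; APD_x is the time from
activation to the first crossing of `V_max − x%·(V_max − RestV_m)` with
linear interpolation; V_p is the voltage at `activation + p%·APD₉₀`;
Ca_min/Ca_max are the Ca²⁺ extrema over the beat's cycle.  The
amplitude-fraction convention for APD levels uses the beat's own V_max
and RestV_m.

A run is excluded from design data if it shows pacemaking (an upstroke
outside every stimulus window, window = onset + 50 ms), RestV_m > −60 mV,
APD₉₀ > 600 ms (failure to repolarize is classified here), or if the
APD₉₀ of the final beat pair differs by more than 5% (relative to the
later beat).  The filter judges the model's steady S1 behavior: in Stage 2
the rest/APD criteria are evaluated on the final S1 beat and the alternans
pair on the last two S1 beats, because the premature S2 beat legitimately
shows a shortened APD and, at short diastolic intervals, its pre-stimulus
window overlaps the previous repolarization — its biomarkers are
restitution measurements, not pathology (a non-repolarizing S2 still
excludes the run).  At the default ranges this removes ≈ 1–2% of
Courtemanche Stage-1 runs (alternans or depolarized rest) and essentially
none of the Stage-2 runs — a rare Stage-2 draw can land on genuine
sustained APD alternans and is then excluded — with a somewhat larger
fraction removed for the Maleckar model, the same ordering reported for
comparable analyses of these models.
A beat-39/40 APD₉₀ difference above 1% but below the exclusion threshold
only logs a steady-state warning.

## Emulator

Each output gets an independent GP with linear mean
`h(x)ᵀβ = β₀ + Σ β_p x_p` and RBF correlation with per-input length
scales δ_p, plus a fixed nugget 10⁻⁷ on the correlation diagonal.
Training integrates β (flat prior) and σ² (Jeffreys-type prior) out
analytically — the Kennedy–O'Hagan weak-prior treatment — leaving a
restricted log-likelihood in δ alone:

    −2·logL(δ) = log|A| + log|HᵀA⁻¹H| + (n − q)·log(yᵀQy),

with A the nugget-augmented correlation matrix, H the linear basis,
q = P + 1 and yᵀQy the generalized residual sum of squares.  σ̂² is the
residual quadratic over (n − q − 2).  Optimization runs L-BFGS-B on
log δ, bounded to [10⁻³, 10³], from 10 initial draws log-uniform on
[0.1, 10]; every restart's likelihood is recorded.  Outputs are z-scored
before training and de-standardized on prediction (the validation and
sensitivity quantities are unchanged by this).  An exactly-linear target
makes the residual vanish; the quadratic is clamped below at 10⁻¹⁰ so the
fit degenerates smoothly to the linear mean.  The posterior predictive
variance includes the mean-coefficient uncertainty term, so it is
σ²-scale far from the design rather than exactly σ².

Validation uses MAPE = (100/N)·Σ|y_s − y_e| / ȳ_s (the validation-set
mean as denominator avoids small-value bias) and the individual standard
error ISE = |y_s − y_e| / sd(y_e).  ISE is named a *standard* error and
is judged against 1.0, so the default denominator is the posterior
standard deviation; the raw-variance form is available via
`ise_denominator="var"`.

## Sensitivity and uncertainty

Inputs are modeled as independent untruncated Gaussians on the normalized
scale (mean 0.5; variances as above).  The variance-0.1 extracellular
class puts noticeable mass outside [0, 1]; this is applied as specified
and the emulator simply extrapolates there.  Indices are computed on the
posterior-mean surface — code uncertainty enters separately, e.g. as the
95% credible band on restitution surfaces — for which every required
moment is a closed form: Gaussian integrals of single RBF factors and of
products of two RBF factors reduce to Gaussians again, so S_w, S_Tw, main
effects E[f_e | x_w = g] on the grid {0, 0.01, …, 1}, and output
mean/variance all come from one set of per-dimension integral tables
(O(P·N²) memory).  The closed forms are verified in the test suite
against an independent pick-freeze Monte-Carlo estimator (Saltelli
first-order / Jansen total-effect, with moment-based standard errors) on
randomized emulator fixtures, at three-standard-error tolerance.

Each index receives the sign of the central finite difference of its main
effect across the grid points adjacent to 0.5; an exactly zero gradient
leaves the index unsigned.  Regression indices B are ordinary multivariate
least squares on column-standardized X and Y (sample s.d., N−1); a
latent-component PLS mode exists behind a flag but the default reproduces
the plain least-squares computation.  For near-additive surfaces S ≈ B²,
which the comparison table quantifies with per-output rank correlations —
meaningful only for outputs shaped by several inputs; an output ruled by
one parameter leaves the remaining ranks to noise.

## Synthetic benchmarks

The toy action potential is piecewise closed-form: a linear upstroke
(slope parameter), a power-law repolarization `V = peak − amp·(t/T)^{1/q}`
whose plateau shape q and duration scale T make every APD and plateau
voltage analytic, a constant diastole, and a pulse-shaped Ca²⁺ transient.
Restitution enters as `T(DI) = T∞·(1 − s·e^{−DI/100 ms})`, monotone in DI
for s ∈ [0, 1).  Each parameter moves its biomarkers monotonically, so
dominant-input recovery and main-effect signs have unambiguous ground
truth.  The toy model emulates the *statistical* structure of the real
workflow (smooth deterministic maps on the hypercube, a filter with
plantable violations); it does not emulate ionic mechanisms, so toy-based
tests validate the pipeline machinery, not cardiac electrophysiology —
the cell-model tests and the G_Kur experiment carry that weight.

## Problem sizes

The Stage-1 reference workflow in `scripts/acceptance.py` uses 300 design
and 50 validation Courtemanche runs (40 beats each) — design density of
15 runs per input dimension, matching the ten-per-dimension rule of thumb
with margin — and trains nine emulators (APD₉₀ plus the eight
weak-interaction outputs) with the full 10 restarts; it completes in
about 15 minutes on one CPU.  The acceptance tests in the suite run the
same workflow plus 200 Stage-2 runs and the six G_Kur simulations.
Toy-based tests use 30–100 runs.

## Known limitations

* Cell-model validation is against published steady-state biomarkers, not
  a trace-level reference implementation; residual transcription
  differences below that resolution would go undetected.
* The Maleckar implementation inherits the Nygren cleft/buffer structure;
  its absolute APD is on the short side of the published range, while all
  directional behavior (including the G_Kur effect reversal against
  Courtemanche) is reproduced.
* Sobol indices exclude emulator code-uncertainty by construction;
  outputs whose emulator fits poorly (high MAPE) inherit that error.
* The Gaussian input measure is untruncated; for the 0.1-variance class
  roughly a third of its mass lies outside the design cube, where the
  emulator extrapolates with inflated variance.
* No higher-order Sobol indices, estimated nuggets, non-RBF kernels, or
  multi-output/time-series emulation.
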