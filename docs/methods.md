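# Methods

This note documents the models, numerical choices and design decisions
behind `t2soflc`, in the order data flows through a simulation.

## Patient model

### Structure

The patient is a 2-input/2-output block-triangular system. Atracurium
infusion u₁ (normalized units) drives an effect-site concentration
through the third-order-with-zero transfer function G11 (dead time
1 min), which feeds the Hill curve; paralysis is the Hill effect on a
0–1 scale. Isoflurane concentration u₂ (%) drives the MAP change
through the first-order G22 (dead time 0.42 min) and additionally adds
to paralysis through the second-order interaction path G12 (gain 0.27
of full paralysis per % isoflurane, dead time 1 min); the summed
paralysis is clamped to [0, 1]. Atracurium never affects MAP. The
atracurium path is modelled by its pharmacodynamic transfer function
directly; a stand-alone pharmacokinetic block with gain 9.94 and the
same time constants exists in the literature lineage and is available
behind `PlantParameters.pk_cascade` (off by default — cascading both
would double the shared poles). The units linking the linear-path
output to the Hill input (µg/mL vs. normalized infusion) are not
defined by the source model; `PlantParameters.u1_scale` (default 1)
exposes the conversion.

### Discretization

Each linear block is realized in modal (parallel first-order) form via
partial fractions over its distinct real poles. For a piecewise
constant input the zero-order-hold step of each section,
`y ← e^(−dt/T) y + c (1 − e^(−dt/T)) u`, is *exact*, and the parallel
sum therefore reproduces the continuous block exactly at the sample
points; the DC gain equals the block gain to rounding error by
construction. Dead times are input-side ring buffers of
`round(τ/dt)` steps, so a block's response to a step from rest is
exactly zero before its dead time. The sampling interval is
dt = 0.01 min (100 intervals per minute; 30,000 intervals for a
300-minute run). Requesting `dt` at or above the fastest time constant
raises an error rather than silently discretizing badly. Tests compare
the discrete trajectories against `scipy.signal.lsim` on the
continuous blocks (< 0.5% of the steady amplitude) and against a
Hill-composed oracle for the nonlinear path.

### Nonfixed patient and measurement noise

Parametric uncertainty multiplies every gain, time constant and Hill
parameter by `1 + 0.01·z` with fresh standard-normal `z` at every
sampling instant (serially uncorrelated, not a random walk); the
multiplier is clamped positive so signs and stability are preserved.
Dead times are excluded because the delay-buffer length is fixed at
discretization. Measurement noise is additive and zero-mean:
`measured = clean + f·SD_ref·z` with `f` ∈ {0.1, 0.2} and fixed
reference scales SD_ref = 0.1 (paralysis, 0–1 scale) and 10 mmHg
(MAP), chosen as clinically plausible signal variabilities. (Deriving
the reference from the clean signal's own SD over the induction phase
is not usable: clean MAP is constant before the controller starts, so
its SD would be zero.)

## Fuzzy machinery

### Sets and partitions

All membership functions are triangular. Inputs use seven labels
(NB…PB) evenly spaced on [−1, 1] with 50% overlap. An interval type-2
set blurs a triangle's feet outward (upper MF) and inward (lower MF)
by the FOU half-width; the default width is 5% of the universe span.
A zSlices set stacks n nested FOUs at z = k/n whose widths shrink
linearly, `w_k = w·(1 − (k−1)/n)`, so one slice reproduces the
interval set exactly and the stack converges on the principal triangle
as z → 1; the default is five slices. `build_fou_from_stats` offers
the statistics-driven construction (triangle centred on a signal mean,
FOU width `scale·sd`, optionally one nested slice per patient-like
subgroup ordered by dispersion); since no real patient statistics ship
with the package, the controller uses the geometric defaults.

The engine normalizes every set kind to a stack of interval slices:
type-1 is a single degenerate slice, interval type-2 a single slice.
One code path therefore serves all three controller kinds, and the
degeneracy chain (zSlices(1) ≡ interval; zero-width FOU ≡ type-1) holds
to machine precision end-to-end, which the acceptance suite checks on
closed-loop runs.

### Inference, type reduction, defuzzification

Mamdani min–max: rule firing intervals use the minimum t-norm per
bound; fired consequents are truncated at their firing bounds and
aggregated by pointwise maximum on a 1001-point output grid (< 0.1%
centroid error). Type reduction is the classic iterative Karnik–Mendel
procedure computing the interval centroid [y_l, y_r]; each iteration
is O(1) via prefix sums over the sorted grid, and the tests verify
exact agreement with exhaustive switch-point search on all small
grids. A degenerate (type-1) aggregate short-circuits to the ordinary
centroid. Defuzzification is the interval midpoint; zSlices combine
per-slice midpoints weighted by their z levels.

### Output semantics

The output labels are ZE, PS, PM, PB — *unsigned adjustment
magnitudes*. The output partition places ZE's peak at zero magnitude
(its triangle extends symmetrically to −1/3 of scale) so that an
all-ZE inference defuzzifies to exactly zero; PS, PM, PB peak at 1/3,
2/3 and 1. The crisp magnitude is clamped to [0, 1]. The controller is
velocity-form: each channel integrates
`direction · magnitude · rate · u_max` per minute, clamped to
[0, u_max], where the direction is the sign that reduces the channel's
own error (more atracurium while paralysis is below set point, more
isoflurane while MAP is above set point). A position-form reading
(magnitudes as absolute drug levels) was prototyped and rejected: the
expert tables' cross-pair cells then create positive-feedback corners,
and the label-quantized self-organizing corrections (1/3 of full scale
per label) permanently deform an absolute control surface, whereas as
increments they act only transiently.

## Self-organizing layer

The 4-input/2-output problem is decomposed into the six unordered
input pairs; each channel's rule-base holds 2-input rules over all six
pairs, and the six defuzzified subsystem magnitudes are superposed
(summed, clipped to [0, 1]). Superposition rather than averaging is
deliberate: averaging lets five quiet subsystems dilute the active
one's command six-fold, which makes the required steady drug level
unreachable from the shipped tables.

The performance index is a 7×7 monotone lookup from the channel's
(error, integrated-error) labels — expressed in "drug demand"
orientation, i.e. the muscle-relaxation error is negated — to a
correction label NB…PB. At each control step the correction computed
from the *current* deviation is applied to the rules fired one plant
dead time earlier (atracurium 1 min, isoflurane 0.42 min; ring-buffer
history): per subsystem, the maximally firing rule's consequent is
shifted by the correction's signed offset multiplied by the direction
sign in force at the responsible step, saturating at ZE/PB; an
antecedent combination with no rule receives a new rule with
consequent `saturate(ZE + offset)`. A ZE correction is a strict no-op.
When no rule fires for a subsystem its contribution is zero and a
neutral (ZE) rule is seeded at the current labels, which keeps reduced
rule-bases operational. An optional per-rule modification cool-down of
one dead time exists (`so_cooldown`) but is off by default — it made
no measurable difference in velocity form.

Rule usage is tracked as fire counts over inference operations (six
operations per channel per control step); `extract_rules` removes
rules fired in less than a threshold percentage (default 1%) of
operations, the package's notion of trivial rules.

## Controller gains and timing

Errors are scaled so ±0.2 paralysis and ±30 mmHg map to the [−1, 1]
universes. Integrated errors are leaky (20-minute forgetting time
constant, an anti-windup measure: pure integrals rail and park the
system in extreme performance-index cells) and scaled by 2.0
paralysis·min and 300 mmHg·min. Full drug scales are u₁_max = 2
normalized units and u₂_max = 4%. The full-strength (PB) adjustment
rates are 0.5%/min of full scale for atracurium and 2%/min for
isoflurane: the atracurium loop's 34.4-min dominant lag combined with
a Hill slope of ≈ 1.8 per unit at the operating point limit-cycles at
faster rates, while the 2.4-min isoflurane loop tolerates a faster
one. The controller updates every 0.1 min (within the cadence of
clinical train-of-four and MAP measurements); the plant steps at
0.01 min.

## Simulation protocol and metrics

300 minutes in two stages (switch at 150 min, configurable): paralysis
set points 0.8 then 0.9, MAP 100 then 90 mmHg. The induction bolus
holds u₁ = 5 units for 5 minutes; the block then settles with both
drugs off until minute 15, when the controller takes over (MAP is
untouched, hence constant at 120 mmHg, during those 15 minutes). The
set-point ordering is configurable — the deeper-block-second default
(0.8 → 0.9) is one of the two orderings a surgical plan might use.

Per stage, over its final 50 minutes: the **steady-state error** is
the absolute difference between the time-averaged clean response and
the set point (averaging first, so zero-mean noise and symmetric
ripple do not register as error), and the **control stability** is the
population SD of the drug signal over the same window, i.e. dosing
smoothness once the set-point transient — identical for every
controller — is over. A whole-active-period SD is also available.
Repeated runs use matched seeds across configurations; groups are
compared with Kruskal–Wallis and ordered hypotheses with one-tailed
Wilcoxon signed-rank tests at α = 0.05 (both from `scipy.stats`;
identical paired vectors report p = 1).

## What the synthetic conditions do and do not show

The generator emulates intra-patient variability (parametric white
noise), instrument noise (additive measurement noise) and the
multivariable interaction between the two drug paths. It does not
emulate inter-patient covariates (age, weight), drifting or piecewise
physiology (the parameter noise is serially uncorrelated around a
fixed nominal), propofol induction, or real device dynamics. Passing
tests therefore demonstrate correctness of the algorithms and
convergence of the control loops on this reference patient, not
clinical performance.

Two further caveats matter when comparing controller kinds. First,
input FOUs for this controller family would ideally be built from real
patient statistics; none ship with the package, so the controller uses
geometric defaults (5% of span) and its numbers describe this
reference patient only. Second, under these defaults and with the no-rule-
fires fallback keeping every controller kind operational, the three
engines' crisp outputs differ by well under 1% per step and the
velocity-form integrator filters most of what remains: measured
differences between type-1, interval and zSlices controllers (and
between expert and extracted rule-bases) on this plant are small
(single-digit percentages) and can change sign between seeds. The
repeated-run acceptance comparison reports these differences honestly
rather than enforcing a separation the conditions do not produce.

## Known limitations

- Poles of every linear block must be distinct (true of the shipped
  parameters; the modal realization divides by pole differences).
- The checkerboard structure of the expert tables leaves label
  combinations with no rule; coverage there relies on the seeding and
  self-organizing add paths, so early-run behavior depends on the
  adaptation being enabled (`adapt=False` with the raw tables is a
  diagnostic mode, not a controller recommendation).
- Firing percentages count a rule as fired when its upper firing bound
  is positive in the widest slice; other conventions would shift the
  extraction threshold's meaning.
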