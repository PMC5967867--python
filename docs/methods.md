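# Methods

## Receptor model

The receptor is a continuous-time Markov chain.  The base activation scheme
is a linear chain

    R  ⇄  RA  ⇄  RA2  ⇄  O

with two sequential agonist-binding steps and one concerted gating step.
Association rates carry statistical factors 2 and 1 (two then one vacant
site), dissociation 1 and 2.  The co-agonist requirement of NMDA receptors
(glutamate plus glycine) is collapsed onto a single agonist axis: the model
is used at saturating agonist where the distinction is immaterial, and
agonist/co-agonist potency analysis lives in the data-analysis modules, not
in the state scheme.

Each allosteric modulator adds occupancy layers to the chain.  Under
`MODEL1` a receptor carries at most one modulator (mutually exclusive
site); under `MODEL2` every combination of bound modulators is reachable
(independent sites).  A modulator is parameterised by

| parameter | unit | meaning |
|---|---|---|
| `k_on` | 1/(µM·s) | association rate, identical in all states |
| `k_off_reference` | 1/s | dissociation from the fully agonist-bound closed state (RA2) |
| `gating_factor` | — | factor on the opening rate β while bound (>1 PAM, <1 NAM) |
| `state_dependence_factor` | — | fold-increase of affinity once both agonist molecules are bound |
| `blocking` | — | if set, bound states conduct nothing (full-block limit for oracles) |

### Thermodynamic closure

Efficacy and use-dependence couple binding to activation, so per-state
dissociation rates cannot be chosen freely without silently breaking
microscopic reversibility — the classic failure mode of hand-built
schemes.  Here they are *derived*: each base state gets an affinity weight
φ (φ = 1 at RA2, 1/`state_dependence_factor` for apo and singly-bound
states, ×`gating_factor` at O), the state's dissociation rate is
`k_off_reference`/φ, and within modulator-bound layers each base transition
is adjusted by the ratio of φ across the step (applied to the opening rate
for the gating step, to the agonist dissociation rate for binding steps —
the latter is precisely how the model expresses modulator-enhanced agonist
potency).  Every cycle of the expanded graph then closes exactly; the
constructor additionally verifies all basis cycles numerically at relative
tolerance 1e-9.

### Solvers and numerical choices

* Stationary occupancy: null-space of Qᵀ (SVD-based; a null space of
  dimension ≠ 1 raises a structure error), and independently stiff ODE
  relaxation of dπ/dt = πQ (BDF, rtol 1e-10/atol 1e-14) in growing time
  windows until the derivative max-norm falls below 1e-10, with a horizon
  of 1e4 s of model time — slow modulator steps on stiff gating need long
  horizons.  The two routes are cross-checked against each other in the
  test suite (1e-8 max-norm over randomised schemes).
* Relaxations: piecewise propagation with matrix exponentials per sampling
  interval; the system starts at the equilibrium of the first protocol
  segment.
* Readout: occupancy summed over conducting states with unit weights
  (configurable per base state); states carrying a `blocking` modulator
  conduct nothing.  Units are fixed throughout: µM, seconds.

### Default (demonstration) receptor

The rate constants of the published oocyte work are not tabulated anywhere,
so the package documents its own defaults and treats them as configuration:
agonist k_on 10 /(µM·s), k_off 40 /s (K_d 4 µM), β 50 /s, α 5000 /s.  The
resulting maximal open probability ≈ 0.0099 matches the very low open
probability characteristic of GluN2D-containing receptors.  The demo PAM
(K_d 2.4 µM at RA2, gating factor 2.5) potentiates saturating-agonist
responses to ≈ 266% of control and the demo NAM (K_d 0.20 µM, gating
factor 0.15) inhibits to a submaximal plateau of ≈ 16% — the two
modulator phenotypes the model is meant to emulate, with affinities on the
scale of the measured EC50/IC50 values (2.4 and 0.20 µM).  Both modulators
bind 100-fold more tightly once both agonist molecules are bound,
expressing the observed use-dependence ("high-affinity binding only with
both agonists bound").  All of this is overridable through the YAML scheme
configuration (`allomod dump-default-config`).

The low open probability is also what makes the `MODEL2` prediction clean:
with β ≪ α the response is nearly linear in the open-state bias, modulator
effects multiply, and the normalised NAM curve is almost independent of the
PAM background (residual dose-ratio deviations of a few percent arise from
the thermodynamically forced state-dependence of binding).  At high open
probabilities even independent sites interact detectably through gating —
a model prediction, not an artifact.

## Dose-response machinery

Two fixed Hill forms: modulator (ratio to control, parameters EC50, h,
Extent, plateau 1 + Extent) and agonist (fraction of max, EC50 and h).
Fitting is per replicate, parameterised internally in log10(EC50)
(bounds 1e-6–1e6 µM; h ∈ [0.2, 8]; Extent ∈ [−1, 50]), with multi-start
initialisation: EC50 seeded at the geometric mean of the tested
concentrations and at each concentration, h at {0.8, 1, 1.5} when free;
best residual wins, near-ties broken toward the EC50 closest to the tested
range.  The optimiser is bounded trust-region least squares.

Replicate EC50s are summarised as the geometric mean with a t-based 95%
interval on log10(EC50); Extent as arithmetic mean ± SEM.  Agonist-potency
fold shifts are computed per paired replicate (control/treated ratio,
geometric-mean summary) rather than as a ratio of group means — group-mean
ratios are not reproducible from paired designs — with a CI-overlap flag
from the two groups' log-EC50 intervals.

A screening rule is applied before fitting modulator curves: a replicate
whose response at 30 µM differs from control by 15% or less is flagged
"not fit" instead of fitted (the rule is skipped when 30 µM was not
tested, and can be disabled).

## Dose-ratio diagnostic

Each PAM level is normalised to its own zero-NAM response (this also makes
dose ratios exactly invariant to uniform rescaling of the response axis),
fitted with the modulator Hill form, and (ratio − 1) is regressed on [PAM]
by ordinary least squares.  Verdict thresholds, chosen far from the
boundary between the two stark phenotypes and fully configurable:
INDEPENDENT_SITES when max |ratio − 1| ≤ 0.10 across levels;
SHARED_SITE when R² ≥ 0.98 and the slope's 95% CI excludes zero from
above; INDETERMINATE otherwise.  The flatness test is evaluated first,
since a flat ratio set carries no meaningful regression.  Per-level Hill
slopes are reported as a parallel-shift diagnostic but do not gate the
verdict.  In the binding-only limit (single conducting state, full-block
NAM, silent PAM) the simulated diagnostic reproduces the Gaddum closed
form to the regression's numerical precision, which the tests use as an
independent oracle.

## Kinetics

Relaxations are fitted with ΔI(t) = A·(1 − e^(−t/τ)) + c, optionally + m·t
for records with a slow linear second phase (no double-exponential form is
offered; the linear term is the deliberate, minimal description of the
second phase).  τ is profiled: for fixed τ the model is linear in
(A, c, m), so a decade grid over the record length followed by bounded
scalar refinement gives a global fit without multi-start fragility.
Convergence is honest: the amplitude must exceed three residual standard
deviations (and a machine-level floor), and τ must lie well inside the
sampled window, otherwise parameters are withheld.

Observed onset rates follow 1/τ = k_ON·[M] + k_OFF; OLS gives k_ON
(slope) and k_OFF (intercept), cross-checked against washout 1/τ when
available (>2-fold disagreement is flagged), and K_d = k_OFF/k_ON, so the
identity K_d·k_ON = k_OFF holds by construction.  Racemization series are
fitted as first-order approach to the racemic asymptote with the same
profiling strategy; half-life = ln 2 / rate, reported in minutes.

## Mutant classification

Responses in modulator are expressed per replicate as % of the same
construct's agonist-only response.  Mutant vs wild type comparison uses
t-based confidence intervals (the standard choice at n = 4–18) at the 99%
level: overlap ⇒ UNCHANGED; otherwise the mutant mean's position relative
to the 100% line decides — between wild type and 100% ⇒ LOSS, farther from
100% on the wild-type side ⇒ AUGMENTED, across 100% ⇒ INVERTED.  The
LOSS/AUGMENTED boundary (distance from 100% on the wild-type side) is this
package's explicit definition of an otherwise qualitative colour scheme.
Raising the CI level can only move calls toward UNCHANGED.

## Synthetic data: what it does and does not emulate

Generators cover five-point half-log modulator CRCs (default 0.3–30 µM)
with 4–18-style replicate counts and mean-preserving multiplicative
lognormal scatter (5% CV default — proportional, as normalised oocyte
responses scatter), mono-exponential concentration-jump trace pairs with
additive Gaussian instrument noise, first-order racemization courses
(truth settable to the 197-min scale), and mutant panels drawn around
specified means.  They deliberately do **not** emulate desensitisation,
contaminant co-agonist artifacts, series resistance, rundown, or solution
exchange limitations; passing recovery tests therefore demonstrates the
correctness of the estimators under the stated noise models, not robustness
to every failure mode of real recordings.  Noiseless outputs are pure
functions of the truth and round-trip through the corresponding fitters to
machine precision; seeds change noise realisations only.

## Problem sizes

The packaged verification runs use: 9-point NAM grids at 4 PAM levels for
the dose-ratio demos; 100 randomised schemes for the solver cross-check;
200 seeded studies (n = 8 replicates, 5-point design) for CI coverage;
three concentrations × three cells with records spanning ~6 observed time
constants for kinetic recovery; 200 seeded panels for classifier accuracy;
25-point series over four half-lives for racemization.  These sizes give
stable statistics while keeping a full run to minutes on one CPU.

## Known limitations

* The base chain is fixed-topology (linear; optional gating step); branched
  or desensitised schemes are out of scope, as are single-channel
  (stochastic) simulation and voltage dependence.
* `gating_factor` attaches to the final gating step; schemes with multiple
  open states would need per-state efficacy weights.
* The dose-ratio verdict thresholds are calibrated for the stark contrast
  of the two topologies; weakly interacting sites will legitimately return
  INDETERMINATE.
* Racemization fits assume a known-form single exponential; mixtures of
  enantiomers with very different potencies superimposed on instrument
  drift are not modelled.
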