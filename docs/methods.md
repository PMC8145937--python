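# Methods

## Structural model

One oral dose at t = 0 enters an absorption delay chain with mean
transit time MTT and a non-integer number of transit compartments NN.
Rather than approximating NN by an integer chain, the depot receives
the analytic transit input

    in(t) = F·D · ktr·(ktr·t)^NN · e^(−ktr·t) / Γ(NN+1),   ktr = (NN+1)/MTT,

whose integral over [0, ∞) is exactly the available dose F·D.  The
depot empties into a central compartment (first-order ka); central drug
leaves with total clearance CL out of volume V.  A fraction F_ent of
that outflow is diverted into a gall-bladder compartment; the remainder
(1 − F_ent)·CL/V is irreversible elimination.  The gall bladder
releases into the depot at rate k_Ehc·E(t)·A_gb with the two-midpoint
sigmoid

    E(t) = t^γ / (t^γ + T_gb1^γ)    while t <  T_gb1 + 3 h
         = t^γ / (t^γ + T_gb2^γ)    once  t ≥  T_gb1 + 3 h,

γ = 40.  The recirculated drug bypasses the transit chain: delay on
re-entry is already captured by ka.  The states are (depot, central,
gall bladder, cumulative eliminated); concentrations are
1000·A_central/V in µg/L.

**Clearance-splitting convention.**  "First-order transfer multiplied
by F_ent" is read as: CL is *total* clearance, split into a biliary
fraction F_ent and an eliminated fraction 1 − F_ent.  This is the
standard gall-bladder parameterisation and keeps the mass balance
closed: since every biliary molecule eventually returns and is
reabsorbed, AUC∞ = 1000·F·D / ((1 − F_ent)·CL), which the solver is
tested against.  The alternative reading (elimination at the full
CL/V with the biliary path added on top) is available as
`cl_mode="additional"` on `StructuralParams`; under it
AUC∞ = 1000·F·D/CL.

**Default parameters** (`StructuralParams()`): F_rel 1.62, MTT 3.24 h,
NN 1.72, ka 1.6 h⁻¹, CL 3.33 L/h, V 8.17 L, F_ent 0.215,
k_Ehc 0.212 h⁻¹, T_gb1 8.14 h, T_gb2 12.2 h, γ 40, reset offset 3 h.
γ and the reset offset are fixed quantities of the emptying model but
exposed for sensitivity analysis.  Note these disposition estimates
imply a terminal half-life of ≈ 1.7 h, much shorter than the 20–25 h
observed for sorafenib; the model is used as estimated, and no
terminal-phase quantity is treated as a target.

## Numerics

`t^40` overflows quickly, so E(t) is evaluated in log space as
`expit(γ·(log t − log T_gb))`; the transit input likewise via
`exp(log ktr + NN·log(ktr·t) − ktr·t − lnΓ(NN+1))`.  Integration is
piecewise: the solver restarts at the E(t) branch discontinuity
(T_gb1 + 3 h) and is capped at a 0.25 h maximum step inside
[T_gb1 − 1, T_gb2 + 2] so the near-step emptying cannot be stepped
over.  Single profiles use DOP853 at rtol 1e−8 / atol 1e−10; the
Monte-Carlo engine stacks all subject-period profiles of a scenario
into one linear ODE system (individual ka, CL, V; shared emptying
times, so shared steep windows) and solves it with RK45 at rtol 1e−7 /
atol 1e−9 in chunks of ≤ 6000 profiles.  The batched and per-profile
paths agree to ~1e−8 relative and both are tested against analytic
oracles (mass balance including undelivered transit mass via the
regularised incomplete gamma; AUC∞ closed form; the F_ent = 0
reduction to a plain transit/one-compartment model).

## Synthetic data

The generator emulates the single-dose healthy-volunteer study: 17
protocol sampling times from 0 to 168 h; either the four-arm replicated
two-period design (same treatment in both periods) or a balanced 2×2
crossover (test vs reference, sequences RT/TR split half and half).
Random effects are exponential: ka, CL, V carry IIV (87.3, 26.1,
21.5 %CV), CL carries IOV redrawn each period (9.0 %CV), and
observations get proportional residual error (37.6 %CV).  %CV values
are converted to log-scale SDs by the exact log-normal relation
ω = √log(1+(CV/100)²) for every component, including the residual term,
which is then applied as `pred·(1+ε)` and truncated at zero.  IIV/IOV
correlations are not identifiable from the published summary, so all
random effects are diagonal and IOV draws are independent across
periods.  The residual model is proportional-only by default (an
additive component is configurable but defaults to 0 µg/L).  LLOQ
censoring at 5 µg/L is available but off by default: the simulated
bioequivalence trials analyse uncensored values.

What the generator does *not* emulate: meal-time covariates, dropout,
assay imprecision structure beyond the proportional term, parameter
uncertainty (fixed effects are treated as known), and the multiple-peak
irregularity beyond what the two-emptying-time model produces.  Tests
passing on these synthetic data therefore validate the simulation
machinery and its statistics, not the model's fit to any real profile.

## NCA and crossover analysis

AUClast uses linear trapezoids for ascending segments and the log rule
(C₁−C₂)/ln(C₁/C₂)·Δt for strictly descending positive segments;
segments touching zero fall back to linear.  Cmax/Tmax come from the
observed values, first occurrence on ties.  λz is fitted by log-linear
regression over tails of ≥ 3 points strictly after Tmax, selecting the
best adjusted R² (ties within 1e−4 prefer the longer tail); it is
optional and skipped inside the trial engine, which only needs Cmax and
AUClast.  BLQ records are excluded except a leading pre-dose zero,
which anchors the AUC.

The 2×2 analysis is ordinary least squares of the log metric on
subject, period and treatment fixed effects.  For complete balanced
data this equals both the subject-random mixed model and the textbook
paired-difference analysis (the equality is tested to 1e−10); the
sequence term is exactly aliased with the subject effects, so a
separate sequence flag would be inert and is not exposed.  Subjects
missing a period are dropped; at least three evaluable subjects per
sequence are required.  GMR = exp(treatment effect), 90 % CI from the
t distribution on n − 2 df, bioequivalence when the CI lies within
[0.80, 1.25] (evaluated separately for Cmax and AUClast and jointly).
The intrasubject CV is 100·√(exp(ω²)−1) from the residual SD ω.

## Monte-Carlo engine

A scenario = (test dose, n subjects): `n_trials` independent 2×2 trials
against reference 200 mg are simulated and analysed, and the proportion
achieving bioequivalence is reported with the Wald normal-approximation
CI p̂ ± 1.959964·√(p̂(1−p̂)/n_trials), kept in its plain form (zero width
at p̂ ∈ {0, 1}) for fidelity to the simulation protocol it mirrors.
Per-trial random streams derive from `SeedSequence([seed, trial, k])`,
so any trial is reproducible in isolation and results are independent
of batching order; grid cells in `scan_grid` get seeds from
(master seed, dose, n), with an optional common-random-numbers mode
that shares subjects across doses at a given n.  The argmax summary
uses the joint (both-metrics) proportion as the headline, since the
dose-selection question requires Cmax *and* AUClast equivalence;
per-metric argmaxes are reported alongside.

The default is 500 trials per scenario; the shipped reproduction runs
(`scripts/acceptance.py`, `sorabeq reproduce`) use 200 trials per dose
at n = 36, which estimates proportions with a Wald half-width ≤ 0.07
and leaves the dose ranking stable across seeds.

## Known limitations

* The fitted disposition parameters give an unrealistically short
  terminal half-life (see above); λz/t½ outputs reflect the model, not
  observed sorafenib kinetics.
* Wald intervals degenerate at proportions of 0 or 1.
* The crossover fit assumes homoscedastic log-scale residuals shared by
  test and reference; no replicate-design or reference-scaled analysis
  is provided.
* Simulated trials share the protocol's fixed sampling grid; sparse or
  irregular designs are untested.
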