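# Methods

## Model

Each harm is an event tree reduced to a single path: an ordered chain of
contingent events, every one of which must occur for the harm to occur. With
conditional probabilities `N_i` (each conditional on all upstream events
having occurred), the per-transfusion harm probability is the product along
the chain. The model therefore assumes:

* **Conditional decomposition** — each `N_i` is already conditional on its
  predecessors, so multiplying them is exact, not an independence
  approximation *within* a chain.
* **Independent uncertainty** — the *uncertainty distributions* of different
  inputs are sampled independently; no correlation structure between inputs
  is modelled. A consequence used throughout for ground truth: the expected
  harm probability is the product of the input means.
* **Additive combination across harms** — the "any harm" probability is the
  sum of per-harm probabilities, capped at 1. The three harms are not
  mutually exclusive (they share chain prefixes), but at per-transfusion
  risks of 1e-5..1e-3 the difference from the exact union
  `1 − Π(1 − p_h)` is below 1e-5, far under the 2-significant-figure display
  precision. The sum also reproduces the published "any harm" table rows from
  the per-harm rows exactly at display precision, which is why it is the
  default; `combined_risk(..., method="union")` gives the exact form.
* **Scope exclusions** — ABO incompatibility and hyperhaemolysis are outside
  the modelled harms; within-episode unit counts are not modelled, so a
  policy mix (fraction of episodes served D-positive) scales risk linearly
  at the episode level.

The three shipped harms: HTR at the index transfusion (pre-existing anti-D
reacting with transfused D-positive cells), HTR at a future transfusion
(anti-D formed after the index transfusion), and HDFN death or lifelong
disability in a future pregnancy. Two populations share the chain: all
recipients, and D-negative females of childbearing potential, implemented as
per-event *population overrides* (the subgroup-defining events are fixed at
probability 1) rather than duplicated configs, so there is a single source of
truth for the chain.

## Inputs and configuration

Every chain input is a distribution on [0, 1] from one of five families —
point, uniform, triangular, beta, log-uniform — each with closed-form mean
and variance (log-uniform suits inputs uncertain over orders of magnitude).
Configs are YAML (schema_version 1) validated with structured errors that
name the offending id; serialisation round-trips exactly.

The shipped `default_config.yaml` carries the model *structure* (14 events,
3 harms, 2 populations) with placeholder uniform bands of plausible
magnitude, each marked as such in `source_note`; its event labels are
best-effort. The original study's input distributions live in supplementary
material not shipped here, so the published risk means/CIs, the 1.0%
break-even benefit and the 11% alloimmunization sensitivity index are not
reproducible from this repository alone. **Transcription path**: copy each
published input distribution into the `inputs:` block (same ids), adjust the
`survivor_life_years` distribution, and run `rhdrisk run`; a 1000-iteration
run of a 14-event config takes milliseconds.

## Monte Carlo

Per iteration one value is drawn per input; harms and their additive
combination are evaluated per iteration. Defaults: 1000 iterations
(overridable; several tests use 1e5 for tighter tolerances), 95% level.

* **Point summary** — mean of the probability samples, then converted to
  reciprocal "1 in N" form (not the mean of reciprocals; the reciprocal is a
  display transform of the expectation).
* **Credibility interval** — equal-tailed empirical quantiles with linear
  interpolation between order statistics. Quantile convention is a genuine
  free choice; linear interpolation is the common default and is
  cross-checked against a brute-force sort-based oracle in the tests.
  Reciprocal CIs are reported sorted ascending.
* **RNG** — one root seed; every input draws from its own substream derived
  by hashing `(seed, input_id)` (SHA-256, platform-stable). Adding, removing
  or re-parametrising one input never perturbs another input's draws, and
  population overrides use separate `(seed, population, event)` streams.
  Same seed + same config is bit-identical.
* **Degenerate inputs** — with all inputs point masses every sample equals
  the analytic chain product exactly (float-exact per sample; the sample
  *mean* can differ by ~1 ulp through pairwise summation).
* **Zero probability** — reported as a "no events expected" sentinel
  (reciprocal ∞), never a division error.
* Display rounding is 2 significant figures, matching risk-table convention;
  raw values are always retained alongside.

## Population and time scaling

Annual episodes = incidence per million per year × population/10⁶ × subgroup
fraction (83 × 67 = 5561 for England-scale defaults). Years to first event =
risk reciprocal ÷ annual episodes, applied to the mean and both CI endpoints
(monotone transform). The subgroup's ~100 episodes/year enters as a
configured `subgroup_fraction` (100/5561 ≈ 0.017982), not a hard-coded count.

Two internal inconsistencies of the published years table are documented
rather than reproduced: its all-recipients index-HTR cell prints 4.8 where
the rounded risk table regenerates 2.7e4/5561 = 4.855 → 4.9 (evidently
computed from unrounded simulation output), and its CI endpoint cells show
the same unrounded-source drift (regeneration agrees within 10%). The
regeneration tests check mean cells at 2 significant figures excluding the
flagged cell, and CI cells at the looser tolerance.

## Life-years trade-off

A fatal or permanently disabling HDFN event is costed at 83 undiscounted
life-years (life expectancy at birth); no QALY weighting or discounting.
Per transfused subgroup patient, benefit `s` (absolute percentage points of
survival) gains `(s/100) × L_surv` expected life-years, where `L_surv` is a
configured distribution of life-years per averted trauma death; HDFN loses
`p × 83`. The bootstrap (default 10,000 replicates) resamples `p` from the
Monte Carlo output sample and `L_surv` from its distribution, using one
replicate set scanned across the whole benefit grid — making the exceedance
probability non-decreasing in `s` by construction — and reports the smallest
grid value reaching 95% exceedance, or "not reached". With degenerate inputs
this reproduces the closed form `100·p·83/L_surv` to within one grid step
(default grid 0–2% in 0.005% steps). The shipped `L_surv` placeholder
(triangular 20–40–60 years) is *not* the original study's survival model,
which is not described in its main text.

## Sensitivity analysis

First-order Sobol index `S_i = Var(E[Y|N_i]) / Var(Y)`: the expected
fractional reduction in output variance if `N_i` were known exactly.
Estimator: pick-freeze (Saltelli 2010 radial form) with two independent
input matrices A, B and per-input hybrids,
`S_i ≈ mean(Y_B (Y_ABi − Y_A)) / Var(Y)`; default 2¹⁴ rows per matrix.
Raw estimates are retained; display values are clipped to [0, 1] since
estimator noise can stray slightly outside. An output variance ≤ 1e-24 is
treated as zero (constant outputs can register variance ~eps² numerically)
and yields index 0 with a warning. The tests cross-check against the
closed-form decomposition of a linear toy model (S = 0.2/0.8) and against an
independent brute-force double-loop conditional-variance oracle on two-input
models. Scatterplot export reuses the simulation substreams, so exported
pairs are exactly the draws of a `run_simulation` call with the same seed;
`conditional_fix` turns one input into a point mass for conditional-risk
("if alloimmunization risk were exactly v") runs. Total-order indices and
correlated inputs are out of scope.

## Synthetic scenarios

`generate_scenario` builds random chains whose analytic risk equals a target
scale *exactly*: per-event means are `target^{w_i}` with Dirichlet exponents
summing to 1, then wrapped in a random admissible family parametrised to
that exact mean. Targets default to the 1e-3..1e-4 regime so tests exercise
realistic small-probability arithmetic. `paper_shaped_scenario` emits the
full 14-event/3-harm/2-population shape with per-harm reciprocals near the
1e4/1e5/1e4 orders of magnitude of the published all-recipient rows. What
the generator deliberately does **not** emulate: the actual published
parameter values, correlation between inputs, or any non-[0,1] chain input —
so passing recovery tests demonstrates correct uncertainty propagation, not
agreement with the published risk estimates.

## Problem sizes and numerical choices

Convergence and recovery tests use 1e5 iterations (Monte Carlo standard
errors computed from the closed-form product variance
`Π(σ_i²+μ_i²) − Πμ_i²`), 4-SE acceptance bands, and 20-scenario sweeps;
Sobol checks use 5 replicates of 2¹³-row matrices with 3-replication-SD
bands. These sizes give stable, seconds-scale runs on one CPU. Probabilities
are multiplied directly in double precision — at 14 factors of ≥1e-3 scale,
well away from underflow.

## Known limitations

* Placeholder inputs: shipped results illustrate the machinery, not the
  published estimates.
* No inter-input correlation, no within-episode unit structure, no
  demographic projection of trauma incidence.
* The additive "any harm" convention mildly overstates risk relative to the
  exact union (immaterial at these scales, switchable).
* The life-years analysis ignores morbidity short of the modelled endpoints
  and uses undiscounted life-years.
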