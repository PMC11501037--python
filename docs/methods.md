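# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a methods appendix: what is computed, under which
assumptions, and where a convention had to be chosen.

## Task structure and data model

A *trial* is one passage through the T-maze: a choice of the left or right
arm, which deliver solutions of fixed value.  A *session* is a maximal block
with a constant side-to-solution mapping; the designated (higher- or
varying-value) side alternates across sessions, emulating the twice-weekly
bottle swap.  Rewards are deterministic: every trial delivers the full value
of the chosen side's solution (water/saccharin 1, sucrose 3,
nicotine+saccharin 0.3, dimensionless).  Trial indices are 1-based per
animal; sides are a closed {L, R} enum; solution identity lives on the
session (`value_low`, `value_high`), not on the trial, because the decision
model consumes only values.

Animals enter the analysis only if they made strictly more than 5 trials
per day over their observation window (`filter_by_trial_rate`, strict
inequality).  `days_observed` is taken from log metadata rather than
inferred from timestamps, which are optional.

## Choice descriptors

Five statistics per animal, all fractions in [0, 1] internally (percent
only at presentation):

* **Switch** = 1 − |p_L − p_R| over all trials pooled.  This is the
  declared renormalisation: it is 0 for a single-side animal, 1 for an
  exactly even split, and monotone in side imbalance.
* **SwWat / SwSuc** (`sw_low` / `sw_high`): over consecutive within-session
  trial pairs (t, t+1) whose trial-t outcome was the low/high value, the
  fraction with a side change at t+1.  Pairs spanning a bottle swap are
  excluded by default because the outcome class of the boundary trial is
  ambiguous there; a config flag can include them.
* **Pref**: unweighted mean over sessions of the fraction of choices on the
  designated side, so long sessions do not dominate.
* **SideBias**: |2m − 1| with m the session-mean left-choice fraction.
  Because the designated side alternates across sessions, averaging per
  session first cancels reward tracking and isolates a fixed side
  preference.

Undefined statistics (no trials, no qualifying pair) are NaN and animals
carrying any are rejected by name when the descriptor matrix is assembled.
The matrix is min-max scaled per column onto [0, 1] before archetypal
analysis (constant columns collapse to 0 with a warning); the scaling
record is kept so archetype coordinates can be reported in raw units.

## Archetypal analysis

Given the scaled n×5 matrix X, the model minimises ‖X − A Z‖²_F with
simplex-constrained rows of A (composition weights) and Z = D X with
convex rows of D (archetypes confined to the data hull).  The fit
alternates (i) per-animal simplex least squares given Z and (ii) an
unconstrained least-squares target for Z re-projected onto the hull via D.
Each simplex subproblem is non-negative least squares on a system augmented
with a sum-to-one penalty row (constant 200), followed by exact
renormalisation of the weights.  Restarts (default 10) initialise Z at k
distinct random data rows; the best residual wins; within a restart an
iterate that would raise the residual (possible only through the hull
projection) terminates the run at the previous best, so the accepted
residual history is non-increasing by construction.  Fits are bit-for-bit
reproducible from (X, k, restarts, seed).

With k = 3 the archetypes are named from their raw-unit coordinates:
Tracker = maximal Pref; among the remaining two, Non-Switcher = maximal
SideBias; Explorer = the rest.  Ties warn and break deterministically
(side bias, then switch, then index).  Compositions are visualised in a
ternary plot with vertices (0,0), (1,0), (0.5, √3/2).

Test fixture note: the planted-vertex recovery test draws convex weights
from a sparse symmetric Dirichlet (concentration 0.2).  Archetypes can
never leave the data hull, so vertex recovery to 1e−3 requires data near
the corners; a flat Dirichlet at n = 300 leaves the hull several
hundredths away from each vertex, while concentration 0.2 puts multiple
points within ~1e−4 of each corner.

## Decision model

Per animal, expected values V_L, V_R start at v0 and only the chosen
side's value is updated by the delta rule V ← V + α(R − V).  Choice
probability is a softmax over the value difference plus perseveration:
P_R(t) = σ(β(V_R − V_L) + χ(C_R(t−1) − C_L(t−1))), with the choice
indicators C coded 0/1 so their difference is ±1, and the perseveration
term 0 on the first trial.  Values persist across bottle swaps: a swap
changes which side pays which value, not the animal's estimates.

* **Fitting** uses v0 = 0 (animals start the valued context naive to both
  arms in likelihood terms); **simulation** uses v0 = 1 (animals arrive
  from a water-only context where each arm was worth 1).  Both are explicit
  config fields; the asymmetry is intentional and surfaced here.
* Bounds: α ∈ (0, 1], β ∈ (0, 20], χ ∈ [−2, 2]; the open ends are realised
  with a numerical floor of 1e−6 for the optimiser.
* The negative log-likelihood floors per-trial probabilities at 1e−12
  before the log so pathological parameter corners cannot produce −∞
  during search.  This floor is part of the defined likelihood; the
  independent test oracle applies it too.
* Maximum likelihood uses multi-start bounded L-BFGS-B: four fixed starts
  spanning the box — (0.5, 1, 0), (0.9, 5, 0), (0.05, 5, 0), (0.3, 0.5, 0)
  — then seeded uniform draws up to `n_starts` (default 20); ties within
  1e−9 go to the earlier start.  Records with fewer than 10 trials are
  refused.  BIC = 2·nll + p·ln(n) with p = 3 (full) or 2 (χ = 0 variant);
  the likelihood-ratio statistic 2(nll_reduced − nll_full) is tested
  against χ²(1), clipping numerically negative values to 0 with a warning.
* The sequential inner loop is numba-jitted when numba is importable and
  falls back to the identical pure-Python function otherwise.

## Generative simulation

The simulator replays the policy forward: draw the side from P_R, deliver
the chosen side's current value, update that value.  Schedules default to
6 alternating sessions of 50 choices (the bottle-swap cadence mapped to 3
days per session), starting on the left; the starting side is configurable.

Three counterfactual experiments are built on top:

* **Value-difference sweep**: reference side fixed at 1, varying side
  1 + ΔV over the default grid {−1, 0, 1, 2, 3}; `pref` is measured toward
  the varying side.  Replicate r of group g uses the child seed (g, r) for
  every ΔV — common random numbers, so condition contrasts are not
  inflated by simulation noise, and the ΔV = 2 column is identical to a
  plain water/sucrose simulation under the same seeds.
* **Attribution study**: a fitted cohort is re-simulated with parameters
  reassigned — singly (`shuffle_alpha/beta/chi`) or as whole triplets
  (`random_triplet`), always by permutation so marginals are preserved;
  summaries group by each animal's original archetype label.  Separation is
  quantified as the mean absolute between-group gap of descriptor means.
* **Cross-context prediction**: one continuous 12-session run, values
  (1, 3) then (1, 0.3), designated side alternating throughout; learned
  values carry across the boundary by default (`carry_values=False` resets
  them for sensitivity analysis), and descriptors are computed per
  6-session block.

All stochastic stages derive per-unit generators from the master seed via
`SeedSequence` spawn keys, so any sub-simulation can be reproduced in
isolation and every output is byte-identical under a repeated run.

## Synthetic cohorts

The generator emulates the study conditions, not any particular cohort.
Latent triplets are uniform in per-profile boxes:

| profile      | α            | β          | χ        | trials/day |
|--------------|--------------|------------|----------|------------|
| Tracker      | [0.5, 0.95]  | [0.5, 2.5] | [−1, 1]  | [15, 25]   |
| Explorer     | [0.1, 0.35]  | [0.2, 0.7] | [−1, 1]  | [10, 18]   |
| Non-Switcher | [0.01, 0.05] | [3, 10]    | [−1, 1]  | [5, 10]    |

The boxes encode the profile signatures (Tracker: fast learning, soft
choice; Non-Switcher: slow learning, near-deterministic choice, which
glues it to a side; Explorer: intermediate) and were calibrated against
two binding requirements the generator must satisfy by design: descriptor
+ archetype analysis must relabel ≥ 80 % of planted profiles, and fitting
must recover each latent parameter with Spearman ρ ≥ 0.7 on the 6×50
schedule.  Two consequences of that calibration are worth recording: a
Non-Switcher with α below ~0.01 never builds the value gap that locks it
to a side (it behaves like an Explorer), and χ needs the full [−1, 1]
spread to be recoverable, because in near-deterministic animals χ trades
off against β at 300 trials.

Session length per animal is round(3 × trials/day) — three days between
swaps — over 6 sessions, unless an explicit schedule is given.

Home-cage streams come from a continuous-time Markov chain over the five
compartments (nest N, food F, central hub C, stair S, T-maze T) with the
cage's physical topology (N, F touch only C; S connects C and T):
exponential dwells with per-profile scales, transition rates ×3 in the
dark phase (time 0 = lights-on, 12 h light / 12 h dark), and nest entries
in the light phase drawing a multi-hour resting dwell with a per-profile
probability, which produces the bimodal nest-dwell distribution and
circadian activity modulation of real streams.  Hub-routing rows encode
the observed sign structure (Tracker toward the stair, Explorer toward
nest/food, Non-Switcher resting in the nest).

What the generator does **not** emulate: reward stochasticity, intertrial
timing, satiety or consumption dynamics, social gating of maze access, and
antenna noise.  Passing tests therefore validate the analysis machinery
and its qualitative orderings, not quantitative claims about real animals.

## Home-cage metrics

Residency episodes are maximal same-location runs; the final open episode
is closed at the last event and flagged.  Occupancy fractions are
dwell-time shares over the five compartments; EnA is their Shannon entropy
in nats (0 to ln 5).  NbD counts compartment transitions per day over the
observed span (a warning is raised below one day).  First-order transition
probabilities condition on the source compartment; second-order
("hub-mediated") probabilities condition on leaving a non-hub compartment
and record the next non-hub compartment reached, skipping any number of
consecutive hub visits.  All outgoing rows and occupancy rows sum to 1 to
1e−9; metrics are invariant to splitting episodes into denser
same-location detections.  Consumption is estimated per day as the bottle
change on the chosen side minus the non-chosen side (evaporation control),
averaged over days with both measurements.

Correlations with archetypal composition use Pearson r with two-sided p;
regressions are ordinary least squares reporting slope, adjusted R² and
the slope p.  Group comparisons (`report_group_stats`) are thin wrappers
over scipy rank tests with Holm adjustment — reporting helpers, not
re-derivations.

## Numerical conventions and problem sizes

Alternating-fit tolerance 1e−8 (relative RSS change), optimiser ftol 1e−8,
simplex feasibility enforced to < 1e−9 by exact renormalisation, ternary
round-trips exact to 1e−12.  The validation suite and the acceptance
script run at deliberately modest sizes — 60-animal cohorts (20 per
profile), 200 sweep replicates, 10-day RFID streams, 300-point archetype
problems — chosen so the full chain re-runs in minutes while keeping every
statistical criterion comfortably away from its threshold.

## Known limitations

* The Switch/Pref/SideBias aggregation conventions are declared, not
  reconstructed from a reference implementation; alternatives (pooled
  rather than session-averaged Pref, for example) would shift descriptor
  values without changing the machinery.
* χ identifiability is weak for near-deterministic animals at a few
  hundred trials; fitted χ for such animals should be interpreted through
  the model-comparison columns, not at face value.
* The archetypal decomposition is k = 3 by design; no model-selection
  scree is provided.
* Second-order transition metrics assume the hub topology; event streams
  violating it (direct N→F detections) are still accepted and counted as
  first-order moves.
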