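# Methods

## Model

A QSSPN model has two interaction sets. The *dynamic* set is an extended
Petri net: places with integer token counts (discrete activity levels, with
optional capacities), transitions with typed pre-edges (standard, read,
inhibitor) and standard post-edges. The propensity of transition `t` is
`P_t = c_t · Π_i μ_i(x_i)`: a rate constant times the product of pre-place
activities, each read from a lookup table of strictly increasing integer
thresholds. The *quasi-steady-state* set is a stoichiometric metabolic model
analysed by FBA (`max cᵀv` s.t. `S·v = 0` over internal metabolites,
`l ≤ v ≤ u`). Constraint places map token counts to flux-bound overrides;
objective places map an FBA optimum to a token count. Time is in arbitrary
units (a.u.), rates in 1/a.u.: the simulation orders events, it does not
measure physical time.

Key assumptions:

- metabolic fluxes equilibrate infinitely fast relative to regulatory
  events, so metabolism is always at a flux steady state given current
  bounds (quasi-steady state);
- the regulatory semantics is qualitative: a few token levels, threshold
  rules, and rates that encode relative speed classes rather than measured
  kinetics.

## Activity tables and edge semantics

Tables are left-closed: activity `a_i` applies for token counts in
`[t_i, t_{i+1})`, and the first threshold must be 0 so every count maps to
an activity. This convention is what makes the standard "stop transcription
when the transcript is at its 2-token maximum" rule expressible as the
table `[(0, 1), (2, 0)]`. Inhibition is not a separate mechanism: an
inhibitor edge is shorthand for a table that is positive below a cut-off and
0 at and above it, which keeps the propensity a pure product. Default tables
when none is given: standard/read edges step from 0 to 1 at the edge weight
(resp. 1), inhibitor edges cut off at 1.

## The trajectory loop

Each iteration:

1. **Immediate settlement.** All immediate transitions with positive
   propensity fire one at a time, the next one chosen uniformly at random
   among those currently enabled (asynchronous semantics; ties are a genuine
   source of trajectory variability, so they draw from the trajectory RNG).
   A configurable iteration cap (default 100 000) turns a non-quiescing
   immediate set into a `LivelockError` naming the cycling transitions.
2. **Coupling refresh.** If any constraint place changed since the last
   refresh, its lookup rows are re-read; if the merged override map changed,
   every objective coupling is re-evaluated by FBA and objective places are
   set from their rows. Objective updates can enable immediates and vice
   versa, so steps 1–2 alternate until a joint fixed point (same cap).
3. **Stochastic sampling.** Gillespie: waiting time `~ Exp(Σ P_t)` over
   stochastic transitions, winner chosen proportionally to `P_t`.
   Transitions with positive propensity but insufficient standard-edge
   substrate are masked out of the sum. If the total is 0 the next
   stochastic event is at `+∞`.
4. **Advance.** Time moves to the earliest of: the sampled event, the next
   pending delayed firing, `t + max_timestep` (only when continuous
   transitions exist), `t_max`. Continuous transitions act over the elapsed
   `dt`; then the due event (delayed first on ties) fires if still enabled.

Waiting times are **re-drawn after every state change** rather than carried
across iterations. For exponential waiting times this is distributionally
exact when propensities are unchanged (memorylessness) and is the safe
choice when a coupling update moves a propensity mid-wait.

Delayed stochastic transitions consume and produce **at firing time**,
`delay` a.u. after selection; nothing is reserved at selection. If the
transition is disabled when the delay expires the firing is skipped and
logged. The alternative (consume at selection) would reserve substrate and
cannot be expressed without partial markings; with qualitative token levels
the skip-if-disabled rule is the conservative reading.

Continuous transitions move `⌊acc⌋` tokens where `acc` accumulates
`propensity × dt` across steps; the fractional remainder is carried so that
long-run moved tokens track `∫ P_t dt` even for propensities ≪ 1/timestep.
Plain per-step rounding would silently drop slow flows. Moves are clamped by
available substrate (per standard-edge weight) and by post-place capacity.

Post-place capacity overflow on any firing clamps at the capacity and logs:
in well-formed qualitative models separate inhibitory rules, not capacity,
gate firing, so clamping is a safety net rather than semantics.

## FBA engine

The LP is solved fresh on every call with scipy's HiGHS backend —
deterministic and history-free; warm starts are deliberately not used.
Statuses are `optimal`, `infeasible`, `unbounded` (plus a distinct
`FbaError` for solver failure). During coupling refresh an infeasible LP is
read as objective value 0 — in a producibility model infeasibility means
"cannot produce" — and an unbounded one as `+∞` against the lookup
thresholds. Producibility of a metabolite is the optimum of a temporary
unit-stoichiometry drain reaction; the qualitative cut-off is 10⁻³
(configurable per objective coupling), equivalent to testing "greater than
zero" at LP tolerances. FBA results are cached per distinct bound-override
map, so the number of LP calls per trajectory is bounded by the number of
distinct constraint configurations visited, not the number of events.

## Randomness and reproducibility

One named generator (`numpy.random.Generator` / PCG64) per trajectory. An
ensemble spawns per-trajectory `SeedSequence` streams from the master seed,
so results are identical regardless of execution order and two runs with the
same seed, model and configuration are bitwise identical. The model carries
a semantic content hash (places, transitions, tables, reactions, couplings —
numbers normalised to float) recorded in every trajectory's metadata and
reproducibility manifest.

## Behaviour statistics

Behaviour predicates operate on the stepwise timecourse of one place:
*activation* (reach an upper threshold within a window, optionally hold to
the end), *inhibition* (fall to a lower threshold, optionally hold),
*constant* (never leave the level taken after an equilibration offset),
*burst* (reach the upper threshold, then return to the lower before the
end), plus arbitrary user predicates. Defaults (upper 2, hold to end) match
the worked two-token protocol. Fractions carry exact Clopper–Pearson 95%
CIs computed from beta quantiles — exactness matters because screen
fractions concentrate at 0 and 1, where approximate intervals degenerate.
Significance of a perturbation is CI non-overlap against the reference, the
same rule a screen heatmap uses to decide whether a cell is coloured like
wild type; it is conservative relative to a two-proportion test, which is
intended. Clustering of the knockout matrix is left to downstream tooling;
the TSV export carries fractions, CI bounds and significance flags.

## Fixtures: what they emulate and what they do not

`build_gene_expression_fixture` reconstructs a single-gene negative-feedback
loop: stochastic transcription-factor/binding-site dynamics (complex
formation 100/a.u. — rate limiting; dissociation of the stable complex
10/a.u.; degradations 1/a.u.), immediate transcription and translation with
two-token maxima enforced by inhibitory rules, "no net decay while synthesis
is possible" rules, precursor (dNTPs/AAs) objective places, the protein as a
constraint place gating an enzyme reaction, and an agonist objective place
that evicts the transcription factor. Two reconstruction choices were
genuinely open and are fixed as follows:

- **translation requires the transcript at its full two-token level** (the
  protein is made from the functional transcript); this makes "transcript
  reaches maximum before protein" a structural property rather than a
  race between immediates;
- **the active complex disassembles only under agonist displacement**, not
  on transient dissociation of the site — the complex is the stable species;
  transient site exchange therefore does not interrupt transcription.

The toy metabolic network (12 reactions) reproduces the producibility
semantics that the coupling needs — precursor drains always producible, the
agonist drain producible iff the enzyme bound is open — at hand-solvable
scale. It does not emulate genome-scale properties: no alternative routes,
no shared-cofactor competition of realistic density, no compartmentation.
Passing tests therefore demonstrate the correctness of the coupling logic
and statistics, not performance or biological coverage at genome scale; a
user-supplied genome-scale reconstruction in the tabular or SBML format
exercises the same code paths.

The birth–death net (birth 5/a.u., death 1/a.u. per token via a linear
activity table, capacity 50) calibrates the stochastic core against the
closed-form stationary mean λ/μ. The random-model generator produces valid
nets (tables always start at threshold 0) for property tests; it makes no
attempt at biological plausibility.

## Problem sizes

Default test and reproduction scales: 120-trajectory ensembles (the
standard screen protocol), 200 trajectories for event-order statistics,
100 trajectories × 100 post-burn-in grid points for the birth-death mean,
200 random ≤6-reaction networks for LP/vertex-oracle agreement, 1 000
binomial draws per p for CI coverage. These sizes put Monte Carlo error
well below the qualitative contrasts being tested (fractions near 0 vs
near 1).

## Known limitations

- No tau-leaping or stiff-hybrid error control; continuous transitions use
  a fixed maximal timestep.
- Propensities are recomputed in full after each event (no dependency
  graph); adequate at fixture scale, the first place to optimise for large
  nets.
- The significance rule (CI overlap) does not correct for multiple testing
  across a screen.
- SBML import maps stoichiometry and bounds only; QSSPN-specific
  annotations are not round-tripped.
- Gene–protein–reaction Boolean logic, flux-variability analysis and
  loopless FBA are out of scope.
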