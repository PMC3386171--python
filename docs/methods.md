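# Methods

## Model

`mitoqc` simulates the mitochondrial population of a single cell as a
probability distribution `p(l, t)` over a finite ladder of discrete
functional-quality states `l = 0 … N−1`. State `0` holds fully
dysfunctional mitochondria; they are non-fusogenic (excluded from
fusion–fission) and preferentially removed by mitophagy. The distribution
evolves under a master equation whose right-hand side is the sum of four
process fluxes:

* **Fusion–fission cycles.** Fusion and the subsequent fission are treated
  as one paired event, justified on the long time scales simulated: two
  mitochondria in states `(l, m)` mix content and split into `(l′, m′)`
  with the total quality conserved, `l + m = l′ + m′`. All admissible
  transitions with `l ≤ m`, `l′ ≤ m′` (inputs and outputs ordered to avoid
  double counting, identity transitions dropped) are enumerated once into
  an event list. Each event contributes bilinearly at rate
  `a(t)·s(l)·s(m)·p(l)·p(m)`, charged as a loss at each input slot and a
  gain at each output slot (twice when slots coincide). This bookkeeping
  makes the norm flux and the quality flux of the conserving list vanish
  identically, and it is the convention against which the agent-based
  oracle is matched.
* **Quality decay.** A slow one-step-down drift,
  `rate·s(l)·p(l)` from `l` to `l−1`, modelling cumulative oxidative and
  hydrolytic damage to mitochondrial constituents.
* **Mitophagy and biogenesis under homeostasis.** Mitophagy removes mass
  at `γ(t)·s_mito(l)·p(l)`; biogenesis re-creates it with weights
  `s_ren(l)·p(l)`. The biogenesis (renewal) rate is not a free parameter:
  a homeostatic rheostat recomputes it at every evaluation so total gain
  equals total loss and the number of mitochondria never changes. The time
  at which this adapted rate becomes constant is a practical indicator of
  flow equilibrium.
* **Random molecular damage** (ROS-like hits) is applied inside the time
  step rather than through the flux: a Poisson number of events per step
  (mean `rate·dt`), each picking a source state `l` uniformly from
  `1 … N−1`, a sink uniformly below it, and moving a uniform random
  fraction in `(0, r_max]` of the source mass down. Norm conservation is
  exact by construction.
* **Infectious molecular damage** violates quality conservation during
  content mixing: each listed fusion–fission event is independently
  replaced, with probability `λ_id/λ_ff` (the damaging fraction of
  fusion–fission traffic), by a copy whose outputs are reduced by uniform
  integers in `[0, min(eps_max, output)]`. The perturbed list is redrawn
  every step. `λ_id` is capped by the concurrent fusion–fission rate —
  fusion–fission events are the vehicle of this damage — and in the
  coupled mode it is slaved to the concurrent random-damage rate:
  `λ_id = min(λ_ff, id_max·min(λ_rd/λ_rd_limit, 1))`.

All rates follow a product ansatz `schedule(t) × selectivity(l)` (twice
for the pairwise process). Schedules are Hill courses
`v(t) = v_init + (v_final−v_init)·t^h/(t^h+τ^h)` (`h = 0` means constant
at `v_init`; `v(τ)` is exactly the midpoint) or rectangular pulses on a
half-open interval. Selectivities are Hill functions of the state index
with values in `[0, 1]`; `s_low` is the value at state 0, `s_high` the
asymptotic plateau toward the top (not attained exactly at `l = N−1`).
Fusion–fission and renewal selectivities carry `zero_at_floor`, the
non-fusogenic floor state.

## Integration and readouts

Explicit forward Euler with a fixed step, `p ← p + dt·rhs`, followed by
the random-damage reshuffle where active. The step must be much smaller
than the inverse of the largest rate (enforced at configuration time);
with the defaults (`dt = 0.1` min against a fastest rate of 0.05/min) the
norm is conserved to ~1e−14 per step and the integrator aborts if the
accumulated norm error ever exceeds 1e−7. Negative excursions up to 1e−12
are clamped and renormalised; anything larger raises an instability error
instead of being silently repaired.

Readouts per output time: the non-active fraction `p(0)`, the active
fraction `Σ_{l≥1} p(l)`, mean and standard deviation of the quality index
over all states and over active states only (renormalised; NaN when no
active mass exists, never a silent 0 — the all-states average is easily
distorted by the double-peaked equilibrium shape), the adapted renewal
rate, the norm error, and the deviation factor — the per-minute L1
distance between successive distributions. The deviation factor vanishes
at a flow equilibrium; under random processes it fluctuates around a
constant level. Equilibrium is therefore declared when it drops below a
tolerance in deterministic modes
(the reference scenario uses 5e−9, which empirically corresponds to
state-wise convergence well below 1e−6) or when its 500-step window
average changes by less than 5% between consecutive windows (stochastic
modes).

For the conserving flux the integrator uses a grouped O(N²) kernel
(events grouped by total quality; pair-rate totals from a self-convolution
of `s·p`, gains from a precomputed slot-count matrix) that is
algebraically identical to the event-list sum — the equality is part of
the test contract. Perturbed steps damage events either sparsely (subset
sampling plus a flux correction) or densely (full-vector redraw),
whichever is cheaper; both reproduce the explicit perturbed-list flux
exactly for the same draws.

## Default parameters

All defaults live in `src/mitoqc/data/reference.yaml`; nothing is
hard-coded. Time unit: minutes.

| Parameter | Default | Rationale |
| --- | --- | --- |
| `n_states` | 50 | results are insensitive to the ladder size; 50 balances resolution against event-list growth (20 200 events) |
| fusion–fission rate | 0.05 min⁻¹ | one fusion–fission cycle per ~20 min, the experimentally reported scale |
| decay, mitophagy rates | 1e−4 min⁻¹ | protein turnover with half-lives of days — orders of magnitude slower than fusion–fission |
| selectivities | decay/mitophagy decreasing 1→0.2; fusion–fission/renewal increasing 0→1, zero at floor; Hill midpoint mid-ladder, exponent 2 | qualitative shapes: dysfunctional mitochondria cannot fuse and are removed preferentially; renewal repopulates the fusogenic pool |
| `dt` | 0.1 min | three orders below the inverse fastest rate |
| random damage | plateau 0.05 min⁻¹ (Hill ramp, τ = 2000 min, h = 2), `r_max = 0.5` | ramps in on the multi-thousand-minute aging scale; strong enough to overwhelm the turnover-limited repair flux and produce the population inversion |
| infectious damage | plateau 0.005 min⁻¹ (same ramp), `eps_max = 1` | calibrated so the quality-destruction flux matches the random-damage default — the two damage modes then yield closely similar quasi-equilibria; one quality step per output matches the observed partial loss of membrane potential per fission |
| coupled mode | `rd_limit = 0.025`, `id_max = 0.005` | infectious rate saturates once random damage reaches half its plateau |
| deceleration | Hill decay of the fusion–fission rate to 4% of its initial value (τ = 2000 min, h = 4) | the decelerated rate must fall below the infectious plateau for the fusion–fission cap to bind, which is the mechanism of the deceleration benefit; the aged-cell measurements only bound the reduction from below |
| MIDA survival threshold | `fraction_active` at 60% of its reference-equilibrium value | the all-states average quality is dominated by the dysfunctional state-0 peak of the double-peaked distribution and can invert the comparison; the active fraction is the readout in which the deceleration benefit lives. Both readouts are selectable. |

A note on the infectious-damage magnitude: with output reductions drawn
over the full admissible range, a single damaged event destroys on the
order of half the pair's total quality, so the rate matched to the random
damage default would sit four orders of magnitude below any fusion–fission
rate and the cap `λ_id ≤ λ_ff` could never become active. Capping the
per-output reduction at one quality step keeps single events mild, places
the matched rate within reach of the decelerated fusion–fission rate, and
preserves every structural property (norm conservation, nonpositive
quality flux). The full range remains available via `eps_max: null`.

## Agent-based oracle

An independent finite-population implementation of the same processes:
`M` mitochondria with integer qualities, stored as per-state counts
(agents are exchangeable). Per step: fusion–fission reactions are drawn
per listed event as Poisson counts at propensity
`a·s(l)·s(m)·n_l·n_m/M` — the discrete counterpart of the mean-field
event rate — executed in random order with finite-supply capping, and
damaged per reaction with probability `λ_id/λ_ff` in infectious mode;
decay and mitophagy are per-agent binomials; every removed agent is
immediately replaced by a draw from the renewal weights, so the
population size is exactly constant; random damage moves a binomial
number of agents per event. In conserving mode total quality is conserved
exactly in integer arithmetic.

The equivalence check compares quasi-stationary distributions per state
at three binomial standard errors of a 10⁴-agent population. It runs on
small ladders (N ∈ {3, 5, 8}) with accelerated rates (fusion–fission
0.5 min⁻¹, decay/mitophagy 0.01 min⁻¹, horizon 4500 min) so relaxation is
fast, and it tail-averages both trajectories beyond 500 min: random and
infectious damage make both engines stochastic, and a snapshot of one
trajectory is not an estimator of the process mean. Random damage is made
gentle there (`r_max = 0.02` at a higher event rate of 1 min⁻¹) because
each damage event moves a finite fraction of a whole state's mass at
once; with large `r_max` the tail average of a single trajectory carries
process variance above the binomial sampling floor and the comparison
would test trajectory noise, not correctness.

## What the scenarios show — and what they do not

The scenario drivers generate all inputs themselves; no external data
enter. The reference scenario establishes a healthy flow equilibrium
(>90% active, high mean quality, double-peaked distribution) independent
of the random initial distribution. The damage scenarios start from that
equilibrium and show the inversion signature: the active fraction falls
strongly while the average quality of the *still-active* pool falls only
modestly, with random and infectious damage nearly indistinguishable from
the readouts alone. The aging scenarios show that deceleration of
fusion–fission is neutral without damage, harmful under purely random
damage (it weakens quality maintenance), and protective under infectious
or coupled damage (it throttles the damage carrier). The MIDA comparison
converts the coupled-damage traces into life spans via the survival
threshold; censoring (no crossing within the horizon) is flagged, never
interpolated.

These are statements about the model's state space, not about
mitochondrial biology directly: the model is morphology-free (network
fragmentation is an inference from the non-fusogenic fraction), has no
spatial structure, no explicit mtDNA or protein species, and all damage
parameters are scenario choices rather than measured rates. Passing tests
demonstrate internal consistency (conservation laws, mean-field/agent
agreement, reproducibility) and the qualitative orderings above under the
documented defaults.

## Numerical and design notes

* Problem sizes: the reference scenario integrates N = 50 at `dt = 0.1`
  min until the deviation factor falls below 5e−9 (~1.4e5 simulated
  minutes); damage and aging scenarios run 18 000–20 000 min horizons,
  past the damage-ramp plateau and into quasi-equilibrium. The oracle
  check uses 10⁴ agents.
* The deviation factor is the per-minute L1 distance — nonnegative, zero
  exactly at equilibrium, and cheap; any norm-like choice would serve.
* Ties in damaged fusion–fission outputs are re-sorted so `l′ ≤ m′`;
  reductions are drawn independently per output.
* Pulse schedules are half-open `[start, end)` so that abutting pulses
  partition time without overlap.
* Degenerate rheostat (mitophagy removing mass while no state can receive
  renewal) raises an error rather than silently breaking homeostasis; it
  can only occur when all remaining mass sits at the non-fusogenic floor.
* Biogenesis gain is weighted by `s_ren(l)·p(l)` (renewal re-populates
  the existing fusogenic pool). A p-independent gain profile is a
  plausible alternative reading; it would insert mass at high states even
  when they are empty. The weighted form is what the rheostat balance and
  the oracle's replacement sampling implement.
* Known limitations: forward Euler is first order (the flow equilibrium
  itself is a fixed point of the flux and therefore dt-independent);
  the stochastic quasi-equilibrium detector is a heuristic window rule;
  agent-model propensities use `n_l·n_m` rather than `n_l(n_l−1)` for
  same-state pairs, a deliberate O(1/n_l) mean-field consistency choice
  that is invisible at the tested population sizes.
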