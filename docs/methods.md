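# Methods

## Model

`N = L²` agents occupy an `L × L` square lattice. Boundaries are periodic
(a torus): this is the only boundary condition under which *every* agent
has exactly four von Neumann neighbours, which the decision rules assume.
Each agent `i` carries three variables:

* a population label `A_i ∈ {C, R}` (consensus seeker / reputation
  seeker) — fixed for the run;
* a private attitude `O_i ∈ {a, b}` — fixed for the run;
* a behavior `S_i^t ∈ {silent, express}` — the only dynamic variable.
  An expressing agent always voices its own attitude; lying is outside
  the model.

At each step every agent tallies its four neighbours' *voiced* opinions
into `(n_a, n_b, n_silent)` with `n_a + n_b + n_silent = 4` and classifies
the neighbourhood into exactly one of five local network states:

| local state | condition |
|---|---|
| total silence | `n_a + n_b = 0` |
| stalemate | `n_a = n_b > 0` |
| full majority | `n_a = 4` or `n_b = 4` |
| majority with minority | `n_a, n_b > 0`, `n_a ≠ n_b` |
| partial majority | one opinion voiced by 1–3 neighbours |

The literal set-definitions of stalemate and partial majority overlap with
total silence and full majority respectively; the precedence above makes
the five classes a true partition of the 15 admissible tallies (verified
exhaustively in the tests).

The decision rule, applied identically and simultaneously to all agents
(synchronous / parallel update):

| local state | C, majority att. | C, minority att. | R, majority att. | R, minority att. |
|---|---|---|---|---|
| total silence | silent | silent | express | express |
| stalemate | silent | silent | express | express |
| majority w/ minority | silent | silent | silent | **express** |
| partial majority | **express** | silent | silent | silent |
| full majority | **express** | silent | silent | silent |

"Majority attitude" means the agent's own attitude equals the locally
voiced majority opinion. Total silence and stalemate carry no majority
information, so the rule there depends on the population only.

## Initialization

Exactly `round(ρN)` agents (round-half-up) are made reputation seekers and
placed uniformly at random; attitudes are i.i.d. Bernoulli(`p_a`) and
initial behaviors i.i.d. Bernoulli(`p_express`). The exact-count placement
(rather than per-agent Bernoulli typing) makes the swept density the
actual composition of every lattice; at `ρ = 0.5` it coincides with the
Bernoulli(0.5) recipe up to sampling. All draws come from one
`numpy.random.Generator` seeded per run.

## Equilibrium detection

The update is deterministic on the finite space of `2^N` behavior
configurations, so every trajectory is eventually periodic and the first
*repeated configuration* identifies the equilibrium exactly: if the
configuration at step `t` equals the one first seen at `t₁`, the transient
has length `t₁` and the period is `τ = t − t₁`. The simulator hashes each
packed configuration and stops at the first recurrence; the trailing `τ`
recorded steps then cover the cycle exactly once and form the equilibrium
window for all statistics. Runs with no recurrence within the horizon are
flagged *censored*, their cycle length is capped at the horizon, and their
window is the final 10% of recorded steps; they are counted, never
dropped.

The "state" whose recurrence defines the cycle is the full behavior
configuration, not a scalar observable: scalars (e.g. the expressed-opinion
ratio) can collide without true recurrence and would under-estimate
periods. For cross-validation the package also implements the
fixed-horizon estimator that takes, over all time points in the second
half of a run, each point's minimum positive lag to an identical
configuration and returns the maximum of those minima; it provably equals
the exact period whenever the transient ends before half-horizon and one
full period fits in the remaining window (property-tested), and returns a
censored sentinel otherwise.

## Observables

Over the equilibrium window of each run:

* **silence density** — mean fraction of silent agents;
* **δA** = `#a − #b` over private attitudes (constant within a run);
* **δE_t** = `#voicing a − #voicing b`; the indicator here is "is
  expressing": silent agents contribute to neither side, so full
  expression gives `δE = δA` exactly and `θ = 1` (this is the only reading
  under which the scenario taxonomy below is meaningful);
* **θ** = `⟨δE⟩_window / δA`, undefined when `δA = 0`;
* **local-state fractions** — window-averaged fractions of agents in each
  of the five local states (sum to 1);
* **scenario** — `θ < 0`: silent majority; `0 ≤ θ < 1 − ε`: dampened
  majority (the `θ = 0` boundary is assigned here: no sign inversion has
  occurred); `|θ − 1| ≤ ε`: correspondence; `θ > 1 + ε`: amplified
  majority. The band half-width `ε` (default 0.05) operationalizes
  "θ around 1": an exact-equality definition would almost never fire on
  windowed means.

Runs with `δA = 0` (tied attitudes; probability ≈ 8% at `N = 100`) are
flagged, excluded from θ and scenario aggregates, and reported as
exclusion counts; their silence and cycle statistics are kept.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `lattice_side` | 10 | lattice side `L`; `N = L²` agents |
| `r_density` | 0.5 | fraction of reputation seekers (exact count) |
| `p_attitude_a` | 0.5 | P(private attitude = `a`) |
| `p_initial_express` | 0.5 | P(expressing at `t = 0`); the dynamics are insensitive to it beyond the transient |
| `max_steps` | 10000 | per-run horizon (sweeps default to 2000; see below) |
| `epsilon_correspondence` | 0.05 | correspondence band half-width on θ |
| sweep grid | 0.00–1.00 step 0.05 | density grid |
| `replicates` | 200 | runs per (size, density) |

Per-run seeds are derived from the sweep's master seed via
`SeedSequence((base_seed, size, round(density·10⁴), replicate))`, so seeds
are independent of enumeration order and any single record can be replayed
in isolation; each record stores its seed.

## Problem sizes and sampling properties

The shipped experiment scale — `N = 100`, 21 grid densities, 200
replicates, 2000-step horizon — resolves the qualitative structure of the
density dependence: the silence curve rising from ~52% to a ~64% plateau
and falling to ~55% at `ρ = 1`; cycle lengths growing from ~2 at low `ρ`
to a peak around `ρ ≈ 0.8–0.9`; per-density mean θ positive everywhere;
amplified majority modal for `ρ` up to ~0.45 and dampened majority modal
at high `ρ`. Two quantities are intrinsically noisy at this replication:

* the *location* of the silence maximum — the curve's top is flat
  (densities 0.45–0.70 lie within ~0.007 of each other), so the argmax
  can wander a few grid steps between master seeds;
* cycle-length means above `ρ ≈ 0.5`, where a growing fraction of runs
  (up to ~60%) does not recur within 2000 steps and enters the mean at
  the censoring cap.

## Model behavior worth knowing

An all-consensus-seeker lattice (`ρ = 0`) does **not** generically freeze
under synchronous updating: mixed-attitude initial conditions essentially
always end in an exact period-2 "blinker" cycle, because a consensus
seeker voicing into silence falls silent next step while waking its
like-attitude neighbours, which re-wake it. The acceptance script measures
a maximum exact period of 2 and ~52% mean silence at `ρ = 0`. Sequential
(in-place) updating, which damps blinkers into static states, is a
different model and an explicit non-goal here: this package is strictly
synchronous.

## What the generator does and does not emulate

Initial conditions are spatially unstructured: uniform random placement of
populations, i.i.d. attitudes, i.i.d. initial expression. Real social
settings have homophily, correlated attitudes, heterogeneous degree and
mixed motives within a person; none of that is modelled, so passing tests
establish the internal dynamics of this idealized lattice, not predictions
for empirical opinion data. Within the model family, results are exact up
to sampling: the dynamics themselves contain no noise.

## Known limitations

* 200 replicates versus fine-grained curve estimation: argmax-type
  statistics carry grid-step-scale uncertainty (above).
* The 2000-step sweep horizon censors the longest cycles at high `ρ`;
  cycle-length means there are lower bounds (cap-at-horizon), though the
  *location* of the peak is robust to the cap.
* `θ` aggregates are descriptive; no inferential statistics are provided.
* No alternative topologies, agent memory, lying, or asynchronous update
  schemes.
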