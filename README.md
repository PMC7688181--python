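# opinionlattice

Agent-based simulation of public opinion expression in small groups:
why publicly voiced opinions can oscillate — and misrepresent what people
privately think — even when nobody changes their mind.

`opinionlattice` places `N = L²` agents on an `L × L` square lattice with
periodic boundaries, so every agent has exactly four (von Neumann)
neighbours. Each agent holds a **fixed private attitude** (`a` or `b`) and
belongs to one of two populations:

* **Consensus seekers (C)** speak to affirm unity: a C agent expresses its
  attitude only when that attitude is the *only* opinion currently voiced
  in its neighbourhood, and stays silent otherwise.
* **Reputation seekers (R)** speak to be distinctive: an R agent expresses
  under total silence or a stalemate, and as the supported minority voice
  when a majority faces a minority; it never echoes the local majority.

At every step all agents decide *simultaneously* (synchronous update)
whether to voice their own attitude or stay silent, based on the five-way
classification of their neighbours' voiced opinions: total silence,
stalemate, majority-with-minority, partial majority, full majority.
Because the update is deterministic on a finite state space, every run
settles into an exact limit cycle (period 1 = frozen public opinion); the
package detects it by first recurrence of the full behavior configuration.

Equilibria are characterized by:

* silence density `S̄` — mean fraction of silent agents over the final cycle;
* attitude gap `δA = #a − #b` (private, constant) and expressed gap
  `δE_t = #voicing-a − #voicing-b` (public, oscillating);
* the **public–private opinion discrepancy** `θ = ⟨δE⟩_cycle / δA`, which
  sorts runs into *amplified majority* (`θ > 1`), *correspondence*
  (`θ ≈ 1`), *dampened majority* (`0 ≤ θ < 1`) and *silent majority*
  (`θ < 0`, the voiced majority is the attitudinal minority).

The experiment harness sweeps the reputation-seeker density `ρ` from 0 to
1 with replicated, individually re-seedable runs and aggregates these
observables per density.

## Worked example

```python
import opinionlattice as ol

config = ol.SimulationConfig(lattice_side=10, r_density=0.65, max_steps=2000, seed=7)
trajectory, cycle = ol.run_simulation(config)
record = ol.equilibrium_record(trajectory, cycle)
print(f"transient = {cycle.transient_length} steps")
print(f"cycle length tau = {cycle.cycle_length}")
print(f"attitude gap dA = {record.delta_A}")
print(f"mean expressed gap <dE> = {record.delta_E_mean:.2f}")
print(f"theta = {record.theta:.2f}  ->  {record.scenario}")
print(f"silence density = {record.silence_density:.2f}")
```

prints

```
transient = 189 steps
cycle length tau = 82
attitude gap dA = -8
mean expressed gap <dE> = -12.80
theta = 1.60  ->  amplified_majority
silence density = 0.69
```

Read: on this 10×10 lattice with 65% reputation seekers the public opinion
settles, after 189 steps, into an 82-step oscillation in which 69% of
agents are silent on average. Privately, attitude `b` leads by 8 agents;
publicly it leads by 12.8 on average — the majority is amplified
(`θ = 1.6`) because the attitudinal minority is disproportionately silent.

The same run from the shell:

```bash
opinionlattice simulate --side 10 --r-density 0.65 --seed 7 --steps 2000 --out out/
opinionlattice sweep --config plan.yaml --out sweep/   # replicated density sweep
opinionlattice summarize --records sweep/records.csv --out sweep/
```

`sweep` writes one tidy CSV row per run (seed, cycle length, silence,
`δA`, `⟨δE⟩`, `θ`, scenario, local-state fractions) plus a per-density
summary and a JSON manifest; interrupted sweeps resume with `--resume`.

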