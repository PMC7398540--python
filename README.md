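# obesinet

Agent-based simulation of obesity spread through a social network, built to
ask a public-health question: *when a weight-loss intervention can only reach
5% of a community each week, whom should it target?* The package compares
two conventional strategies (random individuals; "high-risk" individuals who
are already overweight or obese) against three network-based strategies
(highest degree, betweenness or closeness centrality) on a population of
Chinese adults.

It is written for epidemiological modellers and health-policy researchers:
everything is a plain Python library (numpy/pandas/networkx) with a thin
`obesinet` command-line wrapper.

## The model

Agents live on a static, homophilous scale-free social network grown by
biased preferential attachment: at each growth step, with probability equal
to the network *density* parameter (0.267 for Chinese communities) an extra
edge is inserted between existing members, otherwise the next person joins;
both choices favour high-degree members and similar pairs (same sex, close
age and body weight).

Each agent carries daily energy intake EI, physical-activity energy PA and
body weight BW. Weekly, for each agent *i* with neighbourhood *F_i*:

- social influence per channel: `InfEI_i(t) = mean_{j in F_i} (EI_j(t-1) - EI_i(t-1))`
  (same for PA), zero for isolated agents;
- an agent-level environmental coefficient Env ∈ [0.82, 1.08] modulates it:
  for intake, positive influence is divided by Env (a harmful environment,
  Env < 1, amplifies over-eating pressure) and negative influence is
  multiplied; for activity the roles are reversed;
- a behavioural deadband: EI moves by ±5% (impact I_EI) only when the
  modulated influence exceeds ±T_EI · EI(t−1), with T_EI = 0.07; PA uses
  T_PA = 0.12;
- the energy imbalance EI − EE, discounted by λ = 1/4 because habits change
  gradually, converts to weight via an energy density of 7700 kcal/kg;
- expenditure is recomputed as EE = REE(BW) + 0.10·EI + PA, with REE from
  sex-specific Harris–Benedict-type equations.

Initial states come from a person table (age, sex, height, weight at two
survey waves, 3-day mean intake) under an equilibrium assumption (EI = TEE),
after inclusion filters (age ≥ 24, plausible weight, REE between 60–75% of
TEE, biennial weight change within ±30%). Because the survey extract itself
is not redistributable, `obesinet.synthetic` generates populations with the
published marginal structure of the 2197-person sample (44.9% male, mean BMI
24 kg/m², 36.6% overweight and 13.0% obese under the Chinese 24/28 cutoffs).

## Worked example

```python
import obesinet as ob

pop = ob.generate_population(ob.SyntheticSpec(n=500, seed=17))
res = ob.compare_strategies(pop, ob.SimulationConfig(), n_runs=20, base_seed=5)

ctrl = res[None].mean_bw_change.mean()
print(f"control drift        {ctrl:+.2f} kg")
for s in ("random", "high-risk", "degree", "betweenness", "closeness"):
    print(f"{s:<12} net effect {res[s].mean_bw_change.mean() - ctrl:+.2f} kg")
```

prints

```
control drift        +0.09 kg
random       net effect -2.64 kg
high-risk    net effect -2.42 kg
degree       net effect -5.93 kg
betweenness  net effect -5.25 kg
closeness    net effect -4.85 kg
```

Without intervention the population drifts slightly upward (the harmful-
leaning environment amplifies upward intake pressure). Every strategy lowers
mean weight; targeting by network position roughly doubles the effect of
conventional targeting, and degree centrality does best — hubs both receive
the effect persistently and propagate lowered intake to many neighbours.

The same comparisons are available from the shell:

```
obesinet synth --n 2197 --seed 0 --out pop.csv
obesinet simulate --population pop.csv --strategy degree --replicates 100 --seed 0 --out out/
obesinet sensitivity --synthetic 2197 --replicates 20 --seed 0 --out sens.csv
```

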