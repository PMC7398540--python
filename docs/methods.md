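# Methods

## Model overview

The simulation couples three layers:

1. **A static social network** over the study population, grown once per
   replicate by biased preferential attachment. A growth step is an
   edge-insertion between existing members with probability equal to the
   density parameter (default 0.267, a literature value for Chinese
   community networks), otherwise the next person (in a random arrival
   order) attaches to one existing member. The first endpoint of an edge
   step is chosen proportional to degree; the second, and the attachment
   target of a node step, proportional to degree × homophily weight. The
   homophily kernel is
   `w = gender_boost^[same sex] · exp(−|Δage|/age_scale) · exp(−|ΔBW|/bw_scale)`
   with defaults gender_boost 2, age_scale 10 y, bw_scale 10 kg. The
   mechanism (same-sex, similar-age, similar-weight preference) is specified
   by the underlying model; the exponential-decay form and its scales are
   this package's design choice, the standard similarity kernel when only
   the principle is stated. The seed graph is a 3-node clique (the smallest
   graph on which degree-proportional choice is defined; configurable).
   Degree-biased growth gives the scale-free tail; with density p the
   expected edge count is ≈ seed_edges + (n − seed)/(1 − p), about 3,000
   edges and mean degree 2.7 at n = 2197.

2. **Weekly energy-balance dynamics.** All updates are synchronous from the
   previous week's values, matching the t−1 indexing of the influence
   equations. Influence is the mean neighbour-minus-self difference per
   channel (EI, PA); the per-agent environmental coefficient Env modulates
   it exactly as printed (intake: divide positive influence by Env, multiply
   negative; activity: the reverse); threshold comparisons are strict, so an
   influence exactly at ±T·level changes nothing. Thresholds T_EI = 0.07 and
   T_PA = 0.12 and the Env range [0.82, 1.08] are the calibrated published
   values. The impact constants I_EI and I_PA are **not** published; the
   defaults are 0.05 each, which reproduce the validation moments (mean
   biennial population drift ≈ +0.2 kg, individual-change SD ≈ 2 kg) on the
   synthetic sample, and `experiments.calibrate_impacts` grid-searches them
   against those moments for any other population. λ = 1/4 discounts each
   cycle's imbalance (the reading that λ discounts the imbalance, not the
   behavioural step, follows the source's wording). The energy-density
   formula as a function of initial weight is likewise unpublished; the
   default is the standard constant 7700 kcal/kg with a pluggable
   function-of-initial-BW hook. Env is drawn once per agent per replicate
   from Uniform(0.82, 1.08) and held fixed (a weekly-redraw flag exists).
   Expenditure is recomputed weekly as REE(current BW) + 0.10·EI + PA so the
   three-component TEE identity stays meaningful as weight changes. Body
   weight is floored at 30 kg to avoid non-physical collapse under
   compounding interventions.

3. **Interventions.** Each week 5% of the population is targeted and
   receives a 5% decrease in EI *or* a 5% increase in PA — implemented
   literally as one channel per target per week, chosen uniformly
   (`mode="either-random"`; ei-only/pa-only/both are selectable). Random
   targets are resampled weekly; the high-risk pool (BMI ≥ 24) is
   re-evaluated weekly on current weights; centrality rankings are computed
   once since the network is static. Effects compound for repeatedly
   targeted agents, bounded below by an intake floor at current REE.

## Interpreting intervention magnitudes

With compounding weekly effects, repeatedly targeted agents settle well
below their initial intake, so the absolute intervention effects here
(several kg over two years) are an order of magnitude larger than effects
reported for models that apply the perturbation more transiently; whether
the source platform applied effects once or weekly to the same individuals
is not stated, and the `schedule`/`mode` options bracket the readings. The
*relative* pattern is robust across these readings and is what the test
suite asserts: every strategy reduces weight against the paired control,
network-based targeting beats conventional targeting by several Monte-Carlo
standard errors, and degree ≥ betweenness ≥ closeness.

## Synthetic population

The generator reproduces the published marginals of the 2197-person sample:
sex ~ Bernoulli(0.449); age uniform on 24–88 (no age distribution is
published, so uniform is the minimal assumption); per-sex truncated-normal
heights within [1.30, 1.88] m; BMI from a three-component truncated-normal
mixture on [15,24), [24,28), [28,45) with weights (0.504, 0.366, 0.130) and
component locations (21.45, 25.8, 29.8) fixed once so the mixture mean is
≈ 24 kg/m²; weight = BMI·height². The REE/TEE fraction is uniform on
[0.60, 0.75] and intake is set to TEE (equilibrium), so every generated
person passes the inclusion filters and week-one influence is the only
source of change. Follow-up weight defaults to baseline; an optional
Gaussian biennial change (mean 0.3 kg, SD 3.9 kg, truncated to the ±30%
filter) supports validation-style tests. Attributes are otherwise
independent — the generator does not model the real age×BMI×intake joint
distribution, household structure or survey design, so passing tests show
the pipeline's behaviour under the printed marginals, not fidelity to the
real cohort.

## Inclusion filters

Applied sequentially, each row counted at its first failure: age < 24;
baseline weight in the abnormal set {0, 5.8} kg (matched at 0.1 kg
precision; the two values are treated literally); REE outside 60–75% of
TEE; biennial change rate (bw1 − bw0)/bw0 outside ±30%, with rows lacking a
follow-up weight excluded here under their own count. Filtering is
idempotent. The published exclusion counts refer to the full survey extract,
which is not deposited, so they are not reproducible from the included
sample.

## Experiments and statistics

Replicate r derives all randomness from base_seed + r; control and
intervention runs share seeds (same network, same Env draws), so replicate
differences isolate the intervention. Across-replicate 95% CIs use the
normal approximation mean ± 1.96·SD/√R. The paired t-test is the classical
n−1-df test, with a documented convention for zero-variance differences
(all-zero → p = 1; constant non-zero → p = 0). The sensitivity scan
perturbs each of T_EI, T_PA, λ and Env by ±10% one at a time (Env is a
range, so both endpoints are scaled — the only uniform reading), nine
scenarios including baseline.

## Numerical and implementation choices

- Heights are stored in metres and converted to centimetres inside the REE
  equations (the published coefficients are on the centimetre scale);
  ingestion auto-detects the unit (values ≥ 100 are cm).
- The weekly step is vectorized over agents via a sparse adjacency matrix;
  a pure-scalar trace in the test suite verifies the vectorized step
  agrees exactly on small networks.
- Betweenness and closeness on large graphs are delegated to igraph's C
  implementation; on graphs ≤ 300 nodes networkx is used, and both paths
  are checked against brute-force all-pairs path enumeration in the tests.
- Target-set size is round(coverage·n) with uniform random tie-breaking at
  the score cutoff.
- Connectivity is not enforced; closeness and betweenness are computed
  within components and isolated nodes score 0.

## Problem sizes used by the shipped runs

The packaged test suite runs the strategy-ordering experiment at n = 500
agents × 100 replicates and the acceptance script at the full n = 2197 with
40 comparison replicates and 10 sensitivity replicates of the 104-week
horizon; both choices keep Monte-Carlo error a small fraction of the
effects being compared while completing in minutes on one CPU.

## Known limitations

- No ageing, births, deaths, network turnover or direct weight imitation;
  influence acts only through EI and PA.
- The impact constants and energy-density formula of the source platform
  are unpublished; results are conditional on the documented defaults or on
  the calibration helper's fit.
- Absolute intervention-effect magnitudes depend strongly on the effect
  persistence reading (see above); only relative comparisons should be
  interpreted.
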