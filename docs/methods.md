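# Methods

## Model

The simulator couples two extinction mechanisms on a quantitative
bipartite visitation network (rows plants, columns pollinators, weights
in visits·flower⁻¹·h⁻¹):

* **Plants — stochastic.**  On the primary removal of pollinator *j*,
  every extant plant partner *i* draws a Bernoulli survival with
  probability `P_ij = 1 − IPD_i · d_ij`.  `IPD_i ∈ [0, 1]` is the
  plant's intrinsic dependence on insect pollination (fraction of seed
  set attributable to pollinator visits, `1 − SS_pe/SS_op` from paired
  open-pollination / exclusion experiments).  `d_ij` is the share of
  *i*'s visitation delivered by *j* among the *currently surviving*
  partners, with *j* itself still counted in the denominator at the
  moment of its removal.  After each event the `d` values are
  recomputed from the masked matrix, so survivors compensate the lost
  visitation; `d_ij = 1` for a last surviving partner.  A plant with
  `IPD < 1` can therefore persist with no partners at all, which a
  topological model forbids.
* **Pollinators — topological.**  A pollinator goes secondarily extinct
  exactly when its last extant plant partner dies.  Because each such
  pollinator has, by construction, no surviving plant partners, its
  loss triggers no further plant draws: every cascade settles in a
  single step.  (A fully two-sided stochastic model, with pollinator
  dependence on floral resources, is deliberately out of scope.)
* **No rewiring.**  Interactions lost to an extinction are masked
  permanently.

Removal proceeds until no pollinators remain.  Scenarios: `random`
(uniform order), `generalist` (descending initial degree), `specialist`
(ascending).  Variants: `F` keeps both empirical ingredients, `D`
forces `IPD = 1`, `H` equalises each plant's positive weights
(`d_ij = 1/k_i`), `DH` does both.  The topological baseline (TCM) kills
a plant only when its whole partner set is gone and is blind to weights
and IPD; it shares the scenario/replicate machinery so both models see
identically distributed removal sequences.

## Key statistics

* **Survival surface** — per plant, the fraction of replicates extant
  after each of the `N_P` events (event 0 = 1 by definition).
* **Robustness `R_i`** — trapezoidal area under the survival curve over
  `x = k/N_P ∈ [0, 1]`.  The replicate-averaged curve is integrated
  (with the trapezoid rule this equals the mean of per-replicate
  areas); the averaged curve is the stored artifact.
* **First-removal closed form** — under a uniformly random first
  removal, `E[d_ij] = 1/N_P` (dependence sums to 1 over partners, 0
  elsewhere), so expected survival is `1 − IPD_i/N_P`.  Used as a
  cross-check of the engine, not as part of it.
* **Enumeration oracle** — on networks with ≤ 5 pollinators,
  `exhaustive_expected_survival` walks every removal order and every
  Bernoulli branch (merging probabilistically identical states) and
  returns exact per-event survival probabilities.  It shares no code
  with the Monte-Carlo engines and anchors their tests.
* **Keystone scan** — for each pollinator, its removal from the intact
  network is simulated repeatedly and the settled surviving-plant count
  recorded, alongside covariates computed once on the initial network:
  normalised degree, interaction evenness, eigenvector centrality,
  species strength, guild.

## Numerical and design choices

* **Event indexing.**  A scheduled primary removal whose target already
  went secondarily extinct is skipped but still consumes an event
  index, so every replicate spans exactly `N_P` events and survival
  curves are comparable across replicates; the x-axis is always the
  fraction of scheduled extinction events.
* **Simultaneous draws.**  All partner plants of a removed pollinator
  draw independently against the same pre-removal state; sequential
  draw orders would introduce an arbitrary plant-order artefact.
* **Attack sequences.**  Generalist/specialist orders use the *initial*
  degrees, fixed per replicate (the standard static attack-tolerance
  convention); ties are re-shuffled uniformly each replicate so that
  deterministic tie-breaking cannot bias species-level estimates.  A
  dynamic mode that re-ranks extant pollinators by current degree at
  every event is available (`order_mode="dynamic"`).
* **Engines and reproducibility.**  The production engine vectorises
  all replicates over one `numpy` Generator; a run is bit-reproducible
  from `SimulationConfig.seed`.  A per-replicate reference engine
  (`engine="loop"`, child seeds spawned per replicate) implements the
  cascade step-by-step through `remove_pollinator` and is used in tests
  as an independent route to the same distribution.
* **Eigenvector centrality** is computed on the symmetric
  `(N_A+N_P)`-square weighted adjacency by power iteration
  (tolerance 1e−10, cap 10,000) on the shifted matrix `A + sI`,
  `s = 1 + max row sum`: a bipartite adjacency has a ±λ_max eigenvalue
  pair that defeats unshifted iteration, and the shift leaves the
  leading eigenvector unchanged.  On disconnected networks scores are
  computed on the largest component and other species score 0, with a
  warning.  A binary-adjacency option exists (`weighted=False`);
  weighted is the default for consistency with the quantitative
  network.  Evenness of a single-partner species is defined as 1
  (`ln k = 0` is degenerate; the choice only affects correlation
  covariates, never the simulator).
* **IPD estimation.**  Negative raw IPD (exclusion out-yielding open
  pollination, possible under sampling noise) is clamped to 0 by
  default and logged; the simulator requires `IPD ∈ [0, 1]`.  Community
  summaries use the sample SD (n−1).
* **Spearman correlations** use average ranks for ties; p-values come
  from the usual t-approximation for n > 10 and from exact enumeration
  of all n! rank permutations for n ≤ 10.
* **Correlation outcome.**  "Plant survival" in trait–survival reports
  defaults to the per-plant robustness under the random scenario (the
  whole-cascade aggregate); an event-indexed alternative is a one-line
  change via the survival surface.

## Synthetic communities

The generator produces the statistical structure the analysis assumes,
not a fit to any particular field data set:

* **Topology** — Bernoulli(connectance) bipartite adjacency; isolated
  species are repaired with a single minimal-weight link (keeps the
  realised connectance close to target and generation deterministic).
  Connectance below `max(N_A, N_P)/(N_A·N_P)` is rejected as
  infeasible.
* **Weights** — lognormal (default meanlog −2, sdlog 1), matching the
  heavy-tailed visits·flower⁻¹·h⁻¹ magnitudes of field visitation
  surveys.
* **IPD** — beta law solved from a target (mean, SD), feasible iff
  `sd² < mean(1−mean)`; optional zero/one inflation mimics fully
  autonomous and strictly self-incompatible species.  An optional
  Gaussian-copula coupling ties IPD rank to plant-degree rank at a
  target Spearman correlation (`ρ_gauss = 2 sin(πρ_s/6)`), since the
  dependence–connectivity association is a community property worth
  scanning.
* **Seed-set experiments** — `SS_op` lognormal per plant;
  `SS_pe = SS_op(1 − IPD)·η` with unit-mean multiplicative lognormal
  noise of chosen CV.  With zero noise the IPD computation inverts the
  generator exactly.
* **Presets** — `SB` (27 plants × 60 pollinators, connectance 0.15,
  IPD 0.59 ± 0.38) and `PM` (11 × 30, connectance 0.20, IPD
  0.71 ± 0.24): two community scales typical of Mediterranean
  plant–pollinator surveys, a species-rich coastal one and a smaller
  montane one with higher average dependence.  Pollinator richness and
  connectance are adjustable placeholders — realistic for networks of
  this size, not estimates of any particular site.

What passing tests on these communities do **not** show: real networks
are nested and modular rather than Erdős–Rényi, sampling effort biases
observed degrees, IPD varies within species and across years, and
visitation frequency is only a proxy for pollination effectiveness.
Directional results (stochastic < topological robustness; dependence
mattering more than weight heterogeneity) are structural properties of
the model and transfer; exact percentages do not.

## Problem sizes

Defaults follow the full protocol: 10,000 replicate removal sequences
per scenario/variant and per keystone deletion.  The test suite runs
reduced replicate counts (50–40,000 depending on the sharpness of the
assertion) and small networks chosen so that each Monte-Carlo check has
its tolerance set by the exact binomial/enumeration standard error of
the quantity under test, typically 3 SE.  The acceptance script runs
the two presets at the full 10,000 replicates.

## Known limitations

* Pollinator extinctions are never stochastic; communities where
  pollinators starve gradually rather than with their last host are
  outside the model.
* No rewiring or behavioural plasticity: the model is conservative
  about compensation beyond the `d_ij` renormalisation.
* The enumeration oracle is factorial in the pollinator count (cap 5).
* Exact Spearman p-values enumerate n! permutations; n = 10 takes
  seconds, larger n falls back to the t-approximation.
* ANOVA-style significance testing between robustness tables is left
  to downstream statistics packages; the tables themselves are the
  artifact.
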