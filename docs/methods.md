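# Methods

This note documents the models, parameter choices, and known limitations
of `imbnet`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Synthetic data: what is emulated, and what is not

The generator produces the joint structure the inference pipeline assumes:

* **Causal network.** A DAG over `n_genes` sampled by fixing a random
  topological order and attaching edges with probability proportional to a
  per-regulator attachment weight — `hub_boost` (default 10) for the
  `n_hubs` designated hub regulators, 1 otherwise — scaled so the expected
  edge count is `mean_out_degree · n_genes`. Hubs are drawn from the
  source-side third of the causal order: a "hub regulator" at the sink end
  of the order would have almost no candidate targets, contradicting the
  construct (master regulators head cascades). Edge effects are signed,
  with magnitude uniform on [0.5, 1.5] **per standard deviation of the
  regulator**: the stored weight is the drawn magnitude divided by the
  regulator's analytic marginal SD, computed in topological order assuming
  unit-variance noise and copy-number input. Without this scaling,
  marginal variance accumulates without bound down cascades (per-gene SD
  grows several-fold), which real log-expression data does not show and
  which creates a variance-ordering artifact well known in causal-discovery
  benchmarking. With it, per-gene SDs stay in roughly [1, 3].
* **Copy number.** Genes (in list order = genomic order) are partitioned
  into contiguous blocks with lengths 1 + Poisson(mean_block_len − 1)
  (default mean 5); each block × sample gets a single N(0, segment_sd)
  log-ratio. This reproduces the key confound: same-block genes share CNA
  exactly, so cis genes in one block are co-expressed without regulation.
* **Expression.** Linear-Gaussian structural equations in topological
  order: parents' weighted sum, plus `cis_effect · cna` for the
  `round(frac_cis · n_genes)` cis genes (positive effects, U(0.5, 1.5)),
  plus N(0, noise_sd) noise. `noise_sd` may be per-gene.
* **Recurrence.** Exponential proportional hazards: failure rate
  `baseline_rate · exp(Σ log_hr · z(driver expression))` with independent
  exponential censoring. Defaults (baseline 0.02/month, censoring
  0.01/month) give median failure around three years and a censored
  fraction comparable to published prostate cohorts. The planted driver
  module is the set of hub regulators, so the survival signal flows through
  the genes the network analysis should single out.
* **Tissue atlas.** Baseline 1.0 everywhere; planted tissue-specific genes
  at `fold` (default 10) in their tissue. Planted truth is returned for
  bookkeeping-exact tests.

Not emulated: RNA-seq count noise, array probe effects, tumor purity,
fusion events, correlated censoring, batch structure. Passing tests
therefore demonstrate correctness of the machinery and identifiability
under the stated generative model, not performance on raw platform data.

## Benchmark scale

The default study conditions are 50 genes × 200 samples, mean out-degree
1.5, 20% cis genes, unit segment and noise SDs, 20 annealing restarts.
These sizes keep a full pipeline run under ~10 s and the whole benchmark
suite within minutes on one CPU while leaving the learning problem
genuinely hard (three-state discretization of 200 samples). Published
applications of this family of methods run thousands of genes and hundreds
to thousands of Monte-Carlo networks; headline statistics from such runs
(network edge counts, specific driver genes, cohort hazard ratios) are
scale- and data-dependent and are not reproduced here.

## Preprocessing

* **Cis-CNA detection.** Per-gene Spearman correlation of expression with
  own copy number, one-sided for positive association (copy gain should
  raise expression), BH-corrected; called cis at q < 0.05. Spearman is
  robust to the heavy tails of log-ratio data. Note a structural
  false-positive route: a non-cis gene regulated by a same-block cis gene
  inherits correlation with its own block's CNA. At the default settings
  this inflates the called set modestly (observed in the worked example:
  15 called vs 10 planted).
* **Informative genes.** Union of the top variance fraction and all called
  cis genes, in input row order. The variance fraction defaults to 1.0 at
  benchmark scale (all genes informative); real-data runs would lower it.
  A clinical table is accepted for trait-anchored selection but unused by
  the default rule.
* **Discretization.** Exact 1-D k-means, k = 3, solved by scanning all
  contiguous two-breakpoint splits of the unique values with prefix-sum
  costs. Exactness matters: Lloyd iterations from fixed quantile seeds can
  empty the middle cluster and stop in poor local optima. States are
  numbered by ascending cluster mean; genes with < 3 distinct values map
  to the middle state; the procedure is deterministic, tie-consistent, and
  invariant to increasing affine transforms.

## Network learning

* **Score.** BDeu with equivalent sample size 1 and three states;
  decomposable per node. Max in-degree 3 bounds the 3^k parent
  configurations against 200 samples.
* **Prior.** log κ added per edge: κ_bonus = 10 when the regulator is
  cis-flagged, κ_penalty = 0.1 when the target is cis-flagged and the
  regulator is not. The prior encodes that genetics points downstream; its
  main measurable effect is orientation anchoring of cis-adjacent edges,
  so its benefit is assessed by *directed* edge-recovery AUPRC, paired
  across data seeds with replicate-averaged consensus per condition (the
  per-restart annealing noise exceeds the per-seed effect size, so single
  unpaired runs are uninformative). Both κ values are configurable; the
  defaults are deliberately strong-but-soft (|log κ| ≈ 2.3, comparable to
  a few units of log-likelihood).
* **Search.** Simulated annealing, proposals uniform over add (50%),
  delete (25%), reverse (25%); cycle-creating and in-degree-violating
  proposals rejected outright; Metropolis acceptance on the total score
  under a geometric schedule from T = 2.0 to 0.05 over 30 000 steps. The
  best structure visited is returned. 30 000 steps ≈ 12 proposals per
  ordered gene pair at 50 genes; raising it improves precision with
  diminishing returns.
* **Consensus.** Directed edge kept iff present in ≥ 30% of restarts
  (frequency recorded), then cycles resolved by repeatedly deleting the
  minimum-frequency edge on a detected cycle, ties broken on the
  lexicographically smallest (regulator, target); deletions are logged on
  the returned object. Direction-ambiguous edges can appear in both
  directions above threshold; cycle resolution then keeps the majority
  direction.

## Downstream analytics

* **Degrees** are counts of distinct neighbors within `hops` undirected
  steps (default 1). **Neighborhood overlap** between two networks is a
  one-sided hypergeometric upper tail in an explicit universe (the union
  of both node sets by default — the published analyses leave the universe
  unstated, so it is an argument).
* **Key regulators**: descendants within 3 directed hops, threshold
  mean + 2 sd over all genes; nothing is called when the counts have zero
  spread. On a 50-gene network this rule calls ~1–4 genes, consistent in
  proportion with the hundreds called on ~10⁴-gene networks.
* **Distinct key drivers** drop any key regulator directly regulated by a
  higher-degree key regulator; mutual equal-degree edges drop the
  lexicographically later gene; output ordered by descending degree.
* **Seed subnetworks**: induced subgraph on seeds plus first undirected
  neighbors, keeping connected components with ≥ `min_component_seeds`
  seeds (default 3).
* **Mediators**: mean *directed* shortest-path distance from each driver
  (the analysis asks for common *downstream* genes; an undirected variant
  would conflate upstream regulators). Genes unreachable from any driver
  get infinite mean distance and are excluded from the decile; the top
  ⌈frac · n⌉ by smallest mean distance are called common downstream genes,
  ties at the cutoff included.
* **Signature ROC**: nested subnetworks by undirected radius around a seed
  gene; each radius contributes the point (|S_h|/N, |S_h ∩ sig|/|S_h|).
  The y-coordinate is a precision-like quantity but is implemented as the
  published formulas print it; partial AUC integrates the interpolated
  curve over 1 − specificity ∈ [0, 0.1] and normalizes by the window so a
  saturated curve scores 1. Empirical permutation p-values use +1
  smoothing, (1 + #{null ≥ observed}) / (n_perm + 1).

## Survival

Univariate Cox fits per gene on z-scored expression (coefficients are log
hazard ratios per SD, comparable across genes), Wald p, BH correction
(configurable to Bonferroni); zero-variance and non-converging genes are
skipped with warnings; the screen requires ≥ 10 events. Gene-low groups
fit N(μ, σ) to the reference by moments (reference n ≥ 5; at n ≥ 50 the
difference from small-sample-corrected ML is negligible) and call a tumor
low when its lower-tail probability is < p_cut. Quantile splits label the
lowest ⌈frac · n⌉ samples low, boundary ties included. Group comparisons
report the log-rank p and the Cox hazard ratio of the low-group indicator.
Cox fits use lifelines' default Efron handling for tied event times.

## Tissue calls

Per gene, tissues are z-scored against the gene's own across-tissue mean
and sample SD (ddof = 1); preferential at z ≥ 2 (configurable);
flat genes yield no calls; calls are non-exclusive. The tally counts genes
of interest preferentially expressed per tissue, descending.

## Pipeline

Stages run in dependency order; each derives its seed from the global seed
keyed by the stage name (so stages are independently reproducible), writes
TSV/GraphML artifacts, and records inputs, outputs, a parameter hash, wall
time, and warnings in a manifest. A stage with an unchanged parameter hash
and intact outputs is skipped on re-run. Unknown configuration keys are
rejected; every run writes the fully resolved configuration.

## Numerical and degenerate-input conventions

* Empirical p-values are never zero (+1 smoothing).
* `resolve_cycles` is deterministic under ties (lexicographic victim).
* Empty driver lists, empty networks, single survival groups, zero-variance
  references, and sub-minimum sample counts raise ValueError rather than
  returning silently degenerate results.
* Seeds are accepted as any integer; derived seeds are reduced mod 2³¹−1.

## Known limitations

* BDeu on discretized linear-Gaussian data genuinely prefers some false
  edges at n = 200 (discretization breaks exact conditional-independence
  screening), so skeleton precision plateaus around 0.6–0.8 at the
  benchmark scale regardless of search effort; this is a property of the
  score, not the optimizer.
* Edge directions inside Markov-equivalence classes are identified only by
  the in-degree cap, v-structures, or cis anchors; reach-based driver
  calls on non-anchored cascade roots are accordingly unstable.
* The cis prior assumes cis genes are poor targets of transcriptional
  regulation; in data where cis genes have strong transcriptional parents,
  the penalty trades away those edges.
* The consensus thresholds directed edges, so an edge whose direction
  splits evenly across restarts can drop below threshold in both
  directions even when its skeleton support is high.
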