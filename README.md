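# imbnet

Copy-number-informed Bayesian gene-network inference for tumor profiling
studies, with the downstream analytics used to turn a learned network into
biology: key regulators, distinct key drivers, shortest-path common
mediators, recurrence-associated subnetworks, gene-low survival
stratification, and tissue-preferential expression tallies.

## The problem

Co-expression alone cannot distinguish regulation from confounding: genes
that sit in the same copy-number-altered (CNA) genomic block are
co-expressed because they are co-amplified or co-deleted, not because one
regulates the other. Somatic copy number, however, is causally upstream of
expression — a gene whose expression tracks its own copy number (a
**cis-CNA gene**) is anchored by genetics and makes a credible regulator
but a poor target of purely transcriptional control. `imbnet` exploits
this asymmetry to orient and denoise network reconstruction from tumor
expression profiles.

## The model

Expression is discretized per gene into three states (low/medium/high) by
exact 1-D k-means. A directed network `G` over genes is scored by the BDeu
marginal likelihood with a cis-anchored structure prior:

```
score(G) = Σ_g  log P(x_g | x_parents(g))          (BDeu, ess = 1, r = 3 states)
         + Σ_(u→v) log κ(u, v)                     (structure prior)

κ(u→v) = κ_bonus   (10)  if u is cis-flagged
       = κ_penalty (0.1) if v is cis-flagged and u is not
       = 1               otherwise
```

Cis genes are called per gene by a one-sided Spearman test of expression
against own copy number with Benjamini–Hochberg control (FDR 0.05).
Structure search is simulated annealing over add/delete/reverse single-edge
moves (max in-degree 3, geometric cooling); a **consensus network** keeps
the directed edges appearing in ≥ 30% of independent restarts and removes
any residual cycles weakest-edge-first.

Downstream, on the consensus network:

* **key regulators** — genes whose count of directed descendants within 3
  hops exceeds mean + 2 sd over all genes;
* **distinct key drivers** — key regulators not directly regulated by a
  higher-degree key regulator;
* **common downstream genes** — the top decile of genes by smallest mean
  directed shortest-path distance from a driver set;
* **recurrence screens** — per-gene univariate Cox proportional-hazards
  fits on z-scored expression with BH correction; gene-low groups are
  called against a Normal fitted to a reference tissue and compared by
  log-rank test and Cox hazard ratio;
* **network accuracy** — the fraction of inferred regulations supported by
  a reference interaction/pathway collection, with node-label permutation
  nulls, and a signature ROC (nested seed-gene subnetworks vs an external
  signature) summarized by partial AUC at specificity > 90%.

A synthetic-data module generates ground-truth causal networks with hub
regulators, block-structured CNA profiles, linear-Gaussian expression,
proportional-hazards recurrence coupled to planted drivers, and a tissue
atlas with planted tissue-specific genes — so every stage is testable with
known truth and no external downloads.

## Worked example

```python
from imbnet import synthetic, preprocess, bayesnet, neteval, topology

truth = synthetic.generate_ground_truth_dag(
    n_genes=50, n_hubs=3, mean_out_degree=1.5, frac_cis=0.2, seed=11
)
cna = synthetic.simulate_cna(truth, n_samples=200, segment_sd=1.0, seed=11)
expr = synthetic.simulate_expression(truth, cna, noise_sd=1.0, seed=12)

cis = preprocess.detect_cis_cna(expr, cna, fdr_threshold=0.05)
cis_genes = [c.gene for c in cis if c.is_cis]
disc = preprocess.discretize_expression(expr)

net = bayesnet.learn_consensus(disc, cis_flags=cis_genes, n_restarts=20, seed=100)
prec, rec = neteval.skeleton_precision_recall(net.edges.keys(), truth.edges.keys())

ref = neteval.ReferenceCollection.from_pairs("truth", truth.edges.keys())
acc = neteval.edge_accuracy(net, ref)
null_mean, null_sd, p = neteval.permutation_null(net, ref, n_perm=1000, seed=0)

key = [c.gene for c in topology.call_key_regulators(net) if c.is_key]
```

Output:

```
planted cis genes: 10, detected: 15
consensus edges: 56, skeleton precision 0.68, recall 0.50
edge accuracy vs truth: 0.69 (null 0.068 +/- 0.035, p = 0.000999)
key regulators: ['G0033', 'G0049'], planted hubs: ['G0033', 'G0043', 'G0049']
```

Read: of the 56 consensus regulations, 68% match a planted edge
(ignoring direction) while a label-permuted network would match ~7%
(empirical p ≈ 0.001), and both called key regulators are planted hub
drivers. Precision/recall are bounded away from 1 because three-state
discretization of 200 samples carries limited information — the honest
operating point of the method at this scale.

The same flow is available from the shell:

```bash
imbnet run --outdir out --seed 1            # simulate -> ... -> tissue
imbnet survival --outdir out                # re-run a single stage
```

Every run writes a resolved config, a manifest with parameter hashes and
output checksums, and TSV/GraphML artifacts per stage.

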