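# dagwas

Causal graph discovery for GWAS marker prioritisation in autotetraploid
crops (and any dosage-genotyped panel).

Standard association scans hand breeders a list of correlated markers
without saying which ones *drive* a trait and which merely ride along on
linkage disequilibrium or population structure. `dagwas` goes two steps
further:

1. **De-confounded screening.** Every marker's effect on the trait is
   estimated under the partially linear model
   `Y = θD + g(X) + ζ, D = m(X) + ν` by cross-fitted double machine
   learning, with the top-10 genotype principal components `X` absorbing
   stratification; stability selection (100 × 5-fold cross-fitting,
   `P < 10⁻⁴`) keeps only markers with a reproducible de-confounded
   signal.
2. **Structure learning.** A PC-stable constraint-based search with
   Fisher-Z conditional-independence tests (α = 0.05) builds a CPDAG over
   the selected markers plus the trait, orients colliders, closes under
   Meek's rules, forbids phenotype→genotype edges, and prunes to the
   trait's ancestral subgraph.
3. **Role classification.** Markers with a directed edge into the trait
   are **Direct Parent SNPs (DPSs)** — the trait's Markov blanket and the
   precise biomarkers; high-out-degree upstream nodes are **Upstream Hub
   SNPs (UHSs)** — pleiotropic regulators whose signal is diluted along
   mediator chains. Direct-effect edge weights, out-degree rankings and an
   out-of-fold R² comparison of DPS / UHS / random marker panels quantify
   the hierarchy.

A synthetic-cohort generator (`dagwas.simdata`) plants a known causal
architecture — direct parents, hub→mediator chains, an ancestry
confounder — in an admixed autotetraploid dosage panel, so every claim the
pipeline makes can be checked against ground truth.

## Worked example

Simulate a cohort of 500 genotypes × 2,000 dosage markers with 5 planted
direct parents and 2 hubs acting through 2 shared mediators, then run the
whole pipeline (here with the screen scaled to 25 repetitions):

```bash
dagwas simulate --out-dir sim_demo --seed 7
printf 'n_rep: 25\nn_random_draws: 10\n' > demo.yaml
dagwas run-all --config demo.yaml --geno sim_demo/dosages.tsv \
    --pheno sim_demo/phenotype.tsv --out-dir demo_out --seed 7
```

which prints (about a minute on one core):

```
pipeline complete; outputs in demo_out
  qc: {'markers_in': 2000, 'removed_call_rate': 0, 'removed_maf': 343, 'markers_out': 1657}
  pca: {'k': 10, 'explained_variance_ratio': [0.176699, 0.004045, ...]}
  screen: {'markers_screened': 1657, 'selected': 9, 'lambda_gc': 0.9627}
  graph: {'nodes': 10, 'directed_edges': 11, 'undirected_edges': 0}
  roles: {'dps': 7, 'uhs': 2}
  validate: {'DPS': 0.690058, 'UHS': 0.252017, 'random': 0.008544, 'full_selected': 0.685433}
```

Reading the numbers: 343 markers fail the MAF < 0.05 filter; PC1 carries
the two-subpopulation structure (17.7% of variance) and the screen is
calibrated (λ_GC ≈ 0.96, no residual stratification signal); 9 markers
survive stability selection; the learned graph classifies 7 of them as
direct parents and 2 as hubs. The validation table is the headline: the
DPS panel predicts the trait out-of-fold at R² = 0.69, the size-matched
hub panel manages only 0.25 (signal decay through the mediator chain), and
random marker panels of the same size explain essentially nothing.

Because the cohort is simulated, the result can be scored against the
planted truth:

```bash
dagwas recover --graph demo_out/causal_graph.edges.tsv \
    --roles demo_out/roles.tsv --truth sim_demo/truth_edges.tsv
```

```
 parent_precision  parent_recall  hub_precision  hub_recall  shd
              1.0            1.0            1.0         1.0    0
```

— all 7 true trait parents (5 planted parents + 2 mediators) and both
hubs recovered, with the inferred graph matching the true CPDAG exactly.

Each stage is also available separately (`dagwas qc`, `pca`, `blup`,
`screen`, `graph`, `classify`, `validate`) and as library functions
(`dagwas.run_screen`, `dagwas.learn_graph`, ...). See `docs/methods.md`
for the model details, defaults and limitations.

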