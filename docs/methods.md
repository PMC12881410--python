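# Methods

`dagwas` reconstructs a directed marker–trait dependency structure from an
observational dosage panel in three stages — de-confounded screening,
constraint-based structure learning, and topological role classification —
and ships a cohort simulator with planted ground truth so every stage can
be validated end to end. This note documents the models, the defaults and
why they were chosen, the numerical details, and the limits of what the
simulation-based validation shows.

## Partially linear screening model

Each marker dosage `D` (0–4 copies of the alternative allele in an
autotetraploid) is screened for a direct effect on the trait `Y` under the
partially linear model

    Y = θ·D + g(X) + ζ,        D = m(X) + ν,

where `X` are the top-10 principal components of the centred, unit-scaled
marker matrix, serving as proxies for population stratification and
structure-linked environmental confounding. The nuisance functions `g` and
`m` are cross-fitted lasso regressions (5 folds): within each fold both are
estimated on the complement and predicted on the held-out part, and the
partialling-out estimator

    θ̂ = Σ ν̂·ỹ / Σ ν̂²,    ỹ = Y − ĝ(X),  ν̂ = D − m̂(X)

is formed from the stacked out-of-fold residuals. Orthogonality to the
nuisance errors makes the bias second-order: the estimator stays centred
even when both the trait and the dosage load on ancestry.

Implementation notes:

- The lasso is solved in covariance (Gram) form by cyclic coordinate
  descent, vectorised across all response columns that share the design
  (the trait plus every marker). Coefficients match
  `sklearn.linear_model.Lasso` to solver tolerance; the per-response
  penalty is selected on a 30-point geometric path
  (`alpha_max → 1e-3·alpha_max`) by internal 5-fold cross-validation,
  ties resolved toward the sparser fit.
- The variance is the sandwich `Σψ²/(Σν̂²)²` with
  `ψ = ν̂(ỹ − θ̂ν̂)`, multiplied by an HC1-style factor `n/(n − 2(k+1))`
  accounting for the ~2(k+1) parameters the two nuisance fits consume.
  Without this small-sample correction the null statistics at n = 500 are
  visibly inflated (λ_GC ≈ 1.03 instead of ≈ 0.99).
- P-values come from the normal approximation, as cross-fitting theory
  prescribes; confidence intervals are θ̂ ± 1.96·se.
- Markers whose residual treatment variance falls below 1e-4 of their
  dosage variance (constant dosage, or dosage explained by `X` up to
  solver error) are flagged degenerate, reported with θ = 0 and p = 1, and
  never selected.

**Stability selection.** The whole cross-fitted screen is repeated
`n_rep` times (default 100; the bundled recovery benchmarks use 10) with
fold assignments reseeded as `seed + r`. A marker is selected when
`p < 1e-4` in at least a fraction `stability_pi = 0.8` of repetitions.
"Consistently identified" admits a literal reading of 100%; the 0.8
default is configurable to 1.0. The per-marker effect reported in the
screening table is taken from the repetition whose p-value is the (lower)
median across repetitions — stable, and free of the optimism of the
minimum.

**Diagnostics.** λ_GC = median(χ²)/0.4549 with χ² implied by the two-sided
p-values; Bonferroni threshold α/M; Manhattan/Q-Q/volcano/forest tables are
emitted for plotting. Note that λ_GC is a median over correlated markers:
at M ≈ 1,600 its Monte-Carlo standard deviation is ≈ 0.05 even for a
perfectly calibrated screen, so single-cohort values in the 1.05–1.10 range
are compatible with calibration (the mean χ² and the p < 0.05 exceedance
rate are the sharper checks, and both sit at their nominal values in the
null simulations).

## Structure learning

Over the selected markers plus the trait, the PC-stable algorithm learns a
CPDAG:

1. **Skeleton.** Fisher's Z test (`z = atanh(ρ)`,
   statistic `√(n−|S|−3)·|z|`, level α = 0.05) on partial correlations
   obtained by inverting correlation submatrices; conditioning sets grow
   from size 0 to `max_cond = 3`, drawn from per-level frozen adjacencies,
   so the result does not depend on processing order. Nodes are processed
   in sorted ID order and subsets lexicographically — the whole stage is
   deterministic. Dosages are treated as quasi-continuous and standardised;
   a numerically singular submatrix is treated as independence (logged).
   `max_cond = 3` balances test reliability at n = 500 against the depth
   needed to separate hubs from the trait through their mediator set.
2. **Colliders.** Unshielded triples i–k–j are oriented i→k←j using the
   conservative rule: every separating subset of the skeleton adjacencies
   of i and j is enumerated, and the collider is declared only when k
   appears in none of them; triples with conflicting evidence stay
   unoriented (logged). The textbook "k ∉ recorded sepset" rule (to which
   the conservative rule reduces under a perfect CI oracle) is used when
   only sepsets are available. The conservative check matters in practice:
   with finite samples the first recorded separating set for a hub–trait
   pair is often a single mediator, and the literal rule then fabricates a
   trait→mediator collider that the downstream trait constraint converts
   into the loss of a true edge.
3. **Meek closure.** Rules R1–R4 applied to a fixpoint; no new colliders
   or cycles are created (property-tested).
4. **Trait constraints.** A germline genotype cannot be caused by the
   phenotype, so trait→SNP edges are removed as statistical artifacts and
   undirected trait edges are oriented SNP→trait; Meek rules are re-run.
   Constraint enforcement is post-hoc repair after orientation, not
   background knowledge inside PC — simpler, and the effect on the final
   ancestral graph is the same for the sink-constraint case.
5. **Ancestral subgraph.** Only nodes with a *directed* path into the
   trait are retained (undirected edges are not traversed by default;
   `include_undirected`/`--ancestral-include-undirected` gives the
   permissive variant). PC runs on raw dosages by default; a
   `residualize` option learns on PC-residualised dosages instead, for
   users who prefer SNP–SNP edges free of ancestry correlation at the cost
   of interpretability of marginal dependencies.

With a d-separation oracle substituted for the CI test, the
skeleton→collider→Meek core provably recovers the exact CPDAG; the test
suite verifies this exhaustively for all 29,850 DAGs on up to five nodes
and for 300 random sparse six-node DAGs against a brute-force
Markov-equivalence oracle (orientation enumeration, independent of the
Meek implementation).

## Roles and edge weights

Direct Parent SNPs (DPS) are the trait's parents in the final graph — with
the trait constrained childless, exactly its Markov blanket. Upstream Hub
SNPs (UHS) are non-parent nodes ranked by directed out-degree (edges into
the trait excluded), retained at out-degree ≥ 2 by default or as a top-k.
Ties break by (out-degree desc, total degree desc, marker ID asc).

Edge weights quantify direct effects: the CPDAG is extended to one DAG of
its equivalence class by the deterministic Dor–Tarsi procedure (with a
logged orient-in-sorted-order fallback for graphs left extension-free by
the constraint surgery), each child is regressed on its DAG parents with
all variables standardised, and the absolute standardised coefficient is
attached to the edge (ridge 1e-6 fallback under multicollinearity). The
absolute standardised coefficient was chosen because it is comparable
across edges and scales like a direct-effect magnitude; note it tends to 1,
not to the raw slope, as residual noise vanishes.

## Predictive-specificity validation

Out-of-fold R² of ordinary least squares on a marker panel: 5-fold
cross-validation, model fit on training folds, `1 − SS_res/SS_tot` with
the training-fold mean as baseline, pooled over folds — so an
uninformative panel scores at or below zero, matching the negative values
that out-of-sample evaluation produces. The UHS panel is size-matched to
the DPS panel via the out-degree ranking; random control panels of the
same size are drawn without replacement outside DPS ∪ UHS and averaged
over 20 draws (a single draw is seed luck). The "full selected" panel (all
stability-selected markers) is available as an optional fourth set.
Against simulated truth, the package also reports DPS/UHS precision and
recall and the structural Hamming distance between the inferred graph and
the true CPDAG.

## Synthetic cohorts

The generator emulates a clonally replicated autotetraploid diversity
panel: N = 500 individuals, M = 2,000 dosage markers, two admixed
subpopulations (Dirichlet(0.5) ancestry), per-subpopulation ancestral
frequencies Beta(0.5, 0.5) — independent across subpopulations for half
the markers ("differentiated"), shared otherwise — LD blocks of 10 markers
whose frequencies are copied from their predecessor with probability 0.6
plus N(0, 0.02) jitter, dosages Binomial(4, ancestry-weighted frequency),
and 2% missing calls at random.

The trait is driven by five direct-parent markers, two hub markers acting
through two *shared* mediators, and an ancestry confounder
(`y = Σβ·dosage + 1.0·ancestry + N(0,1)`). Design choices that matter:

- **Shared mediators.** A hub with a private mediator is unidentifiable:
  the hub→mediator edge is reversible within the Markov equivalence class,
  so no constraint-based method could ever orient it. Two hubs jointly
  driving the mediator set create colliders (hub1→med←hub2) that make the
  hub out-edges identifiable, while each hub still reaches the trait only
  through mediators (path length ≥ 2) and separates from it given the
  mediator set (size 2 ≤ max_cond).
- **Mediator regeneration by rank-matching.** Mediator dosages are
  replaced by `z = t·s + √(1−t²)·ε` on a latent scale (`s` the combined
  standardised hub signal, `t = hub_transfer = 0.85`) and mapped back by
  rank-matching to the original dosage multiset — the hub→mediator
  dependence is induced while each mediator's marginal distribution is
  preserved exactly.
- **Coherent mediator signs.** Mediator trait-effects share one sign;
  opposite signs would cancel along the shared hub signal and erase the
  hubs' total effects.
- **Effect-size calibration.** `beta_parent = 0.55` with planted markers
  drawn from MAF ∈ [0.3, 0.45] puts every trait carrier near single-
  repetition detection power 0.9 at the `p < 1e-4` stability threshold.
  Planted markers are additionally required to align weakly with the
  top-10 sample PCs: at n = 500 and M ≈ 1,700 the sample PCs absorb a
  variable 15–45% of any coherent correlated block (the hub–mediator
  factor included) — a genuine overcorrection phenomenon of PC adjustment
  that would otherwise make hub detectability a per-seed lottery. The
  implied broad-sense heritability of the default trait is ≈ 0.5.
- **Confounder.** The ancestry score is the individual's proportion of
  subpopulation 0 — continuous under admixture — so differentiated null
  markers correlate with the trait and a naive scan inflates strongly
  (λ_GC ≫ 1.2) while the PC-adjusted screen stays calibrated.
- **SNP→SNP dependencies.** Two mechanisms exist and create different
  truth edges: LD copying correlates *frequencies* of adjacent markers
  (weak individual-level dosage LD, no truth edges — binomial sampling
  dominates), while the hub-transfer mechanism creates individual-level
  dependence and the hub→mediator truth edges. Strong individual-level LD
  proxies, as in the screening-off scenario, are therefore constructed
  explicitly in the tests rather than arising from the frequency-level LD.

What passing the simulation benchmarks does *not* show: real panels have
haplotype-level LD (far stronger marker–marker correlation than the
frequency-copying mechanism), non-additive gene action, genotype ×
environment structure, and informative missingness — none of which the
generator emulates. Recovery rates on this generator are an upper bound on
what the same pipeline would achieve on field data.

**Spatial adjustment.** Plot-level scores from a row × column field layout
are de-noised with `y = μ + genotype + row + column + ε`, all effects
independent random, fitted by EM-REML on Henderson's mixed-model equations
(relative tolerance 1e-6, ≤ 500 iterations, variance floor 1e-8·var(y)).
Returned genotype predictions are `μ + BLUP` on the trait scale. This is a
deliberately lightweight row/column adjustment, not a full spatial REML
with correlated residuals; with 50 row and 30 column levels the estimable
quantities are the realized variances of the drawn effects, which the
benchmarks recover within a few percent.

## Problem sizes used in the bundled benchmarks

Structure-recovery and predictive-specificity benchmarks run ten seeded
cohorts at the full study scale (n = 500, M = 2,000 pre-QC) with the
stability screen scaled to 10 repetitions; the null-calibration benchmarks
use a single repetition on one cohort; the CI-calibration check uses 2,000
replicates at n = 500. The CPDAG-recovery check is exhaustive to five
nodes and sampled at six.

## Known limitations

- Linear nuisances and linear CI tests: dominance, epistasis and other
  non-linear signal are invisible by design.
- `max_cond = 3` cannot separate nodes whose minimal separating sets are
  larger; such nodes keep spurious adjacencies.
- Orientation conflicts and ambiguous triples are resolved conservatively
  and logged, not bootstrapped; no edge-confidence measure is provided.
- PCs are computed once on the full panel, so the screen inherits the
  usual leakage/overcorrection trade-offs of one-shot PC adjustment.
- The trait must be a sink; feedback through selection or experimental
  design violates the model.
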