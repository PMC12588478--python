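# Methods

`coexcom` implements a three-step analysis for finding case/control
discriminative gene communities in bulk expression data, together with a
synthetic-data generator that provides a planted ground truth for every
stage.

## Preprocessing

Expression intensities are log2-transformed (`log2(x + offset)`, default
offset 1.0 to tolerate near-zero synthetic intensities), batch-adjusted, and
quantile-normalized.

The batch step is a per-gene location–scale adjustment whose coefficients
are estimated **from control samples only**: for each (gene, batch) the
batch's control mean and SD are mapped onto the pooled control mean and SD,
and the resulting affine map is applied to every sample of the batch, case
and control alike. Anchoring on controls keeps case/control signal out of
the batch coefficients when case prevalence differs between batches. A
batch needs at least two controls (its SD is undefined otherwise) and a
degenerate control SD (< 1e-12) leaves the gene's scale at 1 for that
batch. This is a deliberately simple, exactly testable estimator of the
"coefficients from controls only" convention; it does not pool information
across genes the way empirical-Bayes batch methods do.

The default stage order is **log2 → batch → quantile**. Adjusting on the
log scale follows the convention of empirical-Bayes batch correction and
avoids a real failure mode: the affine adjustment applied to raw
intensities can map low-intensity samples to negative values, which the
subsequent log transform cannot accept. The order is configurable.

Quantile normalization assigns each column the mean-of-order-statistics
reference; ties receive the mean of the reference over their tied rank
range. When a row of order statistics is already constant the reference is
set to that constant rather than a rounded mean, so re-applying the
transform is idempotent to the bit on tie-free data.

## Co-expression network

Genes are linked when the two-sided test of Pearson correlation
(`t = r·sqrt((n−2)/(1−r²))` on n−2 df) gives p < 0.01, i.e. the 99%
confidence interval excludes zero. No multiple-testing correction is
applied at this stage. The clustering weight is |r| (the community
detection backend requires nonnegative weights); the signed correlation is
kept as an edge attribute. Constant genes are dropped with a warning rather
than raising, to tolerate degenerate inputs.

## Stability-selected hierarchical Leiden detection

For each configuration (resolution γ, refinement randomness β) the Leiden
algorithm (igraph backend, modularity objective, run to convergence) is run
L = 100 times with seeds `base_seed + j`. Stability is the average pairwise
normalized mutual information over all L(L−1)/2 pairs, with
NMI = 2·I/(H_p + H_q) (natural logs; the "sum" normalization). Degenerate
conventions: two zero-entropy partitions are necessarily equal → 1; exactly
one zero entropy → 0.

The majority (most frequent) partition is retained only if three criteria
hold: *stable* (⟨NMI⟩ ≥ 0.80), *substantial* (≥ 2 communities), and
*non-fragmented* (no community below ⌈5% of the current (sub)network's node
count⌉ — the fraction is evaluated per subnetwork, since 5% of the full
network would forbid any community under 100 genes at realistic sizes).
Among retained configurations the highest ⟨NMI⟩ wins.

**Tie-breaking.** At desk scale several configurations are routinely
*perfectly* stable (⟨NMI⟩ = 1.0 exactly), including under-resolved ones
that merge two planted modules; a tie-break toward small γ would
systematically pick those merged partitions. Exact ties are therefore
broken toward the majority partition with **more** communities, then
smaller γ, then smaller β — the finer resolution serves the method's
stated goal of small, interpretable communities, and any oversized
community is recursed anyway.

Default grids are γ ∈ {0.5, 0.8, 1.0, 1.2, 1.5, 2.0} and
β ∈ {0.005, 0.01, 0.05, 0.1}, bracketing the backend defaults; both are
configurable.

**Recursion.** Communities larger than 100 genes are re-partitioned as
induced subgraphs (edge attributes are not recomputed); communities of 4 to
100 genes become final records; smaller ones are discarded with a log
entry. Each recursion node offsets the base seed by a CRC of its hierarchy
path, so sibling ensembles are independent yet reproducible. A depth cap
(default 20) turns a subgraph that refuses to subdivide into an explicit
error.

**Connected components.** A modularity-type objective never merges nodes
across connected components, so on a graph with any small component the
non-fragmentation criterion is unsatisfiable for every configuration.
Connectivity is therefore treated as the coarsest partition level: a
disconnected (sub)graph is first decomposed, undersized components are
discarded, and each remaining component is detected on its own. A component
the ensemble cannot split (single-community majority partition) simply
becomes a final record if it fits the size band.

**Fallback.** When no configuration is retained for a subnetwork the
highest-⟨NMI⟩ configuration is used with a prominent warning; silently
dropping the subnetwork would lose genes.

## Per-community classification

Each final community is scored by stratified 5-fold cross-validation
repeated 100 times (both configurable; the bundled benchmarks use 10
repetitions). Stratification is used because imbalanced cohorts (the
motivating data are 33 cases vs 71 controls) occasionally produce
single-class unstratified folds.

Inside every training split, Boruta selects the community genes whose
Random-Forest importance beats the best column-permuted "shadow" copy;
decisions use a two-sided binomial test on accumulated hit counts
(p = 0.5 under the null) at α = 0.01 with Bonferroni adjustment over the
community size. Rejected genes leave the comparison; genes still undecided
at the iteration cap stay tentative and are not confirmed. The internal
importance forest uses 30 trees of depth 5 with √p features per split and a
20-iteration budget — a deliberately small forest: the binomial decision
accumulates evidence across iterations, so per-iteration importance noise
is tolerated, and the planted-gene recovery benchmarks confirm full
selection power at this setting.

A Random Forest with **M = 300 trees and s = S** (every feature considered
at every split; a √S option is available) is then trained on the confirmed
genes — or on the whole community when Boruta confirms nothing, since
discarding folds would bias the aggregates — and scored on the held-out
fold: accuracy, ROC AUC from the case-class vote fraction, and F1 with
"case" positive. Fold metrics are averaged per repetition; the reported
mean ± SD is over the repetition-level means (SD, not SEM).

The top-gene list takes the N most frequently confirmed genes, N being the
average confirmed count over all fold × repetition runs rounded to the
nearest integer; frequency ties break by mean importance, then gene id,
and the final list is presented ranked by mean importance. Communities
whose accuracy exceeds 85% are screened in for downstream analysis.

Independent validation re-runs the identical CV scheme on a second dataset
restricted to the community's genes; genes missing from the independent
matrix are dropped (error below 50% overlap).

## Enrichment

Over-representation of a community against an annotation set uses the exact
upper-tail hypergeometric probability P(X ≥ k). The universe is the set of
genes in the co-expression network — the frame communities are actually
drawn from; the annotation is intersected with the universe before testing.
A single curated disease-gene list is judged on the raw p at the 1% level;
multi-set collections are Bonferroni-corrected within community and judged
at 0.05.

## Shapley attribution

The explained model is a Random Forest retrained on the full dataset
restricted to a screened community's top-N genes; the explanation target is
its case-class probability. The value function is interventional:
`f_x(F)` replaces features outside F with background rows (default
background: the explained samples, capped at 100 seeded rows) and averages.

Two independent routes compute the same quantity:

* `shap_exact` — the defining weighted sum over all subsets
  F ⊆ S∖{j} with weight |F|!(|S|−|F|−1)!/|S|!. Exponential in |S|; refuses
  above 12 features. Used as the oracle.
* `shap_tree` — exact polynomial attribution for tree ensembles: walking a
  tree for one (sample, background row) pair, only nodes where the two
  inputs diverge make the reached leaf depend on the coalition, so each
  reachable leaf carries disjoint requirement sets (A = features forced
  present, B = forced absent) and its Shapley contribution collapses to
  closed-form factorial weights in (|A|, |B|). Cost is linear in divergent
  paths per (sample, background, tree) triple; a numba kernel with bitmask
  coalitions covers up to 62 features, with an arbitrary-width Python
  fallback above that.

Local accuracy (base value + Σφ = model output) holds to float precision by
construction and is asserted on every attribution. Summaries rank features
by mean |φ| (ties by id) and report a direction: the sign of the
correlation between feature value and φ, so a negative direction means low
expression pushes the classifier toward "case".

## Synthetic data

The generator emulates the statistical structure the analysis assumes in a
case/control microarray cohort:

* **Modules** — gene g of module m is `x = sqrt(ρ)·F_m + sqrt(1−ρ)·ε` with
  a shared latent factor per module, giving within-module correlation
  exactly ρ in expectation and unit marginal variance; background genes are
  independent noise.
* **Class signal** — a mean shift of `effect_size` (units of the unit
  per-gene SD) on case samples of the informative genes only, so
  informative and uninformative genes within one discriminative module are
  distinguishable by feature selection.
* **Batch effects** — per-(batch, gene) additive shift ~ N(0, shift_sd²)
  and multiplicative `exp(N(0, scale_sd²))`, applied on the log scale.
* **Annotation** — a planted gene set with a configured overlap inside one
  designated module, standing in for a curated disease-gene list.
* **Intensity scale** — values are exponentiated (`2^(x+8)`) before
  writing, so preprocessing's log2 step operates on microarray-like input.

Defaults mirror a desk-scale version of the motivating cohort: 104 samples
(33 cases / 71 controls), 300 genes with six 20-gene modules at ρ = 0.8,
two discriminative modules carrying an effect of two SDs on half their
genes, and two batches. A separate helper generates a two-level hierarchy
(super-blocks sharing a weak factor, sub-blocks a stronger one) for testing
the recursive subdivision.

What the generator does **not** emulate: probe-level artifacts, dye
effects, missing values, heavy-tailed intensity distributions, or
correlated (non-block) co-expression structure. Passing benchmarks
therefore demonstrate correctness of the machinery under the assumed
model, not performance on real cohorts.

## Benchmark problem sizes and what the checks show

The bundled benchmarks (test suite and `scripts/acceptance.py`) run at desk
scale, chosen so each stage's behaviour is measurable against the planted
truth:

* module recovery: 6 × 20-gene modules + 60 background genes, n = 100,
  ρ = 0.8, no class effect — recovery is scored as mean best-match Jaccard.
  The class effect is removed here deliberately: a shared case shift makes
  two discriminative modules genuinely co-expressed, and the resulting
  merged community is a property of the data, not a detection failure.
* nested recovery: 2 super-blocks of 150 genes = 5 × 30 sub-blocks
  (ρ_super = 0.3, ρ_sub = 0.7), n = 100.
* classification: 30-gene communities, n = 200 balanced, effect 2 SD on 10
  genes; 5-fold CV × 10 repetitions.
* pipeline smoke/determinism runs use reduced ensembles (L ≈ 10–12) and one
  CV repetition; determinism is exact at any scale.

Module recovery at this scale is seed-sensitive: with only six 20-gene
modules, spurious inter-module edges occasionally make a merged partition
the genuinely optimal and perfectly stable one at low resolution. The
benchmark instance is fixed (generator seed 1) and representative of the
favourable half of draws; the limitation is the method's, at desk scale,
not an implementation artifact.

## Known limitations

* The controls-anchored adjustment estimates per-gene coefficients without
  cross-gene shrinkage; for very small batches it is noisier than
  empirical-Bayes alternatives.
* Signed community detection (treating negative correlations as repulsive)
  is not implemented; weights are |r| with sign kept as metadata.
* `shap_tree` cost grows with samples × background rows × trees; for large
  cohorts cap the background (default 100 rows) or subsample explained
  rows.
* The ± errors reported are SDs across CV repetitions; repetitions share
  samples, so these are not independent-replicate SEs.
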