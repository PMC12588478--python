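# coexcom

**Disease-discriminative gene communities from co-expression networks.**

`coexcom` is for transcriptomics researchers who want to move beyond
single-gene differential expression in case/control cohorts: it finds
*communities* of co-expressed genes, asks which communities discriminate
cases from controls, and explains *which genes inside a community* drive
that discrimination. The pipeline has three steps:

1. **Network & communities.** Genes are linked when the Pearson correlation
   of their expression profiles is significant at the 99% level (two-sided
   p < 0.01), weighted by |r|. Communities come from the Leiden algorithm
   run L = 100 times per (resolution γ, randomness β) configuration;
   a configuration is kept only if its majority partition is *stable*
   (average pairwise normalized mutual information
   ⟨NMI⟩ = 2/(L(L−1))·Σ_{a<b} NMI(p_a, p_b) ≥ 0.80), *substantial* (more
   than one community) and *non-fragmented* (no community under 5% of the
   network being partitioned). Oversized communities (> 100 genes) are
   recursively re-partitioned; final communities hold 4–100 genes.
2. **Classification.** Each community is scored by stratified 5-fold
   cross-validation repeated 100 times: Boruta feature selection (shadow
   features, binomial decisions) inside every training fold, then a Random
   Forest (M = 300 trees, s = S features per split) scored on the held-out
   fold (accuracy, AUC, F1). Communities above 85% mean accuracy are
   screened in, and an independent dataset can be validated with the same
   scheme.
3. **Explanation.** Screened communities are tested for over-representation
   of annotation gene sets (exact hypergeometric upper tail; Bonferroni
   across sets), and each community classifier is explained with Shapley
   values
   φ_j(x) = Σ_{F⊆S∖{j}} |F|!(|S|−|F|−1)!/|S|! · [f_x(F∪{j}) − f_x(F)],
   computed exactly for tree ensembles by a polynomial tree-path algorithm
   (with the subset-enumeration form as a built-in cross-check).

A synthetic-data module generates cohorts with planted modules, planted
class signal, batch effects and a planted annotation set, so every stage is
verifiable against a known ground truth — no external downloads required.

## Worked example

```python
from coexcom import (SyntheticConfig, generate_dataset, preprocess_pipeline,
                     build_network, hierarchical_detect, evaluate_community,
                     screen_communities, enrich_all, CVConfig)
from coexcom.network import graph_summary

cfg = SyntheticConfig(seed=1)          # 300 genes, 33 cases / 71 controls
matrix, metadata, truth = generate_dataset(cfg)
processed = preprocess_pipeline(matrix, metadata)   # log2, batch, quantile
graph = build_network(processed, alpha=0.01)
print("network:", graph_summary(graph))

records = hierarchical_detect(graph, L=25, base_seed=1)
cv = CVConfig(n_folds=5, n_repetitions=5, base_seed=1)
performances = [evaluate_community(processed, metadata, r, cv) for r in records]
for p in performances:
    print(f"{p.community_id}: acc={p.accuracy_mean:.2f}±{p.accuracy_sd:.2f} "
          f"auc={p.auc_mean:.2f} N={p.boruta_avg_selected:.1f}")
print("screened (>85% accuracy):", screen_communities(performances))

results = enrich_all({r.community_id: r.genes for r in records},
                     {"risk_genes": set(truth.annotation_set)},
                     graph.vs["name"])
print("enriched at 1%:", [(r.community_id, r.overlap, round(r.p, 5))
                          for r in results if r.significant_raw])
```

Output:

```
network: {'n_nodes': 300, 'n_edges': 1847, 'density': 0.0412}
C0_0: acc=0.91±0.01 auc=0.95 N=8.3
C0_1: acc=0.82±0.03 auc=0.85 N=7.3
C0_2: acc=0.63±0.06 auc=0.51 N=0.0
...
C0_9: acc=0.62±0.03 auc=0.55 N=0.0
screened (>85% accuracy): ['C0_0']
enriched at 1%: [('C0_0', 6, 6e-05)]
```

Reading this: the generator planted class signal in two of six modules.
Community `C0_0` recovers the first of them — 91% CV accuracy, AUC 0.95,
with Boruta confirming on average N ≈ 8 of its genes — and it carries 6 of
the 10 planted "risk" annotation genes (hypergeometric p = 6·10⁻⁵, well
under the 1% bar). The second signal-bearing community sits at 82% and just
misses the 85% screen at this reduced repetition count. The remaining
communities have no planted signal: Boruta confirms nothing (N = 0) and
accuracy settles near the 0.68 majority-class rate of the imbalanced
33/71 cohort.

## Command line

Every stage is also a subcommand operating on plain-text artifacts
(expression/metadata TSV, edge-list TSV, communities TSV, GMT):

```bash
coexcom simulate --out data/ --seed 1
coexcom run-all --expression data/expression.tsv --metadata data/metadata.tsv \
        --annotation-gmt data/annotation.gmt --out run/ --seed 1
# or stage by stage:
coexcom preprocess --expression data/expression.tsv --metadata data/metadata.tsv --out pre.tsv
coexcom network --expression pre.tsv --out edges.tsv
coexcom communities --edges edges.tsv --out communities.tsv --seed 1
coexcom classify --expression pre.tsv --metadata data/metadata.tsv \
        --communities communities.tsv --out performance.tsv
coexcom enrich --communities communities.tsv --gmt data/annotation.gmt \
        --edges edges.tsv --out enrichment.tsv
coexcom explain --expression pre.tsv --metadata data/metadata.tsv \
        --communities communities.tsv --community-id C0_0 --out-dir xai/
```

`run-all` writes a manifest (config hash, seed, per-stage timings) that
suffices to reproduce the run bit-for-bit.

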