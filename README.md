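# metaferm

Analysis toolkit for metatranscriptome time series from in-vitro batch
fermentations — the kind of experiment where a human faecal inoculum is
incubated with a candidate prebiotic fibre (here isomalto/malto-
polysaccharides, IMMPs, with varying α-(1→6) linkage content) and bulk
mRNA is sequenced at 0/6/12/24/48 h to see *which bacteria do what, when*.

It re-implements the bespoke computational stages such a study needs,
as a tested Python library with a thin CLI:

- **Taxonomic assignment** of assembled genes by a banded
  lowest-common-ancestor: hits filtered at E ≤ 1e-4, bit-score > 50,
  length > 100 nt, then a 10% top band (bit-score, length or identity),
  cascaded over up to three search tiers.
- **Differential expression** vs t0 per condition with TMM normalization
  (edgeR-faithful trimmed mean of M-values) iterated DEGES-style — flag
  candidate DE genes at q < 0.1, renormalize without them, repeat — and
  an exact conditional test (binomial, widened to beta-binomial under
  moment-estimated over-dispersion); final call q < 0.01.
- **Pattern mining** in two rounds: genus co-occurrence clusters by
  stability-assessed k-means (k = 1..20 × 50 restarts, support = mean
  pairwise Adjusted Rand Index, clustergram table), then per-genus
  DBSCAN (minpts = 3, epsilon swept as a percentage of the maximum
  pairwise distance, tau-index model selection) with classification of
  clusters into t0-only / control-late / late-upregulated trajectories.
- **Functional profiling**: RPKM, per-genus activity shares,
  starch-and-sucrose (GH13) pathway expression fractions, per-organism
  per-enzyme tables, EC recovery from free-text domain names, and
  activity-vs-16S Spearman agreement.
- **Cross-project comparison**: Bray–Curtis dissimilarity
  (BC = 1 − Σ min(p,q)), inversion to similarity, 2-D PCA/PCoA.
- **Synthetic data** with planted ground truth (taxonomies, annotated
  gene catalogs, negative-binomial counts with planted genus clusters
  and gene patterns, hit tables with engineered decoys, copula-coupled
  16S tables) so every stage is testable without downloads.

See `docs/methods.md` for the models, assumptions and parameter choices.

## Worked example

Generate a synthetic experiment and push it through every stage:

```sh
metaferm simulate --seed 42 --out-dir run
metaferm lca --hits run/hits.tsv --nodes run/nodes.dmp --names run/names.dmp \
    --out run/lca.tsv
metaferm de --counts run/counts.tsv --samples run/samples.tsv --out-dir run
metaferm cluster-taxa --counts run/counts.tsv --samples run/samples.tsv \
    --genus-map run/lca.tsv --seed 42 --out-dir run
metaferm cluster-genes --de run/de_results.tsv --counts run/counts.tsv \
    --samples run/samples.tsv --genus-map run/lca.tsv --out-dir run
metaferm profile --counts run/counts.tsv --samples run/samples.tsv \
    --catalog run/catalog.tsv --genus-map run/lca.tsv \
    --sixteen-s run/sixteen_s.tsv --out-dir run
```

With seed 42 the `de` stage reports `303 differentially expressed genes
(2 iterations, dispersion 0.356)` of the 320 simulated, and
`cluster-taxa` prints `chosen k = 5` with a
support curve (`run/support_curve.tsv`):

```
k  support
1  1.000000
2  0.365268
3  0.557112
4  0.711448
5  0.879148
6  0.700659
7  0.745185
8  1.000000
```

Support is the mean pairwise Adjusted Rand Index across 50 k-means
restarts — how reproducibly that number of genus groups is found.  k = 1
and k = 8 (= number of genera) are trivially stable and excluded from
the choice.  The resulting partition in `run/taxa_clusters.tsv` puts
*Bacteroides* with *Clostridium*, *Bifidobacterium* with *Escherichia*,
and *Enterococcus* with *Ruminococcus* — three of the four planted
co-occurrence groups recovered exactly on this noisy run.  `profile`
prints `pooled activity-vs-16S Spearman rho = 0.865` (the generator's
default rank coupling is 0.8), and `run/pathway_fractions.tsv` gives
per-sample GH13 expression fractions (0.12–0.29 here).

Pattern classification on the full five-condition design mostly reports
OTHER: with 25 (condition, time) cells, a gene's share rarely reaches
the 0.15 "expressed" threshold in any single cell.  The focused
experiment-A-like fixtures (2 conditions × 3 time points, see
`tests/test_acceptance.py`) recover the three planted trajectory classes
at 100% co-membership.

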