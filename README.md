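# assemblyscope

Community-assembly analysis for amplicon (ASV) count tables along an
environmental gradient:

- **io_core** — count-table I/O (TSV and BIOM 2.1), sample metadata, newick
  trees, rarefaction (hypergeometric, seeded), Good's coverage, prevalence
  filtering (strict `>` threshold).
- **synthetic** — ground-truth generators: Yule trees, lognormal
  metacommunities, and study-level tables (6 altitudes x 2 seasons x ~10
  samples) under known assembly regimes (neutral dispersal-drift,
  homogeneous/variable selection, dispersal limitation, mixed). The neutral
  generator is Dirichlet-multinomial with concentration `N*m*p`, the
  stationary distribution assumed by the Sloan fit, so migration-rate
  recovery is a clean end-to-end test.
- **diversity** — Shannon / bias-corrected Chao1 / Gini-Simpson, Bray-Curtis,
  weighted UniFrac (normalized by default), PCoA, PERMANOVA, within-group
  similarity, distance-decay and gradient OLS regressions, taxonomy
  aggregation, Kruskal-Wallis.
- **network** — per-group Spearman co-occurrence networks (|r| > 0.5 and
  p < 0.05, both strict), topology statistics (nodes, edges, signs,
  negative/positive ratio, Louvain modularity with fixed seed), and
  topology-vs-altitude Spearman correlations (exact permutation p for few
  groups).
- **nullmodels** — MNTD / SES.MNTD, betaMNTD / betaNTI under a
  tip-label-shuffling null, Bray-Curtis Raup-Crick (RC_bray), and the
  five-way process classification (variable selection, homogeneous
  selection, dispersal limitation, homogenizing dispersal, drift) with
  per-group partitioning.
- **neutral** — Sloan neutral-model fit (occurrence frequency vs mean
  relative abundance), migration-rate estimate m, fit R^2, Wilson-interval
  taxon partition (above / neutral / below), per-group fits.

## CLI

All commands take global `--seed` (default 20230), `--out-dir`,
`--log-level`, `--threads`.

```sh
# simulate a gradient study with known ground truth
assemblyscope --seed 1 --out-dir sim simulate \
    --regime neutral_drift --m 0.1 --reads 2000 --taxa 300 --samples-per-group 10

# alpha/beta diversity, PCoA, PERMANOVA, distance-decay
assemblyscope --seed 1 --out-dir div diversity \
    --counts sim/counts.tsv --metadata sim/metadata.tsv --tree sim/tree.nwk

# per-group co-occurrence networks and topology
assemblyscope --seed 1 --out-dir net network \
    --counts sim/counts.tsv --metadata sim/metadata.tsv

# SES.MNTD, betaNTI, RC_bray, process partition
assemblyscope --seed 1 --out-dir null nullmodels \
    --counts sim/counts.tsv --metadata sim/metadata.tsv --tree sim/tree.nwk

# Sloan neutral-model fits per altitude x season group
assemblyscope --seed 1 --out-dir neu neutral \
    --counts sim/counts.tsv --metadata sim/metadata.tsv
```

Runs with the same `--seed` are byte-identical.

## Notes on conventions

- Shannon uses the natural log; Chao1 is the bias-corrected form.
- Rarefaction subsamples without replacement (one draw per sample).
- Weighted UniFrac defaults to the normalized variant; pass
  `normalized=False` (CLI `--unifrac-raw`) for raw branch-length sums.
- betaMNTD/betaNTI are abundance-weighted by default; the null shuffles
  taxon labels across the analyzed table's taxon pool, 999 draws by default.
- Boundary values classify by strict inequality: betaNTI exactly +-2 and
  RC exactly +-0.95 fall through to the next rule.
- The Sloan fit uses detection limit d = 1/N (N = mean sample depth) by
  default; `detection="binomial"` replaces the beta-tail approximation
  with the exact binomial detection probability, which removes the
  upward bias of the fitted m at moderate depths.
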