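# chromloop

Loop-level statistics connecting 3D chromatin loops to gene regulation.

Chromosome-conformation assays such as HiChIP yield sets of *loops* — pairs
of cis anchor intervals whose spatial contact depends on a protein factor or
histone mark (e.g. SATB1, CTCF, H3K27ac in developing T cells). `chromloop`
implements the downstream statistics that tie such loop sets to transcription:

- **Overlap / engulfment scoring of loop sets.** For a query loop with span
  `[left_anchor.start, right_anchor.end)`, the overlap score against a
  reference loop set is `max_ref overlap_bp(query span, ref span) /
  |query span|` — 1.0 means full containment (engulfment), 0.0 no overlap.
  Observed score distributions are contrasted with scores of randomly
  shuffled loops (rigid spans, capacity-weighted placement across the
  genome) via a two-sided Wilcoxon rank-sum test.
- **Transcriptional insulation.** Per loop,
  `score = |mean expr(genes inside span) − mean expr(genes in equal-size
  flanks)|` with per-gene expression `log10(counts / gene length + 0.01)`,
  compared against shuffled loops re-drawn until they contain a gene.
- **Permutation overlap enrichment.** Observed count of A-intervals hitting
  any B-interval vs `n` shuffles of A; `p = #(null > observed) / n`,
  enrichment = observed / mean null.
- **Bootstrap accessibility at binding sites.** Per-site score = log10 mean
  signal over center ± 250 bp; `p = #(permuted means > real mean) / n`
  (n = 100), plus the low-accessibility site subset below the 10-shuffle
  average cutoff.
- **Loop classification and category enrichment** by promoter (TSS + 5 kbp)
  and enhancer (center ± 50 bp) content of anchors, with a
  ratio-of-proportions and Fisher's exact test per category.
- **Differential-loop linking scores.** Per gene,
  `score = #overinteracting − #underinteracting` loops with an anchor on the
  gene (a loop counts once even if both anchors hit), correlated with
  expression log2FC by Spearman rank after removing |score| > 40 outliers;
  hypergeometric gene-set enrichment and the T-cell subset signature filter
  (group mean ≥ 2× every other group).
- **A linear model of expression change**: 7 gene bins (upstream −4..−2 kbp,
  promoter −2 kbp..TSS, three body thirds, TTS..+2 kbp, +2..+4 kbp), binary
  binding occupancy per bin, the accessibility difference
  `log10[(KO+0.01)/(WT+0.01)] · log2(total+1)` per bin, and loop-anchor /
  enhancer-link / differential-loop counts per gene, fit by OLS.
- **A synthetic cohort generator** that emulates all inputs with planted,
  recoverable effect sizes (engulfment fraction, insulation shift,
  accessibility drop, loop-linked log2FC, rank-coupled linking scores) and a
  truth table.

## Worked example

```bash
chromloop simulate --seed 42 --out-dir demo/          # synthetic bundle
chromloop loop-compare demo/satb1_loops.bedpe demo/ctcf_loops.bedpe \
    --chrom-sizes demo/chrom.sizes --enhancers demo/enhancers.bed \
    --genes demo/genes.bed --seed 1 --out-dir demo/compare
chromloop enrich demo/peaks.bed --track demo/atac_wt.bedgraph \
    --chrom-sizes demo/chrom.sizes --seed 1 --out-dir demo/enrich
chromloop linking --genes demo/genes.bed --expression demo/expression.tsv \
    --diff-loops demo/h3k27ac_diff_loops.bedpe --seed 1 --out-dir demo/linking
```

prints (to standard error):

```
wrote synthetic bundle (seed 42) to demo/
fraction of query loops overlapping reference: 0.936 (rank-sum p=7.57e-58)
bootstrap accessibility (seed 1, n=100): real mean 0.9396, p=0
linking: Spearman rho=0.591 (p=1.28e-188) on 2000 genes (0 outliers removed)
```

Reading: 93.6% of factor-A loops overlap a factor-B loop (the generator
plants 90% engulfment, and more overlap partially — compare
`demo/compare/overlap_scores.tsv`); accessibility at binding sites is far
above shuffled sites (no permuted mean ever exceeded the real mean, so the
bootstrap p is 0 at n=100); and the planted rank coupling of 0.6 between
per-gene differential-loop linking scores and expression change is recovered
as ρ ≈ 0.59 on 2,000 genes.

The same functions are importable as a library
(`from chromloop import overlap_score, insulation_null, ...`); every
randomized routine takes an explicit seed and is bit-reproducible.

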