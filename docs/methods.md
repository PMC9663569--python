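# Methods

## Coordinate and loop model

All coordinates are 0-based, half-open (BED-native) everywhere in memory;
the on-disk formats (BED, BEDPE, bedGraph, chrom.sizes, TSV) use the same
dialect, so I/O is lossless. A loop is two cis anchor intervals with the
left anchor starting first; its *span* runs from the left anchor's start to
the right anchor's end. Every overlap statistic in the package operates on
spans unless a function explicitly takes anchors. Trans interactions and
blocked (BED12) features are out of scope; BEDPE rows that are trans are
skipped with a logged count, and reversed anchor pairs are canonicalized on
read.

Gene-to-region assignment uses one rule throughout: a gene belongs to a
region iff its span overlaps the region by ≥ 1 bp. This is the simplest
rule consistent with all the statistics that need it (insulation, anchor
counts, classification) and keeping it uniform makes their outputs
comparable.

## Shuffling model

Interval and loop shuffling preserve each item's length; loops move as
rigid units (anchor widths and the inter-anchor gap are conserved), because
the insulation and enrichment nulls treat a loop as one object. Placement
is uniform over all valid (chromosome, start) pairs: a chromosome is drawn
with probability proportional to its number of valid start positions, then
a start uniformly among them. A `same_chromosome` flag restricts each item
to its own chromosome (the common default of shuffling tools); the
cross-genome mode is the package default since the nulls are defined as
"shuffled across the genome". Shuffled items may overlap each other and the
originals: no exclusion is applied, because none is part of the null's
definition. All randomness flows from one seed; library functions accept
either an integer seed or a numpy `Generator`, and the generator spawns
independent child streams per stage so adding a stage never perturbs the
draws of another.

## Overlap score and loop-set comparison

`overlap_score(query, reference) = max_ref overlap_bp(span_q, span_r) /
|span_q|`: 1.0 indicates 100% overlap or engulfment, 0.0 no overlap; with
multiple intersecting reference loops the maximum is used. "Size of a loop"
is interpreted as the span length (outer anchor coordinates), consistent
with the outer-coordinate rule used for loop-overlap fractions;
`fraction_overlapping` likewise counts ≥ 1 bp span overlap. The
score-distribution comparison repeats the scoring for shuffled query loops
and reports a two-sided Wilcoxon rank-sum p.

Loops are classified by anchor content. A promoter window is the TSS
extended 5 kbp *downstream* (into the gene body) on the coding strand — the
direction of the one-sided extension is genuinely ambiguous ("TSS + 5 kbp"),
so the downstream reading was chosen and the extent is configurable
(`promoter_extension`). An enhancer window is the record's center ± 50 bp
(`enhancer_flank`). Category is a deterministic function of the four
anchor-content flags, with cross-anchor promoter–enhancer pairing taking
precedence; a loop whose promoter and enhancer evidence sits on one anchor
with the other anchor empty is still called promoter–enhancer. Category
comparisons between two factors report the ratio of in-category proportions
(factor2 over factor1), a two-sided Fisher exact p per category, and
Benjamini–Hochberg adjusted p across the six categories (the adjustment is
an addition; per-category raw p values are also kept).

## Insulation

Per-gene expression score: `log10(counts / gene length + 0.01)`; the 0.01
pseudocount floors the score at −2 for silent genes. The insulation score
of a loop is the absolute difference between the mean score of genes inside
the span and the mean score of genes in the two equal-size flanking
windows, pooled into a single flank mean (the definition names one mean
over both sides, not a per-side average). Genes straddling the span
boundary count as inside and are excluded from the flank pool; flanks are
clipped at chromosome ends. Loops with an empty inside or flank gene set
are flagged invalid and dropped from the comparison. The null shuffles all
loops per round and re-draws any shuffled loop containing no gene (up to
1,000 attempts, then dropped with a warning); observed vs pooled null
scores are compared with a two-sided rank-sum test.

## Permutation and bootstrap tests

The permutation overlap p is implemented exactly as defined: `p = #(rounds
whose null overlap count is strictly higher than the observed) / n`, with
enrichment = observed / mean null. This estimator has no +1 smoothing and
can return 0; a `conservative` flag switches to (k+1)/(n+1). With heavily
tied, small-count statistics the strict-`>` form is anti-conservative;
calibration (type-I error within [0.03, 0.07] at α = 0.05, 500 null
datasets × 200 permutations) is demonstrated in a regime where the overlap
count takes many values, which is the regime the test is meant for
(hundreds of intervals).

The binding-site bootstrap scores each site as the log10 mean track signal
over the site center ± 250 bp (`peak_flank`; a width-1 site at c scores
[c−250, c+251)), shuffles the windows n = 100 times, and reports `p =
#(permuted mean scores > real mean) / n`. A zero mean signal is floored at
`pseudocount_atac` before the log to avoid −∞. The low-accessibility subset
uses n = 10 shuffles: the cutoff is the average of the per-round mean null
scores and sites scoring strictly below it are returned.

## Accessibility profiles

The TSS profile is the per-offset mean over genes of
`log2((KO + 0.01) / (WT + 0.01))` per bp over TSS ± 1 kbp (vector length
2·1000 + 1), with minus-strand genes flipped so positive offsets are
downstream of transcription; all genes are used. The gene-body profile
splits each body into `n_bins` equal bins (remainder bp in the last bin)
and each 2 kbp flank into `flank_bins` fixed-width bins, computing the
log2 ratio of per-bin *mean* signal; genes shorter than `n_bins` bp are
skipped with a warning.

## Linking scores and enrichment

A gene's anchor count for a loop set is the number of loops with ≥ 1 anchor
overlapping the gene; a loop whose both anchors hit the gene counts once.
The linking score is `#overinteracting − #underinteracting` (positive =
gained contacts in the knockout); this orientation makes the positive
correlation between linking score and expression change read naturally.
`score_per_kb` divides by the gene length in kbp. Before the Spearman
correlation with log2FC, genes with `|score| > 40`
(`outlier_linking_threshold`) are removed as influential outliers; OLS fit
lines are returned overall and stratified by membership in a supplied loop
set for plotting. Both all-gene and significant-only analyses are possible
by pre-filtering the expression records.

Hypergeometric set enrichment reports the upper tail `P(X ≥ k)`, the
expected overlap as the mean of the hypergeometric background
(`|query|·|category| / universe`), and fold = observed / expected. The
signature filter keeps, within each cluster assigned to group G, genes
whose mean expression over G's subsets is ≥ 2-fold ("at least" read as
inclusive) the mean of *every* other group; group-mean vs group-mean was
chosen over per-subset max (the definition is ambiguous) and the fold is a
parameter. Clustering itself is consumed as input, not computed.

## Linear model

Gene bins: upstream [−4, −2) kbp, promoter [−2, 0) kbp relative to the TSS,
three equal body bins (remainder bp to the 3'-most bin; "3 bins" does not
define a split, equal thirds is the natural one), [TTS, +2) and [+2, +4)
kbp, mirrored for minus-strand genes so bin 1 is always most upstream.
Flank bins are clipped at chromosome ends and flagged. Occupancy is 1 iff
any binding site overlaps the bin. The accessibility difference per bin is
`log10[(KO + 0.01)/(WT + 0.01)] · log2(total + 1)` with "total" taken as
KO + WT for the bin (undefined in the source definition; configurable in
spirit — the mean of per-bin track values is used for "reads" so the
predictor is invariant to bin width). Loop predictors: per-factor anchor
counts, the count of loops connecting the gene to an enhancer (one anchor
on the gene, the other on an enhancer window), and over/under-interacting
anchor counts. Ordinary least squares with intercept; predictors are not
standardized by default (a `standardize` option exists for diagnostics);
a rank-deficient design raises an error naming the collinear columns; a
constant response reports R² = 0.

## Synthetic cohort

The generator emulates the pipeline's inputs at desk scale with planted
effects; its defaults are the study conditions for all recovery tests:

- Genome: 8 chromosomes × 50 Mbp. Large enough that 800 factor-B loop spans
  of 100–400 kbp cover ~40% of the genome as a union — a realistic
  reference-loop density that leaves room for shuffled loops to miss them.
- Genes: 2,000 non-overlapping stranded genes, lengths log-normal
  (median ≈ 3 kbp, σ_log = 0.6), placed by rejection sampling (non-overlap
  keeps gene-to-region assignment unambiguous).
- Loops: 500 factor-A loops (spans 20–80 kbp, 5 kbp anchors) placed inside a
  random factor-B span with probability `engulfment_fraction` (default 0.9),
  else uniformly; 800 factor-B loops uniform. Engulfed loops are tagged in
  their names.
- Enhancers: one inside the right anchor of half the A loops
  (`fraction_loops_to_enhancer` = 0.5) plus 300 background enhancers.
- Binding sites: 500 sites, half placed in/near gene bodies (±4 kbp), the
  rest uniform, mutually separated so their signal windows are disjoint;
  5% are "cold" (`cold_site_fraction`).
- Tracks: bedGraph partitions with constant background 1.0 and 50 bp bins
  inside site windows (center ± 250 bp) carrying `peak_signal_ratio` = 10×
  background (cold sites 0.2×) with mild log-normal noise (σ = 0.05); the
  KO track halves hot-site signal (`ko_accessibility_drop` = 0.5). Constant
  background between features keeps files small without changing per-bp
  query semantics.
- Expression: WT mean = gene length × base rate × 10^(N(0, 0.25)) ×
  10^(insulation_shift · in-A-span), i.e. genes inside A-loop spans are
  planted one expression-score unit above their neighbors
  (`insulation_shift` = 1). log2FC = `planted_log2fc_in_A_loops` (−0.5,
  repression in the knockout) per A-anchor hit plus N(0, 0.8) noise; counts
  are negative-binomial (variance = μ + μ²/dispersion, dispersion 10). The
  written log2FC is the planted value (emulating an upstream
  differential-expression estimate); FDR is a BH-adjusted two-sided normal
  p on the planted effect.
- Differential loops: integer target linking scores are drawn from a
  rounded N(0, 2.5) and assigned to genes through a Gaussian copula against
  the expression-noise residual. Coupling to the residual (not the total
  log2FC) keeps the linear model's loop-count coefficients unbiased; the
  copula's latent correlation is widened by two attenuation factors
  measured on the sample itself — the tie attenuation of the discrete score
  distribution and the rank correlation between residual and total log2FC —
  so that Spearman(score, log2FC) approximates `linking_correlation`
  (default 0.6). Each unit of score materializes as one over- or
  under-interacting loop with one anchor inside the gene and the distal
  anchor 50–200 kbp away, rejection-sampled to avoid other genes, so the
  realized scores equal the targets exactly (verified in the truth tests).

What the generator does *not* emulate: realistic chromosome-size spectra
and gene clustering, anchor-level contact counts, mappability/blacklist
structure, overlapping or nested genes, replicate-level count variance, and
1D occupancy differences confounding the differential-loop labels. Passing
recovery tests therefore demonstrate correctness of the statistics under
their own assumptions, not robustness to those real-data complications.

## Numerical choices and problem sizes

Signal-track queries use exclusive-prefix-sum integrals, exact for any
interval; uncovered bp contribute 0. Log of zero means is floored at the
pseudocount. The acceptance/recovery suites run at desk scale: oracle
equivalence on 10³ genes × 10³ loops, hypergeometric exhaustive enumeration
to N = 60, type-I calibration over 500 null datasets × 200 permutations,
insulation and bootstrap nulls with 10–100 shuffles, and OLS recovery on
the 2,000-gene default cohort — the full test suite runs in about a minute
on one CPU.

## Known limitations

- The strict-`>` permutation p is anti-conservative for heavily tied
  statistics (see above); use `conservative=True` for small interval sets.
- `IntervalIndex.overlapping` is O(candidates) per query; adequate for
  ~10⁴-interval sets, not engineered for millions of intervals.
- The odds-ratio formula is a ratio of proportions (as defined), not a true
  odds ratio; the Fisher test is reported alongside for inference.
- The insulation score drops loops without flank genes; in very gene-poor
  regions the comparison uses only the gene-containing subset of loops.
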