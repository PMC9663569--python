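"""Comparison of two factor-dependent loop sets.

The overlap score of a query loop against a reference loop set is
(number of overlapping bp) / (bp size of the query loop), computed on loop
*spans* (outer anchor coordinates); when a query intersects several
reference loops the maximum score is used.  A score of 1 means 100% overlap
or engulfment of the query within a reference span, 0 means no overlap.
Loops are also classified by anchor content (promoter and/or enhancer) and
classes compared between factors with a ratio-of-proportions plus Fisher's
exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import (
    Genome,
    GenomicInterval,
    IntervalIndex,
    Loop,
    merge_intervals,
    overlap_bp,
    shuffle_loops,
)
from .io import RunConfig

__all__ = [
    "overlap_score",
    "score_distribution",
    "fraction_overlapping",
    "merge_loop_anchors",
    "LoopCategory",
    "classify_loop",
    "classify_loops",
    "promoter_regions",
    "enhancer_regions",
    "category_odds_ratio",
    "category_table",
]

CATEGORIES = (
    "promoter-enhancer",
    "promoter-promoter",
    "enhancer-enhancer",
    "promoter-only",
    "enhancer-only",
    "neither",
)


def overlap_score(query: Loop, reference: Sequence[Loop]) -> float:
    """Max over reference loops of span-overlap bp / query span length."""
    span = query.span
    if span.length <= 0:
        raise ValueError("query loop has empty span")
    best = 0.0
    for ref in reference:
        ov = overlap_bp(span, ref.span)
        if ov:
            best = max(best, ov / span.length)
    return best


def score_distribution(
    queries: Sequence[Loop],
    reference: Sequence[Loop],
    genome: Genome,
    seed,
) -> dict:
    """Observed per-query overlap scores vs scores of shuffled queries.

    The same scoring is repeated for randomly shuffled query loops and the
    two distributions compared with a two-sided Wilcoxon rank-sum test.
    """
    observed = np.array([overlap_score(q, reference) for q in queries])
    shuffled_loops_ = shuffle_loops(queries, genome, seed)
    shuffled = np.array([overlap_score(q, reference) for q in shuffled_loops_])
    if observed.size and shuffled.size:
        stat, p = stats.ranksums(observed, shuffled)
    else:
        stat, p = np.nan, np.nan
    return {
        "observed": observed,
        "shuffled": shuffled,
        "statistic": float(stat),
        "pvalue": float(p),
    }


def fraction_overlapping(loopsA: Sequence[Loop], loopsB: Sequence[Loop]) -> float:
    """Fraction of A loops whose span overlaps >= 1 bp with any B span."""
    if not loopsA:
        return 0.0
    index = IntervalIndex([lp.span for lp in loopsB])
    n = sum(
        1
        for lp in loopsA
        if index.any_overlap(lp.chrom, lp.span.start, lp.span.end)
    )
    return n / len(loopsA)


def merge_loop_anchors(loops: Sequence[Loop]) -> list[GenomicInterval]:
    """Anchors from both sides of loops merged into non-overlapping unique
    regions, sorted."""
    anchors: list[GenomicInterval] = []
    for lp in loops:
        anchors.append(lp.left_anchor)
        anchors.append(lp.right_anchor)
    return merge_intervals(anchors)


def promoter_regions(
    genes: Sequence[GenomicInterval], config: RunConfig | None = None
) -> list[GenomicInterval]:
    """Promoter window per gene: TSS extended by ``promoter_extension``
    downstream (into the gene) on the coding strand.

    For an unstranded gene the window extends from the interval start, as on
    the plus strand.
    """
    config = config or RunConfig()
    ext = config.promoter_extension
    out = []
    for g in genes:
        if g.strand == "-":
            tss = g.end  # TSS at the right edge; window extends leftwards
            start, end = max(0, tss - ext), tss
        else:
            tss = g.start
            start, end = tss, tss + ext
        out.append(GenomicInterval(g.chrom, start, end, strand=g.strand, name=g.name))
    return out


def enhancer_regions(
    enhancers: Sequence[GenomicInterval], config: RunConfig | None = None
) -> list[GenomicInterval]:
    """Enhancer windows: center of each record extended ``enhancer_flank``
    bp upstream and downstream."""
    config = config or RunConfig()
    flank = config.enhancer_flank
    out = []
    for e in enhancers:
        center = (e.start + e.end) // 2
        out.append(
            GenomicInterval(
                e.chrom, max(0, center - flank), center + flank, name=e.name
            )
        )
    return out


@dataclass(frozen=True)
class LoopCategory:
    """Anchor-content flags of a loop and the derived category."""

    has_promoter_left: bool
    has_promoter_right: bool
    has_enhancer_left: bool
    has_enhancer_right: bool

    @property
    def category(self) -> str:
        p = self.has_promoter_left or self.has_promoter_right
        e = self.has_enhancer_left or self.has_enhancer_right
        if p and e:
            # promoter and enhancer on opposite anchors -> regulatory pairing;
            # same anchor only -> decided by what the other anchor carries
            pe = (self.has_promoter_left and self.has_enhancer_right) or (
                self.has_promoter_right and self.has_enhancer_left
            )
            if pe:
                return "promoter-enhancer"
            if self.has_promoter_left and self.has_promoter_right:
                return "promoter-promoter"
            if self.has_enhancer_left and self.has_enhancer_right:
                return "enhancer-enhancer"
            # promoter and enhancer share one anchor, the other is empty
            return "promoter-enhancer"
        if self.has_promoter_left and self.has_promoter_right:
            return "promoter-promoter"
        if self.has_enhancer_left and self.has_enhancer_right:
            return "enhancer-enhancer"
        if p:
            return "promoter-only"
        if e:
            return "enhancer-only"
        return "neither"


def classify_loop(
    loop: Loop,
    enhancers: Sequence[GenomicInterval] | IntervalIndex,
    genes: Sequence[GenomicInterval] | IntervalIndex,
    config: RunConfig | None = None,
) -> LoopCategory:
    """Classify one loop by promoter/enhancer presence in its anchors.

    ``genes`` are raw gene models (promoter windows are derived here) unless
    an IntervalIndex of pre-built promoter windows is passed; likewise
    ``enhancers`` are raw records extended around their centers unless
    pre-indexed.
    """
    config = config or RunConfig()
    if not isinstance(genes, IntervalIndex):
        genes = IntervalIndex(promoter_regions(genes, config))
    if not isinstance(enhancers, IntervalIndex):
        enhancers = IntervalIndex(enhancer_regions(enhancers, config))
    la, ra = loop.left_anchor, loop.right_anchor
    return LoopCategory(
        has_promoter_left=genes.any_overlap(la.chrom, la.start, la.end),
        has_promoter_right=genes.any_overlap(ra.chrom, ra.start, ra.end),
        has_enhancer_left=enhancers.any_overlap(la.chrom, la.start, la.end),
        has_enhancer_right=enhancers.any_overlap(ra.chrom, ra.start, ra.end),
    )


def classify_loops(
    loops: Sequence[Loop],
    enhancers: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    config = config or RunConfig()
    prom_idx = IntervalIndex(promoter_regions(genes, config))
    enh_idx = IntervalIndex(enhancer_regions(enhancers, config))
    rows = []
    for i, lp in enumerate(loops):
        cat = classify_loop(lp, enh_idx, prom_idx, config)
        rows.append(
            {
                "loop": lp.name or f"loop_{i}",
                "chrom": lp.chrom,
                "span_start": lp.span.start,
                "span_end": lp.span.end,
                "has_promoter_left": cat.has_promoter_left,
                "has_promoter_right": cat.has_promoter_right,
                "has_enhancer_left": cat.has_enhancer_left,
                "has_enhancer_right": cat.has_enhancer_right,
                "category": cat.category,
            }
        )
    return pd.DataFrame(rows)


def category_odds_ratio(
    f1_in_cat: int, f1_total: int, f2_in_cat: int, f2_total: int
) -> dict:
    """Ratio of in-category proportions (factor2 over factor1) plus a
    two-sided Fisher exact p from the 2x2 table."""
    if f1_total <= 0 or f2_total <= 0:
        raise ValueError("loop totals must be positive")
    infinite = f1_in_cat == 0
    if infinite:
        ratio = np.inf
    else:
        ratio = (f2_in_cat / f2_total) / (f1_in_cat / f1_total)
    table = [
        [f2_in_cat, f2_total - f2_in_cat],
        [f1_in_cat, f1_total - f1_in_cat],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {"ratio": float(ratio), "pvalue": float(p), "infinite": infinite}


def category_table(
    loops1: Sequence[Loop],
    loops2: Sequence[Loop],
    enhancers: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-category comparison of two loop sets with BH-adjusted Fisher p."""
    config = config or RunConfig()
    df1 = classify_loops(loops1, enhancers, genes, config)
    df2 = classify_loops(loops2, enhancers, genes, config)
    n1, n2 = len(loops1), len(loops2)
    rows = []
    for cat in CATEGORIES:
        k1 = int((df1["category"] == cat).sum()) if n1 else 0
        k2 = int((df2["category"] == cat).sum()) if n2 else 0
        res = category_odds_ratio(k1, n1, k2, n2)
        rows.append(
            {
                "category": cat,
                "factor1_in_category": k1,
                "factor1_total": n1,
                "factor2_in_category": k2,
                "factor2_total": n2,
                "ratio": res["ratio"],
                "infinite": res["infinite"],
                "pvalue": res["pvalue"],
            }
        )
    out = pd.DataFrame(rows)
    out["pvalue_bh"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out
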