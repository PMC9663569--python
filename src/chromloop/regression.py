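"""Linear model of expression change from binding, accessibility and loops.

Every gene is described by 7 ordered bins in transcription orientation:
upstream [-4 kbp, -2 kbp), promoter [-2 kbp, TSS), three equal gene-body
bins, [TTS, +2 kbp) and [+2 kbp, +4 kbp).  Per bin the model uses a binary
binding-occupancy bit and an accessibility-difference term
log10[(KO reads + 0.01) / (WT reads + 0.01)] * log2(total reads + 1); per
gene it adds loop-anchor counts (two factors), enhancer-link counts and
differential-loop counts.  Expression log2 fold change is regressed on all
predictors by ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .intervals import Genome, GenomicInterval, IntervalIndex, Loop
from .io import ExpressionRecord, SignalTrack
from .linking import _AnchorIndex, anchor_gene_count

logger = logging.getLogger("chromloop")

__all__ = [
    "GeneBinSet",
    "make_gene_bins",
    "occupancy_bits",
    "atac_diff",
    "enhancer_link_count",
    "assemble_matrix",
    "fit_expression_model",
]

BIN_NAMES = (
    "upstream",
    "promoter",
    "body1",
    "body2",
    "body3",
    "downstream1",
    "downstream2",
)

FLANK_NEAR = 2000
FLANK_FAR = 4000


@dataclass(frozen=True)
class GeneBinSet:
    """The 7 ordered bins of one gene, 5' to 3' in transcription sense.

    ``clipped`` flags that a flanking bin was truncated (or emptied) at a
    chromosome end; an emptied bin is stored as None.
    """

    gene_id: str
    chrom: str
    strand: str
    bins: tuple[tuple[int, int] | None, ...]
    clipped: bool

    def __post_init__(self) -> None:
        if len(self.bins) != 7:
            raise ValueError("a gene bin set has exactly 7 bins")


def make_gene_bins(
    gene: GenomicInterval, genome: Genome | None = None
) -> GeneBinSet:
    """Build the 7-bin scheme for one gene.

    The gene body is split into three near-equal bins with the remainder bp
    in the 3'-most body bin.  Minus-strand genes are mirrored so bin 1 is
    always the most-upstream.  Flanks are clipped at chromosome ends (and
    dropped when fully outside) with ``clipped`` set.
    """
    if gene.length < 3:
        raise ValueError(f"gene {gene.name!r} shorter than 3 bp cannot be binned")
    s, e = gene.start, gene.end
    w = gene.length // 3
    if gene.strand == "-":
        # transcription right-to-left: TSS at e, TTS at s
        body = [(e - w, e), (e - 2 * w, e - w), (s, e - 2 * w)]
        raw = [
            (e + FLANK_NEAR, e + FLANK_FAR),  # upstream -4k..-2k
            (e, e + FLANK_NEAR),  # promoter -2k..TSS
            *body,
            (s - FLANK_NEAR, s),  # TTS..+2k
            (s - FLANK_FAR, s - FLANK_NEAR),  # +2k..+4k
        ]
    else:
        body = [(s, s + w), (s + w, s + 2 * w), (s + 2 * w, e)]
        raw = [
            (s - FLANK_FAR, s - FLANK_NEAR),  # upstream -4k..-2k
            (s - FLANK_NEAR, s),  # promoter -2k..TSS
            *body,
            (e, e + FLANK_NEAR),  # TTS..+2k
            (e + FLANK_NEAR, e + FLANK_FAR),  # +2k..+4k
        ]
    chrom_len = genome.size(gene.chrom) if genome is not None else None
    clipped = False
    bins: list[tuple[int, int] | None] = []
    for lo, hi in raw:
        clo = max(0, lo)
        chi = min(chrom_len, hi) if chrom_len is not None else hi
        if (clo, chi) != (lo, hi):
            clipped = True
        bins.append((clo, chi) if clo < chi else None)
        if clo >= chi:
            clipped = True
    return GeneBinSet(
        gene_id=gene.name,
        chrom=gene.chrom,
        strand=gene.strand,
        bins=tuple(bins),
        clipped=clipped,
    )


def occupancy_bits(
    bins: GeneBinSet, peaks: Sequence[GenomicInterval] | IntervalIndex
) -> np.ndarray:
    """0/1 per bin: 1 iff any peak overlaps the bin by >= 1 bp."""
    if not isinstance(peaks, IntervalIndex):
        peaks = IntervalIndex(peaks)
    bits = np.zeros(7, dtype=int)
    for i, b in enumerate(bins.bins):
        if b is not None and peaks.any_overlap(bins.chrom, b[0], b[1]):
            bits[i] = 1
    return bits


def atac_diff(ko_reads: float, wt_reads: float, total_reads: float) -> float:
    """Accessibility-difference predictor for one bin:
    log10[(KO + 0.01) / (WT + 0.01)] * log2(total + 1)."""
    if ko_reads < 0 or wt_reads < 0 or total_reads < 0:
        raise ValueError("read values must be non-negative")
    return float(
        np.log10((ko_reads + 0.01) / (wt_reads + 0.01)) * np.log2(total_reads + 1)
    )


def enhancer_link_count(
    gene: GenomicInterval,
    loops: Sequence[Loop],
    enhancers: Sequence[GenomicInterval] | IntervalIndex,
) -> int:
    """Loops where one anchor overlaps the gene and the other an enhancer."""
    if not isinstance(enhancers, IntervalIndex):
        enhancers = IntervalIndex(enhancers)
    count = 0
    for lp in loops:
        la, ra = lp.left_anchor, lp.right_anchor
        gene_left = la.chrom == gene.chrom and la.start < gene.end and la.end > gene.start
        gene_right = ra.chrom == gene.chrom and ra.start < gene.end and ra.end > gene.start
        if gene_left and enhancers.any_overlap(ra.chrom, ra.start, ra.end):
            count += 1
        elif gene_right and enhancers.any_overlap(la.chrom, la.start, la.end):
            count += 1
    return count


def _bin_reads(track: SignalTrack, chrom: str, b: tuple[int, int] | None) -> float:
    """Mean track value over a bin (0 for a clipped-away bin).

    The mean (not the sum) is used so the predictor is invariant to bin
    width, which differs between gene bodies.
    """
    if b is None:
        return 0.0
    return float(track.mean(chrom, b[0], b[1]))


def assemble_matrix(
    genes: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    loops_by_factor: Mapping[str, Sequence[Loop]],
    enhancers: Sequence[GenomicInterval],
    over_loops: Sequence[Loop],
    under_loops: Sequence[Loop],
    track_wt: SignalTrack,
    track_ko: SignalTrack,
    expression: Mapping[str, ExpressionRecord],
    genome: Genome | None = None,
) -> pd.DataFrame:
    """Per-gene predictor matrix plus the log2FC response column.

    ``loops_by_factor`` maps factor names (e.g. "satb1", "ctcf") to loop
    sets; per factor the matrix gets an anchor-count column, and the first
    factor additionally an enhancer-link-count column.  Genes without an
    expression record are dropped and logged.
    """
    if genome is not None:
        for g in genes:
            if g.end > genome.size(g.chrom):
                raise ValueError(
                    f"gene {g.name!r} extends beyond chromosome {g.chrom}: "
                    "inconsistent genome build"
                )
    peak_idx = IntervalIndex(peaks)
    factor_idx = {f: _AnchorIndex(lps) for f, lps in loops_by_factor.items()}
    over_idx = _AnchorIndex(over_loops)
    under_idx = _AnchorIndex(under_loops)
    first_factor = next(iter(loops_by_factor), None)

    rows = []
    n_dropped = 0
    for g in genes:
        rec = expression.get(g.name)
        if rec is None:
            n_dropped += 1
            continue
        bins = make_gene_bins(g, genome)
        bits = occupancy_bits(bins, peak_idx)
        row: dict[str, float] = {"gene_id": g.name}
        for i, name in enumerate(BIN_NAMES):
            row[f"occ_{name}"] = int(bits[i])
        for i, name in enumerate(BIN_NAMES):
            wt = _bin_reads(track_wt, g.chrom, bins.bins[i])
            ko = _bin_reads(track_ko, g.chrom, bins.bins[i])
            row[f"atac_{name}"] = atac_diff(ko, wt, ko + wt)
        for f, idx in factor_idx.items():
            row[f"{f}_loop_count"] = anchor_gene_count(g, idx)
        if first_factor is not None:
            row[f"{first_factor}_enhancer_link_count"] = enhancer_link_count(
                g, loops_by_factor[first_factor], enhancers
            )
        row["h3k27ac_over_count"] = anchor_gene_count(g, over_idx)
        row["h3k27ac_under_count"] = anchor_gene_count(g, under_idx)
        row["log2fc"] = rec.log2fc
        rows.append(row)
    if n_dropped:
        logger.warning("dropped %d genes without expression records", n_dropped)
    return pd.DataFrame(rows)


def fit_expression_model(
    matrix: pd.DataFrame, standardize: bool = False
) -> dict:
    """Ordinary least squares of log2FC on all predictors, with intercept.

    Returns the full coefficient table (estimate, SE, t, p) and R^2.  A
    rank-deficient design raises an error naming the collinear columns.
    """
    predictors = [c for c in matrix.columns if c not in ("gene_id", "log2fc")]
    X = matrix[predictors].astype(float)
    y = matrix["log2fc"].astype(float)
    if len(matrix) <= len(predictors) + 1:
        raise ValueError("need more genes than predictors")
    if standardize:
        sd = X.std(ddof=0)
        X = (X - X.mean()) / sd.replace(0, 1.0)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.values)
    if rank < Xc.shape[1]:
        bad = _collinear_columns(Xc)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, Xc).fit()
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "stderr": fit.bse,
            "tvalue": fit.tvalues,
            "pvalue": fit.pvalues,
        }
    )
    with np.errstate(invalid="ignore"):  # constant response yields 0/0
        r2 = float(fit.rsquared)
    if not np.isfinite(r2):  # no variance to explain
        r2 = 0.0
    return {
        "coefficients": table,
        "r_squared": r2,
        "n": int(fit.nobs),
        "fit": fit,
    }


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (greedy diagnosis)."""
    bad = []
    cols = list(X.columns)
    base_rank = np.linalg.matrix_rank(X.values)
    for c in cols:
        rest = X.drop(columns=[c])
        if np.linalg.matrix_rank(rest.values) == base_rank:
            bad.append(c)
    return bad
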