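"""Transcriptional insulation, permutation enrichment and accessibility tests.

The transcriptional insulation score of a loop is the absolute difference
between the mean expression of genes inside the loop span and the mean
expression of genes found in same-size regions immediately upstream and
downstream, where per-gene expression is log10(counts / gene length + 0.01).
Observed scores are compared to scores of randomly shuffled loops
(re-shuffled until they contain at least one gene).

Overlap enrichment between two interval sets uses a shuffling null with
p = (number of permutations whose overlap exceeds the observed) / n, and
accessibility at binding sites uses a bootstrap over shuffled sites with
p = (number of permuted mean values bigger than the real mean) / n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import (
    Genome,
    GenomicInterval,
    IntervalIndex,
    Loop,
    merge_intervals,
    shuffle_intervals,
    shuffle_loops,
)
from .io import RunConfig, SignalTrack

logger = logging.getLogger("chromloop")

__all__ = [
    "expression_score",
    "InsulationResult",
    "insulation_score",
    "insulation_null",
    "permutation_overlap_test",
    "peak_accessibility_test",
    "low_accessibility_subset",
    "tss_profile",
    "gene_body_profile",
]


def expression_score(counts: float, gene_length: int, pseudocount: float = 0.01) -> float:
    """Length-normalized log expression: log10(counts / length + pseudocount)."""
    if counts < 0:
        raise ValueError("counts must be non-negative")
    if gene_length <= 0:
        raise ValueError("gene length must be positive")
    return float(np.log10(counts / gene_length + pseudocount))


@dataclass
class InsulationResult:
    """Insulation of one loop: |mean expression inside - mean in flanks|."""

    loop: str
    inside_mean: float
    flank_mean: float
    score: float
    n_inside: int
    n_flank: int
    valid: bool


def insulation_score(
    loop: Loop,
    genes: Sequence[GenomicInterval] | IntervalIndex,
    expression: Mapping[str, float],
    genome: Genome | None = None,
    _scores: np.ndarray | None = None,
) -> InsulationResult:
    """Insulation of one loop against its equally-sized flanking windows.

    ``expression`` maps gene name to its (already log-transformed) expression
    score.  Genes are assigned to a region by >= 1 bp overlap of the gene
    span.  Flank windows are clipped at chromosome ends when a genome is
    given.  A result with an empty inside or flank gene set is flagged
    invalid.
    """
    if not isinstance(genes, IntervalIndex):
        genes = IntervalIndex(genes)
    if _scores is None:
        _scores = np.array(
            [expression.get(g.name, np.nan) for g in genes.items]
        )
    span = loop.span
    L = span.length
    chrom_len = genome.size(span.chrom) if genome is not None else None

    left_start = max(0, span.start - L)
    right_end = span.end + L
    if chrom_len is not None:
        right_end = min(chrom_len, right_end)

    inside_idx = genes.overlapping(span.chrom, span.start, span.end)
    flank_idx: list[int] = []
    if left_start < span.start:
        flank_idx.extend(genes.overlapping(span.chrom, left_start, span.start))
    if span.end < right_end:
        flank_idx.extend(genes.overlapping(span.chrom, span.end, right_end))
    # a gene straddling a boundary may appear in both flanks; keep unique,
    # and exclude inside genes from the flank pool
    flank_idx = sorted(set(flank_idx) - set(inside_idx.tolist()))

    inside = _scores[inside_idx]
    flank = _scores[np.array(flank_idx, dtype=int)] if flank_idx else np.array([])
    inside = inside[~np.isnan(inside)]
    flank = flank[~np.isnan(flank)]
    valid = inside.size > 0 and flank.size > 0
    inside_mean = float(inside.mean()) if inside.size else np.nan
    flank_mean = float(flank.mean()) if flank.size else np.nan
    score = abs(inside_mean - flank_mean) if valid else np.nan
    return InsulationResult(
        loop=loop.name,
        inside_mean=inside_mean,
        flank_mean=flank_mean,
        score=score,
        n_inside=int(inside.size),
        n_flank=int(flank.size),
        valid=valid,
    )


def insulation_null(
    loops: Sequence[Loop],
    genes: Sequence[GenomicInterval],
    expression: Mapping[str, float],
    genome: Genome,
    seed,
    n: int = 100,
    max_attempts: int = 1000,
) -> dict:
    """Observed insulation scores vs a shuffled-loop null.

    Each shuffle round re-places every loop; a shuffled loop containing no
    gene is re-drawn (up to ``max_attempts``, then dropped with a warning).
    Returns the pooled null scores and a two-sided rank-sum p comparing
    observed and null score distributions.
    """
    if n < 1:
        raise ValueError("need at least one shuffle round")
    index = IntervalIndex(genes)
    scores_arr = np.array([expression.get(g.name, np.nan) for g in index.items])
    if not any(
        index.any_overlap(c, 0, genome.size(c)) for c in genome.names
    ):
        raise ValueError("no genes on the given genome")
    rng = np.random.default_rng(seed)

    observed = [
        insulation_score(lp, index, expression, genome, _scores=scores_arr)
        for lp in loops
    ]
    obs_scores = np.array([r.score for r in observed if r.valid])

    null_scores: list[float] = []
    n_dropped = 0
    for _ in range(n):
        shuffled = shuffle_loops(loops, genome, rng)
        for lp in shuffled:
            attempts = 0
            while not index.any_overlap(lp.chrom, lp.span.start, lp.span.end):
                attempts += 1
                if attempts >= max_attempts:
                    lp = None
                    break
                lp = shuffle_loops([lp], genome, rng)[0]
            if lp is None:
                n_dropped += 1
                continue
            res = insulation_score(lp, index, expression, genome, _scores=scores_arr)
            if res.valid:
                null_scores.append(res.score)
    if n_dropped:
        logger.warning(
            "dropped %d shuffled loops that never contained a gene", n_dropped
        )
    null_arr = np.array(null_scores)
    if obs_scores.size and null_arr.size:
        _, p = stats.ranksums(obs_scores, null_arr)
    else:
        p = np.nan
    return {
        "observed": observed,
        "observed_scores": obs_scores,
        "null_scores": null_arr,
        "pvalue": float(p),
        "n_dropped": n_dropped,
    }


def _count_overlapping(
    chroms: Sequence[str],
    starts: np.ndarray,
    ends: np.ndarray,
    merged_b: dict[str, tuple[np.ndarray, np.ndarray]],
) -> int:
    """Number of intervals (given as parallel arrays) overlapping merged B."""
    count = 0
    for c, s, e in zip(chroms, starts, ends):
        entry = merged_b.get(c)
        if entry is None:
            continue
        bs, be = entry
        i = np.searchsorted(be, s, side="right")
        if i < bs.size and bs[i] < e:
            count += 1
    return count


def permutation_overlap_test(
    setA: Sequence[GenomicInterval],
    setB: Sequence[GenomicInterval],
    genome: Genome,
    seed,
    n: int = 1000,
    conservative: bool = False,
    same_chromosome: bool = False,
) -> dict:
    """Shuffling-based overlap enrichment of interval set A against set B.

    Observed statistic: number of A intervals overlapping >= 1 B interval.
    A is shuffled ``n`` times; enrichment = observed / mean null count and
    p = (number of rounds whose null count is strictly higher than the
    observed) / n.  ``conservative`` switches to (k+1)/(n+1) smoothing.
    """
    if n < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    merged = merge_intervals(setB)
    merged_b: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merged:
        merged_b.setdefault(iv.chrom, ([], []))
    for iv in merged:
        merged_b[iv.chrom][0].append(iv.start)
        merged_b[iv.chrom][1].append(iv.end)
    merged_b = {
        c: (np.array(v[0]), np.array(v[1])) for c, v in merged_b.items()
    }

    a_chroms = [iv.chrom for iv in setA]
    a_starts = np.array([iv.start for iv in setA])
    a_ends = np.array([iv.end for iv in setA])
    observed = _count_overlapping(a_chroms, a_starts, a_ends, merged_b)

    lengths = a_ends - a_starts
    # pre-compute placement capacities once; vectorize the n rounds
    names_by_len: dict[int, tuple[list[str], np.ndarray]] = {}
    null_counts = np.empty(n, dtype=int)
    for r in range(n):
        if same_chromosome:
            chroms = a_chroms
            caps = np.array([genome.size(c) for c in a_chroms]) - lengths + 1
            if np.any(caps < 1):
                raise ValueError("an interval does not fit on its chromosome")
            starts = rng.integers(0, caps)
        else:
            chroms = []
            starts = np.empty(len(setA), dtype=np.int64)
            for i, L in enumerate(lengths):
                key = int(L)
                if key not in names_by_len:
                    nm = [c for c, s in genome.chrom_sizes.items() if s >= key]
                    if not nm:
                        raise ValueError(
                            f"interval of length {key} longer than every chromosome"
                        )
                    cp = np.array([genome.size(c) - key + 1 for c in nm], dtype=float)
                    names_by_len[key] = (nm, cp / cp.sum(), cp)
                nm, probs, cp = names_by_len[key]
                j = rng.choice(len(nm), p=probs)
                chroms.append(nm[j])
                starts[i] = rng.integers(0, int(cp[j]))
        null_counts[r] = _count_overlapping(
            chroms, starts, starts + lengths, merged_b
        )

    mean_null = float(null_counts.mean())
    k = int((null_counts > observed).sum())
    p = (k + 1) / (n + 1) if conservative else k / n
    logger.info(
        "permutation overlap test: observed=%d mean_null=%.2f n=%d p=%.4g",
        observed,
        mean_null,
        n,
        p,
    )
    return {
        "observed": observed,
        "mean_null": mean_null,
        "null_counts": null_counts,
        "enrichment": observed / mean_null if mean_null > 0 else np.inf,
        "pvalue": float(p),
        "n": n,
    }


def _peak_windows(
    peaks: Sequence[GenomicInterval], flank: int
) -> list[GenomicInterval]:
    """Center each peak and extend ``flank`` bp up- and downstream.

    A peak of width 1 at position c yields [c - flank, c + flank + 1): the
    window always includes the center base itself.
    """
    out = []
    for p in peaks:
        center = (p.start + p.end) // 2
        out.append(
            GenomicInterval(p.chrom, max(0, center - flank), center + flank + 1)
        )
    return out


def _window_scores(
    windows: Sequence[GenomicInterval],
    track: SignalTrack,
    pseudocount: float,
) -> np.ndarray:
    """log10 of the mean track value per window, floored at ``pseudocount``."""
    means = np.array(
        [track.mean(w.chrom, w.start, w.end) for w in windows], dtype=float
    )
    return np.log10(np.maximum(means, pseudocount))


def peak_accessibility_test(
    peaks: Sequence[GenomicInterval],
    track: SignalTrack,
    genome: Genome,
    seed,
    n: int = 100,
    config: RunConfig | None = None,
) -> dict:
    """Bootstrap test of accessibility at binding sites vs shuffled sites.

    Each site is centered and extended ``peak_flank`` bp both ways; the
    per-site score is the log10 mean track value over the window.  The
    windows are shuffled across the genome ``n`` times and
    p = (number of permuted mean values bigger than the real mean) / n.
    """
    if not peaks:
        raise ValueError("no peaks given")
    if track.is_empty():
        raise ValueError("signal track is empty")
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    windows = _peak_windows(peaks, config.peak_flank)
    scores = _window_scores(windows, track, config.pseudocount_atac)
    real_mean = float(scores.mean())
    null_means = np.empty(n)
    for r in range(n):
        shuffled = shuffle_intervals(windows, genome, rng)
        null_means[r] = _window_scores(
            shuffled, track, config.pseudocount_atac
        ).mean()
    p = float((null_means > real_mean).sum() / n)
    logger.info(
        "peak accessibility bootstrap: real_mean=%.4f n=%d p=%.4g", real_mean, n, p
    )
    return {
        "scores": scores,
        "real_mean": real_mean,
        "null_means": null_means,
        "pvalue": p,
        "n": n,
    }


def low_accessibility_subset(
    peaks: Sequence[GenomicInterval],
    track: SignalTrack,
    genome: Genome,
    seed,
    n: int = 10,
    config: RunConfig | None = None,
) -> list[GenomicInterval]:
    """Binding sites whose accessibility is below the shuffled-site average.

    The cutoff is the average of the per-round mean log10 accessibility
    scores over ``n`` random shuffles of the centered/extended sites; sites
    scoring strictly below the cutoff are returned.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    windows = _peak_windows(peaks, config.peak_flank)
    scores = _window_scores(windows, track, config.pseudocount_atac)
    round_means = np.empty(n)
    for r in range(n):
        shuffled = shuffle_intervals(windows, genome, rng)
        round_means[r] = _window_scores(
            shuffled, track, config.pseudocount_atac
        ).mean()
    cutoff = float(round_means.mean())
    return [p for p, s in zip(peaks, scores) if s < cutoff]


def tss_profile(
    genes: Sequence[GenomicInterval],
    track_wt: SignalTrack,
    track_ko: SignalTrack,
    config: RunConfig | None = None,
) -> np.ndarray:
    """Mean per-bp log2 accessibility fold change (KO vs WT) around TSSs.

    Each TSS is centered and extended ``tss_flank`` bp up- and downstream;
    minus-strand genes are flipped so positive offsets point downstream of
    transcription.  Returns a vector of length 2 * tss_flank + 1 for offsets
    -flank .. +flank.
    """
    if track_wt.is_empty() or track_ko.is_empty():
        raise ValueError("signal tracks must be non-empty")
    config = config or RunConfig()
    flank = config.tss_flank
    pc = config.pseudocount_atac
    width = 2 * flank + 1
    acc = np.zeros(width)
    n_used = 0
    for g in genes:
        tss = g.end - 1 if g.strand == "-" else g.start
        start = tss - flank
        if start < 0:
            continue
        wt = track_wt.values(g.chrom, start, start + width)
        ko = track_ko.values(g.chrom, start, start + width)
        lfc = np.log2((ko + pc) / (wt + pc))
        if g.strand == "-":
            lfc = lfc[::-1]
        acc += lfc
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable genes for the TSS profile")
    return acc / n_used


def gene_body_profile(
    genes: Sequence[GenomicInterval],
    track_wt: SignalTrack,
    track_ko: SignalTrack,
    n_bins: int = 50,
    flank_bins: int = 10,
    flank_length: int = 2000,
    config: RunConfig | None = None,
) -> np.ndarray:
    """Binned mean log2 accessibility fold change across scaled gene bodies.

    Each gene body is split into ``n_bins`` equal bins (remainder bp to the
    last bin); the up- and downstream ``flank_length`` regions into
    ``flank_bins`` fixed-width bins each.  Orientation is strand-aware.
    Genes shorter than ``n_bins`` bp are skipped with a warning.  Returns a
    vector of length n_bins + 2 * flank_bins, 5' flank first.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    config = config or RunConfig()
    pc = config.pseudocount_atac
    total = n_bins + 2 * flank_bins
    acc = np.zeros(total)
    n_used = 0
    n_skipped = 0

    def bin_edges(start: int, end: int, k: int) -> np.ndarray:
        w = (end - start) // k
        edges = start + w * np.arange(k + 1)
        edges[-1] = end  # remainder to the last bin
        return edges

    for g in genes:
        if g.length < n_bins:
            n_skipped += 1
            continue
        left = (g.start - flank_length, g.start)
        right = (g.end, g.end + flank_length)
        if left[0] < 0:
            n_skipped += 1
            continue
        edges = []
        if flank_bins:
            edges.append(bin_edges(left[0], left[1], flank_bins))
        edges.append(bin_edges(g.start, g.end, n_bins))
        if flank_bins:
            edges.append(bin_edges(right[0], right[1], flank_bins))
        vals = []
        for eds in edges:
            wt = track_wt.mean(g.chrom, eds[:-1], eds[1:])
            ko = track_ko.mean(g.chrom, eds[:-1], eds[1:])
            vals.append(np.log2((np.asarray(ko) + pc) / (np.asarray(wt) + pc)))
        lfc = np.concatenate(vals)
        if g.strand == "-":
            lfc = lfc[::-1]
        acc += lfc
        n_used += 1
    if n_skipped:
        logger.warning("gene body profile: skipped %d genes", n_skipped)
    if n_used == 0:
        raise ValueError("no usable genes for the gene-body profile")
    return acc / n_used
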