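"""Synthetic cohort generator with planted, recoverable effects.

Emulates the inputs of the loop-analysis pipeline at desk scale: a small
multi-chromosome genome, non-overlapping stranded gene models, a nested
two-factor cis loop architecture (small factor-A loops engulfed in larger
factor-B loops with a controllable fraction), enhancers linked to loop
anchors, binding sites with elevated accessibility, WT/KO signal tracks
with a planted accessibility drop at sites, negative-binomial expression
counts with loop-linked expression effects, and differential (over/under-
interacting) loops whose per-gene linking score is rank-coupled to
expression change through a Gaussian copula.

Every planted assignment is recorded in a truth table so each downstream
statistic has ground truth.  A fixed seed regenerates a byte-identical
bundle.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Genome, GenomicInterval, IntervalIndex, Loop
from .io import (
    ExpressionRecord,
    SignalTrack,
    write_bed,
    write_bedpe_loops,
    write_chrom_sizes,
    write_expression_table,
)
from .linking import _AnchorIndex

__all__ = ["SimulationConfig", "SyntheticBundle", "generate_counts", "generate_dataset"]


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Effect directions mirror the modelled biology: the knockout loses
    accessibility at binding sites (``ko_accessibility_drop`` < 1) and genes
    in factor-A loops are repressed (negative ``planted_log2fc_in_A_loops``
    per anchor hit).  ``linking_correlation`` is the target Spearman
    correlation between per-gene linking scores and expression log2FC.
    """

    seed: int = 42
    n_chromosomes: int = 8
    chrom_length: int = 50_000_000
    n_genes: int = 2000
    gene_length_meanlog: float = 8.0  # median ~3 kbp
    gene_length_sdlog: float = 0.6
    n_factorA_loops: int = 500
    a_span_range: tuple[int, int] = (20_000, 80_000)
    n_factorB_loops: int = 800
    b_span_range: tuple[int, int] = (100_000, 400_000)
    anchor_width: int = 5000
    engulfment_fraction: float = 0.9
    fraction_loops_to_enhancer: float = 0.5
    n_background_enhancers: int = 300
    enhancer_width: int = 200
    n_peaks: int = 500
    peak_width: int = 300
    fraction_peaks_at_genes: float = 0.5
    cold_site_fraction: float = 0.05
    cold_site_ratio: float = 0.2
    peak_signal_ratio: float = 10.0
    ko_accessibility_drop: float = 0.5
    background_signal: float = 1.0
    track_bin: int = 50
    planted_log2fc_in_A_loops: float = -0.5
    insulation_shift: float = 1.0
    expression_dispersion: float = 10.0
    expression_noise_sd: float = 0.8
    base_rate: float = 1.0  # expected WT counts per bp of gene
    linking_correlation: float = 0.6
    linking_score_sd: float = 2.5

    def __post_init__(self) -> None:
        for name in (
            "engulfment_fraction",
            "fraction_loops_to_enhancer",
            "cold_site_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not -1.0 <= self.linking_correlation <= 1.0:
            raise ValueError("linking_correlation must be in [-1, 1]")
        for name in ("n_genes", "n_factorA_loops", "n_factorB_loops", "n_peaks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.expression_dispersion <= 0:
            raise ValueError("expression_dispersion must be positive")
        if max(self.a_span_range) > self.chrom_length or max(
            self.b_span_range
        ) > self.chrom_length:
            raise ValueError("loop spans larger than chromosomes are infeasible")


@dataclass
class SyntheticBundle:
    """In-memory view of one generated dataset."""

    config: SimulationConfig
    genome: Genome
    genes: list[GenomicInterval]
    loops_a: list[Loop]
    loops_b: list[Loop]
    over_loops: list[Loop]
    under_loops: list[Loop]
    enhancers: list[GenomicInterval]
    peaks: list[GenomicInterval]
    track_wt: SignalTrack
    track_ko: SignalTrack
    expression: dict[str, ExpressionRecord]
    truth: pd.DataFrame


def generate_counts(mean, dispersion: float, seed) -> np.ndarray | int:
    """Negative-binomial draw(s) with variance = mean + mean^2 / dispersion."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_arr = np.atleast_1d(np.asarray(mean, dtype=float))
    if np.any(mean_arr < 0):
        raise ValueError("mean must be non-negative")
    p = dispersion / (dispersion + mean_arr)
    out = rng.negative_binomial(dispersion, p)
    if np.isscalar(mean) or np.ndim(mean) == 0:
        return int(out[0])
    return out


def _uniform_placement(
    rng: np.random.Generator, genome: Genome, length: int
) -> tuple[str, int]:
    names = [n for n, s in genome.chrom_sizes.items() if s >= length]
    if not names:
        raise ValueError(f"length {length} longer than every chromosome")
    caps = np.array([genome.size(n) - length + 1 for n in names], dtype=float)
    j = rng.choice(len(names), p=caps / caps.sum())
    return names[j], int(rng.integers(0, int(caps[j])))


def _place_genes(
    rng: np.random.Generator, genome: Genome, config: SimulationConfig
) -> list[GenomicInterval]:
    """Non-overlapping stranded genes with log-normal lengths."""
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    genes: list[GenomicInterval] = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        length = int(
            np.clip(
                rng.lognormal(config.gene_length_meanlog, config.gene_length_sdlog),
                200,
                50_000,
            )
        )
        for _ in range(1000):
            chrom, start = _uniform_placement(rng, genome, length)
            occ = occupied[chrom]
            k = bisect.bisect_left(occ, (start, start + length))
            ok = True
            if k > 0 and occ[k - 1][1] > start:
                ok = False
            if ok and k < len(occ) and occ[k][0] < start + length:
                ok = False
            if ok:
                occ.insert(k, (start, start + length))
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    GenomicInterval(
                        chrom,
                        start,
                        start + length,
                        strand=strand,
                        name=f"gene_{i:0{width}d}",
                    )
                )
                break
        else:
            raise ValueError("could not place genes without overlap; genome too small")
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _make_loop(
    chrom: str, start: int, span_len: int, anchor: int, name: str, label: str = "none"
) -> Loop:
    return Loop(
        GenomicInterval(chrom, start, start + anchor),
        GenomicInterval(chrom, start + span_len - anchor, start + span_len),
        label=label,
        name=name,
    )


def _place_loops_b(
    rng: np.random.Generator, genome: Genome, config: SimulationConfig
) -> list[Loop]:
    loops = []
    lo, hi = config.b_span_range
    for i in range(config.n_factorB_loops):
        span = int(rng.integers(lo, hi + 1))
        chrom, start = _uniform_placement(rng, genome, span)
        loops.append(_make_loop(chrom, start, span, config.anchor_width, f"B_{i:04d}"))
    return loops


def _place_loops_a(
    rng: np.random.Generator,
    genome: Genome,
    config: SimulationConfig,
    loops_b: Sequence[Loop],
) -> tuple[list[Loop], np.ndarray]:
    loops = []
    lo, hi = config.a_span_range
    engulfed = np.zeros(config.n_factorA_loops, dtype=bool)
    b_spans = [lp.span for lp in loops_b]
    for i in range(config.n_factorA_loops):
        span = int(rng.integers(lo, hi + 1))
        inside = rng.random() < config.engulfment_fraction
        if inside:
            hosts = [s for s in b_spans if s.length >= span]
            host = hosts[int(rng.integers(0, len(hosts)))]
            start = int(rng.integers(host.start, host.end - span + 1))
            chrom = host.chrom
            engulfed[i] = True
        else:
            chrom, start = _uniform_placement(rng, genome, span)
        loops.append(
            _make_loop(chrom, start, span, config.anchor_width, f"A_{i:04d}")
        )
    return loops, engulfed


def _place_peaks(
    rng: np.random.Generator,
    genome: Genome,
    config: SimulationConfig,
    genes: Sequence[GenomicInterval],
) -> tuple[list[GenomicInterval], np.ndarray]:
    """Binding sites, mutually separated so signal windows stay disjoint.

    A fraction of sites is placed in or near gene bodies (uniform over the
    gene span extended 4 kbp both ways), the rest uniformly on the genome.
    """
    sep = 2 * (config.peak_width + 600)
    placed: dict[str, list[int]] = {c: [] for c in genome.names}
    peaks = []
    for i in range(config.n_peaks):
        for _ in range(1000):
            if genes and rng.random() < config.fraction_peaks_at_genes:
                g = genes[int(rng.integers(0, len(genes)))]
                lo = max(0, g.start - 4000)
                hi = min(genome.size(g.chrom), g.end + 4000) - config.peak_width
                if hi <= lo:
                    continue
                chrom, start = g.chrom, int(rng.integers(lo, hi))
            else:
                chrom, start = _uniform_placement(rng, genome, config.peak_width)
            centers = placed[chrom]
            center = start + config.peak_width // 2
            k = bisect.bisect_left(centers, center)
            if (k > 0 and center - centers[k - 1] < sep) or (
                k < len(centers) and centers[k] - center < sep
            ):
                continue
            centers.insert(k, center)
            peaks.append(
                GenomicInterval(
                    chrom, start, start + config.peak_width, name=f"peak_{i:04d}"
                )
            )
            break
        else:
            raise ValueError("could not place separated binding sites")
    cold = rng.random(config.n_peaks) < config.cold_site_fraction
    return peaks, cold


def _build_tracks(
    rng: np.random.Generator,
    genome: Genome,
    peaks: Sequence[GenomicInterval],
    cold: np.ndarray,
    config: SimulationConfig,
) -> tuple[SignalTrack, SignalTrack]:
    """WT and KO accessibility tracks.

    Constant background everywhere except binding-site windows, which carry
    elevated (or, for cold sites, depressed) signal at ``track_bin``
    resolution with mild multiplicative noise; the KO track is scaled down
    at hot sites by ``ko_accessibility_drop``.
    """
    bg = config.background_signal
    flank = 250
    rows_wt: dict[str, list[tuple[int, int, float]]] = {c: [] for c in genome.names}
    rows_ko: dict[str, list[tuple[int, int, float]]] = {c: [] for c in genome.names}
    windows: dict[str, list[tuple[int, int, float, float]]] = {
        c: [] for c in genome.names
    }
    for peak, is_cold in zip(peaks, cold):
        center = (peak.start + peak.end) // 2
        w0 = max(0, center - flank)
        w1 = min(genome.size(peak.chrom), center + flank + 1)
        wt_level = bg * (config.cold_site_ratio if is_cold else config.peak_signal_ratio)
        ko_level = wt_level * (1.0 if is_cold else config.ko_accessibility_drop)
        windows[peak.chrom].append((w0, w1, wt_level, ko_level))
    for chrom in genome.names:
        pos = 0
        size = genome.size(chrom)
        for w0, w1, wt_level, ko_level in sorted(windows[chrom]):
            if w0 > pos:
                rows_wt[chrom].append((pos, w0, bg))
                rows_ko[chrom].append((pos, w0, bg))
            edges = list(range(w0, w1, config.track_bin)) + [w1]
            for a, b in zip(edges[:-1], edges[1:]):
                noise = float(np.exp(rng.normal(0.0, 0.05)))
                rows_wt[chrom].append((a, b, wt_level * noise))
                rows_ko[chrom].append((a, b, ko_level * noise))
            pos = w1
        if pos < size:
            rows_wt[chrom].append((pos, size, bg))
            rows_ko[chrom].append((pos, size, bg))

    def to_track(rows: dict[str, list[tuple[int, int, float]]]) -> SignalTrack:
        recs = {}
        for chrom, items in rows.items():
            arr = np.array(items, dtype=float)
            recs[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        return SignalTrack(recs)

    return to_track(rows_wt), to_track(rows_ko)


def _plant_differential_loops(
    rng: np.random.Generator,
    genome: Genome,
    genes: Sequence[GenomicInterval],
    residual: np.ndarray,
    log2fc: np.ndarray,
    gene_index: IntervalIndex,
    config: SimulationConfig,
) -> tuple[list[Loop], list[Loop], np.ndarray]:
    """Over/under-interacting loops realizing rank-coupled linking scores.

    Target integer scores are drawn from a rounded normal and assigned to
    genes through a Gaussian copula against the expression-noise residual
    (coupling to the residual rather than to the total log2FC keeps the
    linear model's loop-count coefficients unbiased), calibrated so that
    Spearman(score, log2FC) approximates ``linking_correlation``.  Two
    attenuation factors are measured on the sample itself and divided out:
    the tie attenuation of the discrete score distribution and the rank
    correlation between the residual and the total log2FC.
    """
    n = len(genes)
    z1 = stats.norm.ppf(stats.rankdata(residual) / (n + 1))
    pool = np.sort(np.round(rng.normal(0.0, config.linking_score_sd, n)).astype(int))
    # tie-attenuation of the discretized scores, measured against a latent
    # normal of matching ranks
    probe = np.sort(rng.normal(size=n))
    atten = float(stats.spearmanr(pool, probe).statistic)
    resid_factor = float(stats.spearmanr(residual, log2fc).statistic)
    target = config.linking_correlation
    latent_s = np.clip(
        target / max(atten * resid_factor, 1e-9), -0.999, 0.999
    )
    rho = 2 * np.sin(np.pi * latent_s / 6)  # Spearman -> Pearson for a copula
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.normal(size=n)
    order = np.argsort(np.argsort(z2, kind="stable"), kind="stable")
    scores = pool[order]

    over: list[Loop] = []
    under: list[Loop] = []
    aw = config.anchor_width
    for i, g in enumerate(genes):
        s = int(scores[i])
        if s == 0:
            continue
        label = "overinteracting" if s > 0 else "underinteracting"
        dest = over if s > 0 else under
        anchor_w = min(aw, g.length)
        size = genome.size(g.chrom)
        for k in range(abs(s)):
            for _ in range(100):
                dist = int(rng.integers(50_000, 200_001))
                right = rng.random() < 0.5
                if right and g.end + dist + aw <= size:
                    o0 = g.end + dist
                elif not right and g.start - dist - aw >= 0:
                    o0 = g.start - dist - aw
                else:
                    continue
                if gene_index.any_overlap(g.chrom, o0, o0 + aw):
                    continue
                gene_anchor = GenomicInterval(g.chrom, g.start, g.start + anchor_w)
                other = GenomicInterval(g.chrom, o0, o0 + aw)
                left, rgt = (
                    (gene_anchor, other)
                    if gene_anchor.start <= other.start
                    else (other, gene_anchor)
                )
                dest.append(
                    Loop(left, rgt, label=label, name=f"{label[:4]}_{g.name}_{k}")
                )
                break
    return over, under, scores


def generate_dataset(
    config: SimulationConfig | None = None, out_dir: str | Path | None = None
) -> SyntheticBundle:
    """Generate a complete synthetic bundle; optionally write it to disk.

    The written bundle (chrom.sizes, genes BED, three BEDPE loop files,
    enhancers/peaks BED, two bedGraph tracks, expression TSV, truth TSV) is
    byte-identical across runs with the same configuration.
    """
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(config.seed)
    (
        rng_genes,
        rng_b,
        rng_a,
        rng_enh,
        rng_peaks,
        rng_tracks,
        rng_expr,
        rng_link,
    ) = [np.random.default_rng(s) for s in ss.spawn(8)]

    genome = Genome(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    )
    genes = _place_genes(rng_genes, genome, config)
    loops_b = _place_loops_b(rng_b, genome, config)
    loops_a, engulfed = _place_loops_a(rng_a, genome, config, loops_b)

    # enhancers: one inside the right anchor of a subset of A loops, plus
    # uniform background enhancers
    enhancers: list[GenomicInterval] = []
    ew = config.enhancer_width
    for i, lp in enumerate(loops_a):
        if rng_enh.random() < config.fraction_loops_to_enhancer:
            ra = lp.right_anchor
            start = int(rng_enh.integers(ra.start, ra.end - ew))
            enhancers.append(
                GenomicInterval(ra.chrom, start, start + ew, name=f"enh_A_{i:04d}")
            )
    for i in range(config.n_background_enhancers):
        chrom, start = _uniform_placement(rng_enh, genome, ew)
        enhancers.append(
            GenomicInterval(chrom, start, start + ew, name=f"enh_bg_{i:04d}")
        )

    peaks, cold = _place_peaks(rng_peaks, genome, config, genes)
    # tag planted cold sites in their names so the truth survives BED round-trips
    peaks = [
        GenomicInterval(
            p.chrom, p.start, p.end, name=p.name + ("_cold" if cold[i] else "")
        )
        for i, p in enumerate(peaks)
    ]
    track_wt, track_ko = _build_tracks(rng_tracks, genome, peaks, cold, config)

    # expression: WT level boosted inside A-loop spans (insulation effect);
    # log2FC shifted per A-anchor hit plus Gaussian noise
    a_anchor_idx = _AnchorIndex(loops_a)
    a_span_idx = IntervalIndex([lp.span for lp in loops_a])
    gene_index = IntervalIndex(genes)
    n = len(genes)
    satb1_counts = np.array(
        [a_anchor_idx.count(g.chrom, g.start, g.end) for g in genes]
    )
    in_a_span = np.array(
        [a_span_idx.any_overlap(g.chrom, g.start, g.end) for g in genes]
    )
    lengths = np.array([g.length for g in genes], dtype=float)
    baseline = 10 ** rng_expr.normal(0.0, 0.25, n)
    wt_mean = (
        lengths
        * config.base_rate
        * baseline
        * 10 ** (config.insulation_shift * in_a_span)
    )
    residual = rng_expr.normal(0.0, config.expression_noise_sd, n)
    log2fc = config.planted_log2fc_in_A_loops * satb1_counts + residual
    ko_mean = wt_mean * 2**log2fc
    wt_counts = generate_counts(wt_mean, config.expression_dispersion, rng_expr)
    ko_counts = generate_counts(ko_mean, config.expression_dispersion, rng_expr)
    pvals = 2 * stats.norm.sf(np.abs(log2fc) / config.expression_noise_sd)
    order = np.argsort(pvals, kind="stable")
    fdr = np.empty(n)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    fdr[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.clip(fdr, 0, 1)
    expression = {
        g.name: ExpressionRecord(
            gene_id=g.name,
            wt_count=int(wt_counts[i]),
            ko_count=int(ko_counts[i]),
            log2fc=float(log2fc[i]),
            fdr=float(fdr[i]),
        )
        for i, g in enumerate(genes)
    }

    over, under, target_scores = _plant_differential_loops(
        rng_link, genome, genes, residual, log2fc, gene_index, config
    )

    truth = pd.DataFrame(
        {
            "gene_id": [g.name for g in genes],
            "in_a_span": in_a_span.astype(int),
            "satb1_anchor_count": satb1_counts,
            "target_linking_score": target_scores,
            "planted_log2fc": log2fc,
            "wt_mean": wt_mean,
        }
    )

    # tag engulfed A loops in their names so the truth survives BEDPE round-trips
    loops_a = [
        Loop(
            lp.left_anchor,
            lp.right_anchor,
            label=lp.label,
            name=lp.name + ("_engulfed" if engulfed[i] else ""),
        )
        for i, lp in enumerate(loops_a)
    ]

    bundle = SyntheticBundle(
        config=config,
        genome=genome,
        genes=genes,
        loops_a=loops_a,
        loops_b=loops_b,
        over_loops=over,
        under_loops=under,
        enhancers=enhancers,
        peaks=peaks,
        track_wt=track_wt,
        track_ko=track_ko,
        expression=expression,
        truth=truth,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(bundle.genome, out / "chrom.sizes")
    write_bed(bundle.genes, out / "genes.bed")
    write_bed(bundle.enhancers, out / "enhancers.bed")
    write_bed(bundle.peaks, out / "peaks.bed")
    write_bedpe_loops(bundle.loops_a, out / "satb1_loops.bedpe")
    write_bedpe_loops(bundle.loops_b, out / "ctcf_loops.bedpe")
    write_bedpe_loops(
        bundle.over_loops + bundle.under_loops, out / "h3k27ac_diff_loops.bedpe"
    )
    _write_track(bundle.track_wt, out / "atac_wt.bedgraph")
    _write_track(bundle.track_ko, out / "atac_ko.bedgraph")
    write_expression_table(bundle.expression, out / "expression.tsv")
    bundle.truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.6g")


def _write_track(track: SignalTrack, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values, _ = track._rec[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")
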