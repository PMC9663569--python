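"""Readers and writers for the plain-text genomics formats the pipeline uses.

Formats: BED (intervals, optional strand in column 6), BEDPE interaction
tables (loops, FitHiChIP-style trailing q-value column), bedGraph signal
tracks, UCSC chrom.sizes, and TSV expression tables.  All coordinates on
disk are BED-dialect (0-based half-open), identical to the in-memory
convention, so reading and writing are lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import Genome, GenomicInterval, Loop

logger = logging.getLogger("chromloop")

__all__ = [
    "RunConfig",
    "SignalTrack",
    "ExpressionRecord",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedpe_loops",
    "write_bedpe_loops",
    "read_bedgraph",
    "read_expression_table",
    "write_expression_table",
]


@dataclass
class RunConfig:
    """Tunable constants of the pipeline, with the published defaults.

    Extents are in bp.  ``promoter_extension`` is the one-sided window a TSS
    is extended by to call a promoter; ``enhancer_flank`` extends the center
    of an enhancer on both sides; ``peak_flank`` likewise for binding sites;
    ``tss_flank`` for TSS accessibility profiles.  Genes whose absolute
    linking score exceeds ``outlier_linking_threshold`` are dropped as
    influential outliers before correlating with expression change.
    """

    seed: int = 0
    n_permutations: int = 1000
    n_bootstrap: int = 100
    promoter_extension: int = 5000
    enhancer_flank: int = 50
    peak_flank: int = 250
    tss_flank: int = 1000
    outlier_linking_threshold: int = 40
    pseudocount_expression: float = 0.01
    pseudocount_atac: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "promoter_extension",
            "enhancer_flank",
            "peak_flank",
            "tss_flank",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pseudocount_expression <= 0 or self.pseudocount_atac <= 0:
            raise ValueError("pseudocounts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ExpressionRecord:
    """Per-gene expression summary consumed from a differential-expression
    analysis: normalized WT/KO counts, log2(KO/WT) and FDR."""

    gene_id: str
    wt_count: float
    ko_count: float
    log2fc: float
    fdr: float | None = None

    def __post_init__(self) -> None:
        if self.wt_count < 0 or self.ko_count < 0:
            raise ValueError(f"negative count for gene {self.gene_id}")
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"FDR {self.fdr} outside [0, 1] for {self.gene_id}")


class SignalTrack:
    """Normalized coverage with bedGraph semantics.

    The track is a partition: sorted, non-overlapping scored intervals per
    chromosome; any uncovered bp has value 0.  Supports mean queries over
    intervals and per-bp extraction for profile aggregation.
    """

    def __init__(self, records: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # records: chrom -> (starts, ends, values), sorted, non-overlapping
        self._rec: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in records.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends[:-1] > starts[1:]):
                bad = int(np.argmax(ends[:-1] > starts[1:]))
                raise ValueError(
                    f"overlapping bedGraph records on {chrom} near "
                    f"{int(starts[bad + 1])}: track must be a partition"
                )
            cum = np.concatenate(
                [[0.0], np.cumsum(values * (ends - starts), dtype=float)]
            )
            self._rec[chrom] = (starts, ends, values, cum)

    @classmethod
    def from_tuples(cls, rows: Sequence[tuple[str, int, int, float]]) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, v in rows:
            by_chrom.setdefault(chrom, []).append((s, e, v))
        recs = {}
        for chrom, items in by_chrom.items():
            arr = np.array(items, dtype=float)
            recs[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(recs)

    @property
    def chroms(self) -> list[str]:
        return list(self._rec)

    def is_empty(self) -> bool:
        return not self._rec

    def _cumulative_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the track over [0, pos) for an array of positions."""
        starts, ends, values, cum = self._rec[chrom]
        j = np.searchsorted(starts, pos, side="right") - 1
        base = np.where(j >= 0, cum[np.maximum(j, 0)], 0.0)
        partial = np.where(
            j >= 0,
            np.maximum(
                0,
                np.minimum(pos, ends[np.maximum(j, 0)]) - starts[np.maximum(j, 0)],
            )
            * values[np.maximum(j, 0)],
            0.0,
        )
        return base + partial

    def mean(self, chrom: str, start, end) -> np.ndarray | float:
        """Mean signal over [start, end); uncovered bp count as 0.

        ``start``/``end`` may be scalars or aligned arrays.
        """
        start_arr = np.atleast_1d(np.asarray(start, dtype=np.int64))
        end_arr = np.atleast_1d(np.asarray(end, dtype=np.int64))
        if chrom not in self._rec:
            out = np.zeros(start_arr.shape, dtype=float)
        else:
            total = self._cumulative_at(chrom, end_arr) - self._cumulative_at(
                chrom, start_arr
            )
            out = total / (end_arr - start_arr)
        if np.isscalar(start) or np.ndim(start) == 0:
            return float(out[0])
        return out

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp signal over [start, end) as an array of length end-start."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._rec:
            return out
        starts, ends, values, _ = self._rec[chrom]
        lo = max(0, int(np.searchsorted(ends, start, side="right")))
        hi = int(np.searchsorted(starts, end, side="left"))
        for k in range(lo, hi):
            a = max(start, int(starts[k]))
            b = min(end, int(ends[k]))
            if b > a:
                out[a - start : b - start] = values[k]
        return out


def read_chrom_sizes(path: str | Path) -> Genome:
    """Read a UCSC-dialect two-column chrom.sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            name, size = parts[0], int(parts[1])
            if name in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = size
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, size in genome.chrom_sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (>= 3 columns; name in col 4, strand in col 6)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            out.append(GenomicInterval(chrom, start, end, strand=strand, name=name))
    return out


def write_bed(items: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in items:
            name = iv.name or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bedpe_loops(path: str | Path) -> list[Loop]:
    """Read loops from a BEDPE interaction table.

    Columns: chr1 start1 end1 chr2 start2 end2 [name] [... q-value last].
    Trans (inter-chromosomal) rows are skipped with a logged warning; anchor
    pairs are reordered so the left anchor starts first.  When more than 6
    columns are present the last numeric column is taken as the q-value
    (FitHiChIP convention); a 7th text column is kept as the loop name and a
    column named/valued over/underinteracting sets the differential label.
    """
    loops: list[Loop] = []
    n_trans = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 columns")
            try:
                c1, s1, e1 = parts[0], int(parts[1]), int(parts[2])
                c2, s2, e2 = parts[3], int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinates") from exc
            if c1 != c2:
                n_trans += 1
                continue
            if s2 < s1:
                (s1, e1), (s2, e2) = (s2, e2), (s1, e1)
            name = ""
            label = "none"
            qvalue = None
            extras = parts[6:]
            if extras:
                try:
                    qvalue = float(extras[-1])
                except ValueError:
                    qvalue = None
                for tok in extras:
                    if tok in ("overinteracting", "underinteracting"):
                        label = tok
                    elif not _is_number(tok) and not name:
                        name = tok
            loops.append(
                Loop(
                    GenomicInterval(c1, s1, e1),
                    GenomicInterval(c2, s2, e2),
                    qvalue=qvalue,
                    label=label,
                    name=name,
                )
            )
    if n_trans:
        logger.warning("skipped %d trans interaction rows in %s", n_trans, path)
    return loops


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_bedpe_loops(loops: Sequence[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            la, ra = lp.left_anchor, lp.right_anchor
            fields = [la.chrom, la.start, la.end, ra.chrom, ra.start, ra.end]
            fields.append(lp.name or ".")
            if lp.label != "none":
                fields.append(lp.label)
            if lp.qvalue is not None:
                fields.append(repr(lp.qvalue))
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack (partition required)."""
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable record") from exc
            if s >= e:
                raise ValueError(f"{path}:{lineno}: start >= end")
            by_chrom.setdefault(chrom, []).append((s, e, v))
    recs = {}
    for chrom, items in by_chrom.items():
        arr = np.array(items, dtype=float)
        recs[chrom] = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )
    return SignalTrack(recs)


def read_expression_table(path: str | Path) -> dict[str, ExpressionRecord]:
    """Read a TSV with header gene_id, wt_count, ko_count, log2fc, fdr."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "wt_count", "ko_count", "log2fc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records: dict[str, ExpressionRecord] = {}
    has_fdr = "fdr" in df.columns
    for row in df.itertuples(index=False):
        gid = str(row.gene_id)
        if gid in records:
            raise ValueError(f"{path}: duplicate gene_id {gid!r}")
        fdr = None
        if has_fdr:
            fdr = float(row.fdr)
            if np.isnan(fdr):
                fdr = None
        records[gid] = ExpressionRecord(
            gene_id=gid,
            wt_count=float(row.wt_count),
            ko_count=float(row.ko_count),
            log2fc=float(row.log2fc),
            fdr=fdr,
        )
    return records


def write_expression_table(
    records: Sequence[ExpressionRecord] | dict[str, ExpressionRecord],
    path: str | Path,
) -> None:
    if isinstance(records, dict):
        records = list(records.values())
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "wt_count": [r.wt_count for r in records],
            "ko_count": [r.ko_count for r in records],
            "log2fc": [r.log2fc for r in records],
            "fdr": [r.fdr if r.fdr is not None else np.nan for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
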