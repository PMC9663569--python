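"""Gene-level statistics tying differential loops to expression change.

A gene's linking score is the difference between the number of
overinteracting and underinteracting loops whose anchors overlap the gene
(positive = gained interactions in the knockout).  A loop with both anchors
on the same gene contributes once.  The score (optionally normalized to
1 kbp of gene length) is correlated with expression log2 fold change after
removing genes with |score| above an outlier threshold.  Set enrichments are
assessed with the upper-tail hypergeometric test, fold enrichment being the
observed overlap divided by the mean of the hypergeometric background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalIndex, Loop
from .io import ExpressionRecord, RunConfig

__all__ = [
    "Gene",
    "LinkingScore",
    "anchor_gene_count",
    "linking_score",
    "linking_scores",
    "expression_linking_correlation",
    "hypergeometric_enrichment",
    "signature_filter",
]


@dataclass(frozen=True)
class Gene:
    """Stranded gene model; the TSS is the 5' end in transcription sense."""

    id: str
    interval: GenomicInterval

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def tss(self) -> int:
        return (
            self.interval.end - 1
            if self.interval.strand == "-"
            else self.interval.start
        )


@dataclass(frozen=True)
class LinkingScore:
    gene_id: str
    n_over: int
    n_under: int

    @property
    def score(self) -> int:
        return self.n_over - self.n_under

    def score_per_kb(self, gene_length: int) -> float:
        return self.score / (gene_length / 1000)


class _AnchorIndex:
    """Index of loop anchors; counts loops (not anchors) hitting a region."""

    def __init__(self, loops: Sequence[Loop]):
        anchors = []
        self._loop_of: list[int] = []
        for i, lp in enumerate(loops):
            anchors.append(lp.left_anchor)
            self._loop_of.append(i)
            anchors.append(lp.right_anchor)
            self._loop_of.append(i)
        self._index = IntervalIndex(anchors)
        self._loop_of = np.array(self._loop_of, dtype=int)

    def count(self, chrom: str, start: int, end: int) -> int:
        hits = self._index.overlapping(chrom, start, end)
        if hits.size == 0:
            return 0
        return int(np.unique(self._loop_of[hits]).size)


def anchor_gene_count(
    gene: GenomicInterval | Gene, loops: Sequence[Loop] | _AnchorIndex
) -> int:
    """Number of loops with >= 1 anchor overlapping the gene span.

    A loop whose both anchors overlap the gene is counted once.
    """
    iv = gene.interval if isinstance(gene, Gene) else gene
    if not isinstance(loops, _AnchorIndex):
        loops = _AnchorIndex(loops)
    return loops.count(iv.chrom, iv.start, iv.end)


def linking_score(
    gene: GenomicInterval | Gene,
    over_loops: Sequence[Loop] | _AnchorIndex,
    under_loops: Sequence[Loop] | _AnchorIndex,
) -> LinkingScore:
    """Per-gene difference between over- and underinteracting anchor hits."""
    gid = gene.id if isinstance(gene, Gene) else gene.name
    return LinkingScore(
        gene_id=gid,
        n_over=anchor_gene_count(gene, over_loops),
        n_under=anchor_gene_count(gene, under_loops),
    )


def linking_scores(
    genes: Sequence[GenomicInterval],
    over_loops: Sequence[Loop],
    under_loops: Sequence[Loop],
) -> pd.DataFrame:
    """Linking scores for many genes as a tidy table."""
    over_idx = _AnchorIndex(over_loops)
    under_idx = _AnchorIndex(under_loops)
    rows = []
    for g in genes:
        ls = linking_score(g, over_idx, under_idx)
        rows.append(
            {
                "gene_id": ls.gene_id,
                "n_over": ls.n_over,
                "n_under": ls.n_under,
                "score": ls.score,
                "score_per_kb": ls.score_per_kb(g.length),
            }
        )
    return pd.DataFrame(rows)


def expression_linking_correlation(
    records: Mapping[str, ExpressionRecord],
    scores: pd.DataFrame,
    config: RunConfig | None = None,
    per_kb: bool = False,
    stratify_by: set[str] | None = None,
) -> dict:
    """Spearman correlation of expression log2FC with the linking score.

    Genes with |score| above ``outlier_linking_threshold`` are removed as
    influential outliers first.  Besides rho and its p, an ordinary
    least-squares line (for plotting) is fitted overall and, when
    ``stratify_by`` supplies a gene set (e.g. genes inside a factor's
    loops), separately for members and non-members.
    """
    config = config or RunConfig()
    col = "score_per_kb" if per_kb else "score"
    df = scores[scores["gene_id"].isin(records)].copy()
    df["log2fc"] = df["gene_id"].map(lambda g: records[g].log2fc)
    n_before = len(df)
    kept = df[df["score"].abs() <= config.outlier_linking_threshold]
    n_outliers = n_before - len(kept)
    if len(kept) < 3:
        raise ValueError("fewer than 3 genes after outlier filtering")
    rho, p = stats.spearmanr(kept[col], kept["log2fc"])

    def ols_line(sub: pd.DataFrame) -> tuple[float, float] | None:
        if len(sub) < 2 or sub[col].nunique() < 2:
            return None
        slope, intercept = np.polyfit(sub[col], sub["log2fc"], 1)
        return float(slope), float(intercept)

    lines = {"all": ols_line(kept)}
    if stratify_by is not None:
        member = kept["gene_id"].isin(stratify_by)
        lines["in_set"] = ols_line(kept[member])
        lines["not_in_set"] = ols_line(kept[~member])
    return {
        "rho": float(rho),
        "pvalue": float(p),
        "n_used": int(len(kept)),
        "n_outliers_removed": int(n_outliers),
        "lines": lines,
    }


def hypergeometric_enrichment(
    query_genes: set[str] | Sequence[str],
    category_genes: set[str] | Sequence[str],
    universe_size: int,
) -> dict:
    """Upper-tail hypergeometric enrichment of one gene set in another.

    Expected overlap is the mean of the hypergeometric background
    (|query| * |category| / universe) and fold = observed / expected;
    p = P(X >= k).
    """
    query = set(query_genes)
    category = set(category_genes)
    k = len(query & category)
    n_q, n_c = len(query), len(category)
    if universe_size < n_q + n_c - k:
        raise ValueError("universe smaller than the union of the two sets")
    expected = n_q * n_c / universe_size
    flagged = expected == 0
    fold = np.nan if flagged else k / expected
    # P(X >= k) with X ~ Hypergeom(N=universe, K=|category|, n=|query|)
    p = float(stats.hypergeom.sf(k - 1, universe_size, n_c, n_q))
    return {
        "overlap": k,
        "expected": expected,
        "fold": fold,
        "pvalue": p,
        "undefined_fold": flagged,
    }


def signature_filter(
    subset_matrix: pd.DataFrame,
    groups: Mapping[str, str],
    cluster_members: Mapping[str, tuple[Sequence[str], str]],
    fold: float = 2.0,
) -> dict[str, list[str]]:
    """Filter cluster genes down to group signature genes.

    ``subset_matrix`` is genes x subsets (normalized expression >= 0);
    ``groups`` maps each subset column to its group (e.g. DN1 -> DN);
    ``cluster_members`` maps a cluster name to (gene list, assigned group).
    Within each cluster assigned to group G, a gene is kept when its mean
    expression over G's subsets is at least ``fold`` times the mean
    expression over every other group's subsets.
    """
    if (subset_matrix.values < 0).any():
        raise ValueError("subset matrix must be non-negative")
    group_cols: dict[str, list[str]] = {}
    for subset, grp in groups.items():
        if subset not in subset_matrix.columns:
            raise ValueError(f"subset {subset!r} missing from the matrix")
        group_cols.setdefault(grp, []).append(subset)
    for grp, cols in group_cols.items():
        if not cols:
            raise ValueError(f"group {grp!r} has no subsets")
    group_means = pd.DataFrame(
        {grp: subset_matrix[cols].mean(axis=1) for grp, cols in group_cols.items()}
    )
    out: dict[str, list[str]] = {}
    for cluster, (genes, grp) in cluster_members.items():
        if grp not in group_cols:
            raise ValueError(f"cluster {cluster!r} assigned to unknown group {grp!r}")
        others = [g for g in group_cols if g != grp]
        kept = []
        for gene in genes:
            if gene not in group_means.index:
                continue
            own = group_means.at[gene, grp]
            if all(own >= fold * group_means.at[gene, o] for o in others):
                kept.append(gene)
        out[cluster] = kept
    return out
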