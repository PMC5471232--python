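"""SNP-to-gene-to-pathway mapping.

Builds merged single-interval gene models from multi-isoform annotation rows,
assigns SNPs to genes through flanked windows (default ±15 kb, motivated by
the observation that most eQTL SNPs fall within 15 kb of their gene), filters
pathways by mappable gene count, and collects each pathway's SNP set.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import IsoformRow, PathwayDef, SnpRecord

__all__ = [
    "GeneModel",
    "PathwaySnpSet",
    "merge_isoforms",
    "assign_snps",
    "filter_pathways",
    "size_bins",
    "collect_pathway_snps",
]

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 15_000
DEFAULT_MIN_GENES = 5
DEFAULT_MAX_GENES = 300
#: the fixed quartile cutpoints of the reference pathway collection,
#: giving size bins [5,9], [10,16], [17,36], [37,300]
REFERENCE_CUTPOINTS = (10, 17, 37)


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene reduced to one genomic interval plus its flanked SNP window."""

    gene_symbol: str
    chrom: str
    start: int
    end: int
    window_start: int
    window_end: int

    @classmethod
    def from_span(
        cls, gene_symbol: str, chrom: str, start: int, end: int, flank: int
    ) -> "GeneModel":
        return cls(
            gene_symbol=gene_symbol,
            chrom=chrom,
            start=start,
            end=end,
            window_start=max(1, start - flank),
            window_end=end + flank,
        )


@dataclass(slots=True)
class PathwaySnpSet:
    """A pathway's mappable genes and the union of their assigned SNPs."""

    pathway_id: str
    gene_symbols: frozenset[str]
    snp_ids: frozenset[str]

    @property
    def testable(self) -> bool:
        return len(self.snp_ids) > 0


def _union_clusters(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union intervals sharing >= 1 bp.  Abutting intervals stay separate."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def merge_isoforms(
    rows: list[IsoformRow],
    snps: list[SnpRecord],
    flank: int = DEFAULT_FLANK,
) -> list[GeneModel]:
    """Collapse isoform rows to one :class:`GeneModel` per gene symbol.

    Overlapping isoforms are unioned.  When disjoint clusters remain, the
    cluster whose flanked window contains the lowest-P SNP is kept; on a tie,
    or when no cluster window contains a SNP, the longest (then leftmost)
    cluster wins.  A symbol annotated on two chromosomes is treated as
    disjoint clusters of one gene, so the same rule picks one.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {s.chrom for s in snps}:
        sub = sorted((s for s in snps if s.chrom == chrom), key=lambda s: s.pos)
        by_chrom[chrom] = (
            np.array([s.pos for s in sub], dtype=np.int64),
            np.array([s.pvalue for s in sub], dtype=float),
        )

    def min_p_in_window(chrom: str, lo: int, hi: int) -> float:
        if chrom not in by_chrom:
            return math.inf
        pos, pv = by_chrom[chrom]
        i, j = np.searchsorted(pos, [lo, hi + 1])
        return float(pv[i:j].min()) if j > i else math.inf

    grouped: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for row in rows:
        grouped.setdefault(row.gene_symbol, {}).setdefault(row.chrom, []).append(
            (row.tx_start, row.tx_end)
        )

    models: list[GeneModel] = []
    for symbol in sorted(grouped):
        clusters: list[tuple[str, int, int]] = []
        for chrom, intervals in grouped[symbol].items():
            clusters.extend((chrom, s, e) for s, e in _union_clusters(intervals))
        if len(grouped[symbol]) > 1:
            logger.info("gene %s annotated on multiple chromosomes", symbol)
        if len(clusters) == 1:
            chrom, s, e = clusters[0]
        else:
            # rank: lowest window min-P, then longest span, then leftmost
            def rank(c: tuple[str, int, int]) -> tuple[float, int, str, int]:
                chrom, s, e = c
                lo, hi = max(1, s - flank), e + flank
                return (min_p_in_window(chrom, lo, hi), -(e - s), chrom, s)

            chrom, s, e = min(clusters, key=rank)
        models.append(GeneModel.from_span(symbol, chrom, s, e, flank))
    return models


def assign_snps(
    genes: list[GeneModel], snps: list[SnpRecord]
) -> dict[str, frozenset[str]]:
    """Map each gene symbol to the SNP ids inside its flanked window.

    Membership is chromosome equality and ``window_start <= pos <=
    window_end`` (endpoints inclusive); a SNP may land in several genes.
    """
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {s.chrom for s in snps}:
        sub = sorted((s for s in snps if s.chrom == chrom), key=lambda s: s.pos)
        by_chrom[chrom] = (
            np.array([s.pos for s in sub], dtype=np.int64),
            [s.snp_id for s in sub],
        )
    out: dict[str, frozenset[str]] = {}
    for g in genes:
        if g.chrom not in by_chrom:
            out[g.gene_symbol] = frozenset()
            continue
        pos, ids = by_chrom[g.chrom]
        i, j = np.searchsorted(pos, [g.window_start, g.window_end + 1])
        out[g.gene_symbol] = frozenset(ids[i:j])
    return out


def filter_pathways(
    pathways: list[PathwayDef],
    available_genes: set[str] | frozenset[str],
    min_genes: int = DEFAULT_MIN_GENES,
    max_genes: int = DEFAULT_MAX_GENES,
) -> list[PathwayDef]:
    """Drop pathways with too few/too many mappable genes.

    Gene lists are first intersected with the available gene models; a
    pathway is retained iff ``min_genes <= |intersection| <= max_genes``.
    Idempotent by construction.
    """
    out = []
    for p in pathways:
        genes = p.gene_symbols & frozenset(available_genes)
        if min_genes <= len(genes) <= max_genes:
            out.append(PathwayDef(p.pathway_id, p.name, frozenset(genes)))
    return out


def size_bins(
    pathways: list[PathwayDef],
    cutpoints: tuple[int, int, int] | None = None,
) -> dict[str, int]:
    """Assign each pathway a size-quartile bin in {1, 2, 3, 4}.

    Cutpoints default to the empirical 25th/50th/75th percentiles of the
    collection's sizes; pass :data:`REFERENCE_CUTPOINTS` (10, 17, 37) to
    reproduce the reference bins [5,9], [10,16], [17,36], [37,300].  Bins are
    left-closed: ``size < q25`` is bin 1, ``q25 <= size < q50`` bin 2, etc.
    """
    sizes = np.array([p.size for p in pathways])
    if cutpoints is None:
        if len(np.unique(sizes)) < 4:
            warnings.warn("fewer than 4 distinct pathway sizes; all in bin 1")
            return {p.pathway_id: 1 for p in pathways}
        q25, q50, q75 = np.percentile(sizes, [25, 50, 75])
    else:
        q25, q50, q75 = cutpoints
    edges = np.array([q25, q50, q75], dtype=float)
    return {
        p.pathway_id: int(np.searchsorted(edges, p.size, side="right")) + 1
        for p in pathways
    }


def collect_pathway_snps(
    pathway: PathwayDef, gene_snps: dict[str, frozenset[str]]
) -> PathwaySnpSet:
    """Union member genes' SNP sets; each SNP appears once."""
    snp_ids: set[str] = set()
    for g in pathway.gene_symbols:
        snp_ids |= gene_snps.get(g, frozenset())
    if not snp_ids:
        logger.info("pathway %s has no mapped SNPs (non-testable)", pathway.pathway_id)
    return PathwaySnpSet(pathway.pathway_id, pathway.gene_symbols, frozenset(snp_ids))
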