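"""Partition SNP sets into LD blocks.

A block is a connected component of the graph whose vertices are the input
SNPs and whose edges join pairs with r² strictly greater than the threshold
(default 0.1).  Grouping is therefore single-linkage/transitive: a chain
a–b–c with r²(a,c) = 0 still forms one block.  Blocking runs at pathway
scope (all of a pathway's SNPs together) or at gene scope (each member
gene's SNPs separately — the "gene" variant of the test, which ignores LD
between genes).

Cross-chromosome r² is forced to 0 before clustering: LD is an
intra-chromosomal phenomenon and reference panels can produce spurious
trans correlations.  SNPs absent from the LD source become singleton blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .data_io import LdSource
from .mapping import PathwaySnpSet

__all__ = ["LdBlock", "block_snps", "block_pathway", "DEFAULT_R2_THRESHOLD"]

DEFAULT_R2_THRESHOLD = 0.1


@dataclass(frozen=True, slots=True)
class LdBlock:
    """A non-empty set of SNPs treated as one statistical unit."""

    block_id: str
    snp_ids: frozenset[str]
    scope_tag: str = "pathway"
    source_gene: str | None = None


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {x: x for x in items}
        self.rank = {x: 0 for x in self.parent}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


def block_snps(
    snp_ids: Iterable[str],
    ld: LdSource,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    *,
    chrom_of: Mapping[str, str] | None = None,
    scope_tag: str = "pathway",
    source_gene: str | None = None,
) -> list[LdBlock]:
    """Connected-component blocks over the r² > threshold graph.

    The comparison is strict (a pair at exactly the threshold does not join).
    Blocks come back sorted by their lexicographically smallest member, which
    also names the block, so output is independent of input ordering.
    """
    if not 0.0 <= r2_threshold < 1.0:
        raise ValueError(f"r2_threshold {r2_threshold} outside [0, 1)")
    members = set(snp_ids)
    if not members:
        return []
    uf = _UnionFind(members)
    for snp in members:
        for other, r2 in ld.neighbors(snp):
            if other <= snp or other not in members or r2 <= r2_threshold:
                continue
            if chrom_of is not None and chrom_of.get(snp) != chrom_of.get(other):
                continue
            uf.union(snp, other)
    comps: dict[str, set[str]] = {}
    for snp in members:
        comps.setdefault(uf.find(snp), set()).add(snp)
    blocks = []
    for comp in sorted(comps.values(), key=min):
        anchor = min(comp)
        bid = f"{source_gene}:{anchor}" if source_gene is not None else anchor
        blocks.append(LdBlock(bid, frozenset(comp), scope_tag, source_gene))
    return blocks


def block_pathway(
    pset: PathwaySnpSet,
    gene_snps: Mapping[str, frozenset[str]],
    ld: LdSource,
    scope: str = "pathway",
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    *,
    chrom_of: Mapping[str, str] | None = None,
) -> list[LdBlock]:
    """Block a pathway's SNPs at pathway or gene scope.

    Gene scope runs :func:`block_snps` per member gene and concatenates; a
    SNP mapped to two member genes then contributes to both genes' blocks
    (per-gene blocking with duplication).
    """
    if scope == "pathway":
        return block_snps(
            pset.snp_ids, ld, r2_threshold, chrom_of=chrom_of, scope_tag="pathway"
        )
    if scope == "gene":
        blocks: list[LdBlock] = []
        for gene in sorted(pset.gene_symbols):
            ids = gene_snps.get(gene, frozenset())
            if not ids:
                continue
            blocks.extend(
                block_snps(
                    ids,
                    ld,
                    r2_threshold,
                    chrom_of=chrom_of,
                    scope_tag="gene",
                    source_gene=gene,
                )
            )
        return blocks
    raise ValueError(f"unknown scope {scope!r}; use 'pathway' or 'gene'")
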