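"""Self-contained synthetic fixtures with known ground truth.

The generator emulates the statistical shape of the real inputs:

* genotypes with stylized block LD — each latent block copies a binary
  haplotype with per-SNP flip noise calibrated so the realized within-block
  dosage r² matches the requested level (for flip probability e the dosage
  correlation between two SNPs of a block is (1-2e)², hence
  e = (1 - w^{1/4}) / 2 for a target r² of w);
* gene annotations with overlapping isoforms, genes spaced so their ±15 kb
  windows never collide;
* optional cross-gene LD: a chosen fraction of adjacent gene pairs share one
  latent block spanning the gene boundary, which is what separates
  pathway-scope from gene-scope blocking;
* pathway collections with configurable size distributions;
* null P-values, either i.i.d. uniform or "ld_coupled" (a Gaussian copula
  with one factor per true LD block, so SNPs of a block share their signal
  the way LD makes real association statistics co-vary — marginals stay
  exactly uniform);
* enriched P-values where a pathway's SNPs are significant (P < 0.05) with a
  prescribed probability.

All randomness flows from ``FixtureSpec.seed`` through named substreams, so
layout, genotypes, pathways and statistics are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .data_io import (
    IsoformRow,
    LdSource,
    PathwayDef,
    SnpRecord,
    ld_from_genotypes,
    write_dosage_matrix,
    write_gene_table,
    write_gmt,
    write_ld_pairs,
    write_summary_stats,
)

__all__ = [
    "FixtureSpec",
    "Fixture",
    "generate_fixture",
    "generate_null_stats",
    "generate_enriched_stats",
]

_GENE_GAP = 40_000  # > 2 * 15 kb flank, so neighbouring windows never overlap
_SNP_SPACING = 500


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic dataset."""

    n_chroms: int = 2
    genes_per_chrom: int = 30
    snps_per_gene: tuple[int, int] = (4, 8)
    #: cycled per gene: each entry is (block_size, within_block_r2 > 0.1)
    block_structure: tuple[tuple[int, float], ...] = ((4, 0.5), (3, 0.5))
    #: fraction of adjacent same-chromosome gene pairs sharing one LD block
    cross_gene_ld_fraction: float = 0.2
    n_pathways: int = 50
    #: (lo, hi) for log-uniform sizes, or an explicit tuple of sizes to resample
    pathway_size_distribution: tuple[int, ...] = (5, 15)
    enriched_pathways: tuple[tuple[str, float], ...] = ()
    n_samples: int = 300
    seed: int = 0


def _substream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


_TAGS = {"layout": 1, "genotypes": 2, "pathways": 3, "stats": 4, "enrich": 5}


@dataclass
class Fixture:
    """A generated dataset plus its ground truth."""

    spec: FixtureSpec
    snp_ids: list[str]
    snp_chrom: dict[str, str]
    snp_pos: dict[str, int]
    dosages: np.ndarray = field(repr=False)
    ld: LdSource = field(repr=False)
    isoforms: list[IsoformRow] = field(repr=False)
    pathways: list[PathwayDef] = field(repr=False)
    #: true latent blocks as (snp id tuple, within_r2)
    true_blocks: list[tuple[tuple[str, ...], float]] = field(repr=False)
    gene_snps: dict[str, frozenset[str]] = field(repr=False)

    @property
    def gene_symbols(self) -> list[str]:
        return sorted(self.gene_snps)

    def pathway_snps(self, pathway_id: str) -> frozenset[str]:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                out: set[str] = set()
                for g in p.gene_symbols:
                    out |= self.gene_snps.get(g, frozenset())
                return frozenset(out)
        raise KeyError(pathway_id)

    def write(self, outdir: str | Path, stats: Sequence[SnpRecord]) -> None:
        """Write the fixture in the external dialects plus a truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_summary_stats(stats, outdir / "summary_stats.tsv")
        write_gene_table(self.isoforms, outdir / "genes.tsv")
        write_gmt(self.pathways, outdir / "pathways.gmt")
        write_ld_pairs(self.ld, outdir / "ld_pairs.tsv")
        write_dosage_matrix(self.dosages, self.snp_ids, outdir / "dosages.tsv")
        truth = {
            "true_blocks": [
                {"snps": list(snps), "within_r2": w} for snps, w in self.true_blocks
            ],
            "enriched_pathways": [
                {"pathway_id": pid, "target_fraction": f}
                for pid, f in self.spec.enriched_pathways
            ],
            "seed": self.spec.seed,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def _draw_sizes(
    dist: tuple[int, ...], n: int, rng: np.random.Generator
) -> np.ndarray:
    if len(dist) == 2 and dist[0] < dist[1]:
        lo, hi = dist
        u = rng.uniform(np.log(lo), np.log(hi + 1), size=n)
        return np.minimum(np.exp(u).astype(int), hi)
    return rng.choice(np.asarray(dist, dtype=int), size=n, replace=True)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Lay out genes and SNPs, simulate genotypes, and build pathways."""
    for size, w in spec.block_structure:
        if size < 1 or not 0.0 < w <= 1.0:
            raise ValueError(f"infeasible block structure entry ({size}, {w})")
    layout_rng = _substream(spec.seed, _TAGS["layout"])

    snp_ids: list[str] = []
    snp_chrom: dict[str, str] = {}
    snp_pos: dict[str, int] = {}
    isoforms: list[IsoformRow] = []
    gene_snps: dict[str, frozenset[str]] = {}
    # per-gene ordered block membership (indices into snp_ids)
    gene_block_lists: dict[str, list[tuple[list[int], float]]] = {}
    gene_order: list[str] = []

    counter = 0
    gene_idx = 0
    n_struct = len(spec.block_structure)
    for ci in range(spec.n_chroms):
        chrom = str(ci + 1)
        pos = 100_000
        for _ in range(spec.genes_per_chrom):
            symbol = f"G{gene_idx:04d}"
            gene_idx += 1
            gene_order.append(symbol)
            lo, hi = spec.snps_per_gene
            n_snps = int(layout_rng.integers(lo, hi + 1))
            start = pos
            idxs: list[int] = []
            for k in range(n_snps):
                sid = f"rs{counter:06d}"
                counter += 1
                snp_ids.append(sid)
                snp_chrom[sid] = chrom
                snp_pos[sid] = pos
                idxs.append(len(snp_ids) - 1)
                pos += _SNP_SPACING
            end = pos - _SNP_SPACING + 200
            third = max(1, (end - start) // 3)
            isoforms.append(IsoformRow(symbol, chrom, "+", start, start + 2 * third))
            isoforms.append(IsoformRow(symbol, chrom, "-", start + third, end))
            gene_snps[symbol] = frozenset(snp_ids[i] for i in idxs)
            # partition this gene's SNPs into latent blocks, cycling the spec
            blocks: list[tuple[list[int], float]] = []
            at = 0
            b = 0
            while at < n_snps:
                size, w = spec.block_structure[b % n_struct]
                blocks.append((idxs[at : at + size], w))
                at += size
                b += 1
            gene_block_lists[symbol] = blocks
            pos += _GENE_GAP

    # fuse boundary blocks of selected adjacent same-chromosome gene pairs
    merged: list[tuple[list[int], float]] = []
    fused_into_prev: dict[str, bool] = {}
    prev_symbol: str | None = None
    for symbol in gene_order:
        blocks = gene_block_lists[symbol]
        fuse = (
            prev_symbol is not None
            and snp_chrom[snp_ids[blocks[0][0][0]]]
            == snp_chrom[snp_ids[gene_block_lists[prev_symbol][0][0][0]]]
            and layout_rng.random() < spec.cross_gene_ld_fraction
        )
        if fuse:
            head, w = blocks[0]
            merged[-1] = (merged[-1][0] + head, min(merged[-1][1], w))
            rest = blocks[1:]
        else:
            rest = blocks
            if blocks:
                merged.append(blocks[0])
                rest = blocks[1:]
        merged.extend(rest)
        prev_symbol = symbol

    # simulate dosages block by block
    geno_rng = _substream(spec.seed, _TAGS["genotypes"])
    n_samples = spec.n_samples
    X = np.zeros((n_samples, len(snp_ids)), dtype=np.int8)
    true_blocks: list[tuple[tuple[str, ...], float]] = []
    for idxs, w in merged:
        e = (1.0 - w**0.25) / 2.0
        h1 = geno_rng.integers(0, 2, size=n_samples)
        h2 = geno_rng.integers(0, 2, size=n_samples)
        for i in idxs:
            f1 = geno_rng.random(n_samples) < e
            f2 = geno_rng.random(n_samples) < e
            X[:, i] = (h1 ^ f1) + (h2 ^ f2)
        true_blocks.append((tuple(snp_ids[i] for i in idxs), w))

    ld = ld_from_genotypes(X, snp_ids, min_store_r2=0.01)

    # pathway collection
    path_rng = _substream(spec.seed, _TAGS["pathways"])
    genes = gene_order
    sizes = _draw_sizes(spec.pathway_size_distribution, spec.n_pathways, path_rng)
    sizes = np.minimum(sizes, len(genes))
    pathways = [
        PathwayDef(
            f"PW{i:04d}",
            f"synthetic pathway {i}",
            frozenset(path_rng.choice(genes, size=int(s), replace=False)),
        )
        for i, s in enumerate(sizes)
    ]
    return Fixture(
        spec=spec,
        snp_ids=snp_ids,
        snp_chrom=snp_chrom,
        snp_pos=snp_pos,
        dosages=X,
        ld=ld,
        isoforms=isoforms,
        pathways=pathways,
        true_blocks=true_blocks,
        gene_snps=gene_snps,
    )


def generate_null_stats(
    fixture: Fixture,
    mode: str = "ld_coupled",
    rho: float = 0.5,
    seed: int | None = None,
) -> list[SnpRecord]:
    """Null P-values for every fixture SNP.

    ``iid``: independent uniform(0, 1] draws.  ``ld_coupled``: a Gaussian
    one-factor copula per true LD block with loading sqrt(rho), so SNPs of a
    block share their signal while marginals stay exactly uniform.
    """
    if mode not in ("iid", "ld_coupled"):
        raise ValueError(f"unknown null mode {mode!r}")
    spec_seed = fixture.spec.seed if seed is None else seed
    rng = _substream(spec_seed, _TAGS["stats"])
    n = len(fixture.snp_ids)
    if mode == "iid":
        p = 1.0 - rng.random(n)  # in (0, 1]
    else:
        z = np.empty(n)
        index = {s: i for i, s in enumerate(fixture.snp_ids)}
        for snps, _w in fixture.true_blocks:
            zb = rng.standard_normal()
            eps = rng.standard_normal(len(snps))
            for k, sid in enumerate(snps):
                z[index[sid]] = np.sqrt(rho) * zb + np.sqrt(1 - rho) * eps[k]
        p = sps.norm.sf(z)  # uniform marginals, upper tail = small p
        p = np.clip(p, 1e-300, 1.0)
    return [
        SnpRecord(sid, fixture.snp_chrom[sid], fixture.snp_pos[sid], float(p[i]))
        for i, sid in enumerate(fixture.snp_ids)
    ]


def generate_enriched_stats(
    fixture: Fixture,
    enrichment: Mapping[str, float] | None = None,
    seed: int | None = None,
    snp_alpha: float = 0.05,
    base_mode: str = "ld_coupled",
    rho: float = 0.5,
) -> list[SnpRecord]:
    """Null stats with enriched pathways' SNPs made significant at a target rate.

    Each SNP of an enriched pathway is redrawn: with probability equal to the
    target fraction from a concentrated small-P component on (0, snp_alpha)
    (density pushed toward 0), otherwise uniform on (snp_alpha, 1).  The
    realized significant fraction therefore has expectation exactly equal to
    the target.  A SNP reachable from two enriched pathways with different
    targets is a configuration error.
    """
    if enrichment is None:
        enrichment = dict(fixture.spec.enriched_pathways)
    base = generate_null_stats(fixture, mode=base_mode, rho=rho, seed=seed)
    target_of: dict[str, float] = {}
    for pid, frac in enrichment.items():
        if not 0.0 < frac < 1.0:
            raise ValueError(f"target fraction {frac} for {pid} outside (0, 1)")
        for sid in fixture.pathway_snps(pid):
            if sid in target_of and target_of[sid] != frac:
                raise ValueError(
                    f"SNP {sid} in two enriched pathways with conflicting targets"
                )
            target_of[sid] = frac
    spec_seed = fixture.spec.seed if seed is None else seed
    rng = _substream(spec_seed, _TAGS["enrich"])
    out = []
    for rec in base:
        t = target_of.get(rec.snp_id)
        if t is None:
            out.append(rec)
            continue
        if rng.random() < t:
            p = snp_alpha * rng.random() ** 3  # concentrated near 0
            p = max(p, 1e-300)
        else:
            p = snp_alpha + (1.0 - snp_alpha) * (1.0 - rng.random())
        out.append(SnpRecord(rec.snp_id, rec.chrom, rec.pos, float(p)))
    return out
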