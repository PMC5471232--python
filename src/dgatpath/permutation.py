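"""Adaptive permutation test against the genome-wide block pool.

The null model compares a pathway of n LD blocks against random "pathways"
of n blocks sampled from the pool of block statistics of *all* analyzed
pathways, built by the identical mapping/blocking/scoring procedure.  The
association P-value is the chance that a resampled score reaches the
observed one, estimated with the add-one correction

    p_assoc = (#{S_perm >= S_obs} + 1) / (N + 1),

so it is never exactly 0 and is floored at 1/(max permutations + 1).

Sampling is staged (1e3, 1e4, 1e5, 1e6 draws by default): after each stage
the interim estimate is checked and sampling stops once it exceeds
``alpha_stop`` (default 0.05) — clearly non-significant pathways cost 1,000
draws, significant ones get the full budget.  Each pathway draws from its
own random substream derived by stable hashing of the pathway id, so
results do not depend on iteration order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data_io import IsoformRow, LdSource, PathwayDef, SnpRecord
from .ld_blocking import block_pathway
from .mapping import (
    GeneModel,
    PathwaySnpSet,
    assign_snps,
    collect_pathway_snps,
    filter_pathways,
    merge_isoforms,
)
from .scoring import ScoredBlock, pathway_score, score_blocks

__all__ = [
    "BlockPool",
    "PathwayResult",
    "RunConfig",
    "RunResult",
    "build_pool",
    "perm_pvalue",
    "run_dgat_path",
    "pathway_subseed",
    "write_results_tsv",
    "DEFAULT_SCHEDULE",
]

DEFAULT_SCHEDULE = (1_000, 10_000, 100_000, 1_000_000)


@dataclass(frozen=True)
class BlockPool:
    """Multiset of block chi-square statistics across all analyzed pathways."""

    stats: np.ndarray

    @property
    def size(self) -> int:
        return int(self.stats.shape[0])


@dataclass(frozen=True, slots=True)
class PathwayResult:
    pathway_id: str
    n_blocks: int
    s_obs: float
    n_perm_used: int
    n_exceed: int
    p_assoc: float
    n_genes_mapped: int = 0
    n_snps: int = 0


@dataclass(frozen=True)
class RunConfig:
    """Everything that parameterises one end-to-end analysis."""

    flank_bp: int = 15_000
    r2_threshold: float = 0.1
    scope: str = "pathway"
    min_genes: int = 5
    max_genes: int = 300
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    alpha_stop: float | None = 0.05
    seed: int = 0
    sampling_mode: str = "without"  # "without" | "with" replacement

    def fingerprint(self) -> str:
        return (
            f"r2={self.r2_threshold} flank={self.flank_bp} scope={self.scope} "
            f"genes=[{self.min_genes},{self.max_genes}] seed={self.seed} "
            f"schedule={','.join(map(str, self.schedule))} "
            f"alpha_stop={self.alpha_stop} sampling={self.sampling_mode}"
        )


@dataclass
class RunResult:
    """Output bundle of :func:`run_dgat_path`."""

    results: list[PathwayResult]
    non_testable: list[str]
    config: RunConfig
    gene_models: list[GeneModel] = field(repr=False, default_factory=list)
    gene_snps: dict[str, frozenset[str]] = field(repr=False, default_factory=dict)
    pathway_genes: dict[str, frozenset[str]] = field(repr=False, default_factory=dict)
    pathway_blocks: dict[str, list[ScoredBlock]] = field(
        repr=False, default_factory=dict
    )
    pool: BlockPool | None = field(repr=False, default=None)


def build_pool(all_pathway_blocks: Mapping[str, Sequence[ScoredBlock]]) -> BlockPool:
    """Concatenate every pathway's block statistics (duplicates kept).

    A genomic block reached through several pathways contributes once per
    pathway, weighting the pool by pathway usage.
    """
    if not all_pathway_blocks:
        raise ValueError("cannot build a permutation pool from zero pathways")
    stats = np.array(
        [sb.chi2 for pid in sorted(all_pathway_blocks) for sb in all_pathway_blocks[pid]],
        dtype=float,
    )
    return BlockPool(stats)


def pathway_subseed(master_seed: int, pathway_id: str) -> int:
    """Stable per-pathway substream seed (< 2**31), order-independent."""
    digest = hashlib.sha256(f"{master_seed}:{pathway_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sample_sums(
    pool: np.ndarray,
    n: int,
    n_draws: int,
    rng: np.random.Generator,
    replace: bool,
) -> np.ndarray:
    """``n_draws`` sums of ``n`` pool values, each draw without (or with)
    replacement *within* itself; draws are independent redraws."""
    m = pool.shape[0]
    if n == 1 or replace:
        idx = rng.integers(0, m, size=(n_draws, n))
        return pool[idx].sum(axis=1)
    if n == m:
        return np.full(n_draws, pool.sum())
    if n <= m // 2:
        # rejection sampling: redraw only rows containing a duplicate index
        idx = rng.integers(0, m, size=(n_draws, n))
        while True:
            srt = np.sort(idx, axis=1)
            bad = (np.diff(srt, axis=1) == 0).any(axis=1)
            if not bad.any():
                break
            idx[bad] = rng.integers(0, m, size=(int(bad.sum()), n))
        return pool[idx].sum(axis=1)
    # dense case: random keys + argpartition, chunked to bound memory
    sums = np.empty(n_draws)
    chunk = max(1, int(2e7) // m)
    for lo in range(0, n_draws, chunk):
        hi = min(lo + chunk, n_draws)
        keys = rng.random((hi - lo, m))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        sums[lo:hi] = pool[idx].sum(axis=1)
    return sums


def perm_pvalue(
    pathway_id: str,
    s_obs: float,
    n_blocks: int,
    pool: BlockPool,
    schedule: Sequence[int] = DEFAULT_SCHEDULE,
    alpha_stop: float | None = 0.05,
    seed: int = 0,
    sampling_mode: str = "without",
) -> PathwayResult:
    """Adaptive Monte-Carlo association P-value for one pathway.

    Draws ``n_blocks`` statistics from the pool per permutation, sums them,
    and counts permuted scores >= ``s_obs``.  Early stopping is checked only
    at schedule stage boundaries so the estimator stays unbiased within a
    stage.
    """
    if sampling_mode not in ("without", "with"):
        raise ValueError(f"unknown sampling_mode {sampling_mode!r}")
    replace = sampling_mode == "with"
    if not replace and n_blocks > pool.size:
        raise ValueError(
            f"pathway {pathway_id}: n_blocks={n_blocks} exceeds pool size "
            f"{pool.size}; use sampling_mode='with' (with replacement)"
        )
    if list(schedule) != sorted(set(schedule)):
        raise ValueError("schedule must be strictly increasing")
    rng = np.random.default_rng(seed)
    n_done = 0
    n_exceed = 0
    for stage in schedule:
        draws = stage - n_done
        sums = _sample_sums(pool.stats, n_blocks, draws, rng, replace)
        n_exceed += int((sums >= s_obs).sum())
        n_done = stage
        p_interim = (n_exceed + 1) / (n_done + 1)
        if alpha_stop is not None and p_interim > alpha_stop:
            break
    return PathwayResult(
        pathway_id=pathway_id,
        n_blocks=n_blocks,
        s_obs=s_obs,
        n_perm_used=n_done,
        n_exceed=n_exceed,
        p_assoc=(n_exceed + 1) / (n_done + 1),
    )


def run_dgat_path(
    snps: list[SnpRecord],
    isoforms: list[IsoformRow],
    pathways: list[PathwayDef],
    ld: LdSource,
    config: RunConfig | None = None,
) -> RunResult:
    """End-to-end analysis: map -> block -> score -> pool -> permute.

    Results are sorted by ascending association P-value (ties by pathway id);
    pathways with no mapped SNPs are reported separately as non-testable.
    """
    cfg = config or RunConfig()
    genes = merge_isoforms(isoforms, snps, flank=cfg.flank_bp)
    gene_snps = assign_snps(genes, snps)
    kept = filter_pathways(
        pathways, set(gene_snps), min_genes=cfg.min_genes, max_genes=cfg.max_genes
    )
    if not kept:
        raise ValueError("no pathway passes the gene-count filter")
    pvals = {s.snp_id: s.pvalue for s in snps}
    chrom_of = {s.snp_id: s.chrom for s in snps}

    psets: dict[str, PathwaySnpSet] = {}
    scored: dict[str, list[ScoredBlock]] = {}
    non_testable: list[str] = []
    for p in kept:
        pset = collect_pathway_snps(p, gene_snps)
        psets[p.pathway_id] = pset
        if not pset.testable:
            non_testable.append(p.pathway_id)
            continue
        blocks = block_pathway(
            pset, gene_snps, ld, scope=cfg.scope, r2_threshold=cfg.r2_threshold,
            chrom_of=chrom_of,
        )
        scored[p.pathway_id] = score_blocks(blocks, pvals)
    if not scored:
        raise ValueError("zero testable pathways")
    pool = build_pool(scored)

    results: list[PathwayResult] = []
    for pid in sorted(scored):
        ps = pathway_score(pid, scored[pid])
        res = perm_pvalue(
            pid,
            ps.s_obs,
            ps.n_blocks,
            pool,
            schedule=cfg.schedule,
            alpha_stop=cfg.alpha_stop,
            seed=pathway_subseed(cfg.seed, pid),
            sampling_mode=cfg.sampling_mode,
        )
        results.append(
            replace(
                res,
                n_genes_mapped=len(psets[pid].gene_symbols),
                n_snps=len(psets[pid].snp_ids),
            )
        )
    results.sort(key=lambda r: (r.p_assoc, r.pathway_id))
    return RunResult(
        results=results,
        non_testable=sorted(non_testable),
        config=cfg,
        gene_models=genes,
        gene_snps=gene_snps,
        pathway_genes={p.pathway_id: p.gene_symbols for p in kept},
        pathway_blocks=scored,
        pool=pool,
    )


def write_results_tsv(
    run: RunResult, path: str | Path, names: Mapping[str, str] | None = None
) -> None:
    """Write the per-pathway results table with a config-fingerprint header."""
    names = names or {}
    with open(path, "w") as fh:
        fh.write(f"# dgatpath {run.config.fingerprint()}\n")
        fh.write(
            "pathway_id\tname\tn_genes_mapped\tn_snps\tn_blocks\ts_obs\t"
            "n_perm_used\tp_assoc\n"
        )
        for r in run.results:
            fh.write(
                f"{r.pathway_id}\t{names.get(r.pathway_id, '')}\t"
                f"{r.n_genes_mapped}\t{r.n_snps}\t{r.n_blocks}\t"
                f"{r.s_obs:.6g}\t{r.n_perm_used}\t{r.p_assoc:.6g}\n"
            )
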