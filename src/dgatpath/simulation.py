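"""Type-I-error and power evaluation designs for the pathway test.

Type I error: pathways are re-assembled by randomly assigning genes, which
breaks biological gene relationships while leaving every SNP's P-value and
the LD structure untouched.  The fraction of such null pathways declared
significant at a nominal level is the empirical type I error rate, reported
overall and within four pathway-size bins.

Power: for each tested pathway, all of its SNPs' P-values are multiplied by
one factor chosen so that a prescribed fraction of them (30/50/70/80% by
default) falls below 0.05; the pathway is then re-scored and tested against
the *unscaled* genome-wide block pool.  Power is the fraction of pathways
with association P < 0.05, again stratified by size bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .data_io import IsoformRow, LdSource, PathwayDef, SnpRecord
from .mapping import REFERENCE_CUTPOINTS, size_bins
from .permutation import RunConfig, RunResult, pathway_subseed, perm_pvalue, run_dgat_path
from .scoring import ScoredBlock, chi2_from_p, pathway_score

__all__ = [
    "Type1Config",
    "PowerConfig",
    "random_pathways",
    "type1_error",
    "rate_table",
    "enrichment_factor",
    "power",
]


@dataclass(frozen=True)
class Type1Config:
    n_random_pathways: int = 1_000
    nominal_alphas: tuple[float, ...] = (0.01, 0.02, 0.05, 0.08, 0.1)
    preserve_sizes: bool = True
    sizes: tuple[int, ...] | None = None  # used when preserve_sizes is False
    bin_cutpoints: tuple[int, int, int] | None = REFERENCE_CUTPOINTS
    seed: int = 0


@dataclass(frozen=True)
class PowerConfig:
    target_fractions: tuple[float, ...] = (0.30, 0.50, 0.70, 0.80)
    snp_alpha: float = 0.05
    power_alpha: float = 0.05
    bin_cutpoints: tuple[int, int, int] | None = REFERENCE_CUTPOINTS
    seed: int = 0


def random_pathways(
    gene_pool: Sequence[str],
    sizes: Sequence[int],
    seed: int = 0,
    id_prefix: str = "RND",
) -> list[PathwayDef]:
    """Assemble null pathways by uniform gene sampling without replacement."""
    rng = np.random.default_rng(seed)
    pool = np.asarray(sorted(gene_pool))
    out = []
    for i, s in enumerate(sizes):
        if s > len(pool):
            raise ValueError(f"requested size {s} exceeds gene pool {len(pool)}")
        genes = rng.choice(pool, size=int(s), replace=False)
        out.append(PathwayDef(f"{id_prefix}{i:05d}", f"random pathway {i}", frozenset(genes)))
    return out


def rate_table(
    pvals: Mapping[str, float],
    bins: Mapping[str, int],
    alphas: Sequence[float],
) -> pd.DataFrame:
    """Exceedance rates per (alpha, size bin) with binomial 95% CIs.

    ``bins`` maps pathway id -> bin in {1..4}; an ``overall`` row per alpha
    aggregates all bins.  Empty bins yield NaN rates.
    """
    rows = []
    groups: dict[object, list[float]] = {"overall": list(pvals.values())}
    for pid, p in pvals.items():
        groups.setdefault(bins[pid], []).append(p)
    for alpha in alphas:
        for key in ["overall", 1, 2, 3, 4]:
            ps = groups.get(key, [])
            n = len(ps)
            if n == 0:
                rows.append((alpha, key, 0, math.nan, math.nan, math.nan))
                continue
            hits = sum(p < alpha for p in ps)
            lo, hi = proportion_confint(hits, n, alpha=0.05, method="wilson")
            rows.append((alpha, key, n, hits / n, lo, hi))
    return pd.DataFrame(
        rows, columns=["alpha", "size_bin", "n", "rate", "ci_low", "ci_high"]
    )


def type1_error(
    snps: list[SnpRecord],
    isoforms: list[IsoformRow],
    ld: LdSource,
    size_source: Sequence[int],
    cfg: Type1Config | None = None,
    run_config: RunConfig | None = None,
) -> tuple[pd.DataFrame, RunResult]:
    """Empirical type I error of the full pipeline on random pathways.

    ``size_source`` is the empirical size distribution to resample pathway
    sizes from (e.g. the sizes of a real collection); with
    ``preserve_sizes=False`` the explicit ``cfg.sizes`` are cycled instead.
    Returns the rate table and the underlying run for inspection.
    """
    cfg = cfg or Type1Config()
    run_config = run_config or RunConfig()
    rng = np.random.default_rng(cfg.seed)
    if cfg.preserve_sizes:
        if not len(size_source):
            raise ValueError("size_source is empty")
        sizes = rng.choice(np.asarray(size_source), size=cfg.n_random_pathways)
    else:
        if not cfg.sizes:
            raise ValueError("preserve_sizes=False requires explicit sizes")
        reps = -(-cfg.n_random_pathways // len(cfg.sizes))
        sizes = (list(cfg.sizes) * reps)[: cfg.n_random_pathways]
    gene_pool = sorted({r.gene_symbol for r in isoforms})
    sizes = np.minimum(np.asarray(sizes, dtype=int), len(gene_pool))
    randoms = random_pathways(gene_pool, sizes, seed=cfg.seed + 1)
    run = run_dgat_path(snps, isoforms, randoms, ld, run_config)
    kept = [
        PathwayDef(pid, "", genes) for pid, genes in run.pathway_genes.items()
    ]
    bins = size_bins(kept, cutpoints=cfg.bin_cutpoints)
    pvals = {r.pathway_id: r.p_assoc for r in run.results}
    return rate_table(pvals, bins, cfg.nominal_alphas), run


def reference_null_experiment(
    seed: int = 0,
    n_random_pathways: int = 500,
    n_replicates: int = 8,
    scope: str = "pathway",
    n_genes_per_chrom: int = 100,
    schedule: tuple[int, ...] = (1_000, 10_000),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The package's standard type-I-error calibration experiment.

    One replicate builds a synthetic dataset — 2 chromosomes x
    ``n_genes_per_chrom`` genes, 4–10 SNPs per gene, block LD with
    within-block r² 0.5, 20% of adjacent gene pairs sharing a block — draws
    block-coupled null P-values, assembles ``n_random_pathways`` random
    pathways with log-uniform sizes from 5 up to the gene-pool size
    (spanning all four reference size bins), and runs the full pipeline.

    Because every random pathway of one replicate shares a single
    realization of the block statistics, a lone replicate estimates the
    dataset-conditional rejection rate with an irreducible error of a
    percentage point or more; the experiment therefore repeats the whole
    construction ``n_replicates`` times on independent data and pools the
    rejection counts, which is what the rate table reports.  Returns the
    pooled table and a per-replicate overall-rate table.  All randomness
    derives from ``seed``; the permutation schedule defaults to 10,000-draw
    stages.
    """
    from .synthetic_data import FixtureSpec, generate_fixture, generate_null_stats

    n_genes = 2 * n_genes_per_chrom
    alphas = (0.01, 0.05, 0.1)
    pooled_pvals: dict[str, float] = {}
    pooled_bins: dict[str, int] = {}
    per_rep = []
    for rep in range(n_replicates):
        rep_seed = seed + 1000 * rep
        spec = FixtureSpec(
            seed=rep_seed,
            n_chroms=2,
            genes_per_chrom=n_genes_per_chrom,
            snps_per_gene=(4, 10),
            block_structure=((4, 0.5), (3, 0.5)),
            cross_gene_ld_fraction=0.2,
            n_pathways=1,  # the real collection is the random one built below
            n_samples=300,
        )
        fx = generate_fixture(spec)
        stats = generate_null_stats(fx, mode="ld_coupled", rho=0.5, seed=rep_seed + 1)
        rng = np.random.default_rng(rep_seed + 2)
        sizes = np.exp(
            rng.uniform(np.log(5), np.log(n_genes), size=n_random_pathways)
        ).astype(int)
        cfg = Type1Config(
            n_random_pathways=n_random_pathways,
            nominal_alphas=alphas,
            preserve_sizes=True,
            seed=rep_seed + 3,
        )
        run_cfg = RunConfig(scope=scope, schedule=schedule, seed=rep_seed + 4)
        tab, run = type1_error(stats, fx.isoforms, fx.ld, sizes, cfg, run_cfg)
        kept = [
            PathwayDef(pid, "", genes) for pid, genes in run.pathway_genes.items()
        ]
        bins = size_bins(kept, cutpoints=cfg.bin_cutpoints)
        for r in run.results:
            key = f"rep{rep}:{r.pathway_id}"
            pooled_pvals[key] = r.p_assoc
            pooled_bins[key] = bins[r.pathway_id]
        overall = tab[tab.size_bin == "overall"]
        per_rep.append(
            {"replicate": rep, **{f"rate_{a}": float(overall[overall.alpha == a].rate.iloc[0]) for a in alphas}}
        )
    pooled = rate_table(pooled_pvals, pooled_bins, alphas)
    return pooled, pd.DataFrame(per_rep)


def enrichment_factor(
    pvals: Sequence[float], target_fraction: float, snp_alpha: float = 0.05
) -> float:
    """Multiplier making at least ``target_fraction`` of P-values significant.

    With k = ceil(target_fraction * n) and p_(k) the k-th smallest P-value,
    f = snp_alpha / p_(k) * (1 - 1e-9): after multiplying every P by f,
    exactly the k smallest fall strictly below ``snp_alpha`` (up to ties),
    the smallest attainable fraction >= target.  f may exceed 1 when the
    pathway is already enriched beyond the target (de-enrichment).
    """
    n = len(pvals)
    if n == 0:
        raise ValueError("pathway has no SNP P-values")
    if not 0.0 < target_fraction < 1.0:
        raise ValueError(f"target fraction {target_fraction} outside (0, 1)")
    k = math.ceil(target_fraction * n)
    p_k = float(np.sort(np.asarray(pvals, dtype=float))[k - 1])
    return snp_alpha / p_k * (1.0 - 1e-9)


def power(
    snps: list[SnpRecord],
    isoforms: list[IsoformRow],
    pathways: list[PathwayDef],
    ld: LdSource,
    cfg: PowerConfig | None = None,
    run_config: RunConfig | None = None,
) -> tuple[pd.DataFrame, RunResult]:
    """Power of the test under the fixed-significant-fraction design.

    The baseline pipeline is run once; per pathway and target fraction its
    SNP P-values are rescaled (capped at 1), its existing blocks re-scored
    (blocking depends only on LD, not on P), and the rescored S_obs is tested
    against the unscaled pool.  Rows are (fraction, size_bin) with the
    fraction of pathways at association P < ``power_alpha``.
    """
    cfg = cfg or PowerConfig()
    run_config = run_config or RunConfig()
    base = run_dgat_path(snps, isoforms, pathways, ld, run_config)
    assert base.pool is not None
    pvals = {s.snp_id: s.pvalue for s in snps}
    kept = [PathwayDef(pid, "", genes) for pid, genes in base.pathway_genes.items()]
    bins = size_bins(kept, cutpoints=cfg.bin_cutpoints)

    pathway_pvals: dict[str, np.ndarray] = {}
    for pid, blocks in base.pathway_blocks.items():
        snp_union = sorted({s for b in blocks for s in b.block.snp_ids})
        pathway_pvals[pid] = np.array([pvals[s] for s in snp_union])

    rows = []
    for frac in cfg.target_fractions:
        sig: dict[str, float] = {}
        for pid, blocks in base.pathway_blocks.items():
            f = enrichment_factor(pathway_pvals[pid], frac, cfg.snp_alpha)
            scaled = {
                s: min(pvals[s] * f, 1.0)
                for b in blocks
                for s in b.block.snp_ids
            }
            rescored: list[ScoredBlock] = []
            for b in blocks:
                rep_p, rep_snp = min((scaled[s], s) for s in b.block.snp_ids)
                rescored.append(
                    ScoredBlock(b.block, rep_snp, rep_p, chi2_from_p(max(rep_p, 1e-300)))
                )
            ps = pathway_score(pid, rescored)
            res = perm_pvalue(
                pid,
                ps.s_obs,
                ps.n_blocks,
                base.pool,
                schedule=run_config.schedule,
                alpha_stop=run_config.alpha_stop,
                seed=pathway_subseed(cfg.seed, f"{pid}@{frac}"),
                sampling_mode=run_config.sampling_mode,
            )
            sig[pid] = res.p_assoc
        tab = rate_table(sig, bins, [cfg.power_alpha])
        tab = tab.rename(columns={"alpha": "fraction", "rate": "power"})
        tab["fraction"] = frac
        rows.append(tab)
    return pd.concat(rows, ignore_index=True), base
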