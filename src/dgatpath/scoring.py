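"""Block scoring: min-P to chi-square(1 df), summed to the pathway score.

Each LD block is represented by its most significant SNP.  That SNP's
P-value is converted to the upper-tail chi-square quantile with one degree
of freedom — the x with ``chi2(1).sf(x) = p`` — and the block statistics are
summed over a pathway to give the observed score S_obs.  No within-block
multiplicity adjustment is applied: the block minimum is upward-biased, but
the permutation pool is built with the identical biased statistic, which is
what keeps the test valid.

Under n independent blocks with representative P-values i.i.d. uniform on
(0, 1), S_obs is exactly chi-square distributed with n degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ld_blocking import LdBlock

__all__ = [
    "ScoredBlock",
    "PathwayScore",
    "chi2_from_p",
    "score_blocks",
    "pathway_score",
    "P_UNDERFLOW_FLOOR",
]

#: P-values below this are clamped before conversion so S_obs stays finite
P_UNDERFLOW_FLOOR = 1e-300


@dataclass(frozen=True, slots=True)
class ScoredBlock:
    block: LdBlock
    rep_snp: str
    rep_p: float
    chi2: float


@dataclass(frozen=True, slots=True)
class PathwayScore:
    pathway_id: str
    n_blocks: int
    s_obs: float


def chi2_from_p(p: float) -> float:
    """Upper-tail chi-square(1 df) quantile of ``p``.

    ``p`` must lie in (0, 1]; values below 1e-300 are clamped to keep the
    statistic finite (isf(1e-300, 1) ≈ 1373).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value {p} outside (0, 1]")
    p = max(p, P_UNDERFLOW_FLOOR)
    return float(stats.chi2.isf(p, df=1))


def score_blocks(
    blocks: Sequence[LdBlock], pvals: Mapping[str, float]
) -> list[ScoredBlock]:
    """Pick each block's lowest-P SNP and convert it to a chi-square statistic.

    Ties on P break to the lexicographically smallest SNP id, keeping output
    deterministic across platforms.
    """
    scored = []
    for block in blocks:
        missing = [s for s in block.snp_ids if s not in pvals]
        if missing:
            raise KeyError(
                f"block {block.block_id}: no P-value for SNP(s) {sorted(missing)}"
            )
        rep_p, rep_snp = min((pvals[s], s) for s in block.snp_ids)
        scored.append(ScoredBlock(block, rep_snp, rep_p, chi2_from_p(rep_p)))
    return scored


def pathway_score(pathway_id: str, scored: Sequence[ScoredBlock]) -> PathwayScore:
    """Sum block chi-square statistics into the observed score S_obs."""
    if not scored:
        raise ValueError(f"pathway {pathway_id}: no scored blocks (non-testable)")
    s_obs = float(np.sum([b.chi2 for b in scored]))
    return PathwayScore(pathway_id, len(scored), s_obs)
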