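"""Post-hoc utilities: Bonferroni thresholds and ranked-overlap curves."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .permutation import PathwayResult

__all__ = ["OverlapCurve", "significance_threshold", "overlap_curve"]


@dataclass(frozen=True)
class OverlapCurve:
    """Cumulative gene count vs percent overlap with an associated-gene list."""

    points: tuple[tuple[int, float], ...]
    max_genes_cap: int


def significance_threshold(n_pathways: int, family_alpha: float = 0.05) -> float:
    """Bonferroni family-wise cutoff ``family_alpha / n_pathways``.

    E.g. testing 5,764 pathways at alpha 0.05 gives 8.7e-6.
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    return family_alpha / n_pathways


def overlap_curve(
    results: Sequence[PathwayResult],
    pathway_genes: Mapping[str, frozenset[str]],
    catalog_genes: set[str] | frozenset[str],
    cap: int = 1000,
) -> OverlapCurve:
    """Percent of accumulated top-pathway genes found in a catalog gene list.

    Walks pathways in rank order (input must be sorted by ascending
    association P, ties by pathway id), accumulating the union of mapped
    genes; one point per pathway that contributes at least one new gene, and
    the walk stops before the union would exceed ``cap``.
    """
    if not catalog_genes:
        raise ValueError("catalog gene list is empty")
    catalog = frozenset(catalog_genes)
    union: set[str] = set()
    points: list[tuple[int, float]] = []
    for r in results:
        genes = pathway_genes.get(r.pathway_id, frozenset())
        new = genes - union
        if not new:
            continue
        if len(union) + len(new) > cap:
            break
        union |= new
        pct = 100.0 * len(union & catalog) / len(union)
        points.append((len(union), pct))
    return OverlapCurve(tuple(points), cap)
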