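"""Readers and writers for the four external inputs.

Everything downstream works on the domain types defined here:

* :class:`SnpRecord` — one row of GWAS summary statistics,
* :class:`IsoformRow` — one transcript interval of a gene annotation,
* :class:`PathwayDef` — one gene set from a GMT file,
* :class:`LdSource` — a symmetric sparse lookup of pairwise r².

Conventions: coordinates are 1-based closed intervals (RefSeq/PLINK style;
BED input is converted on read); chromosome names are normalised by stripping
a leading ``chr`` and upper-casing X/Y; an LD pair absent from the source has
r² = 0, matching the PLINK pair-list convention of omitting below-threshold
pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "RecordError",
    "SnpRecord",
    "IsoformRow",
    "PathwayDef",
    "LdSource",
    "normalize_chrom",
    "read_summary_stats",
    "write_summary_stats",
    "read_gene_table",
    "read_bed_genes",
    "write_gene_table",
    "read_gmt",
    "write_gmt",
    "read_ld_pairs",
    "write_ld_pairs",
    "ld_from_genotypes",
    "read_dosage_matrix",
    "write_dosage_matrix",
]

#: default floor used when zero P-values are clamped instead of rejected
P_FLOOR = 1e-300

DEFAULT_COLUMNS = {"chrom": "CHR", "snp": "SNP", "pos": "BP", "pvalue": "P"}


class FormatError(ValueError):
    """The file as a whole is malformed (missing column, bad header, ...)."""


class RecordError(ValueError):
    """A single record is invalid; the message carries the line number."""


@dataclass(frozen=True, slots=True)
class SnpRecord:
    """One GWAS summary-statistic row."""

    snp_id: str
    chrom: str
    pos: int
    pvalue: float


@dataclass(frozen=True, slots=True)
class IsoformRow:
    """One transcript interval; a gene may contribute several rows."""

    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise RecordError(
                f"isoform of {self.gene_symbol}: tx_start {self.tx_start} > "
                f"tx_end {self.tx_end}"
            )


@dataclass(frozen=True, slots=True)
class PathwayDef:
    """A named gene set."""

    pathway_id: str
    name: str
    gene_symbols: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.gene_symbols)


def normalize_chrom(chrom: str) -> str:
    """``chr1`` -> ``1``, ``chrx`` -> ``X``; unplaced contigs pass through."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.lower() in ("x", "y"):
        return c.upper()
    return c


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    clamp_zero: bool = False,
    p_floor: float = P_FLOOR,
) -> list[SnpRecord]:
    """Read whitespace/tab-delimited summary statistics with a header row.

    Parameters
    ----------
    path:
        Delimited text file; default column names CHR, SNP, BP, P.
    column_map:
        Overrides for the logical->header name mapping, keys among
        ``{"chrom", "snp", "pos", "pvalue"}``.
    clamp_zero:
        If True, P = 0 is clamped to ``p_floor`` instead of rejected.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    for logical, name in cols.items():
        if name not in df.columns:
            raise FormatError(f"missing required column {name!r} (for {logical})")
    records: list[SnpRecord] = []
    seen: set[str] = set()
    # header occupies line 1, so data row i (0-based) is file line i + 2
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        snp_id = str(getattr(row, cols["snp"]))
        try:
            pos = int(getattr(row, cols["pos"]))
            p = float(getattr(row, cols["pvalue"]))
        except (TypeError, ValueError) as exc:
            raise RecordError(f"line {line}: non-numeric field ({exc})") from None
        if not np.isfinite(p) or p < 0 or p > 1:
            raise RecordError(f"line {line}: P-value {p} outside [0, 1]")
        if p == 0:
            if clamp_zero:
                p = p_floor
            else:
                raise RecordError(
                    f"line {line}: P-value is 0 (enable clamp_zero to floor it)"
                )
        if snp_id in seen:
            raise RecordError(f"line {line}: duplicate SNP id {snp_id!r}")
        seen.add(snp_id)
        records.append(
            SnpRecord(snp_id, normalize_chrom(getattr(row, cols["chrom"])), pos, p)
        )
    return records


def write_summary_stats(records: Iterable[SnpRecord], path: str | Path) -> None:
    """Write records in the default CHR/SNP/BP/P dialect, P at full precision."""
    with open(path, "w") as fh:
        fh.write("CHR\tSNP\tBP\tP\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.snp_id}\t{r.pos}\t{r.pvalue!r}\n")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

_GENE_ALIASES = {
    "gene_symbol": ("geneSymbol", "gene_symbol", "gene", "name2", "symbol"),
    "chrom": ("chrom", "chr", "chromosome"),
    "strand": ("strand",),
    "tx_start": ("txStart", "tx_start", "start"),
    "tx_end": ("txEnd", "tx_end", "end"),
}


def read_gene_table(path: str | Path) -> list[IsoformRow]:
    """Read a RefSeq-flat-like isoform table (one row per transcript).

    Header columns are matched case-insensitively against common aliases
    (geneSymbol/gene, chrom/chr, strand, txStart/start, txEnd/end).
    Coordinates are taken as 1-based closed.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for logical, aliases in _GENE_ALIASES.items():
        for alias in aliases:
            if alias.lower() in lower:
                resolved[logical] = lower[alias.lower()]
                break
        else:
            raise FormatError(f"missing gene-table column for {logical!r}")
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            IsoformRow(
                gene_symbol=str(getattr(r, resolved["gene_symbol"])),
                chrom=normalize_chrom(getattr(r, resolved["chrom"])),
                strand=str(getattr(r, resolved["strand"])),
                tx_start=int(getattr(r, resolved["tx_start"])),
                tx_end=int(getattr(r, resolved["tx_end"])),
            )
        )
    return rows


def read_bed_genes(path: str | Path) -> list[IsoformRow]:
    """Read BED6 gene intervals (0-based half-open -> 1-based closed)."""
    rows = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            fields = raw.split("\t")
            if len(fields) < 6:
                raise FormatError(f"line {i}: BED6 needs 6 fields, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            rows.append(
                IsoformRow(
                    gene_symbol=name,
                    chrom=normalize_chrom(chrom),
                    strand=strand,
                    tx_start=int(start) + 1,
                    tx_end=int(end),
                )
            )
    return rows


def write_gene_table(rows: Iterable[IsoformRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("geneSymbol\tchrom\tstrand\ttxStart\ttxEnd\n")
        for r in rows:
            fh.write(f"{r.gene_symbol}\t{r.chrom}\t{r.strand}\t{r.tx_start}\t{r.tx_end}\n")


# ---------------------------------------------------------------------------
# pathways (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[PathwayDef]:
    """Read a GMT file: ``id<TAB>description<TAB>gene1<TAB>gene2...`` per line.

    Duplicate gene symbols within one line are deduplicated; a line whose gene
    list is empty is skipped with a warning; a duplicate pathway id raises.
    """
    defs: list[PathwayDef] = []
    seen: set[str] = set()
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw.strip():
                continue
            fields = raw.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {i}: GMT line needs >=3 tab-separated fields")
            pid, name, *genes = fields
            genes = [g for g in genes if g.strip()]
            if pid in seen:
                raise FormatError(f"line {i}: duplicate pathway id {pid!r}")
            seen.add(pid)
            if not genes:
                warnings.warn(f"GMT line {i}: pathway {pid!r} has no genes; skipped")
                continue
            defs.append(PathwayDef(pid, name, frozenset(genes)))
    return defs


def write_gmt(pathways: Iterable[PathwayDef], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            genes = "\t".join(sorted(p.gene_symbols))
            fh.write(f"{p.pathway_id}\t{p.name}\t{genes}\n")


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

class LdSource:
    """Symmetric sparse pairwise-r² lookup over SNP ids.

    ``r2(a, a)`` is 1; any pair not stored returns 0.  Internally pairs are
    keyed by the sorted id tuple, and an adjacency index is kept so blocking
    can enumerate a SNP's LD partners without scanning the whole table.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None) -> None:
        self._pairs: dict[tuple[str, str], float] = {}
        self._adj: dict[str, list[tuple[str, float]]] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.add_pair(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_pair(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise RecordError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a == b:
            return
        key = self._key(a, b)
        old = self._pairs.get(key)
        if old is not None:
            if old == r2:
                return
            warnings.warn(
                f"conflicting r2 for pair {key}: {old} vs {r2}; keeping max"
            )
            if r2 <= old:
                return
            # replace in adjacency below
            self._adj[a] = [(n, x) for n, x in self._adj[a] if n != b]
            self._adj[b] = [(n, x) for n, x in self._adj[b] if n != a]
        self._pairs[key] = r2
        self._adj.setdefault(a, []).append((b, r2))
        self._adj.setdefault(b, []).append((a, r2))

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(self._key(a, b), 0.0)

    def neighbors(self, snp_id: str) -> list[tuple[str, float]]:
        """All stored partners of a SNP as ``(other_id, r2)`` pairs."""
        return self._adj.get(snp_id, [])

    @property
    def pairs(self) -> dict[tuple[str, str], float]:
        return dict(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)


def read_ld_pairs(path: str | Path) -> LdSource:
    """Read a PLINK ``.ld``-style pair list (needs SNP_A, SNP_B, R2 columns)."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    for col in ("SNP_A", "SNP_B", "R2"):
        if col not in df.columns:
            raise FormatError(f"missing LD column {col!r}")
    src = LdSource()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            r2 = float(row.R2)
        except ValueError:
            raise RecordError(f"line {i + 2}: non-numeric R2 {row.R2!r}") from None
        try:
            src.add_pair(str(row.SNP_A), str(row.SNP_B), r2)
        except RecordError as exc:
            raise RecordError(f"line {i + 2}: {exc}") from None
    return src


def write_ld_pairs(ld: LdSource, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("SNP_A\tSNP_B\tR2\n")
        for (a, b), r2 in sorted(ld.pairs.items()):
            fh.write(f"{a}\t{b}\t{r2!r}\n")


def ld_from_genotypes(
    dosages: np.ndarray,
    snp_ids: Sequence[str],
    *,
    min_store_r2: float = 1e-4,
) -> LdSource:
    """Build an :class:`LdSource` from a samples x SNPs dosage matrix.

    r² is the squared Pearson correlation of dosage columns, clipped to
    [0, 1].  A constant column has undefined correlation; its r² with any
    partner is taken as 0 with a warning.  Pairs with r² below
    ``min_store_r2`` are not stored (they read back as 0, the absent-pair
    convention).
    """
    X = np.asarray(dosages, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("dosage matrix must be 2-D with >= 2 samples")
    if X.shape[1] != len(snp_ids):
        raise ValueError("snp_ids length does not match dosage columns")
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    constant = norms == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant dosage column(s); their r2 is 0"
        )
    norms[constant] = 1.0  # avoid division warnings; rows zeroed below
    Z = Xc / norms
    Z[:, constant] = 0.0
    corr = Z.T @ Z
    r2 = np.clip(corr**2, 0.0, 1.0)
    src = LdSource()
    iu, ju = np.triu_indices(len(snp_ids), k=1)
    keep = r2[iu, ju] >= min_store_r2
    for i, j in zip(iu[keep], ju[keep]):
        src.add_pair(snp_ids[i], snp_ids[j], float(r2[i, j]))
    return src


def read_dosage_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a delimited dosage matrix whose header row holds SNP ids."""
    df = pd.read_csv(path, sep=r"\s+")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_dosage_matrix(
    dosages: np.ndarray, snp_ids: Sequence[str], path: str | Path
) -> None:
    pd.DataFrame(np.asarray(dosages), columns=list(snp_ids)).to_csv(
        path, sep="\t", index=False
    )
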