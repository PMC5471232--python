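import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgatpath.data_io import LdSource
from dgatpath.ld_blocking import block_pathway, block_snps
from dgatpath.mapping import PathwaySnpSet


def ld_of(pairs):
    src = LdSource()
    for a, b, r2 in pairs:
        src.add_pair(a, b, r2)
    return src


def closure_components(ids, r2mat, thr):
    """Brute-force Floyd–Warshall transitive closure oracle."""
    n = len(ids)
    reach = (np.asarray(r2mat) > thr).astype(bool)
    np.fill_diagonal(reach, True)
    for k in range(n):
        reach |= reach[:, k : k + 1] & reach[k : k + 1, :]
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if reach[i, j]}
        seen |= comp
        comps.append(frozenset(ids[j] for j in comp))
    return frozenset(comps)


class TestBlockSnps:
    def test_transitive_grouping(self):
        ld = ld_of([("a", "b", 0.5), ("b", "c", 0.3), ("a", "c", 0.0)])
        blocks = block_snps({"a", "b", "c"}, ld)
        assert [b.snp_ids for b in blocks] == [frozenset({"a", "b", "c"})]
        # matches the 3-node transitive closure oracle
        mat = [[1, 0.5, 0.0], [0.5, 1, 0.3], [0.0, 0.3, 1]]
        assert {b.snp_ids for b in blocks} == closure_components(["a", "b", "c"], mat, 0.1)

    def test_no_edges_gives_singletons(self):
        ld = ld_of([("a", "b", 0.05), ("b", "c", 0.1)])
        blocks = block_snps({"a", "b", "c"}, ld, r2_threshold=0.1)
        assert sorted(b.snp_ids for b in blocks) == [
            frozenset({"a"}), frozenset({"b"}), frozenset({"c"})
        ]

    def test_threshold_is_strict(self):
        ld = ld_of([("a", "b", 0.1)])
        blocks = block_snps({"a", "b"}, ld, r2_threshold=0.1)
        assert len(blocks) == 2

    def test_absent_snps_become_singletons(self):
        ld = ld_of([("a", "b", 0.9)])
        blocks = block_snps({"a", "b", "zzz"}, ld)
        assert frozenset({"zzz"}) in {b.snp_ids for b in blocks}

    def test_cross_chromosome_edges_cut(self):
        ld = ld_of([("a", "b", 0.9)])
        blocks = block_snps({"a", "b"}, ld, chrom_of={"a": "1", "b": "2"})
        assert len(blocks) == 2

    def test_input_order_invariance_and_deterministic_ids(self):
        rng = np.random.default_rng(3)
        ids = [f"s{i:02d}" for i in range(20)]
        pairs = [
            (ids[i], ids[j], float(rng.random()))
            for i, j in itertools.combinations(range(20), 2)
            if rng.random() < 0.1
        ]
        ld = ld_of(pairs)
        b1 = block_snps(list(ids), ld)
        b2 = block_snps(list(reversed(ids)), ld)
        assert b1 == b2
        assert [b.block_id for b in b1] == [min(b.snp_ids) for b in b1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        ids = [f"s{i:02d}" for i in range(n)]
        mat = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.08:
                mat[i, j] = mat[j, i] = rng.random()
        ld = ld_of(
            [(ids[i], ids[j], mat[i, j]) for i, j in zip(*np.nonzero(np.triu(mat)))]
        )
        got = {b.snp_ids for b in block_snps(ids, ld, 0.1)}
        assert got == closure_components(ids, mat, 0.1)

    def test_raising_threshold_never_merges(self):
        rng = np.random.default_rng(9)
        ids = [f"s{i}" for i in range(30)]
        pairs = [
            (ids[i], ids[j], float(rng.random()))
            for i, j in itertools.combinations(range(30), 2)
            if rng.random() < 0.15
        ]
        ld = ld_of(pairs)
        counts = [len(block_snps(ids, ld, t)) for t in (0.0, 0.1, 0.3, 0.6, 0.9)]
        assert counts == sorted(counts)

    def test_empty_input(self):
        assert block_snps(set(), ld_of([])) == []

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            block_snps({"a"}, ld_of([]), r2_threshold=1.0)


@settings(derandomize=True, deadline=None, max_examples=50)
@given(
    n=st.integers(2, 12),
    edges=st.lists(
        st.tuples(st.integers(0, 11), st.integers(0, 11), st.floats(0, 1)),
        max_size=20,
    ),
    thr=st.floats(0, 0.99),
)
def test_blocks_partition_and_separate(n, edges, thr):
    """Blocks always partition the input, and no two SNPs in different
    blocks of one run share r² above the threshold."""
    ids = [f"s{i}" for i in range(n)]
    ld = LdSource()
    for i, j, r2 in edges:
        if i != j and i < n and j < n:
            a, b = ids[i], ids[j]
            if (min(a, b), max(a, b)) not in ld.pairs:
                ld.add_pair(a, b, r2)
    blocks = block_snps(ids, ld, thr)
    members = [s for b in blocks for s in b.snp_ids]
    assert sorted(members) == sorted(ids)  # partition: no loss, no dup
    for b1, b2 in itertools.combinations(blocks, 2):
        for a in b1.snp_ids:
            for c in b2.snp_ids:
                assert ld.r2(a, c) <= thr


class TestBlockPathway:
    def _pset(self, genes, gene_snps):
        snps = frozenset().union(*gene_snps.values())
        return PathwaySnpSet("P", frozenset(genes), snps)

    def test_cross_gene_ld_merges_only_at_pathway_scope(self):
        gene_snps = {"A": frozenset({"s1"}), "B": frozenset({"s2"})}
        pset = self._pset({"A", "B"}, gene_snps)
        ld = ld_of([("s1", "s2", 0.9)])
        assert len(block_pathway(pset, gene_snps, ld, scope="pathway")) == 1
        assert len(block_pathway(pset, gene_snps, ld, scope="gene")) == 2

    def test_single_gene_pathway_scopes_coincide(self):
        gene_snps = {"A": frozenset({"s1", "s2", "s3"})}
        pset = self._pset({"A"}, gene_snps)
        ld = ld_of([("s1", "s2", 0.4)])
        pw = block_pathway(pset, gene_snps, ld, scope="pathway")
        ge = block_pathway(pset, gene_snps, ld, scope="gene")
        assert {b.snp_ids for b in pw} == {b.snp_ids for b in ge}

    def test_pathway_scope_never_more_blocks_than_gene_scope(self, small_fixture):
        from dgatpath.mapping import collect_pathway_snps

        ld = small_fixture.ld
        chrom_of = small_fixture.snp_chrom
        for p in small_fixture.pathways[:10]:
            pset = collect_pathway_snps(p, small_fixture.gene_snps)
            if not pset.testable:
                continue
            npw = len(block_pathway(pset, small_fixture.gene_snps, ld, "pathway",
                                    chrom_of=chrom_of))
            nge = len(block_pathway(pset, small_fixture.gene_snps, ld, "gene",
                                    chrom_of=chrom_of))
            assert npw <= nge

    def test_unknown_scope(self):
        with pytest.raises(ValueError):
            block_pathway(self._pset({"A"}, {"A": frozenset({"s"})}), {}, ld_of([]),
                          scope="chromosome")
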