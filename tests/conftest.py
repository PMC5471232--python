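"""Shared synthetic fixtures.

Everything is generated at test time from fixed seeds; nothing is read from
disk except files the tests themselves write to tmp_path.
"""

import pytest

from dgatpath import FixtureSpec, generate_fixture, generate_null_stats


@pytest.fixture(scope="session")
def small_fixture():
    """A compact dataset: 2 chromosomes, 60 genes, block LD, 30 pathways."""
    return generate_fixture(
        FixtureSpec(
            seed=7,
            n_chroms=2,
            genes_per_chrom=30,
            snps_per_gene=(4, 8),
            block_structure=((4, 0.5), (3, 0.5)),
            cross_gene_ld_fraction=0.2,
            n_pathways=30,
            pathway_size_distribution=(5, 15),
            n_samples=300,
        )
    )


@pytest.fixture(scope="session")
def small_null_stats(small_fixture):
    return generate_null_stats(small_fixture, mode="ld_coupled", rho=0.5, seed=71)
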