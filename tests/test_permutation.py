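import itertools

import numpy as np
import pytest
from scipy import stats as sps

from dgatpath.ld_blocking import LdBlock
from dgatpath.permutation import (
    BlockPool,
    RunConfig,
    build_pool,
    pathway_subseed,
    perm_pvalue,
    run_dgat_path,
)
from dgatpath.scoring import ScoredBlock
from dgatpath.synthetic_data import generate_enriched_stats


def sb(chi2, bid="b"):
    return ScoredBlock(LdBlock(bid, frozenset({bid})), bid, 0.5, chi2)


def exact_tail(pool, n, s_obs):
    """Enumeration oracle: P(sum of n distinct pool values >= s_obs)."""
    combos = list(itertools.combinations(pool, n))
    return sum(sum(c) >= s_obs for c in combos) / len(combos)


class TestBuildPool:
    def test_concatenation(self):
        pool = build_pool({"P1": [sb(3.8)], "P2": [sb(0.4), sb(2.1)]})
        assert sorted(pool.stats) == [0.4, 2.1, 3.8]
        assert pool.size == 3

    def test_shared_statistic_kept_per_pathway(self):
        pool = build_pool({"P1": [sb(3.8, "x")], "P2": [sb(3.8, "x")]})
        assert list(pool.stats) == [3.8, 3.8]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            build_pool({})


class TestPermPvalue:
    def test_nothing_exceeds_runs_to_max(self):
        pool = BlockPool(np.zeros(3))
        res = perm_pvalue("P", 5.0, 1, pool, schedule=(100, 1000), alpha_stop=0.05)
        assert res.n_perm_used == 1000
        assert res.n_exceed == 0
        assert res.p_assoc == pytest.approx(1 / 1001)

    def test_everything_exceeds_stops_at_first_stage(self):
        pool = BlockPool(np.full(3, 10.0))
        res = perm_pvalue("P", 5.0, 1, pool, schedule=(1000, 10_000), alpha_stop=0.05)
        assert res.n_perm_used == 1000
        assert res.p_assoc == pytest.approx(1.0, abs=1e-3)

    def test_estimator_identity(self):
        pool = BlockPool(np.arange(10, dtype=float))
        res = perm_pvalue("P", 12.0, 2, pool, schedule=(500,), alpha_stop=None, seed=1)
        assert res.p_assoc == (res.n_exceed + 1) / (res.n_perm_used + 1)

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_matches_enumeration_oracle(self, n):
        pool_vals = [0.1, 0.5, 1.2, 2.0, 3.5, 5.0]
        pool = BlockPool(np.array(pool_vals))
        s_obs = 4.0
        q = exact_tail(pool_vals, n, s_obs)
        N = 50_000
        res = perm_pvalue("P", s_obs, n, pool, schedule=(N,), alpha_stop=None, seed=5)
        se = np.sqrt(q * (1 - q) / N)
        assert res.p_assoc == pytest.approx(q, abs=max(3 * se, 2 / N))

    def test_monotone_in_s_obs(self):
        pool = BlockPool(np.random.default_rng(0).chisquare(1, size=200))
        ps = [
            perm_pvalue("P", s, 3, pool, schedule=(5000,), alpha_stop=None, seed=2).p_assoc
            for s in (0.5, 2.0, 5.0, 10.0, 20.0)
        ]
        assert ps == sorted(ps, reverse=True)

    def test_without_replacement_requires_big_enough_pool(self):
        pool = BlockPool(np.ones(2))
        with pytest.raises(ValueError, match="with"):
            perm_pvalue("P", 1.0, 3, pool)
        res = perm_pvalue("P", 1.0, 3, pool, schedule=(100,), sampling_mode="with")
        assert res.n_perm_used == 100

    def test_dense_sampling_path_matches_enumeration(self):
        # n > pool/2 exercises the argpartition branch
        pool_vals = [0.1, 0.5, 1.2, 2.0, 3.0]
        pool = BlockPool(np.array(pool_vals))
        q = exact_tail(pool_vals, 4, 5.0)
        res = perm_pvalue("P", 5.0, 4, pool, schedule=(40_000,), alpha_stop=None, seed=3)
        se = np.sqrt(q * (1 - q) / 40_000)
        assert res.p_assoc == pytest.approx(q, abs=3 * se + 1e-4)

    def test_deterministic_given_seed(self):
        pool = BlockPool(np.random.default_rng(1).chisquare(1, size=50))
        a = perm_pvalue("P", 3.0, 2, pool, seed=42, schedule=(1000, 10_000))
        b = perm_pvalue("P", 3.0, 2, pool, seed=42, schedule=(1000, 10_000))
        assert a == b

    def test_early_stop_safe_for_truly_significant_pathways(self):
        # at the first boundary (N=1000) a pathway with true p <= alpha/2
        # produces an interim estimate > alpha (and hence stops wrongly)
        # only with negligible probability; the exact binomial tail is a
        # few parts per million
        alpha = 0.05
        # stop requires (x+1)/1001 > 0.05, i.e. x >= 50
        x_stop = int(np.floor(alpha * (1000 + 1)))
        assert sps.binom.sf(x_stop - 1, 1000, alpha / 2) < 1e-5


def test_subseed_stable_and_bounded():
    s = pathway_subseed(7, "PW0001")
    assert s == pathway_subseed(7, "PW0001")
    assert 0 <= s < 2**31
    assert s != pathway_subseed(8, "PW0001")
    assert s != pathway_subseed(7, "PW0002")


def test_null_pvalues_uniform_under_exchangeability():
    """KS calibration: exchangeable pathway/pool blocks give uniform p_assoc."""
    rng = np.random.default_rng(2024)
    M = 4000
    pool = BlockPool(sps.chi2.isf(1.0 - rng.random(M), 1))
    pvals = []
    for i in range(2000):
        n = int(rng.integers(1, 9))
        s_obs = float(sps.chi2.isf(1.0 - rng.random(n), 1).sum())
        res = perm_pvalue(f"P{i}", s_obs, n, pool, schedule=(2000,), alpha_stop=None,
                          seed=int(rng.integers(2**31)))
        pvals.append(res.p_assoc)
    # support is {1/2001 ... 1}; the add-one shift is < 5e-4, far below the
    # 0.01-level KS radius for 2000 samples (~0.036)
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestRunDgatPath:
    def test_enriched_pathway_ranks_first(self, small_fixture):
        target = small_fixture.pathways[0].pathway_id
        stats = generate_enriched_stats(small_fixture, {target: 0.8}, seed=9)
        run = run_dgat_path(
            stats, small_fixture.isoforms, small_fixture.pathways, small_fixture.ld,
            RunConfig(schedule=(1000, 10_000), seed=4),
        )
        assert run.results[0].pathway_id == target
        assert run.results[0].p_assoc < 0.01

    def test_results_sorted_and_deterministic(self, small_fixture, small_null_stats):
        cfg = RunConfig(schedule=(1000,), seed=11)
        r1 = run_dgat_path(small_null_stats, small_fixture.isoforms,
                           small_fixture.pathways, small_fixture.ld, cfg)
        r2 = run_dgat_path(small_null_stats, small_fixture.isoforms,
                           small_fixture.pathways, small_fixture.ld, cfg)
        assert r1.results == r2.results
        keys = [(r.p_assoc, r.pathway_id) for r in r1.results]
        assert keys == sorted(keys)

    def test_zero_testable_pathways_raises(self, small_fixture, small_null_stats):
        from dgatpath.data_io import PathwayDef

        bogus = [PathwayDef("B", "none", frozenset({"NOPE1", "NOPE2", "NOPE3",
                                                    "NOPE4", "NOPE5"}))]
        with pytest.raises(ValueError):
            run_dgat_path(small_null_stats, small_fixture.isoforms, bogus,
                          small_fixture.ld, RunConfig(schedule=(100,)))
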