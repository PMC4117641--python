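from __future__ import annotations

import itertools
import logging

import numpy as np
import pytest

from netoverlap._rng import derive_rng
from netoverlap.data_io import InteractionNetwork
from netoverlap.errors import ParameterError, SimulationError
from netoverlap.interactome import plus_one
from netoverlap.mc_overlap import (
    MCConfig,
    null_list_significance,
    overlap_test,
    random_plus_one,
    screen_overlap_tests,
)


@pytest.fixture
def star_network():
    return InteractionNetwork(
        edges=[("X", "P"), ("X", "Q"), ("X", "R"), ("X", "S")]
    )


def complete_network(n):
    genes = [f"G{i}" for i in range(n)]
    return InteractionNetwork(edges=list(itertools.combinations(genes, 2)))


class TestRandomPlusOne:
    def test_saturation_returns_all_genes(self):
        net = complete_network(5)
        rng = derive_rng(0, "t")
        got = random_plus_one(net, sorted(net.genes), 5, rng)
        assert got == net.genes

    @pytest.mark.parametrize("target", [1, 2, 3, 4])
    def test_result_size_is_exact(self, star_network, target):
        rng = derive_rng(1, "t")
        for _ in range(20):
            got = random_plus_one(star_network, sorted(star_network.genes), target, rng)
            assert len(got) == target

    def test_hand_traced_truncation(self, star_network):
        # only X in the universe: its +1 is {X,P,Q,R,S}; target 3 must be a
        # 3-subset of those five genes
        rng = derive_rng(2, "t")
        for _ in range(10):
            got = random_plus_one(star_network, ["X"], 3, rng)
            assert len(got) == 3
            assert got <= {"X", "P", "Q", "R", "S"}

    def test_exhaustion_reports_achieved_size(self, star_network):
        rng = derive_rng(3, "t")
        with pytest.raises(SimulationError) as err:
            random_plus_one(star_network, ["X"], 6, rng)
        assert err.value.achieved_size == 5

    def test_invalid_target_rejected(self, star_network):
        with pytest.raises(ParameterError):
            random_plus_one(star_network, ["X"], 0, derive_rng(0, "t"))


class TestOverlapTest:
    def test_tie_saturation_gives_p_one(self):
        # complete graph: every +1 interactome is the whole gene set, so all
        # replicates tie with the observed overlap
        net = complete_network(5)
        universe = sorted(net.genes)
        gwas_p1 = plus_one(net, ["G0"])
        cfg = MCConfig(n_sim=50, rng_seed=0)
        res = overlap_test(net, "G1", gwas_p1, universe, cfg, derive_rng(0, "t"))
        assert res.n_right == res.n_left == cfg.n_sim
        assert res.p == 1.0
        assert res.direction == "larger"  # exact tie rule

    def test_tail_counts_and_p_invariants(self, star_network):
        universe = sorted(star_network.genes)
        gwas_p1 = plus_one(star_network, ["P"])
        cfg = MCConfig(n_sim=200, rng_seed=4)
        res = overlap_test(star_network, "Q", gwas_p1, universe, cfg, derive_rng(4, "t"))
        n_ties = res.n_right + res.n_left - cfg.n_sim
        assert n_ties >= 0
        assert res.p in {k / cfg.n_sim for k in range(1, cfg.n_sim + 1)}
        assert res.p >= 1.0 / cfg.n_sim
        assert res.direction in ("larger", "smaller")

    def test_absent_gene_raises_keyerror(self, star_network):
        gwas_p1 = plus_one(star_network, ["P"])
        with pytest.raises(KeyError):
            overlap_test(
                star_network, "NOPE", gwas_p1, sorted(star_network.genes),
                MCConfig(n_sim=10), derive_rng(0, "t"),
            )

    def test_mid_p_is_smaller_when_ties_exist(self):
        net = complete_network(4)
        universe = sorted(net.genes)
        gwas_p1 = plus_one(net, ["G0"])
        plain = overlap_test(
            net, "G1", gwas_p1, universe, MCConfig(n_sim=40), derive_rng(1, "t")
        )
        mid = overlap_test(
            net, "G1", gwas_p1, universe, MCConfig(n_sim=40, mid_p=True),
            derive_rng(1, "t"),
        )
        assert mid.p < plain.p


class TestScreen:
    def test_single_gene_list_and_sorting(self, make_study):
        net, gwas, hits, truth, universe, spec = make_study(
            n_genes=300, gwas_size=15, hit_size=10, enrichment=0.0, rng_seed=9
        )
        cfg = MCConfig(n_sim=50, rng_seed=9)
        results = screen_overlap_tests(net, hits, gwas, universe, cfg)
        assert len(results) == len(hits)
        ps = [r.p for r in results]
        assert ps == sorted(ps)

    def test_absent_genes_skipped_with_warning(self, star_network, caplog):
        cfg = MCConfig(n_sim=20, rng_seed=0)
        with caplog.at_level(logging.WARNING, logger="netoverlap.mc_overlap"):
            results = screen_overlap_tests(
                star_network, ["Q", "MISSING"], ["P"], sorted(star_network.genes), cfg
            )
        assert [r.gene for r in results] == ["Q"]
        assert any("MISSING" in rec.getMessage() for rec in caplog.records)

    def test_direct_interactor_flag(self):
        # W adjacent to reference seed G, V not
        net = InteractionNetwork(
            edges=[("W", "G"), ("G", "H"), ("V", "H"), ("V", "U"), ("W", "U")]
        )
        cfg = MCConfig(n_sim=20, rng_seed=1)
        results = screen_overlap_tests(net, ["W", "V"], ["G"], sorted(net.genes), cfg)
        flags = {r.gene: r.direct_interactor for r in results}
        assert flags == {"W": True, "V": False}

    def test_identical_seed_gives_identical_tables(self, make_study):
        net, gwas, hits, truth, universe, spec = make_study(
            n_genes=300, gwas_size=15, hit_size=8, enrichment=0.0, rng_seed=5
        )
        cfg = MCConfig(n_sim=40, rng_seed=123)
        first = screen_overlap_tests(net, hits, gwas, universe, cfg)
        second = screen_overlap_tests(net, hits, gwas, universe, cfg)
        assert first == second


class TestNullListSignificance:
    def test_alpha_to_zero_limit(self, make_study):
        net, gwas, hits, truth, universe, spec = make_study(
            n_genes=300, gwas_size=15, hit_size=8, enrichment=0.0, rng_seed=2
        )
        gwas_p1 = plus_one(net, gwas)
        cfg = MCConfig(n_sim=30, n_lists=5, list_size=6, alpha=1e-9, rng_seed=2)
        res = null_list_significance(net, universe, gwas_p1, cfg, k_observed=1)
        assert res.counts_per_list == (0,) * 5
        assert res.mean == 0.0
        assert res.p_ge_k == 0.0

    def test_empty_upper_tail(self, make_study):
        net, gwas, hits, truth, universe, spec = make_study(
            n_genes=300, gwas_size=15, hit_size=8, enrichment=0.0, rng_seed=3
        )
        gwas_p1 = plus_one(net, gwas)
        cfg = MCConfig(n_sim=30, n_lists=5, list_size=6, rng_seed=3)
        res = null_list_significance(net, universe, gwas_p1, cfg, k_observed=0)
        assert res.p_ge_k == 1.0  # every count >= 0
        res2 = null_list_significance(
            net, universe, gwas_p1, cfg, k_observed=max(res.counts_per_list) + 1
        )
        assert res2.p_ge_k == 0.0

    def test_counts_bounded_by_list_size(self, make_study):
        net, gwas, hits, truth, universe, spec = make_study(
            n_genes=300, gwas_size=15, hit_size=8, enrichment=0.0, rng_seed=4
        )
        gwas_p1 = plus_one(net, gwas)
        cfg = MCConfig(n_sim=30, n_lists=4, list_size=6, rng_seed=4)
        res = null_list_significance(net, universe, gwas_p1, cfg, k_observed=1)
        assert all(0 <= c <= cfg.list_size for c in res.counts_per_list)
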