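from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from netoverlap.connectivity import (
    BinProfile,
    bin_profile,
    loglog_slope,
    make_bins,
    rank_by_degree,
    slope_comparison,
    slope_t_test,
)
from netoverlap.data_io import InteractionNetwork
from netoverlap.errors import FitError, ParameterError
from netoverlap.mc_overlap import MCConfig
from netoverlap.synthetic import SyntheticSpec, generate_network


def path_network(n):
    genes = [f"G{i:03d}" for i in range(n)]
    return InteractionNetwork(edges=list(zip(genes, genes[1:])))


class TestRanking:
    def test_tie_rule_lexicographic(self):
        net = InteractionNetwork(edges=[("A", "B"), ("A", "C"), ("A", "D")])
        ranking = rank_by_degree(net)
        assert [g for g, _ in ranking.order] == ["A", "B", "C", "D"]
        assert ranking.rank["A"] == 1

    def test_rank_is_permutation_of_all_genes(self):
        net = path_network(20)
        ranking = rank_by_degree(net)
        assert len(ranking) == 20
        assert sorted(ranking.rank.values()) == list(range(1, 21))

    def test_agrees_with_independent_sort_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(20)]
        edges = [
            (genes[a], genes[b])
            for a, b in (rng.choice(20, size=2, replace=False) for _ in range(40))
        ]
        net = InteractionNetwork(edges=edges)
        nx_graph = net.to_networkx()
        oracle = sorted(nx_graph.nodes, key=lambda g: (-nx_graph.degree(g), g))
        ranking = rank_by_degree(net)
        assert [g for g, _ in ranking.order] == oracle


class TestBinning:
    def test_universe_of_n_bins_genes(self):
        net = path_network(10)
        ranking = rank_by_degree(net)
        scheme = make_bins(ranking, [g for g, _ in ranking.order], n_bins=10)
        assert scheme.universe_counts == (1,) * 10

    def test_uniform_universe_gives_equal_intervals(self):
        net = path_network(100)
        ranking = rank_by_degree(net)
        scheme = make_bins(ranking, [g for g, _ in ranking.order], n_bins=10)
        assert scheme.boundaries == tuple((10 * i + 1, 10 * (i + 1)) for i in range(10))

    def test_hand_traced_walk(self):
        # degrees: A..L; universe genes at known ranks
        net = InteractionNetwork(
            edges=[("A", x) for x in "BCDEFG"]  # A degree 6
            + [("B", x) for x in "CDE"]         # B degree 4
            + [("C", "D"), ("E", "F"), ("G", "H"), ("H", "I"), ("J", "K")]
        )
        net.add_gene("L")
        ranking = rank_by_degree(net)
        order = [g for g, _ in ranking.order]
        universe = order[1], order[3], order[5], order[7], order[9], order[11]
        scheme = make_bins(ranking, universe, n_bins=3)
        # quota 2 per bin: bins close at ranks 4 and 8; tail absorbs the rest
        assert scheme.boundaries == ((1, 4), (5, 8), (9, 12))

    def test_remainder_spread_to_earliest_bins(self):
        net = path_network(30)
        ranking = rank_by_degree(net)
        universe = [g for g, _ in ranking.order][:7]
        scheme = make_bins(ranking, universe, n_bins=3)
        assert scheme.universe_counts == (3, 2, 2)

    def test_conservation_invariants(self):
        net = path_network(50)
        ranking = rank_by_degree(net)
        universe = [g for g, _ in ranking.order][::3]
        scheme = make_bins(ranking, universe, n_bins=5)
        widths = sum(hi - lo + 1 for lo, hi in scheme.boundaries)
        assert widths == len(ranking)
        assert sum(scheme.universe_counts) == len(universe)

    def test_too_few_universe_genes(self):
        net = path_network(10)
        ranking = rank_by_degree(net)
        with pytest.raises(ParameterError):
            make_bins(ranking, [g for g, _ in ranking.order][:3], n_bins=5)


class TestProfile:
    def test_top_rank_gene_lands_in_first_bin(self):
        net = path_network(100)
        ranking = rank_by_degree(net)
        scheme = make_bins(ranking, [g for g, _ in ranking.order], n_bins=10)
        top = ranking.order[0][0]
        profile = bin_profile(scheme, ranking, [top])
        assert profile.counts == (1,) + (0,) * 9

    def test_universe_profile_is_uniform(self):
        net = path_network(100)
        ranking = rank_by_degree(net)
        universe = [g for g, _ in ranking.order]
        scheme = make_bins(ranking, universe, n_bins=10)
        profile = bin_profile(scheme, ranking, universe)
        assert all(f == pytest.approx(0.1) for f in profile.fractions)

    def test_counts_match_brute_force_membership(self):
        net = path_network(60)
        ranking = rank_by_degree(net)
        universe = [g for g, _ in ranking.order][::2]
        scheme = make_bins(ranking, universe, n_bins=5)
        rng = np.random.default_rng(3)
        members = [g for g, _ in ranking.order]
        listed = [members[i] for i in rng.choice(60, size=15, replace=False)]
        profile = bin_profile(scheme, ranking, listed)
        brute = [0] * 5
        for g in listed:
            r = ranking.rank[g]
            for i, (lo, hi) in enumerate(scheme.boundaries):
                if lo <= r <= hi:
                    brute[i] += 1
        assert list(profile.counts) == brute

    def test_missing_genes_logged_and_fraction_denominator_full(self):
        net = path_network(20)
        ranking = rank_by_degree(net)
        scheme = make_bins(ranking, [g for g, _ in ranking.order], n_bins=4)
        profile = bin_profile(scheme, ranking, [ranking.order[0][0], "ABSENT"])
        assert profile.missing == ("ABSENT",)
        assert sum(profile.fractions) == pytest.approx(0.5)


class TestSlope:
    def _scheme(self, boundaries):
        from netoverlap.connectivity import BinningScheme

        return BinningScheme(
            n_bins=len(boundaries),
            boundaries=tuple(boundaries),
            universe_per_bin=1,
            universe_counts=(1,) * len(boundaries),
        )

    def test_flat_profile_gives_zero_slope(self):
        scheme = self._scheme([(1, 10), (11, 100), (101, 1000)])
        profile = BinProfile(counts=(5, 5, 5), fractions=(1 / 3, 1 / 3, 1 / 3))
        fit = loglog_slope(profile, scheme)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_hand_computed_slope(self):
        # (log10(0.05) - log10(0.5)) / (log10(100) - log10(10)) = -1
        scheme = self._scheme([(1, 10), (11, 100)])
        profile = BinProfile(counts=(10, 1), fractions=(0.5, 0.05))
        fit = loglog_slope(profile, scheme)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)

    def test_collinear_points_recovered_exactly(self):
        scheme = self._scheme([(1, 10), (11, 100), (101, 1000)])
        # fractions = 10^(0.7 - 0.6*log10(x)) exactly collinear in log space
        fractions = tuple(10 ** (0.7 - 0.6 * math.log10(x)) for x in (10, 100, 1000))
        profile = BinProfile(counts=(1, 1, 1), fractions=fractions)
        fit = loglog_slope(profile, scheme)
        assert fit.slope == pytest.approx(-0.6, abs=1e-10)
        assert fit.intercept == pytest.approx(0.7, abs=1e-10)

    def test_zero_bins_excluded_and_too_few_points_error(self):
        scheme = self._scheme([(1, 10), (11, 100), (101, 1000)])
        profile = BinProfile(counts=(1, 0, 1), fractions=(0.5, 0.0, 0.05))
        fit = loglog_slope(profile, scheme)
        assert fit.excluded_bins == (1,)
        assert fit.n_points == 2
        lonely = BinProfile(counts=(1, 0, 0), fractions=(0.5, 0.0, 0.0))
        with pytest.raises(FitError):
            loglog_slope(lonely, scheme)

    def test_slope_invariant_to_fraction_scaling(self):
        scheme = self._scheme([(1, 10), (11, 100), (101, 1000)])
        base = (0.5, 0.2, 0.04)
        scaled = tuple(0.37 * f for f in base)
        fit_a = loglog_slope(BinProfile((1, 1, 1), base), scheme)
        fit_b = loglog_slope(BinProfile((1, 1, 1), scaled), scheme)
        assert fit_a.slope == pytest.approx(fit_b.slope, abs=1e-12)
        assert fit_a.intercept != pytest.approx(fit_b.intercept)

    def test_lower_boundary_variant_runs(self):
        scheme = self._scheme([(1, 10), (11, 100)])
        profile = BinProfile(counts=(10, 1), fractions=(0.5, 0.05))
        fit = loglog_slope(profile, scheme, boundary="lower")
        # x = lower boundaries 1 and 11: slope = -1 / log10(11)
        assert fit.slope == pytest.approx(-1.0 / math.log10(11), abs=1e-12)


class TestSlopeComparison:
    def test_t_equals_zero_when_experimental_matches_mc_mean(self):
        t, p = slope_t_test([-0.2, 0.0, 0.2], experimental_slope=0.0, tails="two")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_one_sample_t(self):
        # mc = {-0.1, 0, 0.1}: mean 0, sd 0.1; vs -1.0: t = 1/(0.1/sqrt(3))
        t, p = slope_t_test([-0.1, 0.0, 0.1], experimental_slope=-1.0, tails="two")
        t_hand = 10.0 * math.sqrt(3.0)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(2.0 * stats.t.sf(t_hand, df=2), rel=1e-12)
        t1, p1 = slope_t_test([-0.1, 0.0, 0.1], experimental_slope=-1.0, tails="one")
        assert t1 == pytest.approx(t_hand, rel=1e-12)
        assert p1 == pytest.approx(p / 2.0, rel=1e-12)

    def test_hub_enriched_list_detected(self):
        spec = SyntheticSpec(n_genes=1500, rng_seed=17)
        net = generate_network(spec)
        ranking = rank_by_degree(net)
        rng = np.random.default_rng(17)
        all_genes = [g for g, _ in ranking.order]
        universe = sorted(all_genes[i] for i in rng.choice(1500, 600, replace=False))
        scheme = make_bins(ranking, universe, n_bins=10)
        # hub-enriched: sample universe genes with degree-proportional weights
        weights = np.array([net.degree(g) for g in universe], dtype=float)
        idx = rng.choice(len(universe), size=60, replace=False,
                         p=weights / weights.sum())
        hub_list = [universe[i] for i in idx]
        cfg = MCConfig(n_lists=100, rng_seed=17)
        comp = slope_comparison(net, universe, scheme, hub_list, cfg, tails="two",
                                ranking=ranking)
        assert comp.experimental_slope < 0
        assert comp.p < 0.05
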