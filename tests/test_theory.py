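"""Analytic results: connectivity, degree law, giant component, clustering."""

import math
from itertools import product

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bitsimnet import (
    M_G,
    all_strings,
    clustering_C,
    degree_pmf,
    enumerate_within,
    mu,
    mu_critical,
    neighbor_pair_prob,
    pairwise_hamming,
    richness_approx,
    solve_giant,
    solve_giant_largeN,
    summarize,
)


def _bisect(f, lo, hi, tol=1e-10):
    """Independent bisection oracle (no scipy)."""
    flo = f(lo)
    for _ in range(200):
        mid = (lo + hi) / 2
        if f(mid) * flo > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return (lo + hi) / 2


class TestConnectivityParameter:
    def test_full_threshold_gives_one(self):
        for B in (3, 8, 40):
            assert mu(B, B) == pytest.approx(1.0, abs=1e-14)

    def test_exact_small_case_and_enumeration_crosscheck(self):
        assert mu(6, 2) == pytest.approx(1 / 3, abs=1e-15)
        assert M_G(6, 2) == len(enumerate_within([0] * 6, 2)) == 21

    def test_monotone_in_G(self):
        vals = [mu(10, G) for G in range(1, 11)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mu(5, 0)
        with pytest.raises(ValueError):
            mu(5, 6)


class TestDegreeDistribution:
    def test_degenerate_ends(self):
        g0 = degree_pmf(10, 0.0)
        assert g0[0] == 1.0 and g0[1:].sum() == 0.0
        g1 = degree_pmf(10, 1.0)
        assert g1[-1] == 1.0

    @pytest.mark.parametrize("N,m", [(50, 0.1), (300, 0.01), (1024, 0.004)])
    def test_normalized_with_binomial_mean(self, N, m):
        g = degree_pmf(N, m)
        assert g.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.arange(N) * g).sum() == pytest.approx(m * (N - 1), rel=1e-10)


class TestGiantComponent:
    def test_mu_critical_values(self):
        assert mu_critical(3) == 1.0
        assert mu_critical(1024) == pytest.approx(1 / 1022)
        with pytest.raises(ValueError):
            mu_critical(2)

    def test_subcritical_and_complete(self):
        assert solve_giant(0.5 * mu_critical(100), 100) == (1.0, 0.0)
        assert solve_giant(mu_critical(100), 100) == (1.0, 0.0)
        u, S = solve_giant(1.0, 100)
        assert (u, S) == (0.0, 1.0)

    def test_largeN_fixed_point_against_bisection_oracle(self):
        """At ratio 2 the survival equation u = exp(-2(1-u)) has its
        nontrivial root near 0.2032, giving S near 0.7968."""
        for ratio in (1.5, 2.0, 3.0):
            u_oracle = _bisect(lambda x: x - math.exp(-ratio * (1 - x)), 0.0, 0.999)
            u, S = solve_giant_largeN(ratio)
            assert u == pytest.approx(u_oracle, abs=1e-8)
            assert S == pytest.approx(1 - u_oracle, abs=1e-8)
        assert solve_giant_largeN(2.0)[1] == pytest.approx(0.7968, abs=1e-4)

    def test_largeN_limits(self):
        assert solve_giant_largeN(1.0) == (1.0, 0.0)
        assert solve_giant_largeN(50.0)[1] == pytest.approx(1.0, abs=1e-12)

    def test_finite_N_matches_largeN_at_N_1e4(self):
        N = 10_000
        for ratio in (0.5, 1.5, 2.0, 3.0):
            S_fin = solve_giant(ratio * mu_critical(N), N)[1]
            S_inf = solve_giant_largeN(ratio)[1]
            assert abs(S_fin - S_inf) < 1e-3


class TestRichnessApprox:
    def test_limits_and_linearization(self):
        assert richness_approx(0.0) == 1.0
        assert richness_approx(200.0) == pytest.approx(0.5, abs=1e-12)
        assert richness_approx(0.2) == pytest.approx(1 - 0.1, abs=0.01)


class TestNeighborPairProb:
    def test_two_distance_one_neighbors_always_linked_for_G2(self):
        # two distinct neighbors at H=1 sit at mutual distance exactly 2
        for B in (4, 9, 30):
            assert neighbor_pair_prob(B, 1, 1, 2) == 1.0
            assert neighbor_pair_prob(B, 1, 1, 2, include_identical=False) == 1.0

    def test_full_threshold_is_certain(self):
        B = 7
        for H1, H2 in product(range(1, B + 1), repeat=2):
            assert neighbor_pair_prob(B, H1, H2, B) == 1.0

    def test_matches_exhaustive_pair_enumeration(self):
        """B=6, H1=H2=2, G=2: enumerate all ordered pairs of strings at
        distance 2 from 000000 and count mutual distances <= G."""
        B, H, G = 6, 2, 2
        shell = [s for s in enumerate_within([0] * B, H) if s.sum() == H]
        total = hits = hits_distinct = total_distinct = 0
        for a in shell:
            for b in shell:
                d = int(np.sum(a != b))
                total += 1
                hits += d <= G
                if d > 0:
                    total_distinct += 1
                    hits_distinct += d <= G
        assert neighbor_pair_prob(B, H, H, G) == pytest.approx(hits / total, abs=1e-12)
        assert neighbor_pair_prob(B, H, H, G, include_identical=False) == pytest.approx(
            hits_distinct / total_distinct, abs=1e-12
        )

    @given(st.integers(2, 12), st.data())
    def test_symmetry_in_H1_H2(self, B, data):
        G = data.draw(st.integers(1, B))
        H1 = data.draw(st.integers(1, G))
        H2 = data.draw(st.integers(1, G))
        assert neighbor_pair_prob(B, H1, H2, G) == pytest.approx(
            neighbor_pair_prob(B, H2, H1, G), abs=1e-12
        )


class TestClustering:
    def test_complete_graph_limit(self):
        for B in (3, 6, 11):
            assert clustering_C(B, B) == pytest.approx(1.0, abs=1e-14)
            assert clustering_C(B, B, include_identical=True) == pytest.approx(1.0, abs=1e-14)

    def test_equals_printed_triple_sum_form(self):
        """The weighted-average form equals the expanded triple sum of
        multinomial terms under the same normalization (B=6, G=2)."""
        B, G = 6, 2
        mg = M_G(B, G)
        total = 0.0
        for H1 in range(1, G + 1):
            for H2 in range(1, G + 1):
                h0 = max(0, (H1 + H2 - G + 1) // 2)
                for h in range(h0, min(H1, H2) + 1):
                    if B - H1 - H2 + h < 0:
                        continue
                    total += math.factorial(B) / (
                        math.factorial(h)
                        * math.factorial(H1 - h)
                        * math.factorial(H2 - h)
                        * math.factorial(B - H1 - H2 + h)
                    )
        assert clustering_C(B, G, include_identical=True) == pytest.approx(
            total / mg**2, abs=1e-12
        )

    @pytest.mark.parametrize("G", [1, 2, 3])
    def test_matches_exhaustive_full_network(self, G):
        """Mean local clustering of the full 2^7-node similarity network
        (every string a node) equals the distinct-pair formula; the
        as-printed variant is off by O(1/M_G)."""
        B = 7
        dist = pairwise_hamming(all_strings(B))
        adj = dist <= G
        np.fill_diagonal(adj, False)
        g = nx.from_numpy_array(adj)
        k = adj.sum(axis=1)
        local = nx.clustering(g)
        eligible = [local[i] for i in range(2**B) if k[i] >= 2]
        oracle = float(np.mean(eligible))
        assert clustering_C(B, G) == pytest.approx(oracle, abs=1e-9)
        assert abs(clustering_C(B, G, include_identical=True) - oracle) < 1 / M_G(B, G) + 1e-9

    def test_nondecreasing_in_G(self):
        B = 9
        vals = [clustering_C(B, G) for G in range(1, B + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_small_G_exceeds_er_clustering(self):
        """Metric-induced clustering dwarfs the Erdos-Renyi level z/(N-1)
        at small G for N=1024."""
        N, B = 1024, 20
        for G in (2, 3, 4):
            er = mu(B, G)  # z/(N-1) = mu
            assert clustering_C(B, G) > 10 * er


class TestSummary:
    def test_summary_is_consistent(self):
        s = summarize(1024, 20, 4)
        assert s.mu == pytest.approx(mu(20, 4))
        assert s.z == pytest.approx(s.mu * 1023)
        assert s.ratio == pytest.approx(s.mu / s.mu_c)
        assert s.S == pytest.approx(solve_giant(s.mu, 1024)[1])
        assert 0 <= s.C <= 1
        d = s.to_dict()
        assert d["N"] == 1024 and d["G"] == 4
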