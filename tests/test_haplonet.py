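import math

import networkx as nx
import numpy as np
import pytest
from scipy.stats import poisson

from phylogeo.haplonet import (
    build_network,
    code_indels,
    collapse_haplotypes,
    connection_limit,
    haplotype_distance,
    parsimony_probability,
)
from phylogeo.io import Alignment
from phylogeo.simulate import sim_phylogeography

from conftest import random_haplotype_instance


class TestIndelCoding:
    def test_identical_range_gap(self):
        aln = Alignment(ids=["s1", "s2", "s3"],
                        seqs=["AC--GT", "ACTTGT", "AC--GT"])
        m = code_indels(aln)
        assert m.characters == [(2, 4)]
        assert m.state_string("s1") == "1"
        assert m.state_string("s2") == "0"
        assert m.state_string("s3") == "1"

    def test_nested_gap_scored_inapplicable(self):
        aln = Alignment(ids=["s1", "s2", "s3"],
                        seqs=["A----T", "AG--GT", "AGCCGT"])
        m = code_indels(aln)
        assert m.characters == [(1, 5), (2, 4)]
        assert m.state_string("s1") == "1?"
        assert m.state_string("s2") == "01"
        assert m.state_string("s3") == "00"

    def test_gap_free_alignment_has_no_characters(self):
        aln = Alignment(ids=["a", "b"], seqs=["ACGT", "ACGA"])
        assert code_indels(aln).n_characters == 0

    def test_terminal_gaps_excluded_by_default(self):
        aln = Alignment(ids=["a", "b"], seqs=["--GTAC", "ACGTAC"])
        assert code_indels(aln).n_characters == 0
        assert code_indels(aln, exclude_terminal=False).characters == [(0, 2)]

    def test_permutation_invariant_over_sequences(self):
        rng = np.random.default_rng(0)
        seqs = ["AC--GTAC", "ACTTGT-C", "A----TAC", "ACTTGTAC"]
        ids = ["a", "b", "c", "d"]
        ref = code_indels(Alignment(ids=ids, seqs=seqs))
        for _ in range(5):
            perm = rng.permutation(4)
            m = code_indels(
                Alignment(ids=[ids[i] for i in perm],
                          seqs=[seqs[i] for i in perm])
            )
            assert m.characters == ref.characters
            for sid in ids:
                assert m.states[sid] == ref.states[sid]


class TestCollapse:
    def test_frequencies(self):
        aln = Alignment(ids=list("abcde"),
                        seqs=["ACGT"] * 4 + ["ACGA"])
        t = collapse_haplotypes(aln, code_indels(aln))
        assert sorted(t.frequencies.values()) == [1, 4]

    def test_ambiguity_matches_by_default(self):
        aln = Alignment(ids=["a", "b"], seqs=["ACNT", "ACAT"])
        assert len(collapse_haplotypes(aln, code_indels(aln))) == 1
        assert len(
            collapse_haplotypes(aln, code_indels(aln), ambiguity_matches=False)
        ) == 2

    def test_frequency_sum_equals_n(self, phylo_bundle):
        aln = phylo_bundle.alignment
        t = collapse_haplotypes(aln, code_indels(aln))
        assert sum(t.frequencies.values()) == len(aln)


class TestConnectionLimit:
    def test_alpha_near_one_trusts_single_steps_only(self):
        assert connection_limit(500, 1 - 1e-12) == 1

    def test_monotone_in_sequence_length(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            L = int(rng.integers(50, 2000))
            a = float(rng.uniform(0.5, 0.99))
            assert connection_limit(L, a) <= connection_limit(2 * L, a)

    def test_fixed_limit_bypasses_computation(self):
        assert connection_limit(500, 0.95, fixed_limit=3) == 3

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            connection_limit(100, 1.0)
        with pytest.raises(ValueError):
            connection_limit(100, 0.0)

    def test_dual_route_estimator_agreement(self):
        # independent route: per-site Poisson pmf via scipy, same JC rate
        def prob_route2(L, j):
            if j <= 0:
                return 1.0
            p = j / L
            if p >= 0.75:
                return 0.0
            lam = -0.75 * math.log1p(-4 * p / 3)
            per_site = poisson.pmf(0, lam) + poisson.pmf(1, lam)
            return float(per_site**L)

        def limit_route2(L, alpha):
            j = 1
            while prob_route2(L, j + 1) >= alpha and j <= L:
                j += 1
            return j

        for L in (60, 200, 500, 1500):
            for alpha in (0.5, 0.9, 0.95, 0.99):
                assert parsimony_probability(L, 3) == pytest.approx(
                    prob_route2(L, 3), rel=1e-12
                )
                assert connection_limit(L, alpha) == limit_route2(L, alpha)


def oracle_network(seqs: list[str], limit: int):
    """Independent exhaustive minimal-step connection search.

    Plain Hamming distances, union-find components, and level-by-level
    connection of all cross-component pairs at each distance.
    """
    n = len(seqs)
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(1 for x, y in zip(seqs[i], seqs[j]) if x != y)
            dist[i, j] = dist[j, i] = d
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    connections = []
    for d in range(1, limit + 1):
        comp = [find(i) for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if dist[i, j] == d and comp[i] != comp[j]:
                    connections.append((i, j, d))
        for (i, j, _d) in connections:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return connections


class TestNetwork:
    def test_simple_chain_no_shortcut(self):
        aln = Alignment(ids=["x", "y", "z"], seqs=["AAA", "AAT", "ATT"])
        t = collapse_haplotypes(aln, code_indels(aln))
        g = build_network(t, limit=3)
        obs_edges = {
            tuple(sorted(e)) for e in g.edges if not any(
                g.nodes[n]["is_median"] for n in e
            )
        }
        assert obs_edges == {("H1", "H2"), ("H2", "H3")}

    def test_limit_zero_gives_isolated_nodes(self):
        aln = Alignment(ids=["x", "y"], seqs=["AAA", "AAT"])
        t = collapse_haplotypes(aln, code_indels(aln))
        g = build_network(t, limit=0)
        assert g.number_of_edges() == 0
        assert nx.number_connected_components(g) == 2

    def test_two_step_pair_gets_one_median_vector(self):
        aln = Alignment(ids=["x", "y"], seqs=["AAA", "ATT"])
        t = collapse_haplotypes(aln, code_indels(aln))
        g = build_network(t, limit=2)
        medians = [n for n, d in g.nodes(data=True) if d["is_median"]]
        assert len(medians) == 1
        assert nx.shortest_path_length(g, "H1", "H2") == 2
        assert g.nodes[medians[0]]["frequency"] == 0

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        aln = random_haplotype_instance(rng)
        t = collapse_haplotypes(aln, code_indels(aln))
        g1 = build_network(t, limit=6)
        perm = rng.permutation(len(aln.ids))
        aln2 = Alignment(ids=[aln.ids[i] for i in perm],
                         seqs=[aln.seqs[i] for i in perm])
        t2 = collapse_haplotypes(aln2, code_indels(aln2))
        g2 = build_network(t2, limit=6)
        assert nx.is_isomorphic(
            g1, g2,
            node_match=lambda a, b: (a["is_median"], a["frequency"])
            == (b["is_median"], b["frequency"]),
        )

    def test_components_non_increasing_in_limit(self):
        rng = np.random.default_rng(4)
        aln = random_haplotype_instance(rng)
        t = collapse_haplotypes(aln, code_indels(aln))
        prev = None
        for lim in range(0, 7):
            ncomp = nx.number_connected_components(build_network(t, lim))
            if prev is not None:
                assert ncomp <= prev
            prev = ncomp
        # with a generous limit the network is connected
        assert nx.number_connected_components(build_network(t, 10)) == 1

    def test_indel_characters_count_one_step(self):
        aln = Alignment(ids=["a", "b"], seqs=["AC---T", "ACGCGT"])
        t = collapse_haplotypes(aln, code_indels(aln))
        assert haplotype_distance(t, "H1", "H2") == 1

    def test_matches_exhaustive_search_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            aln = random_haplotype_instance(rng)
            t = collapse_haplotypes(aln, code_indels(aln))
            limit = int(rng.integers(1, 7))
            g = build_network(t, limit)
            labels = t.labels  # H{i+1} corresponds to input order i
            expected = {
                (labels[i], labels[j], d)
                for i, j, d in oracle_network(aln.seqs, limit)
            }
            assert set(map(tuple, g.graph["connections"])) == expected

    def test_low_rate_simulation_recovers_tree_adjacency(self):
        b = sim_phylogeography(
            seed=21, n_tips=10, sub_rate=0.002, indel_rate=0.0, seq_len=400
        )
        aln = b.alignment
        t = collapse_haplotypes(aln, code_indels(aln))
        g = build_network(t, limit=connection_limit(aln.length))
        assert nx.number_connected_components(g) == 1
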