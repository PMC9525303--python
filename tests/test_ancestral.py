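import itertools
import math

import numpy as np
import pytest

from phylogeo.ancestral import (
    BbmConfig,
    area_marginals_exact,
    bbm_sample,
    classify_events,
    node_key,
    parse_event_string,
    render_range,
)
from phylogeo.io import load_tree
from phylogeo.simulate import sim_phylogeography


def brute_force_posterior(tree, tips, areas, rate, max_areas):
    """Independent oracle: enumerate every internal-state assignment per
    area, weight by the product of 2-state transition probabilities, then
    combine per-area marginals over admissible ranges."""
    t = tree.tree
    nodes = list(t.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]

    def p_same(tt):
        return 0.5 * (1 + math.exp(-2 * rate * tt))

    marg = {id(n): {} for n in internal}
    for a in areas:
        tot = {id(n): 0.0 for n in internal}
        z = 0.0
        for combo in itertools.product([0, 1], repeat=len(internal)):
            st = {id(n): s for n, s in zip(internal, combo)}
            for leaf in t.leaf_node_iter():
                st[id(leaf)] = 1 if a in tips[leaf.taxon.label] else 0
            lik = 0.5
            for n in nodes:
                for ch in n.child_nodes():
                    ps = p_same(ch.edge.length or 0.0)
                    lik *= ps if st[id(n)] == st[id(ch)] else 1 - ps
            z += lik
            for n in internal:
                if st[id(n)]:
                    tot[id(n)] += lik
        for n in internal:
            marg[id(n)][a] = tot[id(n)] / z
    out = {}
    for n in internal:
        probs = {}
        for size in range(1, min(len(areas), max_areas) + 1):
            for combo in itertools.combinations(areas, size):
                p = 1.0
                for a in areas:
                    m = marg[id(n)][a]
                    p *= m if a in combo else 1 - m
                probs[frozenset(combo)] = p
        zz = sum(probs.values())
        out[node_key(n)] = {r: p / zz for r, p in probs.items()}
    return out


class TestExactPosterior:
    def test_uniform_tips_give_modal_root_range(self):
        t = load_tree("(a:1,b:1);")
        post = area_marginals_exact(
            t, {"a": {"X"}, "b": {"X"}}, areas=["X", "Y"], rate=0.2
        )
        key = node_key(t.tree.seed_node)
        assert post.modal[key] == frozenset({"X"})
        assert post.node_probs[key][frozenset({"X"})] == max(
            post.node_probs[key].values()
        )

    def test_short_branches_symmetric_split(self):
        t = load_tree("(a:0.0001,b:0.0001);")
        post = area_marginals_exact(
            t, {"a": {"X"}, "b": {"Y"}}, areas=["X", "Y"], rate=1.0
        )
        key = node_key(t.tree.seed_node)
        px = post.node_probs[key][frozenset({"X"})]
        py = post.node_probs[key][frozenset({"Y"})]
        assert px == pytest.approx(py, abs=1e-9)

    @pytest.mark.parametrize(
        "newick,tips,areas,rate,max_areas",
        [
            ("((a:1,b:1):1,c:1);",
             {"a": {"X"}, "b": {"X"}, "c": {"Y"}}, ["X", "Y"], 0.1, 2),
            ("((a:1,b:2):1,(c:1,d:0.5):2);",
             {"a": {"X"}, "b": {"X", "Z"}, "c": {"Y"}, "d": {"Z"}},
             ["X", "Y", "Z"], 0.3, 2),
            ("((a:1,b:1,c:1):1,(d:2,e:1):0.5);",  # polytomy
             {"a": {"X"}, "b": {"Y"}, "c": {"X"}, "d": {"Z"}, "e": {"Z"}},
             ["X", "Y", "Z"], 0.5, 3),
            ("(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1,(i:1,j:1):2);",
             {k: {v} for k, v in zip("abcdefghij", "XXYYZZXYZX")},
             ["X", "Y", "Z"], 0.2, 3),
        ],
    )
    def test_matches_exhaustive_enumeration(self, newick, tips, areas, rate, max_areas):
        t = load_tree(newick)
        post = area_marginals_exact(
            t, tips, areas=areas, rate=rate, max_areas=max_areas
        )
        oracle = brute_force_posterior(t, tips, areas, rate, max_areas)
        for key, probs in oracle.items():
            for r, p in probs.items():
                assert post.node_probs[key][r] == pytest.approx(p, abs=1e-9)

    def test_posteriors_sum_to_one(self):
        t = load_tree("((a:1,b:1):1,c:1);")
        post = area_marginals_exact(
            t, {"a": {"X"}, "b": {"Y"}, "c": {"Z"}},
            areas=["X", "Y", "Z"], rate="ML", max_areas=2,
        )
        for probs in post.node_probs.values():
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_area_and_tip_order(self):
        tips = {"a": {"X"}, "b": {"Y"}, "c": {"X"}}
        p1 = area_marginals_exact(
            load_tree("((a:1,b:1):1,c:1);"), tips, areas=["X", "Y"], rate=0.2
        )
        p2 = area_marginals_exact(
            load_tree("(c:1,(b:1,a:1):1);"), tips, areas=["Y", "X"], rate=0.2
        )
        for key in p1.node_probs:
            for r, p in p1.node_probs[key].items():
                assert p2.node_probs[key][r] == pytest.approx(p, abs=1e-12)

    def test_missing_tip_range_errors(self):
        t = load_tree("(a:1,b:1);")
        with pytest.raises(ValueError, match="b"):
            area_marginals_exact(t, {"a": {"X"}}, areas=["X"])

    def test_max_areas_caps_range_size(self):
        t = load_tree("((a:1,b:1):1,c:1);")
        post = area_marginals_exact(
            t, {"a": {"X"}, "b": {"Y"}, "c": {"Z"}},
            areas=["X", "Y", "Z"], rate=0.5, max_areas=1,
        )
        for probs in post.node_probs.values():
            assert all(len(r) == 1 for r in probs)


class TestMcmc:
    def test_agrees_with_exact_at_protocol_settings(self):
        t = load_tree("((a:1,b:1):1,c:1);")
        tips = {"a": {"X"}, "b": {"X"}, "c": {"Y"}}
        exact = area_marginals_exact(t, tips, max_areas=2, rate="ML")
        mc = bbm_sample(t, tips, config=BbmConfig(max_areas=2), seed=3)
        sup = max(
            abs(p - mc.node_probs[k].get(r, 0.0))
            for k in exact.node_probs
            for r, p in exact.node_probs[k].items()
        )
        assert sup < 0.02

    def test_deterministic_given_seed(self):
        t = load_tree("((a:1,b:1):1,c:1);")
        tips = {"a": {"X"}, "b": {"X"}, "c": {"Y"}}
        cfg = BbmConfig(generations=20_000, sample_every=100)
        m1 = bbm_sample(t, tips, config=cfg, seed=5)
        m2 = bbm_sample(t, tips, config=cfg, seed=5)
        assert m1.node_probs == m2.node_probs

    def test_sample_count_arithmetic(self):
        # 2 runs x 1000 retained, 25% burn-in -> up to 1500 combined
        t = load_tree("(a:1,b:1);")
        tips = {"a": {"X"}, "b": {"X"}}
        mc = bbm_sample(t, tips, config=BbmConfig(max_areas=1), seed=1)
        key = node_key(t.tree.seed_node)
        assert mc.n_samples[key] == 1500


class TestEvents:
    def test_dispersal_then_vicariance_string(self):
        t = load_tree("((a:1,b:1)n1:1,c:1);")
        tips = {"a": {"D"}, "b": {"SC"}, "c": {"D"}}
        modal = {
            node_key(t.tree.seed_node): frozenset({"D"}),
            "a,b": frozenset({"D", "SC"}),
        }
        events = classify_events(t, modal, tips, areas=["D", "SC"])
        strings = [e["string"] for e in events if e["kind"] == "scenario"]
        assert "D → D+SC → D | SC" in strings
        kinds = {e["kind"] for e in events}
        assert "dispersal" in kinds and "vicariance" in kinds

    def test_no_change_gives_no_events(self):
        t = load_tree("((a:1,b:1):1,c:1);")
        tips = {"a": {"X"}, "b": {"X"}, "c": {"X"}}
        modal = {
            node_key(t.tree.seed_node): frozenset({"X"}),
            "a,b": frozenset({"X"}),
        }
        events = classify_events(t, modal, tips, areas=["X"])
        assert [e for e in events if e["kind"] != "scenario"] == []

    def test_overlapping_daughters_not_vicariance(self):
        t = load_tree("((a:1,b:1)m:1,c:1);")
        tips = {"a": {"X", "Y"}, "b": {"X"}, "c": {"X", "Y"}}
        modal = {
            node_key(t.tree.seed_node): frozenset({"X", "Y"}),
            "a,b": frozenset({"X", "Y"}),
        }
        events = classify_events(t, modal, tips, areas=["X", "Y"])
        assert all(e["kind"] != "vicariance" for e in events)
        assert all(e["kind"] != "dispersal" for e in events)

    def test_event_strings_parse_back(self):
        before, gained, split = parse_event_string("D → D+SC → D | SC")
        assert before == frozenset({"D"})
        assert gained == frozenset({"SC"})
        assert split == [frozenset({"D"}), frozenset({"SC"})]

    def test_range_rendering_follows_area_order(self):
        assert render_range({"SC", "D"}, ["D", "SC", "EC"]) == "D+SC"


class TestRecovery:
    def test_modal_root_beats_no_information_baseline(self):
        # low dispersal: the exact reconstruction should recover the true
        # root region far above the 1/|admissible| baseline
        n_rep = 40
        hits = 0
        n_regions, max_areas = 3, 2
        n_admissible = 3 + 3  # singletons + pairs
        for seed in range(n_rep):
            b = sim_phylogeography(
                seed=1000 + seed, n_tips=8, n_regions=n_regions,
                sub_rate=0.0, indel_rate=0.0, dispersal_rate=0.05,
            )
            post = area_marginals_exact(
                b.true_tree, b.true_tip_areas,
                areas=[f"R{i+1}" for i in range(n_regions)],
                max_areas=max_areas, rate="ML",
            )
            root_key = node_key(b.true_tree.tree.seed_node)
            if post.modal[root_key] == b.true_node_areas["root"]:
                hits += 1
        assert hits / n_rep >= 5.0 / n_admissible
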