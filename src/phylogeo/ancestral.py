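"""Bayesian binary ancestral-area reconstruction on a fixed rooted tree.

Each geographic area is an independent two-state (absent/present) Markov
chain with equal stationary frequencies and one rate shared across areas
— the binary analogue of a Jukes–Cantor chain with equal variation across
"sites" (areas).  Per-node range posteriors are the per-area marginal
posteriors multiplied together and renormalized over admissible ranges
(non-empty subsets of at most ``max_areas`` areas).

Two routes compute the same posterior: :func:`area_marginals_exact`
(Felsenstein pruning, inside–outside; the default) and
:func:`bbm_sample` (Metropolis MCMC over the rate and per-node area
indicators, two runs combined after burn-in — the protocol of the
classic Bayesian binary MCMC programs).  Polytomies are handled natively.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .io import PhyloTree

__all__ = [
    "BbmConfig",
    "RangePosterior",
    "node_key",
    "area_marginals_exact",
    "bbm_sample",
    "classify_events",
    "render_range",
    "parse_event_string",
]


@dataclass
class BbmConfig:
    """Settings of the MCMC protocol (defaults follow the classic setup:
    1e6 generations sampled every 1000th, 25% burn-in, two combined runs,
    at most four areas per node, equal ("Jukes–Cantor") state frequencies
    and equal variation across areas)."""

    generations: int = 1_000_000
    sample_every: int = 1000
    burnin_frac: float = 0.25
    n_runs: int = 2
    max_areas: int = 4
    rate_bounds: tuple[float, float] = (1e-4, 1e2)
    sample_rate: bool = False
    tv_warning_threshold: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.burnin_frac < 1.0:
            raise ValueError("burnin_frac must be in (0, 1)")
        if self.max_areas < 1:
            raise ValueError("max_areas must be >= 1")


@dataclass
class RangePosterior:
    """Per-node probabilities over admissible ranges.

    Nodes are keyed by the sorted, comma-joined labels of their subtended
    tips (stable under node-label and tip-order changes).
    """

    areas: list[str]
    node_probs: dict[str, dict[frozenset, float]]
    modal: dict[str, frozenset]
    rate: float
    max_areas: int
    n_samples: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def prob(self, key: str, rng_set) -> float:
        return self.node_probs[key].get(frozenset(rng_set), 0.0)


def node_key(node: dendropy.Node) -> str:
    return ",".join(sorted(leaf.taxon.label for leaf in node.leaf_iter()))


def _admissible_ranges(n_areas: int, max_areas: int) -> list[frozenset]:
    out = []
    for size in range(1, min(n_areas, max_areas) + 1):
        out.extend(frozenset(c) for c in itertools.combinations(range(n_areas), size))
    return out


def _p_same(rate: float, t: float) -> float:
    return 0.5 * (1.0 + math.exp(-2.0 * rate * t))


def _tip_state_vectors(tree, areas, tip_ranges):
    """0/1 state per tip per area; raises on a missing tip."""
    states = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name not in tip_ranges:
            raise ValueError(f"tip {name!r} has no area assignment")
        rng = set(tip_ranges[name])
        unknown = rng - set(areas)
        if unknown:
            raise ValueError(f"tip {name!r} has unknown areas {sorted(unknown)}")
        if not rng:
            raise ValueError(f"tip {name!r} has an empty range")
        states[leaf] = np.array([1 if a in rng else 0 for a in areas], dtype=int)
    return states


def _per_area_loglik(tree, areas, tip_states, rate: float) -> float:
    """Total log-likelihood, summed over independent area chains."""
    total = 0.0
    for ai in range(len(areas)):
        partials = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                s = tip_states[node][ai]
                partials[node] = np.array([1.0 - s, float(s)])
            else:
                lk = np.ones(2)
                for child in node.child_nodes():
                    t = child.edge.length or 0.0
                    ps = _p_same(rate, t)
                    cp = partials[child]
                    lk *= np.array(
                        [ps * cp[0] + (1 - ps) * cp[1],
                         (1 - ps) * cp[0] + ps * cp[1]]
                    )
                partials[node] = lk
        root_lk = 0.5 * partials[tree.seed_node].sum()
        total += math.log(max(root_lk, 1e-300))
    return total


def _ml_rate(tree, areas, tip_states, bounds=(1e-4, 1e2)) -> float:
    res = minimize_scalar(
        lambda lg: -_per_area_loglik(tree, areas, tip_states, math.exp(lg)),
        bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(math.exp(res.x))


def _marginals_one_area(tree, tip_states, ai: int, rate: float) -> dict:
    """Per-node posterior P(state = 1) for one area via inside-outside."""
    inside = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tip_states[node][ai]
            inside[node] = np.array([1.0 - s, float(s)])
        else:
            lk = np.ones(2)
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                ps = _p_same(rate, t)
                cp = inside[child]
                lk *= np.array(
                    [ps * cp[0] + (1 - ps) * cp[1],
                     (1 - ps) * cp[0] + ps * cp[1]]
                )
            inside[node] = lk
    outside = {tree.seed_node: np.array([0.5, 0.5])}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            ps = _p_same(rate, t)
            sib = np.ones(2)
            for other in node.child_nodes():
                if other is child:
                    continue
                to = other.edge.length or 0.0
                po = _p_same(rate, to)
                co = inside[other]
                sib *= np.array(
                    [po * co[0] + (1 - po) * co[1],
                     (1 - po) * co[0] + po * co[1]]
                )
            above = outside[node] * sib
            outside[child] = np.array(
                [ps * above[0] + (1 - ps) * above[1],
                 (1 - ps) * above[0] + ps * above[1]]
            )
    marg = {}
    for node in tree.preorder_node_iter():
        w = inside[node] * outside[node]
        total = w.sum()
        marg[node] = float(w[1] / total) if total > 0 else 0.5
    return marg


def _combine_marginals(
    tree, areas, per_area_m1: dict, max_areas: int
) -> tuple[dict, dict]:
    """Product of per-area marginals, renormalized over admissible
    ranges; modal ties break toward the smaller range then lexicographic."""
    admissible = _admissible_ranges(len(areas), max_areas)
    node_probs: dict[str, dict[frozenset, float]] = {}
    modal: dict[str, frozenset] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        key = node_key(node)
        m1 = np.array([per_area_m1[ai][node] for ai in range(len(areas))])
        probs = {}
        for rng_idx in admissible:
            p = 1.0
            for ai in range(len(areas)):
                p *= m1[ai] if ai in rng_idx else (1.0 - m1[ai])
            probs[rng_idx] = p
        z = sum(probs.values())
        if z <= 0:
            probs = {r: 1.0 / len(admissible) for r in admissible}
        else:
            probs = {r: p / z for r, p in probs.items()}
        named = {
            frozenset(areas[i] for i in r): p for r, p in probs.items()
        }
        node_probs[key] = named
        modal[key] = min(
            named, key=lambda r: (-named[r], len(r), tuple(sorted(r)))
        )
    return node_probs, modal


def area_marginals_exact(
    tree: PhyloTree,
    tip_ranges: dict[str, set[str] | frozenset],
    areas: list[str] | None = None,
    max_areas: int = 4,
    rate: float | str = "ML",
) -> RangePosterior:
    """Exact per-node range posteriors by the pruning algorithm.

    ``rate`` is either a fixed per-area switch rate or ``"ML"`` to
    maximize the joint likelihood over the shared rate first.
    """
    t = tree.tree
    if areas is None:
        areas = sorted({a for rng in tip_ranges.values() for a in rng})
    tip_states = _tip_state_vectors(t, areas, tip_ranges)
    if rate == "ML":
        rate_val = _ml_rate(t, areas, tip_states)
    else:
        rate_val = float(rate)
        if rate_val <= 0:
            raise ValueError("rate must be positive")
    per_area = {
        ai: _marginals_one_area(t, tip_states, ai, rate_val)
        for ai in range(len(areas))
    }
    node_probs, modal = _combine_marginals(t, areas, per_area, max_areas)
    return RangePosterior(
        areas=list(areas), node_probs=node_probs, modal=modal,
        rate=rate_val, max_areas=max_areas,
    )


def _mcmc_run(
    nodes, edges, tip_state, root_idx, n_internal, n_areas, rate0, config, rng
):
    """One Metropolis run; returns retained per-sample internal states.

    ``edges``: list of (parent_idx, child_idx, length).  States are a
    (n_nodes, n_areas) 0/1 array; tip rows are fixed.
    """
    n_nodes = len(nodes)
    state = np.zeros((n_nodes, n_areas), dtype=np.int8)
    state[:] = tip_state  # internal rows randomized below
    # adjacency: per node, list of incident edge indices
    incident = [[] for _ in range(n_nodes)]
    for e_i, (p, c, _t) in enumerate(edges):
        incident[p].append(e_i)
        incident[c].append(e_i)
    internal = [i for i in range(n_nodes) if nodes[i] == "internal"]
    for i in internal:
        state[i] = rng.integers(0, 2, size=n_areas)

    lo, hi = config.rate_bounds
    rate = rate0

    def edge_logp(e_i, rate, lps, lpd):
        p, c, _t = edges[e_i]
        same = state[p] == state[c]
        return float(same.sum() * lps[e_i] + (n_areas - same.sum()) * lpd[e_i])

    def precompute(rate):
        lps = np.empty(len(edges))
        lpd = np.empty(len(edges))
        for e_i, (_p, _c, t) in enumerate(edges):
            ps = _p_same(rate, t)
            lps[e_i] = math.log(max(ps, 1e-300))
            lpd[e_i] = math.log(max(1.0 - ps, 1e-300))
        return lps, lpd

    lps, lpd = precompute(rate)
    total = sum(edge_logp(e, rate, lps, lpd) for e in range(len(edges)))

    retained = []
    n_gens = config.generations
    sample_every = config.sample_every
    for gen in range(1, n_gens + 1):
        if config.sample_rate and rng.random() < 0.1:
            # multiplicative log-uniform window proposal for the rate
            prop = rate * math.exp(rng.uniform(-0.5, 0.5))
            if lo <= prop <= hi:
                lps_p, lpd_p = precompute(prop)
                total_p = sum(
                    edge_logp(e, prop, lps_p, lpd_p) for e in range(len(edges))
                )
                # log-uniform prior on the rate; symmetric proposal in log space
                if math.log(rng.random() + 1e-300) < total_p - total:
                    rate, lps, lpd, total = prop, lps_p, lpd_p, total_p
        else:
            v = internal[int(rng.integers(len(internal)))]
            a = int(rng.integers(n_areas))
            old_local = 0.0
            for e_i in incident[v]:
                p, c, _t = edges[e_i]
                old_local += lps[e_i] if state[p, a] == state[c, a] else lpd[e_i]
            state[v, a] ^= 1
            new_local = 0.0
            for e_i in incident[v]:
                p, c, _t = edges[e_i]
                new_local += lps[e_i] if state[p, a] == state[c, a] else lpd[e_i]
            if math.log(rng.random() + 1e-300) < new_local - old_local:
                total += new_local - old_local
            else:
                state[v, a] ^= 1
        if gen % sample_every == 0:
            retained.append((state[internal].copy(), rate))
    n_burn = int(round(config.burnin_frac * len(retained)))
    return retained[n_burn:], internal


def bbm_sample(
    tree: PhyloTree,
    tip_ranges: dict[str, set[str] | frozenset],
    areas: list[str] | None = None,
    config: BbmConfig | None = None,
    seed: int = 0,
) -> RangePosterior:
    """MCMC range posteriors (two runs combined after burn-in).

    The chain updates the shared per-area rate (multiplicative log-window
    proposal under a log-uniform prior) and one internal-node area
    indicator per generation; per-node range frequencies are tabulated
    from the retained samples over admissible ranges.  Agrees with
    :func:`area_marginals_exact` within Monte-Carlo error; deterministic
    given ``seed``.
    """
    config = config or BbmConfig()
    t = tree.tree
    if areas is None:
        areas = sorted({a for rng in tip_ranges.values() for a in rng})
    n_areas = len(areas)
    tip_states_map = _tip_state_vectors(t, areas, tip_ranges)

    node_list = list(t.preorder_node_iter())
    idx = {id(n): i for i, n in enumerate(node_list)}
    kinds = ["leaf" if n.is_leaf() else "internal" for n in node_list]
    edges = []
    for n in node_list:
        for child in n.child_nodes():
            edges.append((idx[id(n)], idx[id(child)], child.edge.length or 0.0))
    tip_state = np.zeros((len(node_list), n_areas), dtype=np.int8)
    for n in node_list:
        if n.is_leaf():
            tip_state[idx[id(n)]] = tip_states_map[n]

    rate0 = _ml_rate(t, areas, tip_states_map, bounds=config.rate_bounds)
    seeds = np.random.SeedSequence(seed).spawn(config.n_runs)
    all_samples = []
    run_freqs = []
    internal_positions = None
    for r in range(config.n_runs):
        rng = np.random.default_rng(seeds[r])
        retained, internal = _mcmc_run(
            kinds, edges, tip_state, idx[id(t.seed_node)],
            sum(k == "internal" for k in kinds), n_areas, rate0, config, rng,
        )
        internal_positions = internal
        all_samples.append(retained)
        counts = {}
        for st, _rate in retained:
            for row_i in range(st.shape[0]):
                present = frozenset(np.nonzero(st[row_i])[0])
                counts.setdefault(row_i, {}).setdefault(present, 0)
                counts[row_i][present] += 1
        run_freqs.append(counts)

    internal_nodes = [node_list[i] for i in internal_positions]
    keys = [node_key(n) for n in internal_nodes]
    admissible = set(_admissible_ranges(n_areas, config.max_areas))
    node_probs: dict[str, dict[frozenset, float]] = {}
    modal: dict[str, frozenset] = {}
    n_samples: dict[str, int] = {}
    warnings = []
    for row_i, key in enumerate(keys):
        combined: dict[frozenset, int] = {}
        per_run = []
        for counts in run_freqs:
            rc = {
                r: c for r, c in counts.get(row_i, {}).items() if r in admissible
            }
            per_run.append(rc)
            for r, c in rc.items():
                combined[r] = combined.get(r, 0) + c
        total = sum(combined.values())
        if total == 0:
            probs = {frozenset(areas): 1.0}
        else:
            probs = {
                frozenset(areas[i] for i in r): c / total
                for r, c in combined.items()
            }
        node_probs[key] = probs
        modal[key] = min(
            probs, key=lambda r: (-probs[r], len(r), tuple(sorted(r)))
        )
        n_samples[key] = total
        # between-run agreement (total variation distance)
        if len(per_run) == 2:
            t1, t2 = (sum(rc.values()) for rc in per_run)
            if t1 and t2:
                support = set(per_run[0]) | set(per_run[1])
                tv = 0.5 * sum(
                    abs(per_run[0].get(r, 0) / t1 - per_run[1].get(r, 0) / t2)
                    for r in support
                )
                if tv > config.tv_warning_threshold:
                    warnings.append(
                        f"node {key}: run posteriors disagree (TV={tv:.3f})"
                    )
    return RangePosterior(
        areas=list(areas), node_probs=node_probs, modal=modal,
        rate=rate0, max_areas=config.max_areas,
        n_samples=n_samples, warnings=warnings,
    )


def render_range(rng_set, areas: list[str]) -> str:
    order = {a: i for i, a in enumerate(areas)}
    return "+".join(sorted(rng_set, key=lambda a: order.get(a, len(order))))


def classify_events(
    tree: PhyloTree,
    modal: dict[str, frozenset],
    tip_ranges: dict[str, set[str] | frozenset] | None = None,
    areas: list[str] | None = None,
) -> list[dict]:
    """Dispersal / vicariance / local-extinction events from modal ranges.

    Per branch, areas gained relative to the parent's modal range are
    dispersals and areas lost are local extinctions; at a node whose
    daughters' ranges disjointly partition (a subset of) its own range, a
    vicariance is recorded.  Strings use the ``before → before+gained →
    left | right`` arrow notation.
    """
    t = tree.tree
    if areas is None:
        seen = set()
        for r in modal.values():
            seen |= set(r)
        if tip_ranges:
            for r in tip_ranges.values():
                seen |= set(r)
        areas = sorted(seen)

    def range_of(node):
        if node.is_leaf():
            if tip_ranges is None:
                return None
            return frozenset(tip_ranges[node.taxon.label])
        return modal[node_key(node)]

    events: list[dict] = []
    for node in t.preorder_node_iter():
        if node.is_leaf():
            continue
        own = range_of(node)
        parent = node.parent_node
        gained = lost = frozenset()
        if parent is not None:
            prange = range_of(parent)
            gained = own - prange
            lost = prange - own
        children = node.child_nodes()
        child_ranges = [range_of(c) for c in children]
        vicariant = (
            all(r is not None and r for r in child_ranges)
            and len(children) >= 2
            and all(
                not (child_ranges[i] & child_ranges[j])
                for i in range(len(children)) for j in range(i + 1, len(children))
            )
            and frozenset().union(*child_ranges) <= own
        )
        if parent is None and not vicariant:
            continue
        if not gained and not lost and not vicariant:
            continue
        parts = []
        if parent is not None:
            before = range_of(parent)
            parts.append(render_range(before, areas))
            if gained:
                parts.append(render_range(own, areas))
                for a in sorted(gained):
                    events.append(
                        {"node": node_key(node), "kind": "dispersal", "area": a}
                    )
            elif lost or vicariant:
                if own != before:
                    parts.append(render_range(own, areas))
            for a in sorted(lost):
                events.append(
                    {"node": node_key(node), "kind": "local_extinction", "area": a}
                )
        else:
            parts.append(render_range(own, areas))
        if vicariant:
            parts.append(" | ".join(render_range(r, areas) for r in child_ranges))
            events.append({"node": node_key(node), "kind": "vicariance"})
        if len(parts) > 1:
            string = " → ".join(parts)
            events.append(
                {"node": node_key(node), "kind": "scenario", "string": string}
            )
    return events


def parse_event_string(string: str) -> tuple[frozenset, frozenset, list[frozenset]]:
    """Inverse of the scenario rendering: returns (before, gained, split)."""
    stages = [s.strip() for s in string.split("→")]
    before = frozenset(stages[0].split("+"))
    gained: frozenset = frozenset()
    split: list[frozenset] = []
    for stage in stages[1:]:
        if "|" in stage:
            split = [frozenset(p.strip().split("+")) for p in stage.split("|")]
        else:
            after = frozenset(stage.split("+"))
            gained = after - before
    return before, gained, split
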