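"""Statistical-parsimony haplotype networks with simple indel coding.

The stage mirrors the classic chloroplast-haplotype workflow: gaps in the
alignment are recoded as binary presence/absence characters (the "simple"
indel coding of Simmons & Ochoterena), sequences are collapsed into
haplotypes, a statistical-parsimony connection limit is computed, and a
TCS-style network is built by agglomerative minimal-step connection with
median vectors standing in for unsampled intermediates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import AMBIGUITY, Alignment

__all__ = [
    "IndelCharacterMatrix",
    "HaplotypeTable",
    "code_indels",
    "collapse_haplotypes",
    "connection_limit",
    "parsimony_probability",
    "haplotype_distance",
    "build_network",
]

PRESENT, ABSENT, INAPPLICABLE = 1, 0, -1  # -1 renders as '?'


@dataclass
class IndelCharacterMatrix:
    """Binary gap characters from simple indel coding.

    ``characters`` lists distinct gap ranges as half-open 0-based
    ``(start, end)`` tuples; ``states[id]`` is the per-character vector
    with values 1 (gap present), 0 (absent) or -1 (inapplicable: the
    sequence's own, larger gap strictly contains the range).
    """

    characters: list[tuple[int, int]]
    states: dict[str, tuple[int, ...]]

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def state_string(self, sid: str) -> str:
        return "".join(
            "?" if s == INAPPLICABLE else str(s) for s in self.states[sid]
        )


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c == "-" and start is None:
            start = i
        elif c != "-" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def code_indels(aln: Alignment, exclude_terminal: bool = True) -> IndelCharacterMatrix:
    """Simple indel coding of an aligned matrix.

    Every distinct gap range (identical start *and* end in at least one
    sequence) becomes one binary character.  A sequence scores 1 when its
    own gap equals the range, ``?`` (inapplicable) when one of its gaps
    strictly contains the range with different endpoints, and 0 otherwise.
    Terminal gaps are excluded by default — they usually reflect missing
    sequence, not indel events.
    """
    L = aln.length
    per_seq_runs: dict[str, list[tuple[int, int]]] = {}
    observed: set[tuple[int, int]] = set()
    for sid, seq in zip(aln.ids, aln.seqs):
        runs = _gap_runs(seq)
        if exclude_terminal:
            runs = [r for r in runs if r[0] > 0 and r[1] < L]
        per_seq_runs[sid] = runs
        observed.update(runs)
    characters = sorted(observed)
    states: dict[str, tuple[int, ...]] = {}
    for sid in aln.ids:
        runs = per_seq_runs[sid]
        vec = []
        for (cs, ce) in characters:
            value = ABSENT
            for (gs, ge) in runs:
                if (gs, ge) == (cs, ce):
                    value = PRESENT
                    break
                if gs <= cs and ce <= ge and (gs, ge) != (cs, ce):
                    value = INAPPLICABLE
                    break
            vec.append(value)
        states[sid] = tuple(vec)
    return IndelCharacterMatrix(characters=characters, states=states)


@dataclass
class HaplotypeTable:
    """Distinct (sequence, indel-state vector) pairs with membership."""

    labels: list[str]
    sequences: dict[str, str]  # representative aligned sequence per label
    indel_states: dict[str, tuple[int, ...]]
    membership: dict[str, list[tuple[str, str, str]]]  # (id, population, region)

    @property
    def frequencies(self) -> dict[str, int]:
        return {lab: len(self.membership[lab]) for lab in self.labels}

    def __len__(self) -> int:
        return len(self.labels)


def _bases_match(a: str, b: str, ambiguity_matches: bool) -> bool:
    if a == b:
        return True
    if not ambiguity_matches:
        return False
    sa, sb = AMBIGUITY.get(a), AMBIGUITY.get(b)
    if sa is None or sb is None:
        return False
    return bool(sa & sb)


def _same_haplotype(
    seq_a: str, seq_b: str, states_a, states_b, ambiguity_matches: bool
) -> bool:
    if states_a != states_b:
        return False
    for ca, cb in zip(seq_a, seq_b):
        if ca == "-" or cb == "-":
            continue  # gap columns are carried by the indel characters
        if not _bases_match(ca, cb, ambiguity_matches):
            return False
    return True


def collapse_haplotypes(
    aln: Alignment,
    indel_matrix: IndelCharacterMatrix | None = None,
    ambiguity_matches: bool = True,
) -> HaplotypeTable:
    """Collapse sequences into haplotypes.

    Two sequences share a haplotype iff they are identical at every
    position where both carry a base (ambiguity codes match any compatible
    base by default) and their indel-state vectors are identical.
    Sequences are scanned in input order and merged into the first
    matching haplotype; labels are H1, H2, ... in order of first
    appearance.
    """
    if indel_matrix is None:
        indel_matrix = code_indels(aln)
    labels: list[str] = []
    sequences: dict[str, str] = {}
    indel_states: dict[str, tuple[int, ...]] = {}
    membership: dict[str, list[tuple[str, str, str]]] = {}
    for sid, seq in zip(aln.ids, aln.seqs):
        st = indel_matrix.states[sid]
        m = aln.meta.get(sid, {})
        entry = (sid, m.get("population", ""), m.get("region", ""))
        for lab in labels:
            if _same_haplotype(seq, sequences[lab], st, indel_states[lab], ambiguity_matches):
                membership[lab].append(entry)
                break
        else:
            lab = f"H{len(labels) + 1}"
            labels.append(lab)
            sequences[lab] = seq
            indel_states[lab] = st
            membership[lab] = [entry]
    return HaplotypeTable(
        labels=labels, sequences=sequences,
        indel_states=indel_states, membership=membership,
    )


def parsimony_probability(seq_len: int, steps: int) -> float:
    """Probability that a ``steps``-step connection is non-homoplastic.

    Sites are taken as i.i.d. Poisson mutation targets.  The per-site
    divergence is estimated from the observed proportion ``steps/seq_len``
    with the Jukes–Cantor multiple-hit correction, and the probability
    that *no* site was hit more than once (i.e. the observed differences
    are the true mutational path) is returned.  Decreasing in ``steps``.
    """
    if seq_len <= 0:
        raise ValueError("seq_len must be positive")
    if steps <= 0:
        return 1.0
    p = steps / seq_len
    if p >= 0.75:
        return 0.0
    lam = -0.75 * math.log1p(-4.0 * p / 3.0)  # JC-corrected hits per site
    per_site = math.log1p(lam) - lam  # log[(1 + lam) e^-lam]
    return math.exp(seq_len * per_site)


def connection_limit(
    seq_len: int, alpha: float = 0.95, fixed_limit: int | None = None
) -> int:
    """Largest number of steps trusted at confidence ``alpha``.

    Returns the largest j with ``parsimony_probability(seq_len, j) >=
    alpha``, never below 1 (single-step connections are always trusted).
    A user-supplied ``fixed_limit`` bypasses the computation.
    """
    if fixed_limit is not None:
        if fixed_limit < 0:
            raise ValueError("fixed limit must be >= 0")
        return fixed_limit
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    j = 1
    while parsimony_probability(seq_len, j + 1) >= alpha:
        j += 1
        if j > seq_len:
            break
    return j


def haplotype_distance(
    table: HaplotypeTable, lab_a: str, lab_b: str, ambiguity_matches: bool = True
) -> int:
    """Mutational steps between two haplotypes: substitution mismatches
    over columns where both carry a base, plus one step per indel
    character on which they differ ('?' contributes nothing)."""
    sa, sb = table.sequences[lab_a], table.sequences[lab_b]
    d = 0
    for ca, cb in zip(sa, sb):
        if ca == "-" or cb == "-":
            continue
        if not _bases_match(ca, cb, ambiguity_matches):
            d += 1
    for xa, xb in zip(table.indel_states[lab_a], table.indel_states[lab_b]):
        if INAPPLICABLE in (xa, xb):
            continue
        if xa != xb:
            d += 1
    return d


def _median_sequences(table: HaplotypeTable, lab_a: str, lab_b: str) -> list[str]:
    """Materialized intermediates on the a→b path, mutating substitution
    columns in ascending column order, then indel characters in order.
    Only their count and connectivity are contract-bearing."""
    a, b = sorted([lab_a, lab_b])
    seq = list(table.sequences[a])
    target = table.sequences[b]
    diffs = [
        i for i, (ca, cb) in enumerate(zip(seq, target))
        if ca != "-" and cb != "-" and not _bases_match(ca, cb, True)
    ]
    sta, stb = table.indel_states[a], table.indel_states[b]
    indel_diffs = [
        k for k, (xa, xb) in enumerate(zip(sta, stb))
        if INAPPLICABLE not in (xa, xb) and xa != xb
    ]
    out = []
    state = list(sta)
    for i in diffs:
        seq[i] = target[i]
        out.append("".join(seq) + "/" + "".join(map(str, state)))
    for k in indel_diffs:
        state[k] = stb[k]
        out.append("".join(seq) + "/" + "".join(map(str, state)))
    return out[:-1] if out else []  # last mutation reaches b itself


def build_network(
    table: HaplotypeTable, limit: int, ambiguity_matches: bool = True
) -> nx.Graph:
    """TCS-style agglomerative network construction.

    For d = 1..limit, every haplotype pair at mutational distance d whose
    members lie in distinct components (as of the start of level d) is
    connected by a path of d−1 median vectors; all minimal ties are kept,
    so reticulations survive.  Pairs already in one component are skipped.
    Haplotypes still unconnected at d = limit remain separate components.

    Returns a networkx graph with node attributes ``label``, ``frequency``,
    ``is_median``, ``regions`` (";"-joined region:count) and graph
    attributes ``connections`` (list of (u, v, d) actually added) and
    ``limit``.
    """
    g = nx.Graph(limit=limit, connections=[])
    freqs = table.frequencies
    for lab in table.labels:
        counts: dict[str, int] = {}
        for (_sid, _pop, region) in table.membership[lab]:
            counts[region] = counts.get(region, 0) + 1
        g.add_node(
            lab, label=lab, frequency=freqs[lab], is_median=False,
            regions=";".join(f"{r}:{n}" for r, n in sorted(counts.items())),
        )
    labs = table.labels
    dist = {
        (a, b): haplotype_distance(table, a, b, ambiguity_matches)
        for i, a in enumerate(labs) for b in labs[i + 1:]
    }
    mv_counter = 0
    for d in range(1, limit + 1):
        comp = {n: i for i, c in enumerate(nx.connected_components(g)) for n in c}
        for (a, b), dd in dist.items():
            if dd != d or comp[a] == comp[b]:
                continue
            mids = _median_sequences(table, a, b)
            prev = a
            for _k in range(d - 1):
                mv_counter += 1
                mv = f"mv{mv_counter}"
                g.add_node(
                    mv, label=mv, frequency=0, is_median=True, regions="",
                    state=mids[_k] if _k < len(mids) else "",
                )
                g.add_edge(prev, mv, weight=1)
                prev = mv
            g.add_edge(prev, b, weight=1)
            g.graph["connections"].append((a, b, d))
    return g


def network_components(g: nx.Graph) -> list[set[str]]:
    return [set(c) for c in nx.connected_components(g)]


def write_network_graphml(g: nx.Graph, path) -> None:
    """GraphML export (the connection log is flattened to one string)."""
    out = g.copy()
    out.graph["connections"] = ";".join(
        f"{u}-{v}:{d}" for u, v, d in g.graph.get("connections", [])
    )
    nx.write_graphml(out, path)
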