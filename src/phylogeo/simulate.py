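"""Synthetic data with recorded ground truth for every pipeline stage.

Three generators emulate the statistical structure of the field data the
pipeline is built for, at desk scale:

* :func:`sim_phylogeography` — a Yule tree, sequences evolved on it under
  Jukes–Cantor with occasional multi-base deletions, and a geographic
  region token that switches along branches (a dispersal walk).
* :func:`sim_env_occurrences` — spatially autocorrelated environmental
  layers, a known logistic suitability surface, presence points sampled
  from it, and background cells above an elevation threshold.
* :func:`sim_structured_loci` — SNP matrices with K planted clusters whose
  differentiation is controlled by a single ``divergence`` knob.

Every generator is a pure function of its seed: rerunning with the same
arguments yields byte-identical output.  The recorded truth (tree, tip and
node areas, cluster labels, suitability surface, informative layer names)
is sufficient to score every downstream stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.ndimage import gaussian_filter

from .io import (
    Alignment,
    GridStack,
    OccurrenceTable,
    PhyloTree,
    save_alignment,
    save_grid,
    save_occurrences,
    save_tree,
)

import pandas as pd

__all__ = [
    "SimBundle",
    "sim_phylogeography",
    "sim_env_occurrences",
    "sim_structured_loci",
    "shifted_period_stack",
    "save_bundle",
]

BASES = "ACGT"


@dataclass
class SimBundle:
    """Synthetic inputs plus the ground truth needed to score them."""

    seed: int
    alignment: Alignment | None = None
    true_tree: PhyloTree | None = None
    true_tip_areas: dict[str, frozenset[str]] = field(default_factory=dict)
    true_node_areas: dict[str, frozenset[str]] = field(default_factory=dict)
    true_clusters: dict[str, int] = field(default_factory=dict)
    env: GridStack | None = None
    truth_suitability: np.ndarray | None = None
    presences: OccurrenceTable | None = None
    background: OccurrenceTable | None = None
    informative_layers: list[str] = field(default_factory=list)
    beta: np.ndarray | None = None


def _yule_tree(rng: np.random.Generator, n_tips: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Pure-birth tree; branch lengths exponential in 1/(k·λ) per epoch."""
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.edge.length = 0.0
    tips = [tree.seed_node]
    while len(tips) < n_tips:
        wait = rng.exponential(1.0 / (birth_rate * len(tips)))
        for tip in tips:
            tip.edge.length += wait
        idx = rng.integers(len(tips))
        parent = tips.pop(idx)
        for _ in range(2):
            child = parent.new_child()
            child.edge.length = 0.0
            tips.append(child)
    # one final epoch so terminal branches are non-zero
    wait = rng.exponential(1.0 / (birth_rate * len(tips)))
    for tip in tips:
        tip.edge.length += wait
    order = rng.permutation(n_tips)
    for tip, k in zip(tips, order):
        tip.taxon = taxa[int(k)]
    return tree


def _evolve_sequence(
    rng: np.random.Generator, seq: np.ndarray, t: float, sub_rate: float
) -> np.ndarray:
    """JC substitutions: per site Poisson(sub_rate·t) events, each to a
    uniformly chosen different base."""
    out = seq.copy()
    if sub_rate <= 0 or t <= 0:
        return out
    n_events = rng.poisson(sub_rate * t, size=len(seq))
    for pos in np.nonzero(n_events)[0]:
        for _ in range(int(n_events[pos])):
            out[pos] = (out[pos] + rng.integers(1, 4)) % 4
    return out


def _draw_indels(
    rng: np.random.Generator,
    existing: list[tuple[int, int]],
    t: float,
    indel_rate: float,
    seq_len: int,
    mean_len: float,
    allow_overlap: bool,
) -> list[tuple[int, int]]:
    """New deletion ranges on a branch; by default rejection-sampled so no
    range overlaps one already present on the lineage (keeps simple gap
    coding unambiguous in the happy-path fixtures)."""
    gaps = list(existing)
    n_events = rng.poisson(indel_rate * t) if indel_rate > 0 and t > 0 else 0
    for _ in range(n_events):
        for _attempt in range(200):
            length = min(1 + rng.geometric(1.0 / mean_len), seq_len - 2)
            start = int(rng.integers(1, seq_len - length))  # avoid terminal gaps
            cand = (start, start + length)
            if allow_overlap or all(
                cand[1] <= g[0] or cand[0] >= g[1] for g in gaps
            ):
                gaps.append(cand)
                break
    return sorted(gaps)


def sim_phylogeography(
    seed: int,
    n_tips: int = 20,
    n_regions: int = 4,
    seq_len: int = 500,
    sub_rate: float = 0.02,
    indel_rate: float = 0.5,
    dispersal_rate: float = 0.1,
    indel_mean_len: float = 3.0,
    allow_overlapping_gaps: bool = False,
) -> SimBundle:
    """Evolve an alignment and a dispersal walk on a Yule tree.

    Substitutions are Poisson(``sub_rate`` × branch length) per site under
    Jukes–Cantor; deletions arrive as Poisson(``indel_rate`` × branch
    length) events with geometric lengths (mean ``indel_mean_len``) and are
    inherited down the lineage.  Each lineage carries one region token that
    switches to a uniformly drawn different region with probability
    1 − exp(−``dispersal_rate``·t) per branch.  Full truth (tree, per-node
    and per-tip regions) is recorded.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if seq_len < 50:
        raise ValueError("seq_len must be >= 50")
    if min(sub_rate, indel_rate, dispersal_rate) < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    tree = _yule_tree(rng, n_tips)
    regions = [f"R{i + 1}" for i in range(n_regions)]

    root = tree.seed_node
    root_seq = rng.integers(0, 4, size=seq_len)
    root_region = regions[int(rng.integers(n_regions))]
    state: dict[dendropy.Node, tuple[np.ndarray, list[tuple[int, int]], str]] = {
        root: (root_seq, [], root_region)
    }
    node_areas: dict[str, frozenset[str]] = {}
    tip_areas: dict[str, frozenset[str]] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node is root:
            seq, gaps, region = state[root]
        else:
            pseq, pgaps, pregion = state[node.parent_node]
            t = node.edge.length or 0.0
            seq = _evolve_sequence(rng, pseq, t, sub_rate)
            gaps = _draw_indels(
                rng, pgaps, t, indel_rate, seq_len, indel_mean_len,
                allow_overlapping_gaps,
            )
            region = pregion
            if dispersal_rate > 0 and rng.random() < 1.0 - np.exp(-dispersal_rate * t):
                others = [r for r in regions if r != pregion]
                region = others[int(rng.integers(len(others)))] if others else pregion
            state[node] = (seq, gaps, region)
        if node.is_leaf():
            tip_areas[node.taxon.label] = frozenset({region})
        else:
            counter += 1
            label = "root" if node is root else f"n{counter}"
            node.label = node.label or label
            node_areas[node.label] = frozenset({region})
    state[root] = (root_seq, [], root_region)

    ids, seqs, meta = [], [], {}
    for leaf in tree.leaf_node_iter():
        seq, gaps, region = state[leaf]
        chars = [BASES[b] for b in seq]
        for s, e in gaps:
            for i in range(s, e):
                chars[i] = "-"
        sid = leaf.taxon.label
        ids.append(sid)
        seqs.append("".join(chars))
        meta[sid] = {"region": region, "population": region.lower()}
    aln = Alignment(ids=ids, seqs=seqs, meta=meta)
    return SimBundle(
        seed=seed,
        alignment=aln,
        true_tree=PhyloTree(tree=tree),
        true_tip_areas=tip_areas,
        true_node_areas=node_areas,
    )


_INFORMATIVE_NAMES = ["BIO09", "BIO11", "BIO15", "BIO18"]


def _smooth_field(rng: np.random.Generator, shape, smooth_len: float) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal(shape), sigma=smooth_len, mode="wrap")
    field -= field.mean()
    field /= field.std()
    return field


def sim_env_occurrences(
    seed: int,
    nx: int = 100,
    ny: int = 80,
    n_informative: int = 4,
    n_noise: int = 10,
    n_redundant: int = 5,
    smooth_len: float = 5.0,
    n_presence: int = 600,
    elev_threshold: float = 0.0,
    beta_scale: float = 4.0,
    family_weight: float = 0.65,
    redundant_weight: float = 0.95,
) -> SimBundle:
    """Autocorrelated layers, a logistic truth surface, and sampled points.

    Layers are white noise smoothed with a Gaussian kernel of scale
    ``smooth_len`` cells and standardized to mean 0, sd 1.  As in real
    bioclimatic stacks, all candidate layers share a common "climate"
    latent field with loading ``family_weight`` (pairwise r ≈
    family_weight², kept below typical pruning thresholds), and each of
    ``n_redundant`` layers is a near-duplicate of an informative layer
    (r ≈ redundant_weight², above them — food for correlation pruning).
    An ``elev`` layer is built independently.  The defaults emulate a
    19-layer bioclimatic stack of which four variables drive the species.

    Truth suitability is logistic(β·informative layers) with |β| =
    ``beta_scale`` and alternating sign — the strong climatic determinism
    of a montane specialist — recorded in the bundle.  Presences are
    sampled (without replacement) proportionally to suitability among
    cells with elev > ``elev_threshold``; the background is *all* such
    cells, mirroring an "everything above the elevation cutoff" rule.
    """
    if nx < 20 or ny < 20:
        raise ValueError("grid must be at least 20x20")
    if n_informative < 1:
        raise ValueError("need at least one informative layer")
    rng = np.random.default_rng(seed)
    shape = (ny, nx)
    names = []
    layers: dict[str, np.ndarray] = {}
    common = _smooth_field(rng, shape, smooth_len)

    def correlated_field(base: np.ndarray, w: float) -> np.ndarray:
        f = math.sqrt(max(0.0, 1.0 - w * w)) * _smooth_field(rng, shape, smooth_len)
        f = f + w * base
        f -= f.mean()
        f /= f.std()
        return f

    for i in range(n_informative):
        name = _INFORMATIVE_NAMES[i] if i < len(_INFORMATIVE_NAMES) else f"INF{i + 1:02d}"
        names.append(name)
        layers[name] = correlated_field(common, family_weight)
    for i in range(n_noise):
        layers[f"RND{i + 1:02d}"] = correlated_field(common, family_weight)
    for i in range(n_redundant):
        base = layers[names[i % n_informative]]
        layers[f"DUP{i + 1:02d}"] = correlated_field(base, redundant_weight)
    elev = _smooth_field(rng, shape, smooth_len)
    layers["elev"] = elev
    env = GridStack(layers, cell_size=1.0, origin=(0.0, 0.0))

    beta = beta_scale * np.array([(-1.0) ** i for i in range(n_informative)])
    lin = np.zeros(shape)
    for b, name in zip(beta, names):
        lin += b * layers[name]
    truth = 1.0 / (1.0 + np.exp(-lin))

    eligible = elev > elev_threshold
    rows, cols = np.nonzero(eligible)
    if len(rows) == 0:
        raise ValueError("no cells above the elevation threshold")
    if n_presence > len(rows):
        raise ValueError(
            f"n_presence={n_presence} exceeds {len(rows)} eligible cells"
        )
    w = truth[rows, cols]
    p = w / w.sum()
    chosen = rng.choice(len(rows), size=n_presence, replace=False, p=p)
    # cell centres in map units; row 0 is the top of the array
    def centre(r, c):
        return (c + 0.5, (ny - 1 - r) + 0.5)

    pres_xy = [centre(rows[k], cols[k]) for k in chosen]
    presences = OccurrenceTable(
        pd.DataFrame(
            {"id": [f"p{i + 1}" for i in range(n_presence)],
             "x": [xy[0] for xy in pres_xy],
             "y": [xy[1] for xy in pres_xy]}
        ),
        role="presence",
    )
    bg_xy = [centre(r, c) for r, c in zip(rows, cols)]
    background = OccurrenceTable(
        pd.DataFrame(
            {"id": [f"b{i + 1}" for i in range(len(bg_xy))],
             "x": [xy[0] for xy in bg_xy],
             "y": [xy[1] for xy in bg_xy]}
        ),
        role="background",
    )
    return SimBundle(
        seed=seed,
        env=env,
        truth_suitability=truth,
        presences=presences,
        background=background,
        informative_layers=names,
        beta=beta,
    )


def shifted_period_stack(
    env: GridStack,
    informative: list[str] | dict[str, float],
    shift: float = 0.0,
) -> GridStack:
    """A paleo-period stack with shifted climate layers.

    ``informative`` is either a list of layer names (all shifted by the
    scalar ``shift``, in sd units) or a mapping name → per-layer shift.
    To emulate a period that is uniformly more (or less) favourable for a
    species with effect sizes β, shift each layer by ``s·sign(β)``
    (``-s·sign(β)``): with mixed-sign β a constant shift largely cancels.
    Everything else is unchanged.
    """
    if isinstance(informative, dict):
        deltas = dict(informative)
    else:
        deltas = {name: shift for name in informative}
    layers = {}
    for name in env.names:
        arr = env.arrays[name].copy()
        if name in deltas:
            arr = arr + deltas[name]
        layers[name] = arr
    return GridStack(layers, mask=env.mask, cell_size=env.cell_size, origin=env.origin)


def sim_structured_loci(
    seed: int,
    K: int = 3,
    n_per_cluster: int = 10,
    n_loci: int = 100,
    divergence: float = 0.8,
    n_alleles: int = 4,
    concentration: float = 0.5,
) -> tuple[Alignment, dict[str, int]]:
    """SNP matrix with K planted clusters.

    Per locus a common ancestral allele-frequency vector is drawn from a
    sparse symmetric Dirichlet (``concentration`` < 1 gives the L-shaped,
    major-allele-dominated spectrum typical of SNP data); cluster k's
    frequencies are the mixture
    (1 − divergence)·common + divergence·δ(allele_k) with a distinct fixed
    allele per cluster.  ``divergence=1`` fixes each cluster for its own
    allele at every locus; ``divergence=0`` removes all cluster signal.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    if K > n_alleles:
        raise ValueError("K must not exceed the allele count")
    rng = np.random.default_rng(seed)
    ids, seqs, clusters = [], [], {}
    common = rng.dirichlet(np.full(n_alleles, concentration), size=n_loci)
    fixed_allele = rng.permutation(n_alleles)[:K]
    genotypes = np.empty((K * n_per_cluster, n_loci), dtype=int)
    row = 0
    for k in range(K):
        freqs = (1.0 - divergence) * common
        freqs[:, fixed_allele[k]] += divergence
        cum = np.cumsum(freqs, axis=1)
        for _ in range(n_per_cluster):
            u = rng.random(n_loci)
            genotypes[row] = (u[:, None] > cum).sum(axis=1)
            sid = f"s{row + 1}"
            ids.append(sid)
            clusters[sid] = k + 1
            row += 1
    for i, sid in enumerate(ids):
        seqs.append("".join(BASES[a] for a in genotypes[i]))
    meta = {sid: {"region": f"C{clusters[sid]}", "population": ""} for sid in ids}
    return Alignment(ids=ids, seqs=seqs, meta=meta), clusters


def save_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    """Serialize a bundle as the on-disk directory layout the CLI reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth: dict = {"seed": bundle.seed}
    if bundle.alignment is not None:
        save_alignment(bundle.alignment, outdir / "alignment.fasta")
    if bundle.true_tree is not None:
        save_tree(bundle.true_tree, outdir / "tree.nwk")
    if bundle.true_tip_areas:
        pd.DataFrame(
            {"tip": list(bundle.true_tip_areas),
             "areas": [";".join(sorted(v)) for v in bundle.true_tip_areas.values()]}
        ).to_csv(outdir / "areas.csv", index=False)
        truth["node_areas"] = {
            k: sorted(v) for k, v in bundle.true_node_areas.items()
        }
    if bundle.true_clusters:
        truth["clusters"] = bundle.true_clusters
    if bundle.env is not None:
        envdir = outdir / "env"
        envdir.mkdir(exist_ok=True)
        for name in bundle.env.names:
            save_grid(name, envdir / f"{name}.asc", stack=bundle.env)
        truth["informative_layers"] = bundle.informative_layers
        truth["beta"] = list(map(float, bundle.beta)) if bundle.beta is not None else None
    if bundle.presences is not None:
        save_occurrences(bundle.presences, outdir / "presences.csv")
    if bundle.background is not None:
        save_occurrences(bundle.background, outdir / "background.csv")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
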