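"""Relative-rate node dating anchored by normal calibration densities.

Relative node times are the mean root-to-tip path lengths below each node
(the mean-path-length variant of relative-rate dating), normalized so the
root sits at 1 and every tip at 0.  Absolute ages come from a single
scale factor fitted by weighted least squares against calibration points,
each a normal density N(mean, sd) with sd implied by its 95% CI
(sd = (high − low)/3.92).  Age CIs propagate calibration uncertainty only
(delta method on the scale), not topological or branch-length error.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .ancestral import node_key
from .io import PhyloTree

__all__ = [
    "Calibration",
    "ChronoTree",
    "relative_times",
    "apply_calibrations",
]


@dataclass
class Calibration:
    """A normally distributed age prior on the MRCA of ``tips``.

    Ages are in Ma; ``ci95`` is the (low, high) 95% interval and implies
    sd = (high − low)/3.92 under normality.
    """

    tips: frozenset[str]
    mean: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if lo > hi:
            lo, hi = hi, lo
            self.ci95 = (lo, hi)
        if not lo <= self.mean <= hi:
            raise ValueError(
                f"calibration mean {self.mean} outside its CI {self.ci95}"
            )

    @property
    def sd(self) -> float:
        lo, hi = self.ci95
        return (hi - lo) / 3.92


@dataclass
class ChronoTree:
    """A dated tree: relative times, absolute ages and their CIs (Ma)."""

    tree: PhyloTree
    relative: dict[str, float]  # node key -> time in [0, 1], root = 1
    ages: dict[str, float]  # node key -> Ma
    ci: dict[str, tuple[float, float]]
    scale: float
    scale_sd: float

    def table(self, supports: dict[str, float] | None = None) -> pd.DataFrame:
        """Node age table (clade, mean age, 95% CI, support)."""
        rows = []
        for key in sorted(self.ages, key=lambda k: -self.ages[k]):
            lo, hi = self.ci[key]
            rows.append(
                {
                    "clade": key,
                    "mean_age": self.ages[key],
                    "ci_low": lo,
                    "ci_high": hi,
                    "support": (supports or {}).get(key, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def dated_newick(self) -> str:
        t = self.tree.tree.clone(depth=1)
        for node in t.preorder_node_iter():
            if not node.is_leaf():
                key = node_key(node)
                node.label = f"{self.ages.get(key, 0.0):.6g}"
        return t.as_string(schema="newick", suppress_rooting=True).strip()


def relative_times(tree: PhyloTree) -> dict[str, float]:
    """Mean-path-length relative node times, root = 1, tips = 0.

    time(node) is the mean over descendant tips of the node→tip path
    length, computed bottom-up as a tip-count-weighted mean over
    daughters.  Scale-invariant in the branch lengths.
    """
    t = tree.tree
    if tree.n_tips() < 2:
        raise ValueError("need at least 2 tips")
    raw: dict[int, tuple[float, int]] = {}  # id(node) -> (time, n_tips)
    for node in t.postorder_node_iter():
        if node.is_leaf():
            raw[id(node)] = (0.0, 1)
        else:
            num = 0.0
            w = 0
            for child in node.child_nodes():
                ct, cw = raw[id(child)]
                num += cw * (ct + (child.edge.length or 0.0))
                w += cw
            raw[id(node)] = (num / w, w)
    root_time = raw[id(t.seed_node)][0]
    if root_time <= 0:
        raise ValueError("tree has zero total depth; cannot compute relative times")
    out = {}
    for node in t.preorder_node_iter():
        out[node_key(node)] = raw[id(node)][0] / root_time
    return out


def _resolve_calibration_time(
    tree: PhyloTree, rel: dict[str, float], cal: Calibration
) -> float:
    t = tree.tree
    taxa = [t.taxon_namespace.get_taxon(x) for x in cal.tips]
    if any(tx is None for tx in taxa):
        missing = [x for x, tx in zip(cal.tips, taxa) if tx is None]
        raise ValueError(f"calibration tips not in tree: {missing}")
    mrca = t.mrca(taxa=taxa)
    return rel[node_key(mrca)]


def apply_calibrations(
    tree: PhyloTree,
    rel: dict[str, float],
    calibrations: list[Calibration],
) -> ChronoTree:
    """Fit the global time scale to the calibrations by WLS.

    The scale maximizing the product of normal calibration densities in
    the linear model age_i = s·t_i is

        s = Σ(μ_i·t_i/σ_i²) / Σ(t_i²/σ_i²),   var(s) = 1/Σ(t_i²/σ_i²).

    Zero-variance calibrations are fitted exactly (infinite weight); ages
    are s·t with CI ±1.96·t·sd(s).
    """
    if not calibrations:
        raise ValueError("at least one calibration required")
    ts = np.array([_resolve_calibration_time(tree, rel, c) for c in calibrations])
    if np.any(ts <= 0):
        bad = [c.tips for c, t in zip(calibrations, ts) if t <= 0]
        raise ValueError(f"calibrations resolve to zero-time nodes: {bad}")
    mus = np.array([c.mean for c in calibrations])
    sds = np.array([c.sd for c in calibrations])
    exact = sds == 0
    if exact.any():
        s_candidates = mus[exact] / ts[exact]
        if np.ptp(s_candidates) > 1e-9 * max(1.0, abs(s_candidates[0])):
            raise ValueError("conflicting zero-variance calibrations")
        scale = float(s_candidates[0])
        scale_sd = 0.0
    else:
        w = 1.0 / sds**2
        scale = float((mus * ts * w).sum() / (ts**2 * w).sum())
        scale_sd = float(np.sqrt(1.0 / (ts**2 * w).sum()))
    ages = {k: scale * v for k, v in rel.items()}
    ci = {
        k: (max(0.0, a - 1.96 * rel[k] * scale_sd), a + 1.96 * rel[k] * scale_sd)
        for k, a in ages.items()
    }
    return ChronoTree(
        tree=tree, relative=rel, ages=ages, ci=ci,
        scale=scale, scale_sd=scale_sd,
    )
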