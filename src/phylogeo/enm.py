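"""Ensemble species-distribution modeling with probe-based variable
elimination and a PCA consensus, projected across climate periods.

The workflow mirrors the ensemble SDM protocol used for montane plants:

1. screen the layer stack — drop near-zero-variance and linearly
   dependent layers, then step-wise remove layers until every remaining
   pair has |Pearson r| below a threshold (default 0.7);
2. thin occurrences — one point per raster cell, then one point per cell
   of the environmental space spanned by the first two principal
   components of the retained layers;
3. random-probe elimination — per algorithm, repeatedly discard the true
   variable that scores below the best random probe (a uniform variable
   over the same range) until none does; a variable leaves the final set
   only when a majority of algorithms (default 3 of 5) discarded it;
4. fit five learner families (neural net, classification tree,
   quadratic-logistic "maximum-entropy-style", gradient-boosted trees,
   bagged trees), each averaged over bootstrap repetitions;
5. summarize the per-learner suitability maps by their first principal
   component, sign-fixed and min–max rescaled to 0–100;
6. project the fitted learners onto past-period layer stacks and track
   each variable's mean and the pixel count with consensus suitability
   above 30, normalized so the present period equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mean_absolute_error, roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .io import GridStack, OccurrenceTable

__all__ = [
    "EnmConfig",
    "VariableReport",
    "EnsembleResult",
    "LEARNER_FAMILIES",
    "make_learner",
    "prune_variables",
    "filter_occurrences_envspace",
    "probe_elimination",
    "fit_ensemble",
    "consensus_pc1",
    "project_periods",
    "area_above",
]

LEARNER_FAMILIES = ["ann", "cta", "maxent", "brt", "bart"]


@dataclass
class EnmConfig:
    """Knobs of the ensemble workflow (defaults follow the standard
    protocol: ρ = 0.7 correlation cutoff, 3-of-5 probe consensus, 100
    bootstrap repetitions per algorithm, 0–100 consensus scale, area
    counted above suitability 30, environmental thinning at one point per
    unit PC cell)."""

    corr_threshold: float = 0.7
    probe_consensus: int = 3
    n_reps: int = 100
    consensus_rescale: tuple[float, float] = (0.0, 100.0)
    area_threshold: float = 30.0
    pc_cell: float = 1.0
    mae_best: str = "min"  # "min" (MAE read as a loss) or "max" (literal)
    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.corr_threshold < 1.0:
            raise ValueError("corr_threshold must be in (0, 1)")
        if self.probe_consensus > len(LEARNER_FAMILIES):
            raise ValueError("probe_consensus exceeds the number of algorithms")


@dataclass
class VariableReport:
    """Fate of every input variable, with importances where computed."""

    retained: list[str]
    removed: dict[str, str]  # name -> correlated | near-zero-variance |
    #                                  linear-dependence | probe-eliminated
    per_algorithm_importances: dict[str, dict[str, float]] = field(default_factory=dict)
    probe_importances: dict[str, float] = field(default_factory=dict)
    discarded_by: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.retained) & set(self.removed)
        if overlap:
            raise ValueError(f"variables both retained and removed: {overlap}")


@dataclass
class EnsembleResult:
    """Fitted ensemble outputs for the present and any projected periods."""

    learner_grids: dict[str, np.ndarray]
    consensus: np.ndarray  # 0-100, NaN on masked cells
    auc: dict[str, float]
    mae: dict[str, float]
    period_consensus: dict[str, np.ndarray] = field(default_factory=dict)
    trend: pd.DataFrame | None = None
    variable_report: VariableReport | None = None


def make_learner(name: str, seed: int):
    """One configured estimator per learner family (all expose
    ``predict_proba``)."""
    if name == "ann":
        return MLPClassifier(
            hidden_layer_sizes=(8,), max_iter=400, random_state=seed,
            alpha=1e-3,
        )
    if name == "cta":
        return DecisionTreeClassifier(min_samples_leaf=5, random_state=seed)
    if name == "maxent":
        # regularized logistic regression over linear+quadratic features:
        # a maximum-entropy-style model with lq feature classes
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("poly", PolynomialFeatures(degree=2, include_bias=False)),
                ("logit", LogisticRegression(C=1.0, max_iter=2000)),
            ]
        )
    if name == "brt":
        return GradientBoostingClassifier(
            n_estimators=60, max_depth=3, learning_rate=0.1, random_state=seed
        )
    if name == "bart":
        return RandomForestClassifier(
            n_estimators=60, min_samples_leaf=3, random_state=seed
        )
    raise ValueError(f"unknown learner family {name!r}")


# ---------------------------------------------------------------- variables


def _corr_matrix(values: np.ndarray) -> np.ndarray:
    return np.corrcoef(values, rowvar=False)


def prune_variables(
    stack: GridStack,
    background: OccurrenceTable | None = None,
    corr_threshold: float = 0.7,
    exclude: Sequence[str] = ("elev",),
) -> VariableReport:
    """Screen layers: near-zero variance, exact collinearity, then
    step-wise |r| >= threshold removal.

    Correlations are computed over background cells (all unmasked cells
    when no background is given).  At each step the layer with the most
    partners at |r| >= threshold goes first; ties break toward the larger
    mean |r|, then lexicographic name order.  ``exclude`` names layers
    (the elevation layer by default) that are not candidate predictors.
    """
    names = [n for n in stack.names if n not in exclude]
    if len(names) < 2:
        raise ValueError("need at least two candidate layers")
    if background is not None:
        xy = background.xy
        values = np.column_stack(
            [stack.extract(n, xy[:, 0], xy[:, 1]) for n in names]
        )
    else:
        values = stack.valid_values(names)
    removed: dict[str, str] = {}

    keep_idx = []
    for i, n in enumerate(names):
        if np.nanstd(values[:, i]) < 1e-8:
            removed[n] = "near-zero-variance"
        else:
            keep_idx.append(i)
    # exact linear dependence (including duplicated layers): greedy rank
    # check in name order, earlier layers win
    kept: list[int] = []
    for i in keep_idx:
        trial = values[:, kept + [i]]
        if np.linalg.matrix_rank(trial - trial.mean(axis=0), tol=1e-8) <= len(kept):
            removed[names[i]] = "linear-dependence"
        else:
            kept.append(i)
    current = [names[i] for i in kept]
    vals = {n: values[:, names.index(n)] for n in current}
    while True:
        if len(current) < 2:
            break
        mat = np.column_stack([vals[n] for n in current])
        corr = np.abs(_corr_matrix(mat))
        np.fill_diagonal(corr, 0.0)
        partners = (corr >= corr_threshold).sum(axis=0)
        if partners.max() == 0:
            break
        mean_abs = corr.mean(axis=0)
        order = sorted(
            range(len(current)),
            key=lambda i: (-partners[i], -mean_abs[i], current[i]),
        )
        victim = current[order[0]]
        removed[victim] = "correlated"
        current.remove(victim)
    if not current:
        raise ValueError("all layers removed; degenerate stack")
    return VariableReport(retained=current, removed=removed)


# -------------------------------------------------------------- occurrences


def _env_pca(
    stack: GridStack, names: Sequence[str], background: OccurrenceTable
):
    """Standardizer + 2-component PCA fitted on background cells."""
    xy = background.xy
    bg = np.column_stack([stack.extract(n, xy[:, 0], xy[:, 1]) for n in names])
    mean = bg.mean(axis=0)
    sd = bg.std(axis=0)
    sd[sd == 0] = 1.0
    z = (bg - mean) / sd
    # principal axes of the background cloud via SVD (deterministic sign:
    # largest-magnitude loading positive)
    _u, _s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    comps = vt[:2]
    for k in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] = -comps[k]

    def transform(table: OccurrenceTable) -> np.ndarray:
        pts = table.xy
        v = np.column_stack([stack.extract(n, pts[:, 0], pts[:, 1]) for n in names])
        return ((v - mean) / sd) @ comps.T

    return transform


def filter_occurrences_envspace(
    points: OccurrenceTable,
    background: OccurrenceTable,
    stack: GridStack,
    names: Sequence[str],
    pc_cell: float = 1.0,
    seed: int = 0,
) -> OccurrenceTable:
    """Thin points to one per raster cell, then one per PC-space cell.

    The PC space is spanned by the first two principal components of the
    retained layers, fitted on background cells with standardization.
    Within each occupied ``pc_cell`` × ``pc_cell`` bin one point is kept
    uniformly at random (deterministic given ``seed``).
    """
    if len(names) < 2:
        raise ValueError("environmental filtering needs >= 2 retained layers")
    rng = np.random.default_rng(seed)
    df = points.table.copy()
    cells = [stack.cell_of(x, y) for x, y in df[["x", "y"]].to_numpy(dtype=float)]
    df["_cell"] = [f"{r}:{c}" for r, c in cells]
    df = df.groupby("_cell", sort=True).apply(
        lambda g: g.iloc[int(rng.integers(len(g)))], include_groups=False
    ).reset_index(drop=True)
    thinned = OccurrenceTable(df[["id", "x", "y"]], role=points.role)

    transform = _env_pca(stack, names, background)
    pcs = transform(thinned)
    bins = np.floor(pcs / pc_cell).astype(int)
    df2 = thinned.table.copy()
    df2["_bin"] = [f"{a}:{b}" for a, b in bins]
    df2 = df2.groupby("_bin", sort=True).apply(
        lambda g: g.iloc[int(rng.integers(len(g)))], include_groups=False
    ).reset_index(drop=True)
    if df2.empty:
        raise ValueError("environmental filtering removed all points")
    return OccurrenceTable(
        df2[["id", "x", "y"]].sort_values("id").reset_index(drop=True),
        role=points.role,
    )


# ------------------------------------------------------------ probe removal


def _training_table(
    presences: OccurrenceTable,
    background: OccurrenceTable,
    stack: GridStack,
    names: Sequence[str],
) -> tuple[pd.DataFrame, np.ndarray]:
    rows = []
    for table, label in ((presences, 1), (background, 0)):
        xy = table.xy
        vals = np.column_stack(
            [stack.extract(n, xy[:, 0], xy[:, 1]) for n in names]
        )
        df = pd.DataFrame(vals, columns=list(names))
        df["_y"] = label
        rows.append(df)
    data = pd.concat(rows, ignore_index=True)
    y = data.pop("_y").to_numpy()
    return data, y


def _cv_permutation_importance(
    make_model, X: np.ndarray, y: np.ndarray, rng, n_splits=4, n_repeats=3
):
    """Cross-validated permutation importance: mean held-out AUC drop.

    Fitting on in-fold data and permuting on the held-out fold keeps
    flexible learners from awarding importance to memorized noise (which
    would let random probes beat real variables in-sample).
    """
    order = rng.permutation(len(y))
    folds = np.array_split(order, n_splits)
    drops = np.zeros(X.shape[1])
    weight = 0
    for f in folds:
        train = np.setdiff1d(order, f)
        if len(np.unique(y[train])) < 2 or len(np.unique(y[f])) < 2:
            continue
        model = make_model()
        model.fit(X[train], y[train])
        base = roc_auc_score(y[f], model.predict_proba(X[f])[:, 1])
        for j in range(X.shape[1]):
            for _ in range(n_repeats):
                Xp = X[f].copy()
                Xp[:, j] = Xp[rng.permutation(len(f)), j]
                drops[j] += base - roc_auc_score(y[f], model.predict_proba(Xp)[:, 1])
        weight += n_repeats
    if weight == 0:
        raise ValueError("degenerate folds: a class is missing everywhere")
    return drops / weight


def probe_elimination(
    presences: OccurrenceTable,
    background: OccurrenceTable,
    stack: GridStack,
    names: Sequence[str],
    config: EnmConfig | None = None,
    learners: Sequence[str] = LEARNER_FAMILIES,
    seed: int | None = None,
) -> VariableReport:
    """Drop variables that lose to random probes in most algorithms.

    Per algorithm: append one uniform probe per true variable (capped at
    5), each spanning that variable's observed range; fit; compute
    permutation importances (mean AUC drop); discard the worst true
    variable whenever any true variable scores below the best probe;
    regenerate probes and repeat until every true variable beats every
    probe.  A variable is finally removed iff discarded by at least
    ``probe_consensus`` algorithms.  Deterministic given the seed.
    """
    config = config or EnmConfig()
    seed = config.seed if seed is None else seed
    X_df, y = _training_table(presences, background, stack, names)
    lo = X_df.min(axis=0)
    hi = X_df.max(axis=0)
    discarded_by: dict[str, list[str]] = {n: [] for n in names}
    per_algo_imp: dict[str, dict[str, float]] = {}
    probe_imp: dict[str, float] = {}
    algo_seeds = np.random.SeedSequence(seed).spawn(len(learners))
    for algo, sseq in zip(learners, algo_seeds):
        rng = np.random.default_rng(sseq)
        active = list(names)
        while active:
            k = min(len(active), 5)
            probes = {
                f"_probe{j + 1}": rng.uniform(
                    lo[active[j]], hi[active[j]], size=len(X_df)
                )
                for j in range(k)
            }
            X = np.column_stack(
                [X_df[c].to_numpy() for c in active]
                + [probes[p] for p in probes]
            )
            model_seed = int(rng.integers(2**31))
            imp = _cv_permutation_importance(
                lambda: make_learner(algo, model_seed), X, y, rng
            )
            true_imp = imp[: len(active)]
            max_probe = imp[len(active):].max()
            per_algo_imp.setdefault(algo, {}).update(
                {v: float(t) for v, t in zip(active, true_imp)}
            )
            probe_imp[algo] = float(max_probe)
            if true_imp.min() < max_probe:
                worst = active[int(np.argmin(true_imp))]
                active.remove(worst)
                discarded_by[worst].append(algo)
            else:
                break
    votes = {n: len(discarded_by[n]) for n in names}
    removed = {
        n: "probe-eliminated"
        for n in names
        if votes[n] >= config.probe_consensus
    }
    retained = [n for n in names if n not in removed]
    if not retained:
        raise ValueError("probe elimination removed every variable")
    return VariableReport(
        retained=retained,
        removed=removed,
        per_algorithm_importances=per_algo_imp,
        probe_importances=probe_imp,
        discarded_by={n: v for n, v in discarded_by.items() if v},
    )


# ---------------------------------------------------------------- ensemble


def _grid_features(stack: GridStack, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    mask = stack.mask
    feats = np.column_stack([stack.arrays[n][~mask] for n in names])
    return feats, mask


def fit_ensemble(
    presences: OccurrenceTable,
    background: OccurrenceTable,
    stack: GridStack,
    names: Sequence[str],
    n_reps: int = 100,
    seed: int = 0,
    learners: Sequence[str] = LEARNER_FAMILIES,
    test_fraction: float = 0.25,
) -> tuple[EnsembleResult, dict[str, list]]:
    """Fit each learner family ``n_reps`` times on bootstrap draws.

    Per learner the suitability grid is the mean predicted probability
    over repetitions; AUC and MAE are evaluated out-of-bootstrap (each
    repetition scores the rows its draw left out), so every point both
    trains and is held out across repetitions.  Returns the result plus
    the fitted models per learner (for period projection).  Degenerate
    single-class bootstrap draws are redrawn (class-stratified resampling
    makes them rare by design).
    """
    if len(presences) < 10:
        raise ValueError("need at least 10 presences")
    X_df, y = _training_table(presences, background, stack, names)
    X = X_df.to_numpy()
    rng = np.random.default_rng(seed)
    pres_idx = np.nonzero(y == 1)[0]
    bg_idx = np.nonzero(y == 0)[0]

    feats, mask = _grid_features(stack, names)
    grids: dict[str, np.ndarray] = {}
    aucs: dict[str, float] = {}
    maes: dict[str, float] = {}
    fitted: dict[str, list] = {}
    for algo in learners:
        models = []
        grid_sum = np.zeros(feats.shape[0])
        oob_sum = np.zeros(len(y))
        oob_n = np.zeros(len(y))
        for _rep in range(n_reps):
            for _attempt in range(10):
                bp = pres_idx[rng.integers(0, len(pres_idx), len(pres_idx))]
                bb = bg_idx[rng.integers(0, len(bg_idx), len(bg_idx))]
                rows = np.concatenate([bp, bb])
                if len(np.unique(y[rows])) == 2:
                    break
            model = make_learner(algo, int(rng.integers(2**31)))
            model.fit(X[rows], y[rows])
            models.append(model)
            grid_sum += model.predict_proba(feats)[:, 1]
            oob = np.setdiff1d(np.arange(len(y)), rows)
            if len(oob):
                oob_sum[oob] += model.predict_proba(X[oob])[:, 1]
                oob_n[oob] += 1
        mean_grid = grid_sum / n_reps
        arr = np.full(mask.shape, np.nan)
        arr[~mask] = mean_grid
        grids[algo] = arr
        scored = oob_n > 0
        if scored.sum() >= 2 and len(np.unique(y[scored])) == 2:
            pred = oob_sum[scored] / oob_n[scored]
            aucs[algo] = float(roc_auc_score(y[scored], pred))
            maes[algo] = float(mean_absolute_error(y[scored], pred))
        else:  # n_reps == 1 can leave too few out-of-bag rows
            pred = grid_sum[:0]
            full = models[0].predict_proba(X)[:, 1]
            aucs[algo] = float(roc_auc_score(y, full))
            maes[algo] = float(mean_absolute_error(y, full))
        fitted[algo] = models
    consensus = consensus_pc1(list(grids.values()), mask=mask)
    result = EnsembleResult(
        learner_grids=grids, consensus=consensus, auc=aucs, mae=maes
    )
    return result, fitted


def consensus_pc1(
    grids: Sequence[np.ndarray],
    mask: np.ndarray | None = None,
    rescale: tuple[float, float] = (0.0, 100.0),
) -> np.ndarray:
    """First-principal-component consensus of suitability maps.

    Pixels are observations, models variables; columns are centered (the
    maps already share the [0, 1] scale), PC1 is sign-fixed to correlate
    positively with the across-model mean, then min–max rescaled.  The
    output attains both ends of ``rescale`` on unmasked cells.
    """
    if len(grids) < 2:
        raise ValueError("need at least two model grids")
    if mask is None:
        mask = ~np.isfinite(grids[0])
    cols = np.column_stack([g[~mask] for g in grids])
    centered = cols - cols.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("all model grids are constant; consensus undefined")
    _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = centered @ vt[0]
    mean_map = cols.mean(axis=1)
    c = np.corrcoef(scores, mean_map)[0, 1]
    if np.isfinite(c) and c < 0:
        scores = -scores
    lo, hi = rescale
    smin, smax = scores.min(), scores.max()
    if smax == smin:
        raise ValueError("degenerate PC1; consensus undefined")
    scaled = lo + (scores - smin) / (smax - smin) * (hi - lo)
    out = np.full(mask.shape, np.nan)
    out[~mask] = scaled
    return out


def area_above(consensus: np.ndarray, threshold: float = 30.0) -> int:
    """Pixel count with consensus suitability strictly above threshold."""
    return int(np.nansum(consensus > threshold))


def project_periods(
    fitted: dict[str, list],
    period_stacks: dict[str, GridStack],
    names: Sequence[str],
    config: EnmConfig | None = None,
    present: str = "present",
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Project the fitted ensemble onto each period's layer stack.

    Per period: per-learner mean prediction → PC1 consensus → pixel count
    above the area threshold.  The trend table holds each retained
    variable's mean (over unmasked cells) and the area count, divided by
    the present-period row so present = 1.
    """
    config = config or EnmConfig()
    if present not in period_stacks:
        raise ValueError(f"period stacks must include {present!r}")
    consensus_by_period: dict[str, np.ndarray] = {}
    rows = {}
    for period, stack in period_stacks.items():
        missing = [n for n in names if n not in stack]
        if missing:
            raise ValueError(
                f"period {period!r} is missing variables: {missing}"
            )
        feats, mask = _grid_features(stack, names)
        grids = []
        for algo, models in fitted.items():
            s = np.zeros(feats.shape[0])
            for model in models:
                s += model.predict_proba(feats)[:, 1]
            arr = np.full(mask.shape, np.nan)
            arr[~mask] = s / len(models)
            grids.append(arr)
        cons = consensus_pc1(grids, mask=mask, rescale=config.consensus_rescale)
        consensus_by_period[period] = cons
        row = {n: float(np.mean(stack.arrays[n][~mask])) for n in names}
        row["area"] = area_above(cons, config.area_threshold)
        rows[period] = row
    values = pd.DataFrame(rows).T
    ref = values.loc[present]
    trend = values.divide(ref.replace(0, np.nan), axis=1)
    # a zero reference leaves the ratio undefined except where the value
    # equals the reference (0/0 -> 1 by continuity; makes present == 1)
    for col in values.columns:
        if ref[col] == 0:
            same = values[col] == ref[col]
            trend.loc[same, col] = 1.0
    return consensus_by_period, trend
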