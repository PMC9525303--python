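import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from phylogeo.enm import (
    EnmConfig,
    LEARNER_FAMILIES,
    area_above,
    consensus_pc1,
    filter_occurrences_envspace,
    fit_ensemble,
    make_learner,
    probe_elimination,
    project_periods,
    prune_variables,
)
from phylogeo.io import GridStack, OccurrenceTable
from phylogeo.simulate import shifted_period_stack, sim_env_occurrences


def grid_from(vals_by_name, **kw):
    return GridStack({k: np.asarray(v, dtype=float) for k, v in vals_by_name.items()}, **kw)


class TestPruneVariables:
    def test_duplicate_layer_removed_deterministically(self):
        rng = np.random.default_rng(0)
        v1 = rng.standard_normal((20, 20))
        v3 = rng.standard_normal((20, 20))
        g = grid_from({"v1": v1, "v2": v1.copy(), "v3": v3})
        rep = prune_variables(g, corr_threshold=0.7, exclude=())
        assert rep.retained == ["v1", "v3"]
        assert rep.removed["v2"] in {"linear-dependence", "correlated"}
        # rerun is identical
        rep2 = prune_variables(g, corr_threshold=0.7, exclude=())
        assert rep2.retained == rep.retained

    def test_constant_layer_removed_as_near_zero_variance(self):
        rng = np.random.default_rng(1)
        g = grid_from({
            "flat": np.full((20, 20), 3.0),
            "a": rng.standard_normal((20, 20)),
            "b": rng.standard_normal((20, 20)),
        })
        rep = prune_variables(g, exclude=())
        assert rep.removed["flat"] == "near-zero-variance"

    def test_retained_set_satisfies_pairwise_threshold(self):
        # 5 layers with built-in correlation structure; verify post hoc
        rng = np.random.default_rng(2)
        base = rng.standard_normal((30, 30))
        layers = {
            "a": base + 0.1 * rng.standard_normal((30, 30)),
            "b": base + 0.2 * rng.standard_normal((30, 30)),
            "c": rng.standard_normal((30, 30)),
            "d": 0.5 * base + rng.standard_normal((30, 30)),
            "e": rng.standard_normal((30, 30)),
        }
        g = grid_from(layers)
        rho = 0.7
        rep = prune_variables(g, corr_threshold=rho, exclude=())
        vals = np.column_stack([g.arrays[n][~g.mask] for n in rep.retained])
        corr = np.abs(np.corrcoef(vals, rowvar=False))
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < rho
        for name in layers:
            assert (name in rep.retained) != (name in rep.removed)

    def test_all_removed_is_an_error(self):
        g = grid_from({
            "a": np.full((20, 20), 1.0),
            "b": np.full((20, 20), 2.0),
        })
        with pytest.raises(ValueError):
            prune_variables(g, exclude=())


class TestEnvFilter:
    def test_same_raster_cell_collapses_to_one(self):
        rng = np.random.default_rng(3)
        g = grid_from({
            "a": rng.standard_normal((10, 10)),
            "b": rng.standard_normal((10, 10)),
        })
        bg = OccurrenceTable(pd.DataFrame({
            "id": [f"b{i}" for i in range(50)],
            "x": rng.uniform(0, 10, 50), "y": rng.uniform(0, 10, 50),
        }), role="background")
        pts = OccurrenceTable(pd.DataFrame({
            "id": ["p1", "p2"], "x": [2.2, 2.4], "y": [3.3, 3.4],
        }))
        out = filter_occurrences_envspace(pts, bg, g, ["a", "b"], seed=0)
        assert len(out) == 1

    def test_idempotent_and_never_grows(self, env_bundle_small):
        b = env_bundle_small
        names = [n for n in b.env.names if n != "elev"][:3]
        f1 = filter_occurrences_envspace(
            b.presences, b.background, b.env, names, seed=5
        )
        assert len(f1) <= len(b.presences)
        f2 = filter_occurrences_envspace(f1, b.background, b.env, names, seed=5)
        assert sorted(f2.table["id"]) == sorted(f1.table["id"])

    def test_no_two_retained_points_share_a_pc_cell(self, env_bundle_small):
        b = env_bundle_small
        names = [n for n in b.env.names if n != "elev"][:3]
        out = filter_occurrences_envspace(
            b.presences, b.background, b.env, names, pc_cell=1.0, seed=6
        )
        from phylogeo.enm import _env_pca

        transform = _env_pca(b.env, names, b.background)
        pcs = transform(out)
        bins = {tuple(v) for v in np.floor(pcs / 1.0).astype(int)}
        assert len(bins) == len(out)


def probe_fixture(seed):
    """Presence depends only on the single informative layer; one pure
    noise layer (no shared latent)."""
    return sim_env_occurrences(
        seed=seed, nx=50, ny=40, n_informative=1, n_noise=1, n_redundant=0,
        family_weight=0.0, n_presence=150, beta_scale=4.0,
    )


class TestProbeElimination:
    def test_noise_removed_informative_kept_across_seeds(self):
        kept_ok = 0
        removed_ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            b = probe_fixture(100 + seed)
            rep = probe_elimination(
                b.presences, b.background, b.env, ["BIO09", "RND01"],
                seed=seed,
            )
            if "BIO09" in rep.retained:
                kept_ok += 1
            if "RND01" in rep.removed:
                removed_ok += 1
        assert kept_ok == n_seeds
        assert removed_ok == n_seeds

    def test_consensus_threshold_is_enforced(self):
        # with only two algorithms voting, a 3-of-5 consensus can never be
        # reached, so nothing is finally removed
        b = probe_fixture(7)
        rep = probe_elimination(
            b.presences, b.background, b.env, ["BIO09", "RND01"],
            learners=["cta", "bart"], seed=1,
        )
        assert rep.retained == ["BIO09", "RND01"]
        assert rep.removed == {}

    def test_all_variables_eliminated_is_an_error(self):
        # zero informative variables: labels are independent of every layer
        rng = np.random.default_rng(80)
        g = grid_from({
            "x1": rng.standard_normal((30, 30)),
            "x2": rng.standard_normal((30, 30)),
        })
        pres = OccurrenceTable(pd.DataFrame({
            "id": [f"p{i}" for i in range(60)],
            "x": rng.uniform(0, 30, 60), "y": rng.uniform(0, 30, 60),
        }))
        bg = OccurrenceTable(pd.DataFrame({
            "id": [f"b{i}" for i in range(120)],
            "x": rng.uniform(0, 30, 120), "y": rng.uniform(0, 30, 120),
        }), role="background")
        with pytest.raises(ValueError, match="every variable"):
            probe_elimination(pres, bg, g, ["x1", "x2"], seed=0)

    def test_deterministic_given_seed(self):
        b = probe_fixture(9)
        r1 = probe_elimination(
            b.presences, b.background, b.env, ["BIO09", "RND01"], seed=4
        )
        r2 = probe_elimination(
            b.presences, b.background, b.env, ["BIO09", "RND01"], seed=4
        )
        assert r1.retained == r2.retained
        assert r1.per_algorithm_importances == r2.per_algorithm_importances


class TestEnsemble:
    def test_bit_reproducible_with_fixed_seed(self):
        b = probe_fixture(10)
        kw = dict(names=["BIO09", "RND01"], n_reps=1, seed=12)
        r1, _ = fit_ensemble(b.presences, b.background, b.env, **kw)
        r2, _ = fit_ensemble(b.presences, b.background, b.env, **kw)
        for algo in r1.learner_grids:
            ok = ~b.env.mask
            np.testing.assert_array_equal(
                r1.learner_grids[algo][ok], r2.learner_grids[algo][ok]
            )

    def test_grids_positively_correlated_with_truth(self):
        b = probe_fixture(11)
        res, _ = fit_ensemble(
            b.presences, b.background, b.env, ["BIO09", "RND01"],
            n_reps=5, seed=13,
        )
        ok = ~b.env.mask
        for algo, g in res.learner_grids.items():
            rho = spearmanr(b.truth_suitability[ok], g[ok]).statistic
            assert rho > 0, algo

    def test_separable_data_reaches_auc_one(self):
        # presence and background occupy disjoint halves of a gradient
        grad = np.tile(np.linspace(-3, 3, 40), (30, 1))
        rng = np.random.default_rng(14)
        g = grid_from({"grad": grad, "noise": rng.standard_normal((30, 40))})
        xs_p = rng.uniform(30, 40, 40)  # high-gradient cells
        xs_b = rng.uniform(0, 10, 80)  # low-gradient cells
        pres = OccurrenceTable(pd.DataFrame({
            "id": [f"p{i}" for i in range(40)],
            "x": xs_p, "y": rng.uniform(0, 30, 40),
        }))
        bg = OccurrenceTable(pd.DataFrame({
            "id": [f"b{i}" for i in range(80)],
            "x": xs_b, "y": rng.uniform(0, 30, 80),
        }), role="background")
        res, _ = fit_ensemble(pres, bg, g, ["grad", "noise"], n_reps=5, seed=15)
        for algo, auc in res.auc.items():
            assert auc > 0.97, algo


class TestConsensus:
    def test_identical_models_give_rescaled_map(self):
        rng = np.random.default_rng(16)
        m = rng.uniform(0, 1, (20, 20))
        cons = consensus_pc1([m, m.copy(), m.copy()], mask=np.zeros_like(m, bool))
        expected = (m - m.min()) / (m.max() - m.min()) * 100
        np.testing.assert_allclose(cons, expected, atol=1e-8)

    def test_spans_exactly_zero_to_hundred(self):
        rng = np.random.default_rng(17)
        grids = [rng.uniform(0, 1, (15, 15)) for _ in range(4)]
        cons = consensus_pc1(grids, mask=np.zeros((15, 15), bool))
        assert cons.min() == pytest.approx(0.0)
        assert cons.max() == pytest.approx(100.0)

    def test_model_order_invariance(self):
        rng = np.random.default_rng(18)
        grids = [rng.uniform(0, 1, (12, 12)) for _ in range(5)]
        c1 = consensus_pc1(grids, mask=np.zeros((12, 12), bool))
        c2 = consensus_pc1(grids[::-1], mask=np.zeros((12, 12), bool))
        np.testing.assert_allclose(c1, c2, atol=1e-8)

    def test_truth_plus_noise_beats_median_model(self):
        rng = np.random.default_rng(19)
        truth = rng.uniform(0, 1, (25, 25))
        models = [
            np.clip(truth + 0.35 * rng.standard_normal(truth.shape), 0, 1)
            for _ in range(5)
        ]
        mask = np.zeros_like(truth, bool)
        cons = consensus_pc1(models, mask=mask)
        rho_c = spearmanr(truth.ravel(), cons.ravel()).statistic
        rho_models = sorted(
            spearmanr(truth.ravel(), m.ravel()).statistic for m in models
        )
        assert rho_c >= rho_models[len(rho_models) // 2] - 1e-9

    def test_constant_models_are_an_error(self):
        flat = np.full((10, 10), 0.5)
        with pytest.raises(ValueError):
            consensus_pc1([flat, flat], mask=np.zeros((10, 10), bool))


class TestAreaAndTrends:
    def test_area_statistic_on_hundred_pixel_example(self):
        cons = np.full((10, 10), 10.0)
        cons.ravel()[:5] = 40.0
        assert area_above(cons, 30.0) == 5

    def test_identical_period_gives_unit_trend_row(self):
        b = probe_fixture(20)
        names = ["BIO09", "RND01"]
        res, fitted = fit_ensemble(
            b.presences, b.background, b.env, names, n_reps=2, seed=21
        )
        periods = {"present": b.env, "same": b.env}
        cons, trend = project_periods(fitted, periods, names)
        assert np.allclose(trend.loc["present"].to_numpy(), 1.0)
        assert np.allclose(trend.loc["same"].to_numpy(), 1.0)

    def test_missing_variable_in_period_stack_named(self):
        b = probe_fixture(22)
        names = ["BIO09", "RND01"]
        _res, fitted = fit_ensemble(
            b.presences, b.background, b.env, names, n_reps=1, seed=23
        )
        partial = GridStack(
            {"BIO09": b.env.arrays["BIO09"]},
            mask=b.env.mask, cell_size=b.env.cell_size, origin=b.env.origin,
        )
        with pytest.raises(ValueError, match="RND01"):
            project_periods(fitted, {"present": b.env, "lgm": partial}, names)

    def test_favourable_shift_grows_area_like_the_truth(self):
        # single informative layer with positive effect: shifting it up
        # enlarges the truly suitable area; the modeled area trend should
        # track the truth-area ratio
        b = probe_fixture(24)
        names = ["BIO09", "RND01"]
        res, fitted = fit_ensemble(
            b.presences, b.background, b.env, names, n_reps=5, seed=25
        )
        shift = 1.0
        cold = shifted_period_stack(b.env, ["BIO09"], shift)
        _cons, trend = project_periods(
            fitted, {"present": b.env, "shifted": cold}, names
        )
        truth_now = (b.truth_suitability > 0.5)[~b.env.mask].sum()
        lin = 4.0 * (b.env.arrays["BIO09"] + shift)
        truth_shifted = (1 / (1 + np.exp(-lin)) > 0.5)[~b.env.mask].sum()
        truth_ratio = truth_shifted / truth_now
        assert trend.loc["shifted", "area"] > 1.0
        assert trend.loc["shifted", "area"] == pytest.approx(
            truth_ratio, rel=0.5
        )


class TestEndToEnd:
    def test_consensus_tracks_truth_on_default_bundle(self):
        """Regression pin: the full workflow (screen → probe elimination →
        environmental thinning → bootstrap ensemble → PC1 consensus) on the
        default synthetic bundle recovers the planted suitability surface
        (Spearman ρ > 0.5 at the pinned seed; first validated run: 0.65)."""
        seed = 11
        b = sim_env_occurrences(seed=seed)
        screen = prune_variables(b.env, b.background)
        rng = np.random.default_rng(seed + 1)
        rows = sorted(rng.choice(len(b.background), size=1200, replace=False))
        bg_sample = OccurrenceTable(
            b.background.table.iloc[rows].reset_index(drop=True),
            role="background",
        )
        probe = probe_elimination(
            b.presences, bg_sample, b.env, screen.retained, seed=seed + 300
        )
        pres = filter_occurrences_envspace(
            b.presences, b.background, b.env, probe.retained, seed=seed + 100
        )
        bg = filter_occurrences_envspace(
            b.background, b.background, b.env, probe.retained, seed=seed + 200
        )
        res, _fitted = fit_ensemble(
            pres, bg, b.env, probe.retained, n_reps=10, seed=seed + 400
        )
        ok = ~b.env.mask
        rho = spearmanr(b.truth_suitability[ok], res.consensus[ok]).statistic
        assert rho > 0.5
        assert rho == pytest.approx(0.653, abs=0.05)


class TestLearnerRegistry:
    def test_all_families_expose_predict_proba(self):
        X = np.random.default_rng(26).standard_normal((40, 3))
        y = (X[:, 0] > 0).astype(int)
        for name in LEARNER_FAMILIES:
            model = make_learner(name, seed=0)
            model.fit(X, y)
            p = model.predict_proba(X)
            assert p.shape == (40, 2)
            assert np.all((p >= 0) & (p <= 1))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            make_learner("xgb", seed=0)
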