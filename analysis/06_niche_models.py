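#!/usr/bin/env python
"""Ensemble niche modeling with probe elimination and paleo projection.

Reads the environmental bundle under results/data/ (layer stack,
presences, background, recorded truth); runs variable screening, probe
elimination, environmental thinning, the five-learner bootstrap ensemble
and the PC1 consensus; projects a favourable ("cold") and an
unfavourable ("warm") period; writes grids, the variable report and the
area-trend table under results/.
"""

import json
import sys

import numpy as np
from scipy.stats import spearmanr

from phylogeo.enm import (
    area_above,
    filter_occurrences_envspace,
    fit_ensemble,
    probe_elimination,
    project_periods,
    prune_variables,
)
from phylogeo.io import (
    GridStack,
    OccurrenceTable,
    load_grid_stack,
    load_occurrences,
    save_grid,
)
from phylogeo.simulate import shifted_period_stack

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    env = load_grid_stack("results/data/env")
    presences = load_occurrences("results/data/presences.csv", "presence")
    background = load_occurrences("results/data/background.csv", "background")
    truth = json.load(open("results/data/truth.json"))
    informative = truth["informative_layers"]
    beta = truth["beta"]

    screen = prune_variables(env, background)
    rng = np.random.default_rng(SEED)
    rows = sorted(rng.choice(len(background), size=min(1200, len(background)),
                             replace=False))
    bg_sample = OccurrenceTable(
        background.table.iloc[rows].reset_index(drop=True), role="background"
    )
    probe = probe_elimination(
        presences, bg_sample, env, screen.retained, seed=SEED + 2
    )
    pres_f = filter_occurrences_envspace(
        presences, background, env, probe.retained, seed=SEED
    )
    bg_f = filter_occurrences_envspace(
        background, background, env, probe.retained, seed=SEED + 1
    )
    res, fitted = fit_ensemble(
        pres_f, bg_f, env, probe.retained, n_reps=10, seed=SEED + 3
    )

    deltas = {n: float(np.sign(b)) or 1.0 for n, b in zip(informative, beta)}
    periods = {
        "present": env,
        "cold": shifted_period_stack(env, {k: v for k, v in deltas.items()}),
        "warm": shifted_period_stack(env, {k: -v for k, v in deltas.items()}),
    }
    consensus, trend = project_periods(fitted, periods, probe.retained)
    for period, cons in consensus.items():
        g = GridStack({"consensus": cons}, mask=~np.isfinite(cons),
                      cell_size=env.cell_size, origin=env.origin)
        save_grid("consensus", f"results/consensus_{period}.asc", stack=g)
    trend.to_csv("results/area_trend.csv")
    with open("results/variable_report.json", "w") as fh:
        json.dump({"screen_removed": screen.removed,
                   "probe_removed": probe.removed,
                   "retained": probe.retained,
                   "auc": res.auc, "mae": res.mae}, fh, indent=1)

    print(f"screened {len(screen.removed)} of {len(env.names) - 1} layers; "
          f"probe elimination kept {probe.retained}; "
          f"{len(pres_f)}/{len(presences)} presences after thinning")
    print(f"OOB AUC: " + ", ".join(f"{k}={v:.2f}" for k, v in res.auc.items()))
    print(f"area(consensus>30): present {area_above(consensus['present'])} px, "
          f"cold x{trend.loc['cold', 'area']:.2f}, "
          f"warm x{trend.loc['warm', 'area']:.2f} (present = 1)")


if __name__ == "__main__":
    main()
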