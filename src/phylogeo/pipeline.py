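"""End-to-end orchestration: simulate → haplonet/popclust → bbm → chronos,
with the niche-modeling branch running independently; every stage writes
its outputs under one directory and a manifest records seeds, checksums
and versions so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestral import (
    BbmConfig,
    area_marginals_exact,
    bbm_sample,
    classify_events,
    render_range,
)
from .chronos import Calibration, apply_calibrations, relative_times
from .enm import (
    EnmConfig,
    filter_occurrences_envspace,
    fit_ensemble,
    probe_elimination,
    project_periods,
    prune_variables,
)
from .haplonet import (
    build_network,
    code_indels,
    collapse_haplotypes,
    connection_limit,
    write_network_graphml,
)
from .io import load_alignment, load_occurrences, load_tree, save_grid
from .popclust import locus_matrix, search_partition
from .simulate import (
    save_bundle,
    shifted_period_stack,
    sim_env_occurrences,
    sim_phylogeography,
)

__all__ = ["default_config", "derive_seed", "run_pipeline", "report"]

STAGE_ORDER = ["simulate", "haplonet", "popclust", "bbm", "chronos", "enm"]


def default_config(seed: int = 0, outdir: str = "results/pipeline") -> dict:
    """The default desk-scale synthetic run (all stages on)."""
    return {
        "seed": seed,
        "outdir": outdir,
        "stages": {name: True for name in STAGE_ORDER},
        "simulate": {
            "n_tips": 24,
            "n_regions": 4,
            "seq_len": 600,
            # shallow intraspecific divergence: a few dozen variable sites
            "sub_rate": 0.002,
            "indel_rate": 0.3,
            "dispersal_rate": 0.15,
            "env": {},  # sim_env_occurrences defaults
        },
        "haplonet": {"alpha": 0.95, "limit": "auto"},
        "popclust": {"k_max": 10, "levels": 2, "n_runs": 3},
        "bbm": {
            "mode": "exact",
            "max_areas": 4,
            "generations": 100_000,
            "sample_every": 100,
        },
        "chronos": {
            "calibrations": [
                {"tips": "root", "mean": 1.0, "ci95": [0.8, 1.2]},
            ]
        },
        "enm": {
            "n_reps": 10,
            # favourable ("cold", a glacial expansion for a cold-adapted
            # montane plant) and unfavourable ("warm") periods, in sd units
            # along each informative layer's effect direction
            "periods": {"cold": 1.0, "warm": -1.0},
        },
    }


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: stable SHA-256 hash of (global seed, stage name)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(manifest: dict, stage: str, outputs: list[Path]) -> None:
    manifest["stages"][stage] = {
        "status": "ok",
        "outputs": {
            str(p.name): _checksum(p) for p in outputs if p.exists()
        },
    }


def run_pipeline(config: dict | str | Path, log=print) -> dict:
    """Execute the requested stages in dependency order; return manifest.

    A stage failure is recorded and halts only stages that depend on it
    (sequence stages depend on ``simulate``; ``enm`` is independent of
    the sequence branch but shares the simulated bundle).
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "results/pipeline"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {s: True for s in STAGE_ORDER})

    # pre-flight checks
    if not stages.get("simulate", False):
        inputs = config.get("inputs", {})
        if stages.get("chronos") and "tree" not in inputs:
            raise ValueError("chronos enabled but no tree input and no simulate stage")
        if stages.get("haplonet") and "alignment" not in inputs:
            raise ValueError("haplonet enabled but no alignment input")
    if stages.get("chronos") and not config.get("chronos", {}).get("calibrations"):
        raise ValueError("chronos enabled but no calibrations configured")

    manifest: dict = {
        "seed": seed,
        "version": __version__,
        "python": sys.version.split()[0],
        "outdir": str(outdir),
        "stages": {},
    }

    bundle = None
    env_bundle = None
    failed: set[str] = set()

    if stages.get("simulate"):
        sim_cfg = dict(config.get("simulate", {}))
        env_cfg = sim_cfg.pop("env", {})
        s_seed = derive_seed(seed, "simulate")
        bundle = sim_phylogeography(seed=s_seed, **sim_cfg)
        env_bundle = sim_env_occurrences(seed=derive_seed(seed, "simulate-env"), **env_cfg)
        bdir = outdir / "bundle"
        save_bundle(bundle, bdir)
        save_bundle(env_bundle, bdir)
        outputs = sorted(bdir.rglob("*"))
        _record(manifest, "simulate", [p for p in outputs if p.is_file()])
        log(f"[simulate] {len(bundle.alignment)} sequences, "
            f"{env_bundle.env.shape} env grid, seed {s_seed}")

    aln = bundle.alignment if bundle else None
    tree = bundle.true_tree if bundle else None
    tip_areas = bundle.true_tip_areas if bundle else None
    inputs = config.get("inputs", {})
    if aln is None and "alignment" in inputs:
        aln = load_alignment(inputs["alignment"])
    if tree is None and "tree" in inputs:
        tree = load_tree(inputs["tree"])
    if tip_areas is None and "areas" in inputs:
        df = pd.read_csv(inputs["areas"])
        tip_areas = {
            row["tip"]: frozenset(str(row["areas"]).split(";"))
            for _, row in df.iterrows()
        }

    table = None
    if stages.get("haplonet"):
        if aln is None:
            failed.add("haplonet")
            manifest["stages"]["haplonet"] = {"status": "skipped: no alignment"}
        else:
            cfg = config.get("haplonet", {})
            matrix = code_indels(aln)
            table = collapse_haplotypes(aln, matrix)
            lim_cfg = cfg.get("limit", "auto")
            limit = connection_limit(
                aln.length, float(cfg.get("alpha", 0.95)),
                None if lim_cfg == "auto" else int(lim_cfg),
            )
            net = build_network(table, limit)
            write_network_graphml(net, outdir / "network.graphml")
            pd.DataFrame(
                [
                    {"haplotype": lab, "frequency": table.frequencies[lab],
                     "members": ";".join(m[0] for m in table.membership[lab])}
                    for lab in table.labels
                ]
            ).to_csv(outdir / "haplotypes.csv", index=False)
            rows = []
            for lab in table.labels:
                for sid, pop, region in table.membership[lab]:
                    rows.append({"id": sid, "haplotype": lab,
                                 "population": pop, "region": region})
            pd.DataFrame(rows).to_csv(
                outdir / "membership.tsv", sep="\t", index=False
            )
            _record(manifest, "haplonet", [
                outdir / "network.graphml", outdir / "haplotypes.csv",
                outdir / "membership.tsv",
            ])
            manifest["stages"]["haplonet"].update(
                n_haplotypes=len(table), limit=limit,
                n_components=nx.number_connected_components(net),
            )
            log(f"[haplonet] {len(table)} haplotypes, limit {limit}")

    if stages.get("popclust"):
        if aln is None:
            failed.add("popclust")
            manifest["stages"]["popclust"] = {"status": "skipped: no alignment"}
        else:
            cfg = config.get("popclust", {})
            mat, ids = locus_matrix(aln)
            part = search_partition(
                mat, ids=ids,
                k_max=int(cfg.get("k_max", 34)),
                levels=int(cfg.get("levels", 2)),
                n_runs=int(cfg.get("n_runs", 3)),
                seed=derive_seed(seed, "popclust"),
            )
            pd.DataFrame(
                {"id": part.ids,
                 "level1": [part.level1[i] for i in part.ids],
                 "level2": [part.level2[i] for i in part.ids]}
            ).to_csv(outdir / "clusters.csv", index=False)
            (outdir / "clusters_report.json").write_text(
                json.dumps(
                    {"k": part.k, "log_marginal": part.log_marginal,
                     "run_scores": part.run_scores, "seed": part.seed,
                     "best_level": part.best_level},
                    indent=1, sort_keys=True,
                )
            )
            _record(manifest, "popclust", [
                outdir / "clusters.csv", outdir / "clusters_report.json",
            ])
            manifest["stages"]["popclust"].update(k=part.k)
            log(f"[popclust] K per level: {part.k}")

    if stages.get("bbm"):
        if tree is None or tip_areas is None:
            failed.add("bbm")
            manifest["stages"]["bbm"] = {"status": "skipped: no tree/areas"}
        else:
            cfg = config.get("bbm", {})
            max_areas = int(cfg.get("max_areas", 4))
            if cfg.get("mode", "exact") == "mcmc":
                bc = BbmConfig(
                    generations=int(cfg.get("generations", 1_000_000)),
                    sample_every=int(cfg.get("sample_every", 1000)),
                    max_areas=max_areas,
                )
                post = bbm_sample(
                    tree, tip_areas, config=bc, seed=derive_seed(seed, "bbm")
                )
            else:
                post = area_marginals_exact(tree, tip_areas, max_areas=max_areas)
            rows = []
            for key, probs in sorted(post.node_probs.items()):
                for rng_set, p in sorted(
                    probs.items(), key=lambda kv: -kv[1]
                ):
                    if p < 1e-4:
                        continue
                    rows.append(
                        {"node": key,
                         "range": render_range(rng_set, post.areas),
                         "probability": p}
                    )
            pd.DataFrame(rows).to_csv(outdir / "bbm_posterior.csv", index=False)
            events = classify_events(tree, post.modal, tip_areas, post.areas)
            (outdir / "bbm_events.json").write_text(
                json.dumps(events, indent=1, sort_keys=True)
            )
            _record(manifest, "bbm", [
                outdir / "bbm_posterior.csv", outdir / "bbm_events.json",
            ])
            manifest["stages"]["bbm"].update(rate=post.rate)
            log(f"[bbm] rate {post.rate:.4g}, "
                f"{len(post.modal)} internal nodes reconstructed")

    if stages.get("chronos"):
        if tree is None:
            failed.add("chronos")
            manifest["stages"]["chronos"] = {"status": "skipped: no tree"}
        else:
            cfg = config.get("chronos", {})
            rel = relative_times(tree)
            cals = []
            all_tips = frozenset(tree.taxa)
            for c in cfg.get("calibrations", []):
                tips = (
                    all_tips if c["tips"] == "root"
                    else frozenset(str(c["tips"]).split(";"))
                )
                cals.append(
                    Calibration(tips=tips, mean=float(c["mean"]),
                                ci95=tuple(map(float, c["ci95"])))
                )
            chrono = apply_calibrations(tree, rel, cals)
            chrono.table().to_csv(outdir / "node_ages.csv", index=False)
            (outdir / "dated_tree.nwk").write_text(chrono.dated_newick() + "\n")
            _record(manifest, "chronos", [
                outdir / "node_ages.csv", outdir / "dated_tree.nwk",
            ])
            manifest["stages"]["chronos"].update(
                scale=chrono.scale, scale_sd=chrono.scale_sd
            )
            log(f"[chronos] scale {chrono.scale:.4g} ± {chrono.scale_sd:.4g} Ma")

    if stages.get("enm"):
        if env_bundle is None and "env" not in inputs:
            failed.add("enm")
            manifest["stages"]["enm"] = {"status": "skipped: no environment"}
        else:
            cfg = config.get("enm", {})
            e_seed = derive_seed(seed, "enm")
            if env_bundle is not None:
                env = env_bundle.env
                presences = env_bundle.presences
                background = env_bundle.background
            else:
                from .io import load_grid_stack

                env = load_grid_stack(inputs["env"])
                presences = load_occurrences(inputs["presences"], "presence")
                background = load_occurrences(inputs["background"], "background")
            econf = EnmConfig(
                n_reps=int(cfg.get("n_reps", 100)), seed=e_seed
            )
            screen = prune_variables(
                env, background, corr_threshold=econf.corr_threshold
            )
            # variable selection runs on the cell-level points; the
            # PC-space maps used for occurrence thinning are computed from
            # the previously selected variables
            from .io import OccurrenceTable

            rng = np.random.default_rng(e_seed)
            n_bg = min(int(cfg.get("bg_sample", 1200)), len(background))
            bg_rows = sorted(rng.choice(len(background), size=n_bg, replace=False))
            bg_sample = OccurrenceTable(
                background.table.iloc[bg_rows].reset_index(drop=True),
                role="background",
            )
            probe = probe_elimination(
                presences, bg_sample, env, screen.retained,
                config=econf, seed=e_seed + 2,
            )
            final_vars = probe.retained
            pres_f = filter_occurrences_envspace(
                presences, background, env, final_vars,
                pc_cell=econf.pc_cell, seed=e_seed,
            )
            bg_f = filter_occurrences_envspace(
                background, background, env, final_vars,
                pc_cell=econf.pc_cell, seed=e_seed + 1,
            )
            result, fitted = fit_ensemble(
                pres_f, bg_f, env, final_vars,
                n_reps=econf.n_reps, seed=e_seed + 3,
            )
            periods = {"present": env}
            # period shifts move each informative layer along its effect
            # direction: positive = more favourable (a glacial expansion
            # for a cold-adapted montane species), negative = less
            if env_bundle is not None:
                signs = {
                    name: float(np.sign(beta_i)) or 1.0
                    for name, beta_i in zip(
                        env_bundle.informative_layers, env_bundle.beta
                    )
                }
            else:
                signs = {name: 1.0 for name in final_vars}
            for name, shift in cfg.get("periods", {}).items():
                deltas = {k: float(shift) * s for k, s in signs.items()}
                periods[name] = shifted_period_stack(env, deltas)
            consensus_by_period, trend = project_periods(
                fitted, periods, final_vars, config=econf
            )
            from .io import GridStack

            for period, cons in consensus_by_period.items():
                g = GridStack({"consensus": np.nan_to_num(cons, nan=np.nan)},
                              mask=~np.isfinite(cons),
                              cell_size=env.cell_size, origin=env.origin)
                save_grid("consensus", outdir / f"consensus_{period}.asc", stack=g)
            trend.to_csv(outdir / "area_trend.csv")
            (outdir / "variable_report.json").write_text(
                json.dumps(
                    {"screen_removed": screen.removed,
                     "probe_removed": probe.removed,
                     "retained": final_vars,
                     "discarded_by": probe.discarded_by,
                     "auc": result.auc, "mae": result.mae,
                     "n_presence_filtered": len(pres_f)},
                    indent=1, sort_keys=True,
                )
            )
            enm_outputs = [outdir / "area_trend.csv", outdir / "variable_report.json"]
            enm_outputs += [outdir / f"consensus_{p}.asc" for p in periods]
            _record(manifest, "enm", enm_outputs)
            manifest["stages"]["enm"].update(
                retained=final_vars, auc=result.auc,
                n_presences=len(pres_f),
            )
            log(f"[enm] retained {final_vars}, AUCs "
                + ", ".join(f"{k}={v:.2f}" for k, v in result.auc.items()))

    if failed:
        manifest["failed"] = sorted(failed)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest


def report(manifest: dict | str | Path) -> str:
    """Human-readable markdown summary assembled from a run manifest."""
    if isinstance(manifest, (str, Path)):
        manifest = json.loads(Path(manifest).read_text())
    outdir = Path(manifest.get("outdir", "."))
    lines = [f"# Pipeline run report (seed {manifest.get('seed')})", ""]
    stages = manifest.get("stages", {})
    if not stages:
        return "\n".join(lines + ["WARNING: empty manifest — nothing was run."])

    def warn(msg):
        lines.append(f"*WARNING: {msg}*")

    if "haplonet" in stages:
        lines.append("## Haplotype network")
        st = stages["haplonet"]
        if st.get("status") != "ok":
            warn(st.get("status"))
        else:
            lines.append(
                f"{st['n_haplotypes']} haplotypes, connection limit "
                f"{st['limit']}, {st['n_components']} network component(s)."
            )
            mpath = outdir / "membership.tsv"
            if mpath.exists():
                mem = pd.read_csv(mpath, sep="\t")
                per_region = (
                    mem.groupby("region")["haplotype"].nunique().to_dict()
                )
                lines.append(
                    "Haplotypes per region: "
                    + ", ".join(f"{k}: {v}" for k, v in sorted(per_region.items()))
                )
        lines.append("")
    if "popclust" in stages:
        lines.append("## Genetic clustering")
        st = stages["popclust"]
        if st.get("status") != "ok":
            warn(st.get("status"))
        else:
            lines.append(
                f"Optimal clusters: level 1 K={st['k']['1'] if '1' in st['k'] else st['k'][1]}, "
                f"level 2 K={st['k']['2'] if '2' in st['k'] else st['k'][2]}."
            )
        lines.append("")
    if "bbm" in stages:
        lines.append("## Ancestral areas")
        st = stages["bbm"]
        if st.get("status") != "ok":
            warn(st.get("status"))
        else:
            ppath = outdir / "bbm_posterior.csv"
            if ppath.exists():
                post = pd.read_csv(ppath)
                top = post.sort_values("probability", ascending=False).groupby(
                    "node", sort=True
                ).head(1)
                for _, row in top.head(10).iterrows():
                    lines.append(
                        f"- node ({row['node'][:40]}…): {row['range']} "
                        f"(P = {row['probability']:.2f})"
                    )
        lines.append("")
    if "chronos" in stages:
        lines.append("## Node ages")
        st = stages["chronos"]
        if st.get("status") != "ok":
            warn(st.get("status"))
        else:
            apath = outdir / "node_ages.csv"
            if apath.exists():
                ages = pd.read_csv(apath)
                lines.append(ages.head(10).to_string(index=False))
        lines.append("")
    if "enm" in stages:
        lines.append("## Niche modeling")
        st = stages["enm"]
        if st.get("status") != "ok":
            warn(st.get("status"))
        else:
            lines.append(f"Retained variables: {', '.join(st['retained'])}.")
            lines.append(
                "AUC: " + ", ".join(f"{k}={v:.2f}" for k, v in st["auc"].items())
            )
            tpath = outdir / "area_trend.csv"
            if tpath.exists():
                lines.append("")
                lines.append("Area/variable trends (present = 1):")
                lines.append(pd.read_csv(tpath, index_col=0).to_string())
        lines.append("")
    return "\n".join(lines)
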