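"""Full-analysis orchestration: one config in, a directory of result tables out.

A run walks every branch-length realization (base schemes plus perturbed
replicates), computes per-community alpha metrics (PD, MPD, NRI, p) for
individual samples and pooled type-year communities, combines per-group
p-values by Fisher's method, builds weighted and unweighted D_pw matrices
on the designated ordination realization, runs NMDS (+ 95% ellipses) and
PERMANOVA on them, and fits the tree-type mixed models across realizations.
All stage seeds derive deterministically from the master seed via
``numpy.random.SeedSequence(master).spawn``-style child states, so a rerun
with the same config reproduces every stochastic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha_metrics import NullModelSpec, community_metrics, fishers_method, metrics_table
from .beta_metrics import dpw_matrix
from .community import CommunityMatrix, load_community_table, pool_by, pooled_matrix
from .inference import confidence_ellipse, fit_lme_tree_type, nmds, permanova
from .synthetic_data import default_design, simulate_study, simulate_tree, write_study
from .treeio import enumerate_realizations, patristic_distance_matrix, read_newick, \
    resolution_summary, write_newick

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class SimulateBlock:
    n_taxa: int = 199
    resolved_fraction: float = 79 / 198
    replicates: int = 13
    lambda_filter: float = 1.5
    lambda_repulsion: float = 1.0


@dataclass
class RunConfig:
    """Everything a run needs; loadable from YAML via :meth:`from_yaml`."""

    newick: str | None = None
    counts: str | None = None
    metadata: str | None = None
    simulate: SimulateBlock | None = None
    schemes: tuple[str, ...] = ("equal", "ultrametric")
    perturb_reps: int = 10
    amplitude: float = 0.99
    null_reps: int = 999
    weightings: tuple[bool, ...] = (True, False)
    permutations: int = 999
    ordination_scheme: str = "ultrametric"
    seed: int = 0
    outdir: str = "phylocomm_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim is not None:
            cfg.simulate = SimulateBlock(**sim)
        return cfg


def _digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _file_digest(path) -> str:
    with open(path, "rb") as fh:
        return _digest(fh.read())


def _stage_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole analysis; returns (and writes) the run manifest."""
    t0 = time.time()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda *parts: os.path.join(config.outdir, *parts)  # noqa: E731
    (seed_sim, seed_trees, seed_null, seed_ord, seed_perm) = _stage_seeds(config.seed, 5)
    manifest: dict = {
        "package_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": {
            "simulate": seed_sim, "realizations": seed_trees,
            "null_models": seed_null, "nmds": seed_ord, "permanova": seed_perm,
        },
        "config": _config_dict(config),
        "inputs": {},
        "outputs": [],
    }

    # ------------------------------------------------ inputs
    if config.simulate is not None:
        sim = config.simulate
        tree = simulate_tree(sim.n_taxa, seed=seed_sim,
                             resolved_fraction=sim.resolved_fraction)
        design = default_design(lambda_filter=sim.lambda_filter,
                                lambda_repulsion=sim.lambda_repulsion,
                                replicates=sim.replicates)
        cm = simulate_study(design, tree, seed=seed_sim)
        paths = write_study(cm, tree, out("inputs"))
        manifest["inputs"] = {k: _file_digest(v) for k, v in paths.items()}
    else:
        if not (config.newick and config.counts and config.metadata):
            raise ValueError("provide newick+counts+metadata paths or a simulate block")
        tree = read_newick(config.newick)
        cm = load_community_table(config.counts, config.metadata, tree=tree)
        manifest["inputs"] = {
            "tree": _file_digest(config.newick),
            "counts": _file_digest(config.counts),
            "metadata": _file_digest(config.metadata),
        }

    rs = resolution_summary(tree)
    manifest["tree"] = {"n_tips": rs.n_tips, "resolved": rs.resolved,
                        "possible": rs.possible}

    # ------------------------------------------------ realizations
    realizations = list(enumerate_realizations(
        tree, schemes=config.schemes, perturb_reps=config.perturb_reps,
        amplitude=config.amplitude, seed=seed_trees,
    ))
    manifest["realizations"] = [label for label, _ in realizations]
    os.makedirs(out("trees"), exist_ok=True)
    for label, rtree in realizations:
        write_newick(rtree, out("trees", f"{label}.nwk"))

    pools = pool_by(cm, ("tree_type", "year"))
    pooled_counts, pooled_meta = pooled_matrix(pools)

    # ------------------------------------------------ alpha metrics
    null_seeds = _stage_seeds(seed_null, len(realizations) * 2)
    alpha_frames = []
    for r, (label, rtree) in enumerate(realizations):
        dist = patristic_distance_matrix(rtree)
        for p, (counts, meta, level) in enumerate((
            (cm.counts, cm.meta, "individual"),
            (pooled_counts, pooled_meta, "pooled"),
        )):
            null = NullModelSpec(reps=config.null_reps,
                                 seed=null_seeds[2 * r + p])
            results = [
                community_metrics(row, rtree, dist, null=null,
                                  community_id=str(cid))
                for cid, row in counts.iterrows()
            ]
            frame = metrics_table(results)
            frame.insert(0, "level", level)
            frame.insert(0, "realization", label)
            frame["tree_type"] = meta["tree_type"].to_numpy()
            frame["year"] = meta["year"].to_numpy()
            if level == "individual":
                frame["tree_id"] = meta["tree_id"].to_numpy()
            alpha_frames.append(frame)
    alpha = pd.concat(alpha_frames, ignore_index=True)
    alpha.to_csv(out("alpha_metrics.csv"), index=False)

    # Fisher's combined p per type-year group over individual communities
    focal = alpha[(alpha["level"] == "individual")
                  & (alpha["realization"] == config.ordination_scheme)]
    fisher = (
        focal.groupby(["tree_type", "year"])["p_value"]
        .apply(lambda ps: fishers_method(ps.to_numpy()))
        .rename("fishers_p")
        .reset_index()
    )
    fisher.to_csv(out("fishers_method.csv"), index=False)

    # ------------------------------------------------ beta + ordination + PERMANOVA
    ord_tree = dict(realizations)[config.ordination_scheme]
    ord_dist = patristic_distance_matrix(ord_tree)
    perm_rows, nmds_frames, ellipse_rows = [], [], []
    for weighted in config.weightings:
        wlab = "weighted" if weighted else "unweighted"
        for counts, meta, level in (
            (cm.counts, cm.meta, "individual"),
            (pooled_counts, pooled_meta, "pooled"),
        ):
            dm = dpw_matrix(counts, ord_dist, weighted=weighted)
            dm.to_dataframe().to_csv(out(f"dpw_{level}_{wlab}.csv"))
            nm = nmds(dm, seed=seed_ord)
            coords = nm.coordinates.copy()
            coords["tree_type"] = meta["tree_type"].to_numpy()
            coords["year"] = meta["year"].to_numpy()
            coords.insert(0, "level", level)
            coords.insert(0, "weighting", wlab)
            coords["stress"] = nm.stress
            nmds_frames.append(coords.rename_axis("community_id").reset_index())
            for es in confidence_ellipse(nm.coordinates, meta["tree_type"]):
                ellipse_rows.append({
                    "weighting": wlab, "level": level, "tree_type": es.group,
                    "center_1": es.center[0], "center_2": es.center[1],
                    "cov_11": es.covariance[0, 0], "cov_12": es.covariance[0, 1],
                    "cov_22": es.covariance[1, 1], "conf_level": es.level,
                })
            pr = permanova(dm, meta[["tree_type", "year"]],
                           permutations=config.permutations, seed=seed_perm)
            tab = pr.to_dataframe()
            tab.insert(0, "weighting", wlab)
            tab.insert(0, "level", level)
            perm_rows.append(tab)
    pd.concat(nmds_frames, ignore_index=True).to_csv(out("nmds_coordinates.csv"), index=False)
    pd.DataFrame(ellipse_rows).to_csv(out("nmds_ellipses.csv"), index=False)
    pd.concat(perm_rows, ignore_index=True).to_csv(out("permanova.csv"), index=False)

    # ------------------------------------------------ LME across realizations
    lme_rows = []
    for level, pooled_flag in (("individual", False), ("pooled", True)):
        sub = alpha[alpha["level"] == level]
        for metric, value_col, with_rich in (
            ("PD", "PD", True), ("MPD", "MPD", False), ("NRI", "NRI", False),
        ):
            df = sub.rename(columns={value_col: "value"})[
                ["value", "tree_type", "year", "realization", "richness"]
                + (["tree_id"] if level == "individual" else [])
            ].dropna(subset=["value"])
            res = fit_lme_tree_type(df, pooled=pooled_flag, include_richness=with_rich)
            tab = res.to_dataframe()
            tab.insert(0, "metric", metric)
            tab.insert(0, "analysis", level)
            lme_rows.append(tab)
    pd.concat(lme_rows, ignore_index=True).to_csv(out("lme_contrasts.csv"), index=False)

    manifest["outputs"] = sorted(
        os.path.relpath(os.path.join(root, f), config.outdir)
        for root, _, files in os.walk(config.outdir) for f in files
        if f != "manifest.json"
    )
    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
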