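"""Synthetic phylogenies and communities emulating the hybrid-zone study design.

The generator stands in for the unpublished field data: a partially
resolved ~200-taxon tree (Yule topology with polytomies collapsed to a
target resolution), and arthropod-like samples laid out as 3 host tree
types x 4 years x replicate trees. Assembly processes are controllable:

* FILTERING — a host type selects taxa near a type-specific *focal* lineage
  (inclusion weight exp(-lambda * d(focal, taxon))), the phylogenetic
  signature of environmental filtering; used for both parental types, each
  with its own focal, so replicate communities of a type are clustered
  around the same clade and dominant taxa are shared within a type.
* REPULSION — taxa are added sequentially with weight
  exp(+lambda * min distance to the already-included set), producing
  overdispersion; used for hybrid hosts.
* NEUTRAL — uniform sampling; lambda = 0 reduces every process to this.

Richness per sample targets the study's occupancy regime (individual trees
hold a few percent of the taxon pool; pooled type-year communities around a
third) and abundances follow a skewed geometric series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .treeio import (
    PatristicDistances,
    apply_equal_branch_lengths,
    parse_newick,
    patristic_distance_matrix,
    write_newick,
)

__all__ = [
    "AssemblySpec",
    "StudyDesign",
    "simulate_tree",
    "assemble_community",
    "simulate_study",
    "default_design",
]

PROCESSES = ("neutral", "filtering", "repulsion")


@dataclass(frozen=True)
class AssemblySpec:
    """One assembly process acting on one host type.

    ``strength`` (lambda, unitless per node-step of branch length) scales
    the filtering/repulsion weights; 0 reduces to neutral sampling.
    ``richness_frac`` is the mean fraction of the taxon pool per sample and
    ``abundance_mean`` the mean abundance of a present species (geometric
    series). ``focal`` pins the filtering focal taxon (drawn uniformly when
    None). ``rank_abundance_by_proximity`` assigns the largest abundances to
    the taxa closest to the focal, so replicate communities filtered by the
    same host share their dominant species.
    """

    process: str = "neutral"
    strength: float = 0.0
    richness_frac: float = 0.075
    abundance_mean: float = 2.6
    focal: str | None = None
    rank_abundance_by_proximity: bool = True

    def __post_init__(self):
        if self.process not in PROCESSES:
            raise ValueError(f"unknown process {self.process!r}")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """The sampling layout: tree types x years x replicate trees."""

    tree_types: tuple[str, ...] = ("Fremont", "hybrid", "narrowleaf")
    years: tuple[int, ...] = (2000, 2001, 2002, 2003)
    replicates: int = 13
    specs: Mapping[str, AssemblySpec] = field(default_factory=dict)

    def __post_init__(self):
        if self.replicates < 1 or not self.tree_types or not self.years:
            raise ValueError("all design counts must be >= 1")


def default_design(
    lambda_filter: float = 1.5,
    lambda_repulsion: float = 1.0,
    richness_frac: float = 0.075,
    abundance_mean: float = 2.6,
    replicates: int = 13,
) -> StudyDesign:
    """The study-condition defaults: filtered parental types, repulsed hybrids."""
    return StudyDesign(
        replicates=replicates,
        specs={
            "Fremont": AssemblySpec("filtering", lambda_filter,
                                    richness_frac, abundance_mean),
            "narrowleaf": AssemblySpec("filtering", lambda_filter,
                                       richness_frac, abundance_mean),
            "hybrid": AssemblySpec("repulsion", lambda_repulsion,
                                   richness_frac, abundance_mean,
                                   rank_abundance_by_proximity=False),
        },
    )


def _yule_newick(n_tips: int, rng: np.random.Generator) -> str:
    """Pure-birth topology: split a uniformly chosen extant lineage until
    ``n_tips`` are present; rendered as newick with labels t001..tNNN."""
    children: dict[int, list[int]] = {0: [1, 2]}
    leaves = [1, 2]
    nxt = 3
    while len(leaves) < n_tips:
        i = int(rng.integers(len(leaves)))
        leaf = leaves[i]
        children[leaf] = [nxt, nxt + 1]
        leaves[i] = nxt
        leaves.append(nxt + 1)
        nxt += 2
    width = len(str(n_tips))
    labels = iter(f"t{i + 1:0{width}d}" for i in range(n_tips))

    def render(node: int) -> str:
        if node not in children:
            return next(labels)
        return "(" + ",".join(render(c) for c in children[node]) + ")"

    return render(0) + ";"


def simulate_tree(
    n_tips: int,
    seed: int | None = None,
    resolved_fraction: float | None = None,
) -> dendropy.Tree:
    """Rooted Yule-topology tree with unit branch lengths.

    ``resolved_fraction`` collapses uniformly chosen internal (non-root)
    nodes until the resolution summary (root excluded) hits
    ``round(resolved_fraction * (n_tips - 1))`` exactly, emulating a
    partially resolved composite supertree. Same seed, same newick.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    tree = parse_newick(_yule_newick(n_tips, rng))
    if resolved_fraction is not None:
        target = int(round(resolved_fraction * (n_tips - 1)))
        internal = [
            nd for nd in tree.preorder_internal_node_iter() if nd is not tree.seed_node
        ]
        current = len(internal)
        if not 0 <= target <= current:
            raise ValueError(
                f"cannot reach {target} resolved nodes from {current}"
            )
        doomed = rng.choice(len(internal), size=current - target, replace=False)
        for i in sorted(doomed, reverse=True):
            internal[i].edge.collapse()
    return apply_equal_branch_lengths(tree)


def _weighted_subset(weights: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``size`` distinct indices with probability proportional to
    ``weights`` (Gumbel top-k on log-weights)."""
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    keys = logw + rng.gumbel(size=weights.size)
    return np.argpartition(-keys, size - 1)[:size]


def assemble_community(
    tree_or_distances,
    spec: AssemblySpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Draw one community (abundance vector over all taxa) under ``spec``."""
    if isinstance(tree_or_distances, PatristicDistances):
        dist = tree_or_distances
    else:
        dist = patristic_distance_matrix(tree_or_distances)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(dist.taxa)
    target = spec.richness_frac * n
    richness = int(np.clip(rng.poisson(target), 2, n))

    lam = spec.strength
    focal_idx: int | None = None
    if spec.process == "filtering" and lam > 0:
        focal_idx = (
            dist.index[spec.focal] if spec.focal is not None
            else int(rng.integers(n))
        )
        d = dist.values[focal_idx]
        w = np.exp(-lam * (d - d.min()))
        chosen = _weighted_subset(w, richness, rng)
    elif spec.process == "repulsion" and lam > 0:
        first = int(rng.integers(n))
        chosen_list = [first]
        min_d = dist.values[first].copy()
        for _ in range(richness - 1):
            w = np.exp(lam * (min_d - min_d.max()))
            w[chosen_list] = 0.0
            w /= w.sum()
            pick = int(rng.choice(n, p=w))
            chosen_list.append(pick)
            np.minimum(min_d, dist.values[pick], out=min_d)
        chosen = np.array(chosen_list)
    else:  # neutral, or lambda == 0
        chosen = rng.choice(n, size=richness, replace=False)

    counts = rng.geometric(p=1.0 / spec.abundance_mean, size=richness)
    if focal_idx is not None and spec.rank_abundance_by_proximity:
        # closest-to-focal taxa get the largest counts -> shared dominants
        order = np.argsort(dist.values[focal_idx][chosen], kind="stable")
        counts = np.sort(counts)[::-1]
        chosen = chosen[order]
    out = pd.Series(0, index=list(dist.taxa), dtype=int)
    out.iloc[chosen] = counts
    return out


def simulate_study(
    design: StudyDesign,
    tree: dendropy.Tree,
    seed: int | None = None,
) -> CommunityMatrix:
    """One full survey: a sample per (tree type, year, replicate tree).

    For filtering types without a pinned focal, one focal taxon is drawn per
    tree type and shared by all its replicates and years — the host
    environment, not the individual tree, does the filtering. Fully
    reproducible from ``seed``.
    """
    needs_lengths = any(
        nd.edge.length is None for nd in tree.preorder_node_iter()
        if nd is not tree.seed_node
    )
    if needs_lengths:
        tree = apply_equal_branch_lengths(tree)
    dist = patristic_distance_matrix(tree)
    rng = np.random.default_rng(seed)

    specs: dict[str, AssemblySpec] = {}
    for tt in design.tree_types:
        spec = design.specs.get(tt, AssemblySpec())
        if spec.process == "filtering" and spec.focal is None and spec.strength > 0:
            spec = replace(spec, focal=dist.taxa[int(rng.integers(len(dist.taxa)))])
        specs[tt] = spec

    rows, meta_rows = {}, []
    for tt in design.tree_types:
        for year in design.years:
            for rep in range(1, design.replicates + 1):
                sample_id = f"{tt}_{year}_r{rep:02d}"
                rows[sample_id] = assemble_community(dist, specs[tt], rng=rng)
                meta_rows.append(
                    {"sample_id": sample_id, "tree_id": f"{tt}_t{rep:02d}",
                     "tree_type": tt, "year": year}
                )
    counts = pd.DataFrame(rows).T
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CommunityMatrix(counts, meta.loc[counts.index])


def write_study(cm: CommunityMatrix, tree: dendropy.Tree, outdir) -> dict:
    """Write the simulated survey in the community module's CSV formats plus
    the newick tree; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "counts": os.path.join(outdir, "community_counts.csv"),
        "metadata": os.path.join(outdir, "community_metadata.csv"),
        "tree": os.path.join(outdir, "tree.nwk"),
    }
    cm.counts.rename_axis("sample_id").to_csv(paths["counts"])
    cm.meta.rename_axis("sample_id").to_csv(paths["metadata"])
    write_newick(tree, paths["tree"])
    return paths
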