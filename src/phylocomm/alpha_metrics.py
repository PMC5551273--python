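"""Within-community phylogenetic structure: Faith's PD, MPD, SES/NRI, Fisher's p.

The net relatedness index (NRI) is the sign-reversed standardized effect
size of mean pairwise distance (MPD) against a richness- and
abundance-preserving null:

    NRI = -(MPD_obs - mean(MPD_null)) / sd(MPD_null)

so NRI > 0 means co-occurring taxa are closer relatives than expected
(phylogenetic clustering, the environmental-filtering signature) and
NRI < 0 means overdispersion. The default null is a taxa-label shuffle on
the patristic distance matrix: each replicate relabels the community's taxa
as a uniformly random subset of the full taxon pool of the same richness,
carrying the observed abundance multiset along. One-sided (clustering)
rank p-values use the (r + 1)/(n + 1) correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .treeio import PatristicDistances, TreeValidationError

__all__ = [
    "NullModelSpec",
    "MetricResult",
    "faith_pd",
    "mpd",
    "ses_mpd",
    "fishers_method",
    "community_metrics",
    "metrics_table",
]


@dataclass(frozen=True)
class NullModelSpec:
    """Null-model settings for SES/NRI.

    ``scheme`` options: ``taxa_shuffle`` (default; relabel community taxa as
    a random same-size subset of the full pool) or ``pool_sample``
    (equivalent draw expressed as subset sampling; kept separate so
    alternative pools can be plugged in).
    """

    reps: int = 999
    scheme: str = "taxa_shuffle"
    seed: int | None = None


@dataclass(frozen=True)
class MetricResult:
    """One community's row of the alpha-diversity results table."""

    community_id: str
    richness: int
    pd_value: float | None
    mpd_obs: float
    null_mean: float
    null_sd: float
    ses: float
    nri: float
    p_value: float
    degenerate: bool = False


def _abundance_items(abundances) -> tuple[list[str], np.ndarray]:
    if isinstance(abundances, pd.Series):
        items = [(str(k), float(v)) for k, v in abundances.items() if v > 0]
    elif isinstance(abundances, Mapping):
        items = [(str(k), float(v)) for k, v in abundances.items() if v > 0]
    else:  # iterable of taxa -> presence
        items = [(str(k), 1.0) for k in abundances]
    taxa = [k for k, _ in items]
    f = np.array([v for _, v in items], dtype=float)
    return taxa, f


def faith_pd(community, tree: dendropy.Tree, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity: total branch length of the minimal
    subtree spanning the community's taxa.

    With ``include_root=True`` (default) the spanning subtree is rooted at
    the tree's root, so PD is defined even for a single taxon (its
    root-to-tip path length). With ``include_root=False`` the stem above the
    community's most recent common ancestor is excluded, and a single-taxon
    community is undefined (raises).
    """
    taxa, _ = _abundance_items(community)
    if not taxa:
        raise ValueError("empty community: PD undefined")
    if len(taxa) == 1 and not include_root:
        raise ValueError("single-taxon PD undefined with include_root=False")
    wanted = set(taxa)
    tip_labels = {str(l.taxon.label).strip() for l in tree.leaf_node_iter()}
    missing = wanted - tip_labels
    if missing:
        raise ValueError(f"taxa not on tree: {sorted(missing)[:5]}")

    total = 0.0
    n_wanted = len(wanted)
    # Edge is on the spanning subtree iff its subtree holds >=1 member;
    # edges holding ALL members lie on the root-to-MRCA stem.
    count_below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = 1 if str(node.taxon.label).strip() in wanted else 0
        else:
            c = sum(count_below[ch] for ch in node.child_nodes())
        count_below[node] = c
        if node is tree.seed_node:
            continue
        if c > 0 and (include_root or c < n_wanted):
            if node.edge.length is None:
                raise TreeValidationError("unset branch length; apply a scheme first")
            total += node.edge.length
    return total


def mpd(
    abundances,
    distances: PatristicDistances,
    weighted: bool = True,
    include_conspecific: bool = False,
) -> float:
    """Mean pairwise patristic distance within a community.

    Unweighted: mean of d_ij over unordered pairs of distinct present taxa.
    Weighted: sum_{i != j} f_i f_j d_ij / sum_{i != j} f_i f_j. By default
    conspecific pairs (same taxon, d = 0) are excluded from the denominator;
    ``include_conspecific=True`` instead averages over all pairs of distinct
    *individuals*, which shrinks MPD for communities dominated by one taxon.
    """
    taxa, f = _abundance_items(abundances)
    if len(taxa) < 2:
        raise ValueError("MPD requires at least two distinct taxa")
    d = distances.submatrix(taxa)
    if not weighted:
        iu = np.triu_indices(len(taxa), k=1)
        return float(d[iu].mean())
    num = float(f @ d @ f)  # diagonal is zero
    total = f.sum()
    if include_conspecific:
        denom = total * total - total  # ordered pairs of distinct individuals
    else:
        denom = total * total - float((f * f).sum())
    return num / denom


def _null_mpds(
    taxa_idx: np.ndarray,
    f: np.ndarray,
    values: np.ndarray,
    reps: int,
    rng: np.random.Generator,
    weighted: bool,
    include_conspecific: bool,
) -> np.ndarray:
    n = values.shape[0]
    k = taxa_idx.size
    picks = np.empty((reps, k), dtype=int)
    for r in range(reps):
        picks[r] = rng.choice(n, size=k, replace=False)
    sub = values[picks[:, :, None], picks[:, None, :]]  # (reps, k, k)
    if not weighted:
        iu = np.triu_indices(k, k=1)
        return sub[:, iu[0], iu[1]].mean(axis=1)
    num = np.einsum("i,rij,j->r", f, sub, f)
    total = f.sum()
    if include_conspecific:
        denom = total * total - total
    else:
        denom = total * total - float((f * f).sum())
    return num / denom


def ses_mpd(
    abundances,
    distances: PatristicDistances,
    null: NullModelSpec = NullModelSpec(),
    weighted: bool = True,
    include_conspecific: bool = False,
    alternative: str = "clustering",
    community_id: str = "",
    pd_value: float | None = None,
) -> MetricResult:
    """Standardized effect size of MPD against the taxa-shuffle null; NRI = -SES.

    Each null replicate preserves the community's richness and abundance
    multiset exactly. ``alternative``: ``"clustering"`` (one-sided, low MPD;
    default, matching the direction in which significance is reported) or
    ``"two-sided"``. If the null has zero spread (e.g. the community contains
    the whole taxon pool) the result is flagged degenerate with NRI = 0.
    """
    if null.scheme not in ("taxa_shuffle", "pool_sample"):
        raise ValueError(f"unknown null scheme {null.scheme!r}")
    taxa, f = _abundance_items(abundances)
    if len(taxa) < 2:
        raise ValueError("SES(MPD) requires at least two distinct taxa")
    obs = mpd(abundances, distances, weighted=weighted,
              include_conspecific=include_conspecific)
    idx_map = distances.index
    taxa_idx = np.array([idx_map[t] for t in taxa], dtype=int)
    rng = np.random.default_rng(null.seed)
    nulls = _null_mpds(
        taxa_idx, f, distances.values, null.reps, rng, weighted, include_conspecific
    )
    mu = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    # a replicate that redraws the observed community ties with it exactly;
    # without a tolerance float jitter would split such ties at random
    tol = 1e-9 * max(1.0, abs(obs))
    r_low = int((nulls <= obs + tol).sum())
    r_high = int((nulls >= obs - tol).sum())
    p_low = (r_low + 1) / (null.reps + 1)
    p_high = (r_high + 1) / (null.reps + 1)
    if alternative == "clustering":
        p = p_low
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if sd <= 1e-12:
        return MetricResult(
            community_id=community_id, richness=len(taxa), pd_value=pd_value,
            mpd_obs=obs, null_mean=mu, null_sd=sd, ses=0.0, nri=0.0,
            p_value=1.0, degenerate=True,
        )
    ses = (obs - mu) / sd
    return MetricResult(
        community_id=community_id, richness=len(taxa), pd_value=pd_value,
        mpd_obs=obs, null_mean=mu, null_sd=sd, ses=ses, nri=-ses,
        p_value=p, degenerate=False,
    )


def fishers_method(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: X^2 = -2 sum(ln p) ~ chi-square(2k)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * p.size))


def community_metrics(
    abundances,
    tree: dendropy.Tree,
    distances: PatristicDistances,
    null: NullModelSpec = NullModelSpec(),
    weighted: bool = True,
    community_id: str = "",
) -> MetricResult:
    """PD + MPD + SES/NRI for one community (one Table-style results row)."""
    pdv = faith_pd(abundances, tree)
    return ses_mpd(
        abundances, distances, null=null, weighted=weighted,
        community_id=community_id, pd_value=pdv,
    )


def metrics_table(results: Sequence[MetricResult]) -> pd.DataFrame:
    """Tidy results frame (community id, richness, PD, MPD, null mean/SD, NRI, p)."""
    return pd.DataFrame(
        [
            {
                "community_id": r.community_id,
                "richness": r.richness,
                "PD": r.pd_value,
                "MPD": r.mpd_obs,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "NRI": r.nri,
                "p_value": r.p_value,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
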