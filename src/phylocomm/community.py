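"""Sample x taxon abundance tables with host-tree metadata.

A *sample* is the arthropod community censused on one tree in one year.
Metadata carry the tree id, the host tree type (Fremont cottonwood,
F1 hybrid, or narrowleaf cottonwood) and the census year. Backcross hybrids
are genetically indistinguishable from narrowleaf and are recoded as such on
load. Analyses run both on individual samples and on communities pooled by
tree type (optionally crossed with year), with abundances summed exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREE_TYPES = ("Fremont", "hybrid", "narrowleaf")
#: metadata labels accepted on input and their canonical recoding
_TYPE_RECODE = {
    "fremont": "Fremont",
    "hybrid": "hybrid",
    "f1": "hybrid",
    "narrowleaf": "narrowleaf",
    "backcross": "narrowleaf",
}

__all__ = [
    "TREE_TYPES",
    "CommunityMatrix",
    "PooledCommunity",
    "OccupancySummary",
    "CommunityValidationError",
    "load_community_table",
    "pool_by",
    "pooled_matrix",
    "occupancy_summary",
]


class CommunityValidationError(ValueError):
    pass


@dataclass
class CommunityMatrix:
    """Validated abundance counts (samples x taxa) plus per-sample metadata.

    ``counts`` is an integer DataFrame indexed by sample id; ``meta`` is
    indexed identically with columns ``tree_id``, ``tree_type``, ``year``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        counts, meta = self.counts, self.meta
        if not counts.index.equals(meta.index):
            missing = counts.index.difference(meta.index)
            if len(missing):
                raise CommunityValidationError(
                    f"samples lacking metadata: {list(missing)[:5]}"
                )
            meta = meta.loc[counts.index]
        for col in ("tree_id", "tree_type", "year"):
            if col not in meta.columns:
                raise CommunityValidationError(f"metadata missing column {col!r}")
        bad_types = set(meta["tree_type"]) - set(TREE_TYPES)
        if bad_types:
            raise CommunityValidationError(f"unknown tree type labels: {sorted(bad_types)}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise CommunityValidationError("abundances must be integers")
            counts = counts.round().astype(int)
            arr = counts.to_numpy()
        if (arr < 0).any():
            raise CommunityValidationError("negative abundances are not allowed")
        empty = counts.index[arr.sum(axis=1) == 0]
        if len(empty):
            logger.warning(
                "dropping %d empty sample(s) (phylogenetic metrics are undefined "
                "on empty communities): %s", len(empty), list(empty)[:5],
            )
            counts = counts.drop(index=empty)
            meta = meta.drop(index=empty)
        self.counts = counts
        self.meta = meta.loc[counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def match_tree(self, tip_labels: Iterable[str], drop_missing: bool = False) -> "CommunityMatrix":
        """Check every taxon with a positive entry maps to exactly one tree tip.

        Unknown taxa raise (naming them) unless ``drop_missing`` is set, in
        which case their columns are removed with a logged report.
        """
        tips = {str(t).strip() for t in tip_labels}
        present = self.counts.loc[:, self.counts.sum(axis=0) > 0].columns
        unknown = [t for t in present if str(t).strip() not in tips]
        if unknown:
            if not drop_missing:
                raise CommunityValidationError(
                    f"taxa absent from the phylogeny: {unknown[:10]}"
                    + (" ..." if len(unknown) > 10 else "")
                )
            logger.warning("dropping %d taxa absent from the phylogeny: %s",
                           len(unknown), unknown[:10])
            return CommunityMatrix(self.counts.drop(columns=unknown), self.meta.copy())
        return self


@dataclass(frozen=True)
class PooledCommunity:
    """Abundances summed over all samples sharing a grouping key."""

    key: tuple
    key_names: tuple[str, ...]
    abundances: pd.Series = field(repr=False)
    n_samples: int = 0

    @property
    def community_id(self) -> str:
        return "_".join(str(k) for k in self.key)


def _canonical_type(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _TYPE_RECODE:
        raise CommunityValidationError(
            f"unknown tree type label {label!r}; expected one of "
            f"{sorted(set(_TYPE_RECODE))}"
        )
    return _TYPE_RECODE[key]


def load_community_table(
    counts_path,
    metadata_path,
    tree=None,
    drop_missing: bool = False,
    sep: str | None = None,
) -> CommunityMatrix:
    """Read a delimited samples x taxa table and its metadata CSV.

    The counts table has sample ids in the first column and taxon ids as the
    header row; metadata columns are ``sample_id, tree_id, tree_type, year``.
    Backcross tree types are recoded to narrowleaf (with a logged count).
    If ``tree`` (a dendropy tree) is given, taxa are validated against its
    tips; unknown taxa raise unless ``drop_missing`` is set.
    """
    kw = {"sep": sep} if sep is not None else {"sep": None, "engine": "python"}
    counts = pd.read_csv(counts_path, index_col=0, **kw)
    counts.index = counts.index.astype(str).str.strip()
    counts.columns = counts.columns.astype(str).str.strip()
    meta = pd.read_csv(metadata_path, **kw)
    if "sample_id" not in meta.columns:
        raise CommunityValidationError("metadata must have a sample_id column")
    meta = meta.set_index(meta["sample_id"].astype(str).str.strip()).drop(columns="sample_id")

    raw_types = meta["tree_type"].astype(str)
    meta["tree_type"] = [_canonical_type(t) for t in raw_types]
    n_backcross = int((raw_types.str.strip().str.lower() == "backcross").sum())
    if n_backcross:
        logger.info("recoded %d backcross sample(s) as narrowleaf", n_backcross)

    cm = CommunityMatrix(counts, meta)
    if tree is not None:
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        cm = cm.match_tree(labels, drop_missing=drop_missing)
    return cm


def pool_by(matrix: CommunityMatrix, keys: Sequence[str]) -> list[PooledCommunity]:
    """Sum abundances over samples sharing the same values of ``keys``.

    ``keys`` is a non-empty subset of ``{"tree_type", "year"}`` (order
    defines the grouping key order). Integer conservation is exact.
    """
    keys = tuple(keys)
    if not keys:
        raise ValueError("empty key set: nothing to pool by")
    allowed = {"tree_type", "year"}
    if not set(keys) <= allowed:
        raise ValueError(f"pooling keys must be among {sorted(allowed)}, got {keys}")
    grouped = matrix.counts.groupby([matrix.meta[k] for k in keys], sort=True)
    out = []
    for key, block in grouped:
        key = key if isinstance(key, tuple) else (key,)
        out.append(
            PooledCommunity(
                key=tuple(key),
                key_names=keys,
                abundances=block.sum(axis=0),
                n_samples=len(block),
            )
        )
    return out


def pooled_matrix(pools: Sequence[PooledCommunity]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack pooled communities into (counts, meta) frames for downstream use."""
    counts = pd.DataFrame(
        {p.community_id: p.abundances for p in pools}
    ).T
    counts.index.name = "community_id"
    meta = pd.DataFrame(
        [dict(zip(p.key_names, p.key), n_samples=p.n_samples) for p in pools],
        index=counts.index,
    )
    return counts, meta


@dataclass(frozen=True)
class OccupancySummary:
    """Mean occupancy (fraction of the taxon pool present per community) and
    mean abundance per present species, with ranges across communities."""

    n_communities: int
    n_taxa_pool: int
    mean_fraction_present: float
    min_fraction_present: float
    max_fraction_present: float
    mean_abundance_per_species: float
    min_abundance_per_species: float
    max_abundance_per_species: float


def occupancy_summary(counts: pd.DataFrame) -> OccupancySummary:
    """Summarize occupancy for a communities x taxa count table.

    The taxon pool is the table's full column set, so the fractions are
    directly comparable to "percent of all species present" figures.
    """
    arr = counts.to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError("empty community table")
    present = arr > 0
    richness = present.sum(axis=1)
    if (richness == 0).any():
        raise ValueError("communities with no taxa present")
    frac = richness / arr.shape[1]
    mean_ab = arr.sum(axis=1) / richness
    return OccupancySummary(
        n_communities=arr.shape[0],
        n_taxa_pool=arr.shape[1],
        mean_fraction_present=float(frac.mean()),
        min_fraction_present=float(frac.min()),
        max_fraction_present=float(frac.max()),
        mean_abundance_per_species=float(mean_ab.mean()),
        min_abundance_per_species=float(mean_ab.min()),
        max_abundance_per_species=float(mean_ab.max()),
    )
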