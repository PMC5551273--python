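"""Phylobetadiversity: between-community mean pairwise distance (D_pw).

D_pw between communities A and B is the mean patristic distance over all
cross-community taxon pairs. Cross pairs of the *same* taxon contribute
d = 0 — this is what makes the abundance-weighted variant informative when
communities share dominant taxa: two assemblages dominated by the same
species are near-identical under weighting even if their rare tails differ.

Weighted:   D_pw(A, B) = (f' D g) / (sum f * sum g)
Unweighted: the same with presence/absence vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .treeio import PatristicDistances

__all__ = ["DpwMatrix", "dpw_pair", "dpw_matrix", "dpw_self"]


@dataclass(frozen=True)
class DpwMatrix:
    """Community x community D_pw distances for one weighting mode.

    The diagonal is stored as 0 (ordination input requires zero
    self-distance); the self-inclusive mean of a community is available
    separately via :func:`dpw_self` for diagnostics.
    """

    community_ids: tuple[str, ...]
    values: np.ndarray
    weighted: bool

    def to_dataframe(self) -> pd.DataFrame:
        ids = list(self.community_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)

    def to_long(self) -> pd.DataFrame:
        ids = list(self.community_ids)
        rows = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append({"community_a": ids[i], "community_b": ids[j],
                             "dpw": self.values[i, j]})
        return pd.DataFrame(rows)


def _vector(abundances, distances: PatristicDistances, weighted: bool) -> np.ndarray:
    v = np.zeros(len(distances.taxa), dtype=float)
    idx = distances.index
    items = abundances.items() if hasattr(abundances, "items") else (
        (t, 1.0) for t in abundances
    )
    for t, a in items:
        if a > 0:
            v[idx[str(t)]] = a if weighted else 1.0
    if v.sum() == 0:
        raise ValueError("empty community: D_pw undefined")
    return v


def dpw_pair(comm_a, comm_b, distances: PatristicDistances, weighted: bool = True) -> float:
    """D_pw between two communities (abundance mappings/Series, or taxon
    iterables treated as presence)."""
    f = _vector(comm_a, distances, weighted)
    g = _vector(comm_b, distances, weighted)
    return float(f @ distances.values @ g) / (f.sum() * g.sum())


def dpw_self(comm, distances: PatristicDistances, weighted: bool = True) -> float:
    """Self-inclusive mean pairwise distance of one community, D_pw(A, A).

    Zero only for singleton communities; diagnostic, not ordination input.
    """
    return dpw_pair(comm, comm, distances, weighted=weighted)


def dpw_matrix(
    communities,
    distances: PatristicDistances,
    weighted: bool = True,
    community_ids: Sequence[str] | None = None,
) -> DpwMatrix:
    """All-pairs D_pw. ``communities`` is a communities x taxa DataFrame or a
    sequence of abundance mappings; the result's diagonal is 0."""
    if isinstance(communities, pd.DataFrame):
        ids = [str(i) for i in communities.index]
        vecs = [_vector(row, distances, weighted) for _, row in communities.iterrows()]
    else:
        communities = list(communities)
        ids = list(community_ids) if community_ids is not None else [
            f"community_{i}" for i in range(len(communities))
        ]
        vecs = [_vector(c, distances, weighted) for c in communities]
    if len(vecs) < 2:
        raise ValueError("need at least two communities")
    F = np.vstack(vecs)
    totals = F.sum(axis=1)
    vals = (F @ distances.values @ F.T) / np.outer(totals, totals)
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0  # enforce exact numeric symmetry
    return DpwMatrix(community_ids=tuple(ids), values=vals, weighted=weighted)
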