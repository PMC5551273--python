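"""Phylogeny I/O, branch-length scenarios, patristic distances, and resolution.

The composite arthropod supertree underlying the analysis is a literature
summary: its topology is trustworthy at ordinal/familial rank but it carries
no meaningful branch lengths. All analyses therefore run over *branch-length
scenarios*: every branch set to one "node step" (EQUAL), an ultrametric
variant obtained by lengthening only the most basal branches
(ULTRAMETRIC), and, for sensitivity analysis, replicates of either scheme
with independent Uniform(-a, +a) noise added to every branch.

Trees are held as :class:`dendropy.Tree` objects throughout; polytomies are
preserved (the supertree is deliberately only partially resolved) and the
root carries no branch of its own.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from typing import Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "BranchLengthScheme",
    "SchemeBase",
    "PatristicDistances",
    "ResolutionSummary",
    "NewickParseError",
    "TreeValidationError",
    "read_newick",
    "parse_newick",
    "write_newick",
    "apply_equal_branch_lengths",
    "apply_ultrametric_by_basal_extension",
    "perturb_branch_lengths",
    "patristic_distance_matrix",
    "resolution_summary",
    "enumerate_realizations",
]


class NewickParseError(ValueError):
    """Malformed newick input; carries the approximate character offset."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (near character offset {offset})"
        super().__init__(message)


class TreeValidationError(ValueError):
    """A tree violates a structural requirement (labels, branch lengths)."""


class SchemeBase(str, enum.Enum):
    EQUAL = "equal"
    ULTRAMETRIC = "ultrametric"


@dataclass(frozen=True)
class BranchLengthScheme:
    """A branch-length scenario: base scheme plus optional uniform noise.

    ``amplitude`` is unitless (branch lengths are in node steps); a seeded
    perturbation adds an independent Uniform(-amplitude, +amplitude) draw to
    every branch after the base scheme is applied.
    """

    base: SchemeBase = SchemeBase.EQUAL
    perturb_seed: int | None = None
    amplitude: float = 0.99

    @property
    def label(self) -> str:
        if self.perturb_seed is None:
            return self.base.value
        return f"{self.base.value}_perturbed_s{self.perturb_seed}"


@dataclass(frozen=True)
class ResolutionSummary:
    """Topological resolution of a rooted tree.

    ``possible`` is ``n_tips - 1``; ``resolved`` counts internal nodes,
    excluding the root by default (so a star tree scores 0). The convention
    is exposed because published resolution counts are sensitive to it.
    """

    n_tips: int
    resolved: int
    possible: int
    include_root: bool = False

    @property
    def fraction(self) -> float:
        return self.resolved / self.possible if self.possible else 0.0


@dataclass(frozen=True)
class PatristicDistances:
    """Symmetric tip-to-tip path-length matrix for one branch-length realization."""

    taxa: tuple[str, ...]
    values: np.ndarray  # (n, n) float, zero diagonal

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.taxa)}

    def distance(self, a: str, b: str) -> float:
        idx = self.index
        return float(self.values[idx[a], idx[b]])

    def submatrix(self, taxa: Sequence[str]) -> np.ndarray:
        idx = self.index
        ii = np.array([idx[t] for t in taxa], dtype=int)
        return self.values[np.ix_(ii, ii)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.taxa), columns=list(self.taxa))


def _validate_tips(tree: dendropy.Tree) -> list[str]:
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lbl is None or str(lbl).strip() == "" for lbl in labels):
        raise TreeValidationError("every tip must carry a non-empty label")
    labels = [str(lbl).strip() for lbl in labels]
    seen: set[str] = set()
    dups = {lbl for lbl in labels if lbl in seen or seen.add(lbl)}  # type: ignore[func-returns-value]
    if dups:
        raise TreeValidationError(f"duplicate tip labels: {sorted(dups)}")
    return labels


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a newick string into a rooted :class:`dendropy.Tree`.

    Branch lengths may be omitted (a scheme fills them in later); quoted
    labels are supported; duplicate tip labels are rejected.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "duplicate taxon labels" in str(exc).lower():
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        offset = getattr(exc, "col_num", None)
        raise NewickParseError(f"malformed newick: {exc}", offset=offset) from exc
    tree.is_rooted = True
    _validate_tips(tree)
    return tree


def read_newick(path) -> dendropy.Tree:
    """Read a single newick tree from ``path``."""
    with open(path, "r") as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize ``tree`` as newick (branch lengths as ``:<float>`` when set)."""
    out = io.StringIO()
    tree.write(
        file=out,
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def apply_equal_branch_lengths(tree: dendropy.Tree, length: float = 1.0) -> dendropy.Tree:
    """Return a copy with every non-root branch set to ``length`` (default 1 node step).

    The root carries no branch of its own.
    """
    out = _clone(tree)
    for node in out.preorder_node_iter():
        if node is out.seed_node:
            node.edge.length = None
        else:
            node.edge.length = float(length)
    return out


def _heights(tree: dendropy.Tree) -> dict:
    """Max node-to-descendant-tip path length per node (0 at tips)."""
    h: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            h[node] = 0.0
        else:
            h[node] = max(c.edge.length + h[c] for c in node.child_nodes())
    return h


def apply_ultrametric_by_basal_extension(tree: dendropy.Tree) -> dendropy.Tree:
    """Make the tree ultrametric by lengthening only the most basal branches.

    Every tip's root-to-tip path is brought up to the maximum root-to-tip
    depth of the input by adding the deficit to the branch *nearest the root*
    that is private to the deficient subtree; no branch is ever shortened.
    An already-ultrametric tree is returned unchanged (up to a copy).
    """
    out = _clone(tree)
    for node in out.preorder_node_iter():
        if node is not out.seed_node and node.edge.length is None:
            raise TreeValidationError("branch lengths must be set before ultrametricizing")
    h = _heights(out)
    # Top-down: every child subtree is stretched (at its stem) to its
    # parent's height, which leaves all root-to-tip depths equal to the
    # original maximum depth.
    for node in out.preorder_node_iter():
        if node.is_leaf():
            continue
        target = h[node]
        for c in node.child_nodes():
            deficit = target - (c.edge.length + h[c])
            if deficit > 0:
                c.edge.length += deficit
    return out


def perturb_branch_lengths(
    tree: dendropy.Tree, amplitude: float = 0.99, seed: int | None = None
) -> dendropy.Tree:
    """Add an independent Uniform(-amplitude, +amplitude) draw to every branch.

    Reproducible for a fixed ``seed``; raises if any perturbed branch would
    become non-positive (naming the offending branch), since downstream
    distances require strictly positive lengths.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    out = _clone(tree)
    rng = np.random.default_rng(seed)
    for node in out.preorder_node_iter():
        if node is out.seed_node:
            continue
        if node.edge.length is None:
            raise TreeValidationError("branch lengths must be set before perturbing")
        delta = rng.uniform(-amplitude, amplitude) if amplitude > 0 else 0.0
        new_len = node.edge.length + delta
        if new_len <= 0:
            label = node.taxon.label if node.taxon else f"internal node above {_first_tip(node)}"
            raise TreeValidationError(
                f"perturbation drives branch to {label!r} to {new_len:.4g} <= 0; "
                f"reduce amplitude (got {amplitude})"
            )
        node.edge.length = new_len
    return out


def _first_tip(node) -> str:
    for leaf in node.leaf_iter():
        return leaf.taxon.label if leaf.taxon else "<unlabeled>"
    return "<empty>"


def patristic_distance_matrix(tree: dendropy.Tree) -> PatristicDistances:
    """Tip-to-tip path-length matrix (taxa in sorted label order).

    Computed from root-to-node depths and most-recent-common-ancestor depths
    in a single postorder sweep: d(i, j) = depth_i + depth_j - 2 * depth_MRCA.
    """
    labels = sorted(_validate_tips(tree))
    index = {lbl: i for i, lbl in enumerate(labels)}
    n = len(labels)

    depth: dict = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise TreeValidationError(
                f"unset branch length above {_first_tip(node)!r}; apply a scheme first"
            )
        depth[node] = depth[node.parent_node] + node.edge.length

    depth_of = np.zeros(n, dtype=float)
    for leaf in tree.leaf_node_iter():
        depth_of[index[str(leaf.taxon.label).strip()]] = depth[leaf]

    dist = np.zeros((n, n), dtype=float)
    # Postorder merge: when subtrees join at a node, that node is the MRCA of
    # every cross-subtree tip pair.
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = np.array([index[str(node.taxon.label).strip()]], dtype=int)
            continue
        merged = np.empty(0, dtype=int)
        for c in node.child_nodes():
            tips_c = below.pop(c)
            if merged.size:
                d = depth_of[merged][:, None] + depth_of[tips_c][None, :] - 2.0 * depth[node]
                dist[np.ix_(merged, tips_c)] = d
                dist[np.ix_(tips_c, merged)] = d.T
            merged = np.concatenate([merged, tips_c])
        below[node] = merged

    return PatristicDistances(taxa=tuple(labels), values=dist)


def resolution_summary(tree: dendropy.Tree, include_root: bool = False) -> ResolutionSummary:
    """Count resolved internal nodes against the ``n_tips - 1`` possible.

    With ``include_root=False`` (default) the root does not count as a
    resolved relationship, so a star tree scores 0 and a fully bifurcating
    rooted tree scores ``n_tips - 2`` of ``n_tips - 1``.
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    internal = [nd for nd in tree.preorder_internal_node_iter()]
    resolved = len(internal) if include_root else len(internal) - 1
    resolved = max(resolved, 0)
    return ResolutionSummary(
        n_tips=n_tips,
        resolved=resolved,
        possible=max(n_tips - 1, 0),
        include_root=include_root,
    )


def enumerate_realizations(
    tree: dendropy.Tree,
    schemes: Sequence[SchemeBase | str] = (SchemeBase.EQUAL, SchemeBase.ULTRAMETRIC),
    perturb_reps: int = 10,
    amplitude: float = 0.99,
    seed: int | None = None,
) -> Iterator[tuple[str, dendropy.Tree]]:
    """Yield every branch-length realization: each base scheme plus
    ``perturb_reps`` independently perturbed replicates of it.

    Defaults give 2 + 2*10 = 22 trees. Perturbed ultrametric trees are NOT
    re-ultrametricized: the noise is meant to break the scheme's exact
    assumptions, which is the point of the sensitivity analysis.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(len(schemes) * max(perturb_reps, 0) + 1)[1:]] \
        if perturb_reps > 0 else []
    k = 0
    for scheme in schemes:
        base = SchemeBase(scheme)
        realized = apply_equal_branch_lengths(tree)
        if base is SchemeBase.ULTRAMETRIC:
            realized = apply_ultrametric_by_basal_extension(realized)
        yield base.value, realized
        for _ in range(perturb_reps):
            s = child_seeds[k] % (2**31)
            k += 1
            yield f"{base.value}_perturbed_s{s}", perturb_branch_lengths(
                realized, amplitude=amplitude, seed=s
            )
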