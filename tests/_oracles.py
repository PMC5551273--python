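"""Independent brute-force oracles used to check the library's fast paths.

Everything here walks explicit root-paths on the dendropy node structure,
deliberately avoiding the traversal tricks the implementation uses.
"""

from __future__ import annotations

import itertools

import numpy as np


def root_path(tree, label):
    """List of nodes from a tip up to (and including) the root."""
    node = next(
        l for l in tree.leaf_node_iter() if str(l.taxon.label).strip() == label
    )
    path = [node]
    while path[-1].parent_node is not None:
        path.append(path[-1].parent_node)
    return path


def patristic_oracle(tree, a, b):
    """Path-walking distance: climb both tips to the root, cut at the LCA."""
    pa, pb = root_path(tree, a), root_path(tree, b)
    ancestors_a = {id(n): i for i, n in enumerate(pa)}
    for j, n in enumerate(pb):
        if id(n) in ancestors_a:
            i = ancestors_a[id(n)]
            return sum(x.edge.length for x in pa[:i]) + sum(
                x.edge.length for x in pb[:j]
            )
    raise AssertionError("no common ancestor found")


def faith_pd_oracle(tree, taxa, include_root=True):
    """Union of edges on the tips' root-paths; optionally strip the shared stem."""
    edge_sets = []
    for t in taxa:
        path = root_path(tree, t)
        edge_sets.append({id(n): n for n in path[:-1]})  # root has no edge
    union = {}
    for es in edge_sets:
        union.update(es)
    if not include_root:
        shared = set(edge_sets[0])
        for es in edge_sets[1:]:
            shared &= set(es)
        for k in shared:
            union.pop(k)
    return sum(n.edge.length for n in union.values())


def mpd_oracle(abundances, dist, weighted, include_conspecific=False):
    """Explicit double loop over taxon pairs."""
    taxa = [t for t, v in abundances.items() if v > 0]
    num = den = 0.0
    for i in taxa:
        for j in taxa:
            if i == j:
                continue
            w = abundances[i] * abundances[j] if weighted else 1.0
            num += w * dist.distance(i, j)
            den += w
    if weighted and include_conspecific:
        for i in taxa:
            den += abundances[i] * (abundances[i] - 1)
    return num / den


def dpw_oracle(comm_a, comm_b, dist, weighted):
    """Explicit double loop over cross-community pairs (shared taxa count, d=0)."""
    ta = [t for t, v in comm_a.items() if v > 0]
    tb = [t for t, v in comm_b.items() if v > 0]
    num = den = 0.0
    for i in ta:
        for j in tb:
            w = comm_a[i] * comm_b[j] if weighted else 1.0
            num += w * dist.distance(i, j)
            den += w
    return num / den


def exhaustive_ses_p(taxa_count, dist, observed_mpd):
    """Exact one-sided (clustering) p over all same-size presence subsets."""
    n = len(dist.taxa)
    vals = []
    for subset in itertools.combinations(range(n), taxa_count):
        sub = dist.values[np.ix_(subset, subset)]
        iu = np.triu_indices(taxa_count, k=1)
        vals.append(sub[iu].mean())
    vals = np.asarray(vals)
    return (vals <= observed_mpd + 1e-12).mean()


def permanova_exact_p(g, projectors, resid_proj, dfs, df_resid, f_obs):
    """Exact free-permutation p for each term: enumerate all n! row orders."""
    n = g.shape[0]
    count = np.zeros(len(projectors), dtype=int)
    total = 0
    for perm in itertools.permutations(range(n)):
        gp = g[np.ix_(perm, perm)]
        ss = np.array([float(np.sum(p * gp.T)) for p in projectors])
        ss_res = float(np.sum(resid_proj * gp.T))
        f = (ss / dfs) / (ss_res / df_resid)
        count += f >= f_obs - 1e-12
        total += 1
    return count / total
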