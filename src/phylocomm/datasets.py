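"""Bundled example data.

The only bundled file is a *synthetic* stand-in for a composite arthropod
supertree: a Yule topology over 199 taxa whose internal nodes were
collapsed until exactly 79 of the 198 possible relationships (root
excluded) remain resolved — the tip count and resolution of the published
composite supertree this package's analyses are designed around. It is
generated by :func:`phylocomm.synthetic_data.simulate_tree` and carries no
real taxonomy.
"""

from __future__ import annotations

import importlib.resources

import dendropy

from .treeio import parse_newick

__all__ = ["synthetic_supertree", "SYNTHETIC_SUPERTREE_FILE"]

SYNTHETIC_SUPERTREE_FILE = "synthetic_supertree_199.nwk"


def synthetic_supertree() -> dendropy.Tree:
    """Load the bundled synthetic 199-tip, 79/198-resolved supertree stand-in.

    Branch lengths are unset (one node step each is the EQUAL scheme's job).
    """
    text = (
        importlib.resources.files("phylocomm")
        .joinpath("data", SYNTHETIC_SUPERTREE_FILE)
        .read_text()
    )
    return parse_newick(text)
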