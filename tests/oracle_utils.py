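"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: loss mapping is done
by exhaustive subset search, motif matching position by position.
"""

from itertools import combinations

import numpy as np

from endosym.oriskew import IUPAC_CODES
from endosym.trees import PhyloTree

_RC = str.maketrans("ACGT", "TGCA")


def brute_force_min_losses(tree: PhyloTree, lost: frozenset) -> tuple[frozenset, int]:
    """Minimum-cardinality branch subsets whose descendant tips equal
    ``lost``; returns (one minimal subset, number of minimal subsets)."""
    branches = list(tree.branches())
    for size in range(len(branches) + 1):
        covers = [
            combo
            for combo in combinations(branches, size)
            if frozenset().union(*combo) == lost
        ] if size else ([()] if not lost else [])
        if covers:
            return frozenset(covers[0]), len(covers)
    raise AssertionError("no cover found")


def random_rooted_tree(rng: np.random.Generator, n_tips: int) -> PhyloTree:
    """Random topology by sequential pairwise joining."""
    nodes = [f"t{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a}:1,{b}:1)")
    return PhyloTree.from_newick(nodes[0] + ";")


def naive_iupac_hits(seq: str, pattern: str, circular: bool, both: bool):
    """Position-by-position degenerate matcher."""
    seq = seq.upper()
    m = len(pattern)
    L = len(seq)
    text = seq + seq[: m - 1] if circular else seq
    span = L if circular else L - m + 1

    def matches(window: str, pat: str) -> bool:
        return all(w in IUPAC_CODES[p] for w, p in zip(window, pat))

    rc_pat = pattern.upper().translate(
        str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
    )[::-1]
    hits = []
    for i in range(max(span, 0)):
        window = text[i : i + m]
        if matches(window, pattern.upper()):
            hits.append((i + 1, "+"))
        if both and matches(window.translate(_RC)[::-1], pattern.upper()):
            hits.append((i + 1, "-"))
    return sorted(hits)


def dollo_canonical(tree: PhyloTree, losses) -> bool:
    """True when the loss events are exactly the maximal all-lost clades
    (the identifiability condition for exact recovery): fails when e.g. two
    sister branches both lose, which parsimony merges into their parent."""
    losses = set(losses)
    if not losses:
        return True
    lost_tips = frozenset().union(*losses)
    maximal = {
        c
        for c in tree.branches()
        if c <= lost_tips and not (tree.parent(c) or tree.root) <= lost_tips
    }
    return maximal == losses
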