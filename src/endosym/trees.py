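"""Rooted species trees with branches identified by their descendant clade.

Loss events, inversion events and ancestral-state arguments all refer to
branches.  A branch is named by the clade (frozenset of tip names) below its
child node, which is stable under tip reordering and does not depend on any
internal node labels in the input Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import dendropy

__all__ = ["PhyloTree", "Clade", "branch_label"]

#: A branch / node identifier: the set of tip names below it.
Clade = frozenset


def branch_label(clade: Clade) -> str:
    """Human-readable label for a branch: tip name, or ``stem(<tips>)``."""
    tips = sorted(clade)
    if len(tips) == 1:
        return tips[0]
    return "stem(" + ",".join(tips) + ")"


@dataclass(frozen=True)
class PhyloTree:
    """Immutable rooted tree over named tips.

    ``children`` maps each internal clade to its child clades; ``lengths``
    maps each non-root clade to the length of the branch above it (None when
    the source tree carried no lengths).
    """

    taxa: frozenset[str]
    children: dict[Clade, tuple[Clade, ...]]
    lengths: dict[Clade, float | None]

    # -- construction ----------------------------------------------------

    @classmethod
    def from_newick(
        cls, source: str | Path, allow_polytomy_root: bool = False
    ) -> "PhyloTree":
        """Parse a rooted Newick tree.

        A basal polytomy (three or more children at the root) is taken as an
        unrooted tree and rejected unless ``allow_polytomy_root`` is set; the
        caller should root it on an outgroup first.
        """
        text = str(source)
        if isinstance(source, Path) or (
            "(" not in text and Path(text).exists()
        ):
            text = Path(source).read_text()
        tree = dendropy.Tree.get(data=text, schema="newick")
        root_children = tree.seed_node.child_nodes()
        if len(root_children) > 2 and not allow_polytomy_root:
            raise ValueError(
                "tree has a basal polytomy and is treated as unrooted; "
                "root it via an outgroup (or pass allow_polytomy_root=True)"
            )
        if len(root_children) < 2 and tree.seed_node.is_leaf():
            raise ValueError("tree has no internal structure")

        children: dict[Clade, tuple[Clade, ...]] = {}
        lengths: dict[Clade, float | None] = {}

        def build(node: dendropy.Node) -> Clade:
            if node.is_leaf():
                name = node.taxon.label if node.taxon else node.label
                if not name:
                    raise ValueError("unnamed tip in tree")
                clade = frozenset({name.replace(" ", "_")})
            else:
                kids = tuple(build(c) for c in node.child_nodes())
                clade = frozenset().union(*kids)
                children[clade] = kids
            if node.parent_node is not None:
                lengths[clade] = node.edge.length
            return clade

        root = build(tree.seed_node)
        if len(root) != sum(1 for _ in tree.leaf_node_iter()):
            raise ValueError("duplicate tip names in tree")
        return cls(taxa=root, children=children, lengths=lengths)

    # -- structure -------------------------------------------------------

    @property
    def root(self) -> Clade:
        return self.taxa

    def branches(self) -> tuple[Clade, ...]:
        """All branches (every clade except the root), tips included."""
        out = [frozenset({t}) for t in sorted(self.taxa)]
        out.extend(c for c in self.children if c != self.root)
        return tuple(out)

    def postorder(self) -> Iterator[Clade]:
        def walk(clade: Clade) -> Iterator[Clade]:
            for child in self.children.get(clade, ()):
                yield from walk(child)
            yield clade

        return walk(self.root)

    def preorder(self) -> Iterator[Clade]:
        def walk(clade: Clade) -> Iterator[Clade]:
            yield clade
            for child in self.children.get(clade, ()):
                yield from walk(child)

        return walk(self.root)

    def parent(self, clade: Clade) -> Clade | None:
        for parent, kids in self.children.items():
            if clade in kids:
                return parent
        return None

    def mrca(self, tips: Iterable[str]) -> Clade:
        tips = frozenset(tips)
        if not tips <= self.taxa:
            raise KeyError(f"unknown tips: {sorted(tips - self.taxa)}")
        best = self.root
        for clade in self.postorder():
            if tips <= clade and len(clade) < len(best):
                best = clade
        return best

    def is_ancestor(self, a: Clade, b: Clade) -> bool:
        """True iff branch ``a`` is a proper ancestor of branch ``b``."""
        return b < a

    def length(self, clade: Clade) -> float:
        value = self.lengths.get(clade)
        return 1.0 if value is None else value

    def depth_to_tip(self, clade: Clade, tip: str) -> float:
        """Sum of branch lengths strictly below ``clade`` down to ``tip``."""
        if tip not in clade:
            raise KeyError(f"{tip} not under {branch_label(clade)}")
        total = 0.0
        current = clade
        while len(current) > 1:
            current = next(c for c in self.children[current] if tip in c)
            total += self.length(current)
        return total

    def to_newick(self) -> str:
        def render(clade: Clade) -> str:
            if len(clade) == 1:
                body = next(iter(clade))
            else:
                body = "(" + ",".join(render(c) for c in self.children[clade]) + ")"
            length = self.lengths.get(clade)
            return body if length is None or clade == self.root else f"{body}:{length}"

        return render(self.root) + ";"
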