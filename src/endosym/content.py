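"""Ancestral gene content and phylogeny-aware loss mapping.

The last common ancestor (LCA) of a set of reduced genomes is reconstructed
with a union rule: the LCA is credited with every gene that is intact (or
frameshifted only within a homopolymer tract) in at least one sampled genome.
The rule assumes genes are effectively never gained after the ancestor —
horizontal transfer is considered negligible in the isolated intracellular
niche these endosymbionts occupy — so any functional copy anywhere must have
been inherited from the ancestor.  Genes observed solely as pseudogenes are
excluded from the reconstruction and reported separately: they were plausibly
present in the ancestor, but the union rule cannot credit them.

Loss events are mapped under Dollo parsimony (single gain, irreversible
loss).  For each gene the unique minimal explanation of the tip pattern is
the set of branches that root the maximal subtrees whose tips are all
non-functional; pseudogene and absent states are treated identically as loss
of function.  A gene with two or more loss events is a parallel loss: the
same gene was lost independently in lineages separated by one that kept it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .matrix import GeneStatus, OrthologMatrix
from .trees import Clade, PhyloTree, branch_label

__all__ = [
    "GeneSet",
    "LcaContent",
    "LossMap",
    "ParallelLossReport",
    "reconstruct_lca",
    "pan_group_content",
    "core_content",
    "map_losses_dollo",
    "find_parallel_losses",
    "partition_gene_sets",
    "loss_table",
]


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene ids (fused units count once)."""

    label: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass(frozen=True)
class LcaContent:
    """Union-rule LCA reconstruction plus the pseudogene-only remainder."""

    lca: GeneSet
    pseudogene_only: GeneSet


def _functional_genes(matrix: OrthologMatrix, taxa: Sequence[str]) -> frozenset[str]:
    func = matrix.functional()[list(taxa)]
    return frozenset(func.index[func.any(axis=1)])


def reconstruct_lca(matrix: OrthologMatrix) -> LcaContent:
    """Union-rule ancestral gene content over all taxa in the matrix.

    Returns the LCA gene set and, separately, genes never observed with a
    functional copy but observed as a pseudogene somewhere (candidate
    ancestral genes the union rule cannot credit).
    """
    if not matrix.genes:
        raise ValueError("empty ortholog matrix")
    lca = _functional_genes(matrix, matrix.taxa)
    pseudo_only = frozenset(
        g
        for g in matrix.genes
        if g not in lca
        and any(matrix.state(g, t) is GeneStatus.PSEUDOGENE for t in matrix.taxa)
    )
    return LcaContent(
        lca=GeneSet("LCA", lca),
        pseudogene_only=GeneSet("pseudogene_only", pseudo_only),
    )


def pan_group_content(matrix: OrthologMatrix, taxa: Iterable[str]) -> GeneSet:
    """Union rule restricted to a taxon subset (the group's pan content)."""
    taxa = list(taxa)
    if not taxa:
        raise ValueError("empty taxon subset")
    unknown = set(taxa) - set(matrix.taxa)
    if unknown:
        raise KeyError(f"unknown taxa: {sorted(unknown)}")
    return GeneSet("pan(" + ",".join(taxa) + ")", _functional_genes(matrix, taxa))


def core_content(matrix: OrthologMatrix) -> GeneSet:
    """Genes functional in every taxon (the strict core)."""
    if not matrix.genes:
        raise ValueError("empty ortholog matrix")
    func = matrix.functional()
    return GeneSet("core", frozenset(func.index[func.all(axis=1)]))


# -- Dollo loss mapping --------------------------------------------------


@dataclass(frozen=True)
class LossMap:
    """Per-gene minimal Dollo loss events on a fixed rooted tree.

    ``events[gene]`` is the set of branches (clades) each carrying one loss;
    genes with no functional copy anywhere are listed in ``excluded`` and
    carry no mapping.  ``patterns`` keeps the observed tip states for
    reporting.
    """

    tree: PhyloTree
    events: Mapping[str, frozenset[Clade]]
    excluded: frozenset[str]
    patterns: Mapping[str, tuple[tuple[str, GeneStatus], ...]]

    def n_events(self, gene: str) -> int:
        return len(self.events[gene])


def dollo_loss_branches(tree: PhyloTree, lost_tips: frozenset[str]) -> frozenset[Clade]:
    """Minimal branch set explaining a loss pattern under Dollo parsimony.

    The answer is the set of maximal clades whose tips are all lost: placing
    one loss on each such branch reproduces exactly ``lost_tips``, any fewer
    events cannot, and the set is unique (no ties are possible).
    """
    if not lost_tips <= tree.taxa:
        raise KeyError(f"unknown tips: {sorted(lost_tips - tree.taxa)}")
    if lost_tips == tree.taxa:
        raise ValueError("pattern lost in every tip: gene has no functional copy")
    events = []
    for clade in tree.branches():
        if clade <= lost_tips:
            parent = tree.parent(clade) or tree.root
            if not parent <= lost_tips:
                events.append(clade)
    return frozenset(events)


def map_losses_dollo(matrix: OrthologMatrix, tree: PhyloTree) -> LossMap:
    """Map minimal loss events for every gene in the matrix.

    Pseudogene and absent states are both loss of function; intact and
    homopolymer-frameshifted states are both retention.  Genes functional
    nowhere are flagged ``excluded`` (no placement is attempted: under
    irreversible loss the gene cannot be polarised without outside data).
    """
    if frozenset(matrix.taxa) != tree.taxa:
        raise ValueError(
            f"tree tips {sorted(tree.taxa)} do not match matrix taxa "
            f"{sorted(matrix.taxa)}"
        )
    events: dict[str, frozenset[Clade]] = {}
    excluded = []
    patterns = {}
    for gene in matrix.genes:
        patterns[gene] = matrix.pattern(gene)
        functional = matrix.functional_taxa(gene)
        if not functional:
            excluded.append(gene)
            continue
        events[gene] = dollo_loss_branches(tree, tree.taxa - functional)
    return LossMap(
        tree=tree,
        events=events,
        excluded=frozenset(excluded),
        patterns=patterns,
    )


@dataclass(frozen=True)
class ParallelLossReport:
    """Genes lost in two or more independent events."""

    genes: tuple[str, ...]
    events: Mapping[str, frozenset[Clade]]
    patterns: Mapping[str, tuple[tuple[str, GeneStatus], ...]]

    def __len__(self) -> int:
        return len(self.genes)


def find_parallel_losses(lossmap: LossMap) -> ParallelLossReport:
    """Select genes whose Dollo mapping needs >= 2 loss events.

    Equivalently: genes lost independently in lineages separated by a
    lineage that retained the gene.
    """
    genes = tuple(
        sorted(g for g, branches in lossmap.events.items() if len(branches) >= 2)
    )
    return ParallelLossReport(
        genes=genes,
        events={g: lossmap.events[g] for g in genes},
        patterns={g: lossmap.patterns[g] for g in genes},
    )


def loss_table(lossmap: LossMap) -> pd.DataFrame:
    """Tabulate loss events: gene, n_events, branches, tip pattern."""
    code = {
        GeneStatus.INTACT: "+",
        GeneStatus.INTACT_FS_HOMOPOLYMER: "fs",
        GeneStatus.PSEUDOGENE: "psi",
        GeneStatus.ABSENT: "-",
    }
    rows = []
    for gene in sorted(lossmap.events):
        branches = lossmap.events[gene]
        rows.append(
            {
                "gene": gene,
                "n_events": len(branches),
                "branches": ";".join(sorted(branch_label(b) for b in branches)),
                "pattern": ",".join(
                    f"{t}={code[s]}" for t, s in lossmap.patterns[gene]
                ),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_events", "branches", "pattern"])


# -- tri-set partition (Venn counts) --------------------------------------


def partition_gene_sets(
    matrix: OrthologMatrix, groups: Mapping[str, Iterable[str]]
) -> dict[frozenset[str], int]:
    """Venn-region counts of functional gene content across taxon groups.

    ``groups`` must partition the matrix taxa.  Each group's content is its
    union-rule (pan) gene set; every gene functional somewhere falls in
    exactly one region, keyed by the frozenset of group labels holding it.
    All 2^k - 1 regions are reported (zero counts included), so for three
    groups the seven regions of the tri-set diagram.
    """
    groups = {label: list(taxa) for label, taxa in groups.items()}
    flat = [t for taxa in groups.values() for t in taxa]
    if len(flat) != len(set(flat)):
        raise ValueError("groups are not disjoint")
    if set(flat) != set(matrix.taxa):
        raise ValueError("groups do not cover the matrix taxa")
    content = {
        label: pan_group_content(matrix, taxa).members for label, taxa in groups.items()
    }
    labels = sorted(groups)
    regions: dict[frozenset[str], int] = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            regions[frozenset(combo)] = 0
    for gene in matrix.genes:
        holders = frozenset(l for l in labels if gene in content[l])
        if holders:
            regions[holders] += 1
    return regions


def venn_counts_json(regions: Mapping[frozenset, int]) -> str:
    """Serialise Venn-region counts with '&'-joined group labels as keys."""
    import json

    return json.dumps(
        {"&".join(sorted(k)): v for k, v in sorted(regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))},
        indent=1,
    )


def single_gain_candidates(lossmap: LossMap) -> tuple[str, ...]:
    """Genes whose pattern would be cheaper under one gain than under the
    inferred losses — a screen for horizontal-transfer candidates.

    Under an irreversible-loss model these genes still count as parallel
    losses; the screen only reports patterns where the functional tips form
    a single clade reachable by one gain, yet Dollo needs >= 2 loss events.
    The screen never alters the loss mapping: transfer into these isolated
    intracellular genomes is considered very unlikely.
    """
    out = []
    for gene, events in lossmap.events.items():
        if len(events) < 2:
            continue
        functional = frozenset(
            t for t, s in lossmap.patterns[gene] if s.functional
        )
        if functional in lossmap.tree.branches():
            out.append(gene)
    return tuple(sorted(out))
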