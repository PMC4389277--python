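"""Gene-level synteny: inverted-block detection and event polarisation.

Synteny is compared on signed gene orders (ortholog id + strand), not on
nucleotide alignments: in heavily reduced genomes the interesting
rearrangements are whole-gene inversions, and lineage-specific gene loss
would fragment nucleotide-level blocks spuriously.  Genes absent from one
of the two genomes are therefore transparent — skipped when testing
contiguity.

An inverted block between genomes ``a`` and ``b`` is a maximal run of
shared genes that is contiguous in both, appears in reversed relative order
in ``b``, and has every member's strand flipped.  Single-gene strand flips
are excluded.  Circular orders are compared modulo rotation.

Events are placed on tree branches by outgroup polarisation: when the
outgroups agree on the ancestral orientation of a region, the inversion is
assigned to the unique branch separating taxa matching that orientation
from those that do not; otherwise the region is INCONCLUSIVE.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genomes import SignedGeneOrder
from .trees import Clade, PhyloTree, branch_label

__all__ = [
    "InversionRegion",
    "CatalogRegion",
    "BranchAssignment",
    "find_inverted_blocks",
    "merge_regions",
    "region_orientation",
    "assign_inversion_branch",
]

INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class InversionRegion:
    """One inverted block from a pairwise comparison."""

    genes: tuple[str, ...]  # in reference (a) order
    taxon: str  # the genome in which the block is inverted relative to a

    @property
    def gene_count(self) -> int:
        return len(self.genes)

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("inversion regions need >= 2 genes")


def _shared_signed(
    a: SignedGeneOrder, b: SignedGeneOrder
) -> tuple[list[tuple[str, str]], dict[str, int], dict[str, str]]:
    shared = set(a.ids) & set(b.ids)
    a_shared = [(g, s) for g, s in a.order if g in shared]
    b_pos = {}
    b_strand = {}
    i = 0
    for g, s in b.order:
        if g in shared:
            b_pos[g] = i
            b_strand[g] = s
            i += 1
    return a_shared, b_pos, b_strand


def find_inverted_blocks(
    a: SignedGeneOrder, b: SignedGeneOrder
) -> list[InversionRegion]:
    """Maximal inverted blocks of ``b`` relative to reference ``a``.

    Unshared genes are transparent.  A block must be contiguous in both
    shared orders, reversed in relative order, and strand-flipped for every
    member; blocks of a single gene are not reported.
    """
    a_shared, b_pos, b_strand = _shared_signed(a, b)
    n = len(a_shared)
    if n < 2:
        raise ValueError(f"orders share only {n} ortholog(s)")
    circular = a.circular and b.circular

    flipped = [b_strand[g] != s for g, s in a_shared]

    def linked(i: int, j: int) -> bool:
        """Adjacent (in a) flipped genes i -> j continue one inverted run."""
        gi, gj = a_shared[i][0], a_shared[j][0]
        if circular:
            return (b_pos[gi] - b_pos[gj]) % n == 1
        return b_pos[gj] == b_pos[gi] - 1

    # maximal runs of flipped genes linked consecutively
    indices = range(n)
    pairs = [
        (i, (i + 1) % n)
        for i in (indices if circular else range(n - 1))
        if flipped[i] and flipped[(i + 1) % n] and linked(i, (i + 1) % n)
    ]
    succ = {i: j for i, j in pairs}
    pred = {j: i for i, j in pairs}
    regions = []
    if len(succ) == n and circular:  # whole shared order inverted
        genes = tuple(g for g, _ in a_shared)
        return [InversionRegion(genes=genes, taxon=b.taxon)]
    starts = [i for i in succ if i not in pred]
    for start in starts:
        run = [start]
        while run[-1] in succ:
            run.append(succ[run[-1]])
        genes = tuple(a_shared[i][0] for i in run)
        regions.append(InversionRegion(genes=genes, taxon=b.taxon))
    regions.sort(key=lambda r: [g for g, _ in a_shared].index(r.genes[0]))
    return regions


@dataclass(frozen=True)
class CatalogRegion:
    """A merged inversion region across >= 2 genomes.

    ``states`` maps taxon -> "reference" / "inverted" / "missing";
    ``multi_event`` flags regions whose per-taxon inverted gene sets differ
    (candidate inversion hotspots with several separate events).
    """

    label: str
    genes: tuple[str, ...]  # in reference order
    states: Mapping[str, str]
    multi_event: bool = False

    @property
    def gene_count(self) -> int:
        return len(self.genes)


def merge_regions(
    reference: SignedGeneOrder,
    others: Sequence[SignedGeneOrder],
    regions_by_taxon: Mapping[str, Sequence[InversionRegion]] | None = None,
) -> list[CatalogRegion]:
    """Build the region catalog from pairwise comparisons to one reference.

    Overlapping pairwise regions are merged by ortholog-set union; regions
    are labelled A, B, ... by position along the reference.  Per taxon the
    orientation state is "inverted" if that taxon has an inverted block
    intersecting the region, "missing" if it carries none of the region's
    genes, else "reference".
    """
    if regions_by_taxon is None:
        regions_by_taxon = {
            o.taxon: find_inverted_blocks(reference, o) for o in others
        }
    order_by_taxon = {o.taxon: o for o in others}

    # union-find over genes that co-occur in any pairwise region
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    all_regions = [r for rs in regions_by_taxon.values() for r in rs]
    for r in all_regions:
        for g in r.genes:
            union(r.genes[0], g)
    components: dict[str, set[str]] = {}
    for g in parent:
        components.setdefault(find(g), set()).add(g)

    ref_index = {g: i for i, (g, _) in enumerate(reference.order)}
    catalog = []
    sorted_components = sorted(
        components.values(),
        key=lambda genes: min(ref_index.get(g, len(ref_index)) for g in genes),
    )
    labels = list(string.ascii_uppercase)
    for i, genes in enumerate(sorted_components):
        ordered = tuple(sorted(genes, key=lambda g: ref_index.get(g, len(ref_index))))
        states = {reference.taxon: "reference"}
        inverted_sets = []
        for taxon, regions in regions_by_taxon.items():
            mine = [r for r in regions if set(r.genes) & genes]
            if mine:
                states[taxon] = "inverted"
                inverted_sets.append(frozenset().union(*(set(r.genes) for r in mine)))
            elif taxon in order_by_taxon and not (
                set(order_by_taxon[taxon].ids) & genes
            ):
                states[taxon] = "missing"
            else:
                states[taxon] = "reference"
        multi = len(set(inverted_sets)) > 1
        label = labels[i] if i < len(labels) else f"R{i + 1}"
        catalog.append(
            CatalogRegion(label=label, genes=ordered, states=states, multi_event=multi)
        )
    return catalog


def region_orientation(
    region_genes: Sequence[str], reference: SignedGeneOrder, other: SignedGeneOrder
) -> str:
    """Orientation of a region in ``other`` relative to the reference.

    "reference": same relative order and strands; "inverted": reversed
    order with flipped strands; "missing": no region gene present;
    "unresolved": anything else (rearranged within the region).  A single
    shared gene is polarised by strand alone.
    """
    shared = [g for g in region_genes if g in set(other.ids)]
    if not shared:
        return "missing"
    ref_strand = {g: reference.strand(g) for g in shared}
    oth_strand = {g: other.strand(g) for g in shared}
    if len(shared) == 1:
        g = shared[0]
        return "reference" if ref_strand[g] == oth_strand[g] else "inverted"
    pos = [other.position(g) for g in shared]
    same_strands = all(ref_strand[g] == oth_strand[g] for g in shared)
    flipped_strands = all(ref_strand[g] != oth_strand[g] for g in shared)
    ascending = all(b > a for a, b in zip(pos, pos[1:]))
    descending = all(b < a for a, b in zip(pos, pos[1:]))
    if same_strands and ascending:
        return "reference"
    if flipped_strands and descending:
        return "inverted"
    return "unresolved"


@dataclass(frozen=True)
class BranchAssignment:
    """Placement of one inversion event, or INCONCLUSIVE."""

    region: str
    branch: Clade | None
    ancestral_state: str | None
    outgroup_states: Mapping[str, str]

    @property
    def conclusive(self) -> bool:
        return self.branch is not None

    def describe(self) -> str:
        if not self.conclusive:
            return f"{self.region}: {INCONCLUSIVE}"
        return f"{self.region}: {branch_label(self.branch)}"


def assign_inversion_branch(
    region: CatalogRegion,
    tree: PhyloTree,
    reference: SignedGeneOrder,
    outgroup_orders: Iterable[SignedGeneOrder],
) -> BranchAssignment:
    """Polarise one region with outgroups and place the event on a branch.

    The ancestral orientation is the outgroup consensus (all covering
    outgroups must agree and at least one must cover the region).  The event
    goes on the branch whose descendant tips are exactly the ingroup taxa in
    the derived orientation; if no such single branch exists the region is
    INCONCLUSIVE.
    """
    out_states = {
        o.taxon: region_orientation(region.genes, reference, o)
        for o in outgroup_orders
    }
    informative = {t: s for t, s in out_states.items() if s in ("reference", "inverted")}
    if not informative or len(set(informative.values())) != 1:
        return BranchAssignment(region.label, None, None, out_states)
    ancestral = next(iter(informative.values()))

    known = {t: s for t, s in region.states.items() if s in ("reference", "inverted")}
    derived = frozenset(t for t, s in known.items() if s != ancestral)
    if not derived or not derived <= tree.taxa:
        return BranchAssignment(region.label, None, ancestral, out_states)
    candidates = [
        clade
        for clade in tree.branches()
        if clade & frozenset(known) == derived
    ]
    if len(candidates) != 1:
        # several nested branches can imply the same split when some taxa
        # are missing; the event is then not uniquely placeable
        if not candidates:
            return BranchAssignment(region.label, None, ancestral, out_states)
        candidates.sort(key=len)
        if len(candidates) > 1 and len(candidates[0]) != len(candidates[1]):
            # prefer the smallest clade only when it is unambiguous (all
            # larger candidates differ solely by taxa with unknown state)
            return BranchAssignment(
                region.label, candidates[0], ancestral, out_states
            )
        return BranchAssignment(region.label, None, ancestral, out_states)
    return BranchAssignment(region.label, candidates[0], ancestral, out_states)
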