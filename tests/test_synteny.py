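"""Inverted-block detection, region merging and branch assignment."""

import numpy as np
import pytest

from endosym.genomes import SignedGeneOrder
from endosym.synteny import (
    assign_inversion_branch,
    find_inverted_blocks,
    merge_regions,
    region_orientation,
)
from endosym.simulate import (
    apply_inversions,
    blochmannia_tree,
    simulate_inversion_dataset,
)


def order(taxon, genes, circular=False):
    return SignedGeneOrder(taxon, tuple(genes), circular=circular)


A5 = order("a", [("g1", "+"), ("g2", "+"), ("g3", "+"), ("g4", "+"), ("g5", "+")])


def test_identical_orders_have_no_blocks():
    assert find_inverted_blocks(A5, order("b", A5.order)) == []


def test_definitional_three_gene_inversion():
    b = order("b", [("g1", "+"), ("g4", "-"), ("g3", "-"), ("g2", "-"), ("g5", "+")])
    regions = find_inverted_blocks(A5, b)
    assert len(regions) == 1
    assert regions[0].genes == ("g2", "g3", "g4")
    assert regions[0].gene_count == 3


def test_single_gene_strand_flip_excluded():
    b = order("b", [("g1", "+"), ("g2", "-"), ("g3", "+"), ("g4", "+"), ("g5", "+")])
    assert find_inverted_blocks(A5, b) == []


def test_unshared_genes_are_transparent():
    # b lost g3; g2..g4 still read as one inverted run over shared genes
    b = order("b", [("g1", "+"), ("g4", "-"), ("g2", "-"), ("g5", "+")])
    regions = find_inverted_blocks(A5, b)
    assert [r.genes for r in regions] == [("g2", "g4")]


def test_too_few_shared_orthologs_rejected():
    with pytest.raises(ValueError, match="share"):
        find_inverted_blocks(A5, order("b", [("g1", "+"), ("zz", "+")]))


def test_applying_detected_inversion_restores_collinearity():
    b = order("b", [("g1", "+"), ("g4", "-"), ("g3", "-"), ("g2", "-"), ("g5", "+")])
    region = find_inverted_blocks(A5, b)[0]
    idx = [i for i, (g, _) in enumerate(b.order) if g in region.genes]
    flip = {"+": "-", "-": "+"}
    fixed = list(b.order)
    fixed[idx[0] : idx[-1] + 1] = [
        (g, flip[s]) for g, s in reversed(fixed[idx[0] : idx[-1] + 1])
    ]
    assert tuple(fixed) == A5.order
    assert find_inverted_blocks(A5, order("b", fixed)) == []


def test_planted_inversions_recovered_exactly_over_replicates():
    """2-5 disjoint planted inversions on 100-gene circular genomes must be
    recovered with exact gene sets in every replicate."""
    for seed in range(25):
        rng = np.random.default_rng(seed)
        n_events = int(rng.integers(2, 6))
        orders, outgroup, truth = simulate_inversion_dataset(
            rng, n_genes=100, n_events=n_events
        )
        planted = {frozenset(ev["genes"]) for ev in truth.inversions}
        found = set()
        for taxon, o in orders.items():
            for r in find_inverted_blocks(outgroup, o):
                found.add(frozenset(r.genes))
        assert found == planted


def test_merge_regions_catalogs_disjoint_regions_alphabetically():
    ref = A5
    b = order("b", [("g1", "+"), ("g3", "-"), ("g2", "-"), ("g4", "+"), ("g5", "+")])
    c = order("c", [("g1", "+"), ("g2", "+"), ("g3", "+"), ("g5", "-"), ("g4", "-")])
    catalog = merge_regions(ref, [b, c])
    assert [r.label for r in catalog] == ["A", "B"]
    assert catalog[0].genes == ("g2", "g3")
    assert catalog[1].genes == ("g4", "g5")
    assert catalog[0].states == {"a": "reference", "b": "inverted", "c": "reference"}
    assert not catalog[0].multi_event


def test_overlapping_regions_merge_and_flag_multiple_events():
    ref = order("ref", [(f"g{i}", "+") for i in range(1, 11)])
    # taxon b inverts g2..g6; taxon c inverts g4..g8 -> one merged hotspot
    b_order = list(ref.order)
    b_order[1:6] = [(g, "-") for g, _ in reversed(b_order[1:6])]
    c_order = list(ref.order)
    c_order[3:8] = [(g, "-") for g, _ in reversed(c_order[3:8])]
    catalog = merge_regions(ref, [order("b", b_order), order("c", c_order)])
    assert len(catalog) == 1
    assert catalog[0].genes == tuple(f"g{i}" for i in range(2, 9))
    assert catalog[0].multi_event


def test_region_orientation_states():
    ref = A5
    inv = order("x", [("g1", "+"), ("g4", "-"), ("g3", "-"), ("g2", "-"), ("g5", "+")])
    assert region_orientation(("g2", "g3", "g4"), ref, inv) == "inverted"
    assert region_orientation(("g2", "g3", "g4"), ref, ref) == "reference"
    assert region_orientation(("g2", "g3"), ref, order("y", [("g9", "+")])) == "missing"
    scrambled = order("z", [("g3", "+"), ("g1", "+"), ("g2", "-"), ("g4", "+")])
    assert region_orientation(("g2", "g3", "g4"), ref, scrambled) == "unresolved"


def test_event_assigned_to_terminal_branch_when_one_taxon_inverted():
    tree = blochmannia_tree()
    rng = np.random.default_rng(11)
    root = order("root", [(f"g{i}", "+") for i in range(1, 21)], circular=True)
    events = [(frozenset({"obliquus"}), 4, 9)]
    orders, truth = apply_inversions(tree, root, events)
    ref = orders["pennsylvanicus"]
    catalog = merge_regions(ref, [orders[t] for t in orders if t != ref.taxon])
    assert len(catalog) == 1
    outgroup = order("out", root.order, circular=True)
    assignment = assign_inversion_branch(catalog[0], tree, ref, [outgroup])
    assert assignment.branch == frozenset({"obliquus"})


def test_event_assigned_to_stem_branch_of_derived_clade():
    tree = blochmannia_tree()
    root = order("root", [(f"g{i}", "+") for i in range(1, 21)], circular=True)
    stem = frozenset({"turneri", "vafer", "floridanus", "pennsylvanicus"})
    orders, _ = apply_inversions(tree, root, [(stem, 10, 14)])
    ref = orders["pennsylvanicus"]
    catalog = merge_regions(ref, [orders[t] for t in orders if t != ref.taxon])
    outgroup = order("out", root.order, circular=True)
    assignment = assign_inversion_branch(catalog[0], tree, ref, [outgroup])
    assert assignment.branch == stem
    # reference itself carries the inversion: ancestral state is "inverted"
    assert assignment.ancestral_state == "inverted"


def test_disagreeing_outgroups_are_inconclusive():
    tree = blochmannia_tree()
    root = order("root", [(f"g{i}", "+") for i in range(1, 21)], circular=True)
    orders, _ = apply_inversions(tree, root, [(frozenset({"obliquus"}), 4, 9)])
    ref = orders["pennsylvanicus"]
    catalog = merge_regions(ref, [orders[t] for t in orders if t != ref.taxon])
    out1 = order("out1", root.order, circular=True)
    out2 = order("out2", orders["obliquus"].order, circular=True)
    assignment = assign_inversion_branch(catalog[0], tree, ref, [out1, out2])
    assert not assignment.conclusive
    assert assignment.branch is None


def test_region_absent_from_outgroups_is_inconclusive_not_error():
    tree = blochmannia_tree()
    root = order("root", [(f"g{i}", "+") for i in range(1, 21)], circular=True)
    orders, _ = apply_inversions(tree, root, [(frozenset({"obliquus"}), 4, 9)])
    ref = orders["pennsylvanicus"]
    catalog = merge_regions(ref, [orders[t] for t in orders if t != ref.taxon])
    bare = order("out", [("x1", "+"), ("x2", "+")], circular=True)
    assignment = assign_inversion_branch(catalog[0], tree, ref, [bare])
    assert not assignment.conclusive


def test_simulated_branches_recovered_with_informative_outgroup():
    hits = 0
    total = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        orders, outgroup, truth = simulate_inversion_dataset(rng, n_events=2)
        tree = blochmannia_tree()
        ref = orders["pennsylvanicus"]
        others = [orders[t] for t in orders if t != ref.taxon]
        catalog = merge_regions(ref, others)
        truth_by_genes = {frozenset(ev["genes"]): ev["branch"] for ev in truth.inversions}
        for region in catalog:
            branch = truth_by_genes[frozenset(region.genes)]
            assignment = assign_inversion_branch(region, tree, ref, [outgroup])
            total += 1
            if assignment.conclusive:
                assert assignment.branch == branch
                hits += 1
    assert total == 40
    assert hits == total  # disjoint events + ancestral outgroup are informative
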