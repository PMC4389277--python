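"""Synthetic endosymbiont datasets with ground-truth event logs.

The generator produces inputs with the statistical structure the analyses
assume, together with a :class:`TruthLog` that fully explains each dataset:

* gene content evolved by irreversible (Dollo) loss along a fixed rooted
  tree, with per-branch loss probabilities and pseudogene observability
  decaying exponentially with time since loss (recent losses are still
  detectable as pseudogenes, old losses leave no trace);
* circular genomes with two replichores of opposite G/C bias switching at a
  planted origin and terminus, AT-rich overall (GC ~ 0.27-0.30 as in these
  endosymbionts), with codon-aware genes and replication-initiator (DnaA)
  boxes planted in the intergenic flanks of an anchor gene at the origin;
* pseudogenized gene copies with exact requested lesion counts; and
* gene-order inversions applied on known branches.

Every stochastic routine takes a :class:`numpy.random.Generator`; a fixed
seed reproduces every dataset bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomes import Feature, Genome, SignedGeneOrder
from .matrix import GeneStatus, OrthologMatrix
from .oriskew import IUPAC_CODES, MotifPattern, scan_iupac
from .pseudogenes import _homopolymer_run_at
from .trees import Clade, PhyloTree, branch_label

__all__ = [
    "TruthLog",
    "blochmannia_tree",
    "simulate_gene_content",
    "simulate_genome",
    "mutate_to_pseudogene",
    "apply_inversions",
    "simulate_inversion_dataset",
]

#: Study tree: the deepest split isolates obliquus; turneri is sister to the
#: three (collapsed) Camponotus lineages.  Lengths approximate the relative
#: depths of the published phylogeny and act as time units for pseudogene
#: decay.
_STUDY_NEWICK = (
    "(obliquus:1.0,(turneri:0.7,(vafer:0.4,"
    "(floridanus:0.25,pennsylvanicus:0.25):0.15):0.3):0.3);"
)


def blochmannia_tree() -> PhyloTree:
    """The six-taxon study topology (chromaiodes aliased onto
    pennsylvanicus, whose gene content it shares)."""
    return PhyloTree.from_newick(_STUDY_NEWICK)


@dataclass
class TruthLog:
    """Ground truth for one simulated dataset."""

    loss_branches: dict[str, tuple[Clade, ...]] = field(default_factory=dict)
    tip_states: dict[str, dict[str, str]] = field(default_factory=dict)
    origin_position: int | None = None
    terminus_position: int | None = None
    motif_positions: tuple[tuple[int, str], ...] = ()
    inversions: tuple[dict, ...] = ()
    lesions: tuple[dict, ...] = ()
    gene_order: tuple[tuple[str, str], ...] = ()

    def to_json(self, path) -> None:
        payload = {
            "loss_branches": {
                g: [sorted(c) for c in clades]
                for g, clades in self.loss_branches.items()
            },
            "tip_states": self.tip_states,
            "origin_position": self.origin_position,
            "terminus_position": self.terminus_position,
            "motif_positions": list(self.motif_positions),
            "inversions": [
                {**ev, "branch": sorted(ev["branch"])} for ev in self.inversions
            ],
            "lesions": list(self.lesions),
            "gene_order": list(self.gene_order),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# -- gene content under Dollo loss ----------------------------------------


def simulate_gene_content(
    tree: PhyloTree,
    n_genes: int,
    loss_prob: float | Mapping[Clade, float] = 0.05,
    pseudogene_half_life: float = 1.0,
    fs_homopolymer_prob: float = 0.01,
    rng: np.random.Generator | None = None,
) -> tuple[OrthologMatrix, TruthLog]:
    """Evolve presence/absence of ``n_genes`` down the tree.

    Every gene is present at the root.  On each branch a still-functional
    gene is lost with the branch's probability, at a uniform point along the
    branch.  A lost gene is observed at a tip as a PSEUDOGENE with
    probability exp(-t / half_life), t the time from the loss point to the
    tip, else ABSENT.  Functional tips are INTACT, or (with a small
    probability) INTACT_FS_HOMOPOLYMER.
    """
    rng = rng or np.random.default_rng(0)
    if isinstance(loss_prob, Mapping):
        probs = {b: float(loss_prob.get(b, 0.0)) for b in tree.branches()}
    else:
        probs = {b: float(loss_prob) for b in tree.branches()}
    if any(not 0.0 <= p <= 1.0 for p in probs.values()):
        raise ValueError("loss probabilities must lie in [0, 1]")
    if pseudogene_half_life <= 0:
        raise ValueError("pseudogene half-life must be positive")

    taxa = sorted(tree.taxa)
    gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    states: dict[str, list[GeneStatus]] = {}
    truth = TruthLog()

    for gene in gene_ids:
        losses: list[Clade] = []
        time_lost: dict[str, float] = {}  # tip -> time since loss

        def walk(clade: Clade, functional: bool, since_loss: float) -> None:
            for child in tree.children.get(clade, ()):
                child_len = tree.length(child)
                child_functional = functional
                child_since = since_loss + child_len if not functional else 0.0
                if functional and rng.random() < probs[child]:
                    losses.append(child)
                    child_functional = False
                    child_since = child_len * float(rng.random())
                if len(child) == 1:
                    tip = next(iter(child))
                    if not child_functional:
                        time_lost[tip] = child_since
                else:
                    walk(child, child_functional, child_since)

        walk(tree.root, True, 0.0)
        row = []
        for t in taxa:
            if t in time_lost:
                p_obs = float(np.exp(-time_lost[t] / pseudogene_half_life))
                row.append(
                    GeneStatus.PSEUDOGENE
                    if rng.random() < p_obs
                    else GeneStatus.ABSENT
                )
            else:
                row.append(
                    GeneStatus.INTACT_FS_HOMOPOLYMER
                    if rng.random() < fs_homopolymer_prob
                    else GeneStatus.INTACT
                )
        states[gene] = row
        truth.loss_branches[gene] = tuple(losses)
        truth.tip_states[gene] = {
            t: s.value for t, s in zip(taxa, row)
        }

    matrix = OrthologMatrix(
        pd.DataFrame.from_dict(states, orient="index", columns=taxa)
    )
    return matrix, truth


# -- genomes with skewed replichores and planted motifs -------------------


def _base_probs(gc: float, amp: float, leading: bool) -> np.ndarray:
    """Forward-strand base probabilities (A, C, G, T) for one replichore."""
    sign = 1.0 if leading else -1.0
    g = gc / 2 * (1 + sign * amp)
    c = gc / 2 * (1 - sign * amp)
    at = (1 - gc) / 2
    return np.array([at, c, g, at])


_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


def _random_bases(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=probs / probs.sum())])


def _random_gene(rng: np.random.Generator, n_codons: int, probs: np.ndarray) -> str:
    """Codon-aware gene: ATG start, no internal stops, TAA stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_bases(rng, 3, probs)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def instantiate_motif(rng: np.random.Generator, pattern: str) -> str:
    """One concrete sequence drawn uniformly from an IUPAC pattern."""
    return "".join(
        IUPAC_CODES[ch][rng.integers(len(IUPAC_CODES[ch]))] for ch in pattern.upper()
    )


def simulate_genome(
    rng: np.random.Generator,
    order: SignedGeneOrder | None = None,
    taxon: str = "sim",
    n_genes: int = 40,
    genome_length: int = 60_000,
    gene_length_range: tuple[int, int] = (300, 1200),
    gc_content: float = 0.28,
    skew_amplitude: float = 0.6,
    motif: str = "TTWTNCACA",
    n_boxes_upstream: int = 2,
    n_boxes_downstream: int = 0,
    terminus_fraction: float = 0.5,
) -> tuple[Genome, TruthLog]:
    """Build a circular genome with two-replichore skew structure.

    The origin sits at position 1 (the boundary upstream of the first gene,
    the "anchor"); the terminus at ``terminus_fraction`` of the length.  The
    forward strand is G-rich on the first replichore and C-rich on the
    second.  DnaA-box motifs are planted in the anchor's intergenic flanks
    at recorded positions, and accidental extra matches in those flanks are
    scrubbed so the flank hit count equals the planted count.
    """
    if order is None:
        ids = [f"g{i + 1:03d}" for i in range(n_genes)]
        strands = ["+" if rng.random() < 0.5 else "-" for _ in ids]
        order = SignedGeneOrder(
            taxon=taxon, order=tuple(zip(ids, strands)), circular=True
        )
    genes = order.order
    lo, hi = gene_length_range
    lengths = [int(rng.integers(lo // 3, hi // 3 + 1)) * 3 for _ in genes]
    coding = sum(lengths)
    n = len(genes)
    spare = genome_length - coding
    if spare < 60 * (n + 1):
        raise ValueError(
            f"cannot pack {n} genes of {coding} bp into {genome_length} bp"
        )
    # one intergenic gap before each gene plus a closing gap; >= 60 bp each
    cuts = np.sort(rng.choice(spare - 60 * (n + 1), size=n, replace=False))
    gaps = np.diff(np.concatenate([[0], cuts, [spare - 60 * (n + 1)]])) + 60

    terminus = int(genome_length * terminus_fraction)

    def probs_at(pos: int, strand: str = "+") -> np.ndarray:
        leading = pos < terminus
        p = _base_probs(gc_content, skew_amplitude, leading)
        if strand == "-":
            p = p[::-1]  # complement: swap A/T and C/G probabilities
        return p

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0  # 0-based running coordinate
    for (gid, strand), glen, gap in zip(genes, lengths, gaps[:-1]):
        parts.append(_random_bases(rng, int(gap), probs_at(pos)))
        pos += int(gap)
        seq = _random_gene(rng, glen // 3, probs_at(pos, strand))
        if strand == "-":
            seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        parts.append(seq)
        features.append(
            Feature(
                id=gid,
                type="CDS",
                start=pos + 1,
                end=pos + glen,
                strand=strand,
                qualifiers={"gene": gid},
            )
        )
        pos += glen
    parts.append(_random_bases(rng, int(gaps[-1]), probs_at(pos)))
    sequence = list("".join(parts))
    assert len(sequence) == genome_length

    # plant boxes in the anchor's flanks: upstream = [1 .. first gene start),
    # downstream = (first gene end .. second gene start)
    anchor = features[0]
    pattern = MotifPattern(motif)
    m = len(pattern)
    planted: list[tuple[int, str]] = []

    def plant(region_start0: int, region_end0: int, count: int) -> None:
        # region is 0-based half-open; place non-overlapping instances
        width = region_end0 - region_start0
        if count == 0:
            return
        if width < count * (m + 2):
            raise ValueError("flank too short for requested boxes")
        slots = np.sort(rng.choice(width - count * m, size=count, replace=False))
        for k, slot in enumerate(slots):
            at = region_start0 + int(slot) + k * m
            inst = instantiate_motif(rng, motif)
            sequence[at : at + m] = list(inst)
            planted.append((at + 1, "+"))

    up_region = (0, anchor.start - 1)
    second = features[1] if len(features) > 1 else None
    down_region = (anchor.end, (second.start - 1) if second else genome_length)
    plant(*up_region, n_boxes_upstream)
    plant(*down_region, n_boxes_downstream)

    # scrub accidental matches anywhere in the two full intergenic flanks
    # (the upstream flank wraps through the circular junction)
    L = genome_length
    planted_spans = [(p - 1, p - 1 + m) for p, _ in planted]
    planted_starts = {p - 1 for p, _ in planted}
    last_end0 = features[-1].end
    flanks = [
        (last_end0 % L, (anchor.start - 1 - last_end0) % L),  # upstream
        (anchor.end, ((second.start - 1 - anchor.end) % L) if second else L - anchor.end),
    ]
    for start0, width in flanks:
        for _ in range(20):
            sub = "".join(sequence[(start0 + k) % L] for k in range(width))
            extras = [
                h
                for h in scan_iupac(sub, pattern, circular=False)
                if (start0 + h.position - 1) % L not in planted_starts
            ]
            if not extras:
                break
            for h in extras:
                at = (start0 + h.position - 1) % L
                for off in range(m):
                    idx = (at + off) % L
                    if not any(s <= idx < e for s, e in planted_spans):
                        sequence[idx] = "C" if sequence[idx] != "C" else "G"
                        break

    genome = Genome(
        id=taxon, seq="".join(sequence), features=tuple(features), circular=True
    )
    truth = TruthLog(
        origin_position=1,
        terminus_position=terminus + 1,
        motif_positions=tuple(planted),
        gene_order=tuple(genes),
    )
    return genome, truth


# -- pseudogenization ------------------------------------------------------


def mutate_to_pseudogene(
    seq: str,
    n_nonsense: int = 0,
    n_frameshifts: int = 0,
    homopolymer_only: bool = False,
    rng: np.random.Generator | None = None,
    min_run: int = 4,
) -> tuple[str, tuple[dict, ...]]:
    """Plant exact lesion counts in a codon-aware gene sequence.

    Nonsense lesions substitute internal codons with stops; frameshifts are
    single-base insertions, placed inside homopolymer runs >= ``min_run``
    when ``homopolymer_only`` is set and at non-run sites otherwise.
    Returns the mutated sequence and a lesion log.
    """
    rng = rng or np.random.default_rng(0)
    if len(seq) % 3 != 0:
        raise ValueError("gene length must be a multiple of 3")
    n_codons = len(seq) // 3
    if n_nonsense > max(n_codons - 2, 0):
        raise ValueError("more nonsense lesions than internal codons")
    lesions: list[dict] = []
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]

    candidates = [k for k in range(1, n_codons - 1) if codons[k] not in _STOPS]
    for k in rng.choice(len(candidates), size=n_nonsense, replace=False) if n_nonsense else []:
        idx = candidates[int(k)]
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
        codons[idx] = stop
        lesions.append({"type": "nonsense", "codon": idx, "stop": stop})
    mutated = "".join(codons)

    def runs_ge(s: str, k: int) -> list[tuple[int, int]]:
        out = []
        i = 0
        while i < len(s):
            j = i
            while j + 1 < len(s) and s[j + 1] == s[i]:
                j += 1
            if j - i + 1 >= k:
                out.append((i, j))
            i = j + 1
        return out

    # keep indels away from the ends so they cannot be absorbed into
    # free end gaps of the classifier's alignment
    margin = 15
    for _ in range(n_frameshifts):
        if homopolymer_only:
            runs = [
                r
                for r in runs_ge(mutated, min_run)
                if margin <= r[0] and r[1] < len(mutated) - margin
            ]
            if not runs:
                raise ValueError(
                    f"no homopolymer run >= {min_run} bp to host a frameshift"
                )
            i, j = runs[int(rng.integers(len(runs)))]
            at = i + 1  # insert inside the run
            base = mutated[i]
        else:
            at = None
            for _try in range(1000):
                p = int(rng.integers(margin, len(mutated) - margin))
                left, here = mutated[p - 1], mutated[p]
                choice = [b for b in "ACGT" if b != left and b != here]
                b = choice[int(rng.integers(len(choice)))]
                # insertion must not create or extend a run >= min_run
                probe = mutated[:p] + b + mutated[p:]
                if _homopolymer_run_at(probe, p) < min_run:
                    at, base = p, b
                    break
            if at is None:
                raise ValueError("could not place a non-homopolymer frameshift")
        mutated = mutated[:at] + base + mutated[at:]
        lesions.append(
            {
                "type": "frameshift",
                "position": at + 1,
                "base": base,
                "homopolymer": homopolymer_only,
            }
        )
    return mutated, tuple(lesions)


# -- inversions ------------------------------------------------------------


def apply_inversions(
    tree: PhyloTree,
    root_order: SignedGeneOrder,
    events: Sequence[tuple[Clade, int, int]],
) -> tuple[dict[str, SignedGeneOrder], TruthLog]:
    """Propagate inversion events (branch, start idx, end idx) down a tree.

    Indices are 0-based inclusive into the order of the branch's parent
    (after any ancestral events).  Each event reverses the segment and flips
    strands for every descendant of its branch.  Two events on the same
    branch must not overlap.
    """
    by_branch: dict[Clade, list[tuple[int, int]]] = {}
    for clade, start, end in events:
        if not 0 <= start <= end < len(root_order.order):
            raise IndexError(f"event indices {start}..{end} out of range")
        for s, e in by_branch.get(clade, []):
            if start <= e and s <= end:
                raise ValueError(
                    f"overlapping simultaneous events on {branch_label(clade)}"
                )
        by_branch.setdefault(clade, []).append((start, end))

    flip = {"+": "-", "-": "+"}
    truth_events: list[dict] = []
    orders: dict[str, SignedGeneOrder] = {}

    def invert(order: list[tuple[str, str]], s: int, e: int) -> list[tuple[str, str]]:
        segment = [(g, flip[st]) for g, st in reversed(order[s : e + 1])]
        return order[:s] + segment + order[e + 1 :]

    def walk(clade: Clade, order: list[tuple[str, str]]) -> None:
        for child in tree.children.get(clade, ()):
            child_order = order
            for s, e in by_branch.get(child, []):
                truth_events.append(
                    {
                        "branch": child,
                        "genes": tuple(g for g, _ in child_order[s : e + 1]),
                    }
                )
                child_order = invert(child_order, s, e)
            if len(child) == 1:
                tip = next(iter(child))
                orders[tip] = SignedGeneOrder(
                    taxon=tip,
                    order=tuple(child_order),
                    circular=root_order.circular,
                )
            else:
                walk(child, child_order)

    walk(tree.root, list(root_order.order))
    truth = TruthLog(inversions=tuple(truth_events), gene_order=root_order.order)
    return orders, truth


def simulate_inversion_dataset(
    rng: np.random.Generator,
    tree: PhyloTree | None = None,
    n_genes: int = 100,
    n_events: int = 3,
    region_size_range: tuple[int, int] = (2, 34),
    outgroup_name: str = "outgroup",
) -> tuple[dict[str, SignedGeneOrder], SignedGeneOrder, TruthLog]:
    """Plant non-overlapping inversions on random branches.

    All events use disjoint index ranges (so the regions stay disjoint in
    every lineage) and the outgroup keeps the ancestral root order.  Returns
    (tip orders, outgroup order, truth).
    """
    tree = tree or blochmannia_tree()
    ids = [f"g{i + 1:03d}" for i in range(n_genes)]
    strands = ["+" if rng.random() < 0.5 else "-" for _ in ids]
    root = SignedGeneOrder(taxon="root", order=tuple(zip(ids, strands)), circular=True)

    lo, hi = region_size_range
    branches = list(tree.branches())
    events: list[tuple[Clade, int, int]] = []
    taken: list[tuple[int, int]] = []
    attempts = 0
    while len(events) < n_events and attempts < 1000:
        attempts += 1
        size = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, n_genes - size))
        end = start + size - 1
        if any(start <= e + 1 and s - 1 <= end for s, e in taken):
            continue  # keep planted regions separated by >= 1 gene
        branch = branches[int(rng.integers(len(branches)))]
        taken.append((start, end))
        events.append((branch, start, end))
    if len(events) < n_events:
        raise ValueError("could not place the requested number of inversions")
    orders, truth = apply_inversions(tree, root, events)
    outgroup = SignedGeneOrder(
        taxon=outgroup_name, order=root.order, circular=True
    )
    return orders, outgroup, truth
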