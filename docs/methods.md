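# Methods

## Setting and assumptions

The package analyses a small clade of heavily reduced, AT-rich circular
bacterial genomes (obligate intracellular endosymbionts) descended from a
common ancestor by gene degradation and loss. Two assumptions carry the
whole content analysis:

1. **No gene gain.** Horizontal transfer into the isolated intracellular
   niche is treated as negligible. Every functional gene copy observed
   anywhere in the clade is therefore evidence that the gene was present in
   the last common ancestor (the *union rule*), and loss is irreversible
   (Dollo parsimony). A separate screen (`single_gain_candidates`) lists
   genes whose phyletic pattern would be cheaper under a single gain, for
   manual transfer review; it never alters the mapping.
2. **Loss of function is loss.** Pseudogenes and absent genes are treated
   identically in content analyses; a pseudogene is presence evidence for
   the ancestor only if an intact copy exists in some other lineage (genes
   observed solely as pseudogenes are excluded from the ancestral set and
   reported separately — the ancestral reconstruction is therefore a lower
   bound). Genes whose only defect is a frameshift inside a homopolymer
   tract count as functional: transcriptional polymerase slippage can
   restore the frame.

## Dollo loss mapping

For a gene with non-functional tip set *F* (a proper subset of the tips),
the minimal set of loss branches is the set of maximal clades contained in
*F*. This set is unique — no tie-breaking is needed — because any
explanation must cover each maximal all-lost clade with at least one event,
and one event at each such clade root suffices; the implementation asserts
the pattern is not all-lost rather than guessing a root placement. The
test suite and acceptance script verify equality with an exhaustive
minimum-cardinality subset search (and uniqueness of the minimum) on random
trees of up to 8 tips.

**Identifiability of simulated losses.** The generator loses genes along
branches; a lost lineage cannot lose again, so true event sets are always
antichains. Exact recovery by parsimony additionally requires that the true
events are *Dollo-canonical*: no node has all of its children covered by
loss events (two sisters lost independently are merged into one ancestral
event by any parsimony method). Recovery tests condition on this property,
which the test computes directly from the truth log.

## Pseudogene classification

Lesion statistics are extracted from a pairwise candidate/homolog DNA
alignment (Biopython global alignment, match +1 / mismatch −2 / gap open −5
/ extend −0.5, free end gaps so truncations surface as lost coverage; any
aligner producing coordinates can be substituted). Conventions:

- *Nonsense count*: candidate codons read at the homolog's codon boundaries
  through the alignment; an internal homolog codon whose three positions
  all align to candidate bases forming TAA/TAG/TGA is one nonsense
  mutation. (This is the frame a BLASTX-style comparison implies; a
  frameshifted candidate is still read against homolog codons, which is
  exactly how planted stops remain countable.)
- *Frameshift*: an internal indel run whose length is not a multiple of 3.
  Its homopolymer context is the run length of the *indel's own base* in
  the candidate (an insertion adjacent to someone else's run is not
  slippage-correctable); mixed-base indels have context 0.
- *Gap event*: an internal indel run ≥ `gap_min_len` (default 30 bp — the
  published criteria mention "gaps" without a size, so the default is a
  declared choice, exposed in `PseudogeneCriteria`). A terminal homolog
  stretch ≥ `gap_min_len` missing from the candidate sets `truncated`.

Classification (defaults: coverage threshold 0.60, ≥ 2 nonsense at high
coverage, homopolymer run ≥ 4 bp — also a declared choice, no published
length exists):

- `INTACT`: no lesions; `INTACT_FS_HOMOPOLYMER`: every frameshift in a
  qualifying run, no other lesion class.
- `PSEUDOGENE`: (coverage > 0.60 and ≥ 2 nonsense) **or** (≥ 1
  non-homopolymer frameshift and ≥ 2 lesions total) **or** (gap event plus
  truncation) **or** (coverage ≤ 0.60 and ≥ 2 lesions of any class — the
  low-coverage reading of "multiple" lesions).
- anything else: `AMBIGUOUS`, a first-class outcome for manual review (the
  original curation was manual; forcing a binary call would fabricate
  confidence).

Classification is monotone: extra nonsense mutations can never revert a
pseudogene call.

## Replication origin and motif scanning

GC skew (G−C)/(G+C) is computed in 500 bp windows advanced by 50 bp
(defaults); windows with no G or C get skew 0, which keeps the track
bounded on AT-rich genomes. Circular sequences have ⌈L/step⌉ wrapping
windows; linear ones ⌊(L−w)/step⌋+1. The origin is the position of the
global minimum of the cumulative skew (leading-strand G-richness
convention); ties break to the smallest coordinate with a logged warning.
The IUPAC scanner compiles the degenerate pattern to a regular expression
with an overlap-permitting lookahead, scans the circular junction, and by
default scans both strands — replication-initiator boxes function on either
strand in these bacteria, and the published per-strand setting is unstated,
so flank counts are reported per strand. Anchor-flank scanning restricts
hits to the two intergenic spans between the anchor gene and its nearest
annotated neighbours (abutting neighbours give empty flanks and zero hits).

## Inversion detection and polarisation

Synteny is compared on signed ortholog orders, not nucleotides: gene loss
in reduced genomes would fragment nucleotide-level blocks spuriously, and
the published regions are reported in gene counts. An inverted block is a
maximal run of shared orthologs contiguous in both orders, order-reversed
and strand-flipped in one of them; unshared genes are transparent;
single-gene strand flips are excluded (minimum 2 genes). Circular orders
are compared modulo rotation (adjacency is tested modulo the shared-gene
count, which makes detection rotation-invariant). Pairwise regions against
one reference are merged by ortholog-set union, labelled A, B, … along the
reference; merged regions whose per-taxon inverted gene sets differ are
flagged as multi-event candidates (inversion "hotspots"). An event is
placed on the unique branch separating taxa that match the outgroup-
consensus ancestral orientation from those that do not; disagreeing,
uninformative or absent outgroups, or a non-unique branch, yield
`INCONCLUSIVE` rather than a guess. Gene-level reenactment of a
nucleotide-level published catalog is expected, not guaranteed, to
reproduce the same region count; deviations are reported, never silently
reconciled.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, and
every dataset is fully explained by its `TruthLog`.

- **Gene content.** Each gene present at the root; on each branch a
  still-functional gene is lost with the branch's probability (default
  0.05 per branch), at a uniform point along the branch. A lost gene is
  observed as a pseudogene with probability exp(−t/τ), t the time from
  loss point to tip and τ the observability half-life (default 1.0 in
  branch-length units — recent losses leave pseudogenes, ancient ones
  vanish; the published data show exactly this gradient but state no
  model, so exponential decay is the declared stand-in). Functional tips
  are intact, or homopolymer-frameshifted with probability 0.01 (matching
  the few-per-genome frequency in these genomes). The default topology is
  the five-lineage study tree (the two identical-content sister lineages
  collapsed), with branch lengths approximating its relative depths.
- **Genomes.** Circular sequence, origin at position 1, terminus at half
  the length; forward-strand base probabilities G-rich on the first
  replichore and C-rich on the second (GC 0.28, skew amplitude 0.6 by
  default), genes codon-aware (ATG start, no internal stop, TAA stop,
  composition following the local replichore on the gene's own strand) and
  non-overlapping with ≥ 60 bp intergenic gaps. DnaA-box instances are
  planted at recorded positions in the anchor gene's intergenic flanks;
  accidental extra matches in those flanks are scrubbed so the planted
  count is the flank truth. Lesion planting inserts stops on the codon
  grid and single-base insertions (inside runs ≥ 4 bp for homopolymer
  frameshifts, at run-free sites otherwise), keeping indels ≥ 15 bp from
  the gene ends so free-end-gap alignment cannot absorb them.
- **Inversions.** Events (branch, index range) are propagated root-to-tip,
  reversing the segment and flipping strands for all descendants;
  overlapping same-branch events are rejected. The bundled dataset helper
  plants disjoint regions of 2–34 genes on random branches of 100-gene
  circular genomes and keeps an outgroup at the ancestral order.

**What passing tests do and do not show.** The generator's genes are
composition-only (no codon usage, no substitution model), its intergenic
DNA is i.i.d., loss probabilities are homogeneous across genes, and
inversion regions are disjoint by construction. Passing recovery tests
therefore demonstrates correctness of the algorithms under the stated
identifiability conditions — not robustness to assembly error, annotation
noise, overlapping rearrangements or rate heterogeneity in real data.

## Problem sizes and numerical choices

The test suite and acceptance script run the oracle comparisons at 1,000
random patterns (trees ≤ 8 tips), 100 × 10 kb scanner sequences, and 100
replicates each for origin/box, loss-event, pseudogene and inversion
recovery; synthetic genomes in these loops are 30–60 kb with 18–40 genes,
which preserves the two-replichore geometry at a fraction of the
compute of full-size (≈ 750 kb) genomes — the generator's defaults remain
study-scale. Skew arithmetic uses prefix sums (exact); alignment scores
are fixed as above; all randomness flows through a single seeded
`numpy.random.Generator` per run, making every dataset bit-reproducible.

## Known limitations

- The union rule bounds ancestral content from below; genes lost (or fully
  decayed) in every lineage are invisible.
- Degradation statistics depend on the supplied pairwise alignment near
  indel boundaries; alignment-equivalent gap placements inside repeats can
  move a frameshift's context by design (slippage ambiguity is real).
- The inversion module detects inversions only (no transpositions), and
  nested/overlapping events in the same lineage can merge into one region;
  the multi-event flag marks, but does not decompose, such cases.
- Branch assignment needs informative outgroups; regions absent from all
  outgroups stay inconclusive by design.
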