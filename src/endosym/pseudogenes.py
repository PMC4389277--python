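"""Pseudogene classification from pairwise alignments to intact homologs.

A candidate gene region is compared with an intact homolog and its lesions
are tallied: internal stop codons read in the homolog's frame, indels whose
length is not a multiple of three (frameshifts), and large alignment gaps.
Frameshifts that sit inside a homopolymer tract are special: transcriptional
polymerase slippage can restore the reading frame, so a gene whose only
defect is such a frameshift is treated as functional.

Classification is deliberately conservative: a candidate aligning at >60%
coverage must carry at least two nonsense mutations to be called a
pseudogene on stops alone, and evidence that falls short of every rule is
returned as ``AMBIGUOUS`` for manual review rather than forced into a call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .matrix import GeneStatus

__all__ = [
    "DegradationStats",
    "PseudogeneCriteria",
    "PseudogeneSpan",
    "align_pair",
    "compute_degradation_stats",
    "is_homopolymer_frameshift",
    "classify_gene_status",
    "pseudogene_coordinates",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class DegradationStats:
    """Lesion tallies for one candidate vs one intact homolog.

    ``frameshift_contexts`` holds, per frameshift, the length of the
    candidate homopolymer run containing the indel site; ``truncated`` marks
    a terminal stretch of the homolog (>= gap_min_len) missing from the
    candidate.
    """

    coverage_fraction: float
    n_nonsense: int
    n_frameshifts: int
    frameshift_contexts: tuple[int, ...]
    n_gap_events: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction outside [0, 1]")
        if min(self.n_nonsense, self.n_frameshifts, self.n_gap_events) < 0:
            raise ValueError("negative lesion count")

    def n_homopolymer_frameshifts(self, min_run: int) -> int:
        return sum(1 for run in self.frameshift_contexts if run >= min_run)


@dataclass(frozen=True)
class PseudogeneCriteria:
    """Thresholds of the classification rules.

    coverage_threshold : alignment coverage above which >=2 nonsense
        mutations alone suffice for a pseudogene call (0.60).
    min_nonsense_at_high_coverage : the "multiple nonsense mutations" bar.
    homopolymer_min_run : minimum run length (bp) for a frameshift to count
        as slippage-correctable.
    gap_min_len : minimum alignment-gap length (bp) counted as a gap event.
    """

    coverage_threshold: float = 0.60
    min_nonsense_at_high_coverage: int = 2
    homopolymer_min_run: int = 4
    gap_min_len: int = 30

    def __post_init__(self) -> None:
        if min(
            self.coverage_threshold,
            self.min_nonsense_at_high_coverage,
            self.homopolymer_min_run,
            self.gap_min_len,
        ) <= 0:
            raise ValueError("criteria thresholds must be strictly positive")


def align_pair(homolog: str, candidate: str) -> Align.Alignment:
    """Global DNA alignment (free end gaps) of candidate against homolog."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    # free end gaps so truncations surface as missing coverage
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # pragma: no cover - older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner.align(homolog.upper(), candidate.upper())[0]


def _homopolymer_run_at(seq: str, pos0: int) -> int:
    """Length of the maximal identical-base run containing 0-based pos0."""
    if not 0 <= pos0 < len(seq):
        return 0
    base = seq[pos0]
    i = pos0
    while i > 0 and seq[i - 1] == base:
        i -= 1
    j = pos0
    while j + 1 < len(seq) and seq[j + 1] == base:
        j += 1
    return j - i + 1


def is_homopolymer_frameshift(
    seq: str, indel_pos: int, indel_len: int, min_run: int = 4
) -> bool:
    """Does a frameshifting indel sit inside a homopolymer tract?

    ``indel_pos`` is 1-based on the candidate: the first inserted base for an
    insertion, or the base immediately after the junction for a deletion.
    Indels whose length is a multiple of three never frameshift.  The run is
    measured on the candidate around the indel site (both junction sides).
    """
    if not 1 <= indel_pos <= len(seq):
        raise IndexError(f"indel position {indel_pos} outside sequence")
    if abs(indel_len) % 3 == 0:
        return False
    run = max(
        _homopolymer_run_at(seq, indel_pos - 1),
        _homopolymer_run_at(seq, indel_pos - 2),
    )
    return run >= min_run


def compute_degradation_stats(
    candidate: str,
    homolog: str,
    alignment: Align.Alignment | None = None,
    gap_min_len: int = 30,
    homopolymer_min_run: int = 4,
) -> DegradationStats:
    """Extract lesion statistics from a candidate/homolog alignment.

    The homolog must be a full reading frame (length divisible by three).
    Nonsense mutations are candidate codons read at the homolog's codon
    boundaries through the alignment: an internal homolog codon whose three
    positions all align to candidate bases forming a stop is one nonsense
    mutation.  Indel runs inside the aligned core are frameshifts when their
    length is not a multiple of three; runs >= ``gap_min_len`` are gap
    events.  Coverage is the fraction of homolog positions aligned to
    candidate bases.
    """
    candidate = candidate.upper()
    homolog = homolog.upper()
    if len(homolog) % 3 != 0:
        raise ValueError(f"homolog length {len(homolog)} is not a multiple of 3")
    if alignment is None:
        alignment = align_pair(homolog, candidate)
    gapped_h, gapped_c = str(alignment[0]), str(alignment[1])

    n_cols = len(gapped_h)
    both = [gapped_h[i] != "-" and gapped_c[i] != "-" for i in range(n_cols)]
    if not any(both):
        return DegradationStats(0.0, 0, 0, (), 0, truncated=True)
    first = both.index(True)
    last = n_cols - 1 - both[::-1].index(True)

    coverage = sum(both) / len(homolog)
    lead_missing = sum(1 for i in range(first) if gapped_h[i] != "-")
    tail_missing = sum(1 for i in range(last + 1, n_cols) if gapped_h[i] != "-")
    truncated = max(lead_missing, tail_missing) >= gap_min_len

    # candidate coordinate (0-based, next base to consume) per column
    c_pos = 0
    col_cpos = []
    for i in range(n_cols):
        col_cpos.append(c_pos)
        if gapped_c[i] != "-":
            c_pos += 1

    # indel runs inside the aligned core
    n_frameshifts = 0
    contexts: list[int] = []
    n_gap_events = 0
    i = first
    while i <= last:
        if gapped_h[i] == "-" or gapped_c[i] == "-":
            side = "h" if gapped_h[i] == "-" else "c"
            j = i
            while j <= last and (
                (gapped_h[j] == "-") if side == "h" else (gapped_c[j] == "-")
            ):
                j += 1
            run_len = j - i
            if run_len >= gap_min_len:
                n_gap_events += 1
            if run_len % 3 != 0:
                n_frameshifts += 1
                # homopolymer context: the run of the indel's own base --
                # slippage can only correct an indel that copies its tract
                site = col_cpos[i]  # first inserted base / base after junction
                indel_bases = (
                    candidate[site : site + run_len]
                    if side == "h"
                    else gapped_h[i:j]
                )
                run = 0
                if len(set(indel_bases)) == 1:
                    base = indel_bases[0]
                    if side == "h":
                        run = _homopolymer_run_at(candidate, site)
                    elif site > 0 and candidate[site - 1] == base:
                        run = _homopolymer_run_at(candidate, site - 1)
                    elif site < len(candidate) and candidate[site] == base:
                        run = _homopolymer_run_at(candidate, site)
                contexts.append(run)
            i = j
        else:
            i += 1

    # nonsense: candidate codons at homolog codon boundaries
    cols_of_hpos = {}
    h_pos = 0
    for i in range(n_cols):
        if gapped_h[i] != "-":
            cols_of_hpos[h_pos] = i
            h_pos += 1
    n_codons = len(homolog) // 3
    n_nonsense = 0
    for k in range(n_codons - 1):  # the final homolog codon is its stop
        cols = [cols_of_hpos[3 * k + o] for o in range(3)]
        chars = [gapped_c[c] for c in cols]
        if "-" not in chars and "".join(chars) in _STOPS:
            n_nonsense += 1

    return DegradationStats(
        coverage_fraction=min(coverage, 1.0),
        n_nonsense=n_nonsense,
        n_frameshifts=n_frameshifts,
        frameshift_contexts=tuple(contexts),
        n_gap_events=n_gap_events,
        truncated=truncated,
    )


def classify_gene_status(
    stats: DegradationStats, criteria: PseudogeneCriteria | None = None
) -> GeneStatus:
    """Apply the degradation criteria to lesion statistics.

    INTACT: no lesions of any class.  INTACT_FS_HOMOPOLYMER: every
    frameshift sits in a qualifying homopolymer run and no other lesion
    class is present.  PSEUDOGENE requires multiple corroborating lesions
    (or a large truncating gap); anything in between is AMBIGUOUS.
    """
    criteria = criteria or PseudogeneCriteria()
    hp_fs = stats.n_homopolymer_frameshifts(criteria.homopolymer_min_run)
    other_fs = stats.n_frameshifts - hp_fs
    lesions = stats.n_nonsense + other_fs + stats.n_gap_events + int(stats.truncated)

    if lesions == 0:
        if hp_fs:
            return GeneStatus.INTACT_FS_HOMOPOLYMER
        return GeneStatus.INTACT

    high_coverage = stats.coverage_fraction > criteria.coverage_threshold
    if high_coverage and stats.n_nonsense >= criteria.min_nonsense_at_high_coverage:
        return GeneStatus.PSEUDOGENE
    if other_fs >= 1 and lesions >= 2:
        return GeneStatus.PSEUDOGENE
    if stats.n_gap_events >= 1 and stats.truncated:
        return GeneStatus.PSEUDOGENE
    if not high_coverage and lesions >= 2:
        return GeneStatus.PSEUDOGENE
    return GeneStatus.AMBIGUOUS


@dataclass(frozen=True)
class PseudogeneSpan:
    """Annotated extent of a pseudogene on the candidate/genome axis."""

    start: int
    end: int
    internal_gap: bool = False


def pseudogene_coordinates(
    alignment: Align.Alignment | Sequence[tuple[int, int]],
) -> PseudogeneSpan:
    """Envelope of the aligned candidate coordinates, 1-based inclusive.

    Accepts a Biopython alignment or a list of (start, end) local-alignment
    intervals on the candidate; disjoint intervals are flagged as having an
    internal gap.
    """
    if isinstance(alignment, Align.Alignment):
        blocks = [(int(s) + 1, int(e)) for s, e in alignment.aligned[1]]
    else:
        blocks = [(int(s), int(e)) for s, e in alignment]
    if not blocks:
        raise ValueError("empty alignment")
    blocks.sort()
    internal = any(blocks[i + 1][0] > blocks[i][1] + 1 for i in range(len(blocks) - 1))
    return PseudogeneSpan(
        start=blocks[0][0], end=max(e for _, e in blocks), internal_gap=internal
    )
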