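"""GC skew, replication-origin prediction and degenerate motif scanning.

Bacterial replichores leave a compositional signature: the leading strand is
G-rich, so the windowed skew (G - C)/(G + C) changes sign at the origin and
terminus, and the cumulative skew attains its global minimum at the origin.
On these AT-rich endosymbiont genomes all-AT windows do occur; their skew is
defined as 0 to keep the track bounded.

The motif scanner matches IUPAC degenerate patterns (e.g. the DnaA box
TTWTNCACA) on either strand, reporting overlapping hits and scanning across
the circular junction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .genomes import Feature, Genome

__all__ = [
    "SkewParams",
    "SkewTrack",
    "CumSkewTrack",
    "MotifPattern",
    "MotifHit",
    "OriginPrediction",
    "gc_skew_track",
    "cumulative_skew",
    "predict_origin",
    "scan_iupac",
    "boxes_flanking_anchor",
    "IUPAC_CODES",
]

logger = logging.getLogger(__name__)

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SkewParams:
    """Sliding-window geometry: 500 bp windows advanced in 50 bp steps."""

    window: int = 500
    step: int = 50
    circular: bool = True

    def validate(self, length: int) -> None:
        if not 0 < self.step <= self.window <= length:
            raise ValueError(
                f"need 0 < step ({self.step}) <= window ({self.window}) "
                f"<= sequence length ({length})"
            )


@dataclass(frozen=True)
class SkewTrack:
    """Per-window skew values with 1-based window start/center positions."""

    starts: np.ndarray  # 1-based window start
    centers: np.ndarray  # 1-based position of the window midpoint
    values: np.ndarray
    params: SkewParams
    length: int  # source sequence length

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CumSkewTrack:
    """Running sum of per-window skew (rotation-equivariant up to offset)."""

    centers: np.ndarray
    values: np.ndarray
    params: SkewParams
    length: int

    def __len__(self) -> int:
        return len(self.values)


def gc_skew_track(seq: str, params: SkewParams | None = None) -> SkewTrack:
    """Windowed (G - C)/(G + C) over a linear or circular sequence.

    Circular tracks have ceil(L / step) windows starting every ``step`` from
    position 1 and wrapping; linear tracks have floor((L - window)/step) + 1.
    Windows with no G or C get skew 0.
    """
    params = params or SkewParams()
    seq = seq.upper()
    L = len(seq)
    params.validate(L)
    w, s = params.window, params.step
    if params.circular:
        starts = np.arange(0, L, s)
        ext = seq + seq[: w - 1]
    else:
        starts = np.arange(0, L - w + 1, s)
        ext = seq
    is_g = np.frombuffer(ext.encode(), dtype=np.uint8) == ord("G")
    is_c = np.frombuffer(ext.encode(), dtype=np.uint8) == ord("C")
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    g = cg[starts + w] - cg[starts]
    c = cc[starts + w] - cc[starts]
    denom = g + c
    values = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    centers = (starts + w // 2) % L + 1 if params.circular else starts + w // 2 + 1
    return SkewTrack(
        starts=starts + 1, centers=centers, values=values, params=params, length=L
    )


def cumulative_skew(track: SkewTrack) -> CumSkewTrack:
    """Running sum of the windowed skew along the track."""
    if len(track) == 0:
        raise ValueError("empty skew track")
    return CumSkewTrack(
        centers=track.centers,
        values=np.cumsum(track.values),
        params=track.params,
        length=track.length,
    )


@dataclass(frozen=True)
class OriginPrediction:
    """Predicted replication origin position (cumulative-skew minimum)."""

    position: int
    method: str
    anchor_gene: str | None = None
    anchor_distance: int | None = None
    note: str = ""


def _circular_distance(a: int, b: int, length: int) -> int:
    d = abs(a - b) % length
    return min(d, length - d)


def predict_origin(
    cumtrack: CumSkewTrack,
    genome: Genome | None = None,
    anchor: str | None = None,
) -> OriginPrediction:
    """Origin = position of the global minimum of cumulative skew.

    Ties are broken toward the smallest coordinate with a logged warning.
    With an ``anchor`` gene (e.g. the gene the origin is expected to abut)
    and its genome, the circular distance from the prediction to the
    nearest anchor boundary is reported.
    """
    values = cumtrack.values
    minimum = values.min()
    ties = np.flatnonzero(values == minimum)
    note = ""
    if len(ties) > 1:
        note = f"{len(ties)} tied minima; smallest coordinate reported"
        logger.warning("predict_origin: %s", note)
    # report the smallest tied coordinate, not the first tied index
    position = int(cumtrack.centers[ties].min())
    anchor_distance = None
    if anchor is not None:
        if genome is None:
            raise ValueError("anchor lookup requires the genome annotation")
        feat = genome.find_feature(anchor)
        anchor_distance = min(
            _circular_distance(position, feat.start, len(genome)),
            _circular_distance(position, feat.end, len(genome)),
        )
    return OriginPrediction(
        position=position,
        method="cumulative GC-skew minimum",
        anchor_gene=anchor,
        anchor_distance=anchor_distance,
        note=note,
    )


def plot_skew(
    track: SkewTrack,
    cumtrack: CumSkewTrack | None = None,
    origin: "OriginPrediction | None" = None,
    path: str | None = None,
):
    """Plot the windowed (and optionally cumulative) skew track.

    Requires matplotlib (the ``plot`` extra).  Returns the figure; saves to
    ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(track.centers, track.values, lw=0.5, color="seagreen", label="GC skew")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("(G−C)/(G+C)")
    if cumtrack is not None:
        ax2 = ax.twinx()
        ax2.plot(
            cumtrack.centers, cumtrack.values, lw=1.0, color="purple",
            label="cumulative",
        )
        ax2.set_ylabel("cumulative skew")
    if origin is not None:
        ax.axvline(origin.position, color="red", ls="--", lw=1.0)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


@dataclass(frozen=True)
class MotifPattern:
    """IUPAC degenerate pattern with a strand policy."""

    pattern: str
    strand_policy: str = "both"  # "forward" or "both"

    def __post_init__(self) -> None:
        bad = set(self.pattern.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"non-IUPAC characters in pattern: {sorted(bad)}")
        if self.strand_policy not in ("forward", "both"):
            raise ValueError(f"bad strand policy {self.strand_policy!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    def regex(self) -> str:
        return "".join(
            f"[{IUPAC_CODES[ch]}]" if len(IUPAC_CODES[ch]) > 1 else IUPAC_CODES[ch]
            for ch in self.pattern.upper()
        )


@dataclass(frozen=True)
class MotifHit:
    """One degenerate-motif match; position is the 1-based forward-strand
    start of the 9-bp (pattern-length) footprint regardless of strand."""

    position: int
    strand: str
    matched: str  # motif-oriented sequence (reverse-complemented for "-")


def _scan_one_strand(
    seq: str, regex: str, m: int, circular: bool, strand: str
) -> list[MotifHit]:
    L = len(seq)
    text = seq + seq[: m - 1] if circular else seq
    hits = []
    for match in re.finditer(f"(?=({regex}))", text):
        pos = match.start()
        if pos >= L:
            break
        found = match.group(1)
        hits.append(
            MotifHit(
                position=pos + 1,
                strand=strand,
                matched=found if strand == "+" else revcomp(found),
            )
        )
    return hits


def scan_iupac(
    seq: str, pattern: MotifPattern | str, circular: bool = False
) -> list[MotifHit]:
    """All exact degenerate matches of an IUPAC pattern.

    Overlapping matches are reported; with ``circular`` the junction is
    scanned too.  Under the ``both`` strand policy, a reverse-strand hit is
    a window whose reverse complement matches the pattern; its position is
    the forward-strand start of the window.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    seq = seq.upper()
    m = len(pattern)
    if m > len(seq):
        return []
    hits = _scan_one_strand(seq, pattern.regex(), m, circular, "+")
    if pattern.strand_policy == "both":
        rc_pattern = MotifPattern(revcomp(pattern.pattern.upper()), "forward")
        hits += _scan_one_strand(seq, rc_pattern.regex(), m, circular, "-")
    return sorted(hits, key=lambda h: (h.position, h.strand))


@dataclass(frozen=True)
class FlankingBoxes:
    """Motif hits restricted to the two intergenic flanks of an anchor."""

    anchor: str
    upstream_region: tuple[int, int] | None  # 1-based inclusive, None if empty
    downstream_region: tuple[int, int] | None
    hits: tuple[MotifHit, ...]

    @property
    def count(self) -> int:
        return len(self.hits)

    def per_strand_counts(self) -> dict[str, int]:
        return {
            "+": sum(1 for h in self.hits if h.strand == "+"),
            "-": sum(1 for h in self.hits if h.strand == "-"),
        }


def _region_seq(genome: Genome, start: int, end: int) -> str:
    """Sequence of 1-based inclusive [start, end], wrapping if start > end."""
    if start <= end:
        return genome.seq[start - 1 : end]
    return genome.seq[start - 1 :] + genome.seq[:end]


def boxes_flanking_anchor(
    genome: Genome,
    anchor: str,
    pattern: MotifPattern | str = "TTWTNCACA",
    feature_types: Iterable[str] = ("CDS", "gene", "rRNA", "tRNA"),
) -> FlankingBoxes:
    """Scan the two intergenic regions flanking an anchor gene for a motif.

    The intergenic regions run from the anchor's boundaries to the nearest
    annotated neighbour on each side (circularly).  Abutting neighbours give
    zero-length regions and zero hits.  Hit positions are absolute genome
    coordinates; a hit must fit entirely inside its region.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    anchor_feat = genome.find_feature(anchor)
    types = set(feature_types)
    others = [
        f
        for f in genome.features
        if f.type in types
        and not (f.start == anchor_feat.start and f.end == anchor_feat.end)
    ]
    if not others:
        raise ValueError(f"no neighbouring features around {anchor!r}")
    L = len(genome)

    def fwd_gap(a: int, b: int) -> int:  # bases strictly between coords a -> b
        return (b - a - 1) % L

    # nearest neighbour downstream of the anchor end / upstream of its start
    down = min(others, key=lambda f: fwd_gap(anchor_feat.end, f.start))
    up = min(others, key=lambda f: fwd_gap(f.end, anchor_feat.start))

    regions: list[tuple[int, int] | None] = []
    for a, b in (
        (up.end, anchor_feat.start),  # upstream intergenic
        (anchor_feat.end, down.start),  # downstream intergenic
    ):
        gap = fwd_gap(a, b)
        if gap == 0:
            regions.append(None)
        else:
            regions.append(((a % L) + 1, ((b - 2) % L) + 1))

    hits: list[MotifHit] = []
    for region in regions:
        if region is None:
            continue
        start, end = region
        sub = _region_seq(genome, start, end)
        for h in scan_iupac(sub, pattern, circular=False):
            hits.append(
                MotifHit(
                    position=(start - 1 + h.position - 1) % L + 1,
                    strand=h.strand,
                    matched=h.matched,
                )
            )
    return FlankingBoxes(
        anchor=anchor,
        upstream_region=regions[0],
        downstream_region=regions[1],
        hits=tuple(sorted(hits, key=lambda h: h.position)),
    )
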