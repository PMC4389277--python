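"""Annotated circular genomes and signed gene orders.

Thin domain layer over Biopython's GenBank reader/writer.  Coordinates are
1-based inclusive throughout (the GenBank convention); features spanning the
circular junction are kept with ``start > end`` and flagged ``wraps``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .matrix import OrthologMatrix

__all__ = [
    "Feature",
    "Genome",
    "SignedGeneOrder",
    "read_genome_record",
    "write_genome_record",
    "extract_gene_order",
    "read_gene_order_tsv",
    "write_gene_order_tsv",
]

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class Feature:
    """One annotated feature, GenBank 1-based inclusive coordinates."""

    id: str
    type: str
    start: int
    end: int
    strand: str  # "+" or "-"
    qualifiers: Mapping[str, str] = field(default_factory=dict)
    wraps: bool = False  # spans the circular junction (start > end)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.wraps and not (1 <= self.start <= self.end):
            raise ValueError(f"bad coordinates {self.start}..{self.end}")


@dataclass(frozen=True)
class Genome:
    """Circular (or linear) annotated nucleotide sequence."""

    id: str
    seq: str
    features: tuple[Feature, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        for f in self.features:
            if f.end > len(self.seq) or f.start > len(self.seq):
                raise ValueError(f"feature {f.id} outside sequence ({len(self.seq)} bp)")
            if f.wraps and not self.circular:
                raise ValueError(f"wrapping feature {f.id} on a linear genome")

    def __len__(self) -> int:
        return len(self.seq)

    def feature_seq(self, f: Feature) -> str:
        """Feature nucleotide sequence on its own strand."""
        if f.wraps:
            raw = self.seq[f.start - 1 :] + self.seq[: f.end]
        else:
            raw = self.seq[f.start - 1 : f.end]
        return raw if f.strand == "+" else str(Seq(raw).reverse_complement())

    def find_feature(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.id == feature_id or f.qualifiers.get("gene") == feature_id:
                return f
        raise KeyError(f"feature {feature_id!r} not found in genome {self.id}")


def _feature_id(sf: SeqFeature, index: int) -> str:
    for key in ("locus_tag", "gene", "protein_id"):
        if key in sf.qualifiers:
            return sf.qualifiers[key][0]
    return f"feature_{index}"


def read_genome_record(path: str | Path) -> Genome:
    """Read a single-record GenBank flat file.

    Multi-record files and records without sequence are rejected.  Pseudogene
    features stay identifiable through their ``pseudo``/``pseudogene``
    qualifiers.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one record in {path}, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) < 2:
        raise ValueError(f"record {rec.id} has no sequence")
    circular = rec.annotations.get("topology", "linear") == "circular"
    features = []
    for i, sf in enumerate(rec.features):
        if sf.type == "source":
            continue
        quals = {k: v[0] for k, v in sf.qualifiers.items() if v}
        for flag in ("pseudo", "pseudogene"):
            if flag in sf.qualifiers:
                quals.setdefault(flag, "")
        strand = "-" if sf.location.strand == -1 else "+"
        parts = sf.location.parts
        if len(parts) > 1 and int(parts[0].end) == len(seq):
            # origin-spanning join(a..L,1..b)
            start, end, wraps = int(parts[0].start) + 1, int(parts[-1].end), True
        else:
            start, end, wraps = int(sf.location.start) + 1, int(sf.location.end), False
        features.append(
            Feature(
                id=_feature_id(sf, i),
                type=sf.type,
                start=start,
                end=end,
                strand=strand,
                qualifiers=quals,
                wraps=wraps,
            )
        )
    return Genome(id=rec.id, seq=seq, features=tuple(features), circular=circular)


def write_genome_record(genome: Genome, path: str | Path) -> None:
    """Write a :class:`Genome` as a single-record GenBank flat file."""
    rec = SeqRecord(Seq(genome.seq), id=genome.id, name=genome.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.circular else "linear"
    strand_of = {"+": 1, "-": -1}
    for f in genome.features:
        if f.wraps:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, len(genome.seq), strand_of[f.strand]),
                    SimpleLocation(0, f.end, strand_of[f.strand]),
                ]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand_of[f.strand])
        quals = {k: [v] for k, v in f.qualifiers.items()}
        quals.setdefault("locus_tag", [f.id])
        rec.features.append(SeqFeature(loc, type=f.type, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


@dataclass(frozen=True)
class SignedGeneOrder:
    """Ordered (ortholog id, strand) list for one genome."""

    taxon: str
    order: tuple[tuple[str, str], ...]
    circular: bool = True

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.order]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate ortholog ids in order for {self.taxon}")
        for _, s in self.order:
            if s not in "+-":
                raise ValueError(f"bad strand {s!r}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.order)

    def strand(self, gene: str) -> str:
        for g, s in self.order:
            if g == gene:
                return s
        raise KeyError(gene)

    def position(self, gene: str) -> int:
        return self.ids.index(gene)


def extract_gene_order(
    genome: Genome,
    matrix: OrthologMatrix,
    ortholog_qualifier: str = "gene",
    feature_types: Sequence[str] = ("CDS",),
) -> SignedGeneOrder:
    """Project a genome annotation to a signed ortholog order.

    Features (default CDS) whose ``ortholog_qualifier`` value appears among
    the matrix genes are kept, sorted by start coordinate; the rest are
    skipped with a logged count.  Wrapping features sort at their start.
    """
    known = set(matrix.genes)
    kept: list[tuple[int, str, str]] = []
    skipped = 0
    for f in genome.features:
        if f.type not in feature_types:
            continue
        gid = f.qualifiers.get(ortholog_qualifier, f.id)
        if gid in known:
            kept.append((f.start, gid, f.strand))
        else:
            skipped += 1
    if not kept:
        raise ValueError(
            f"no features in {genome.id} carry a matrix ortholog id "
            f"(qualifier {ortholog_qualifier!r})"
        )
    if skipped:
        logger.info("extract_gene_order(%s): skipped %d features", genome.id, skipped)
    kept.sort()
    return SignedGeneOrder(
        taxon=genome.id,
        order=tuple((g, s) for _, g, s in kept),
        circular=genome.circular,
    )


def write_gene_order_tsv(order: SignedGeneOrder, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ortholog\tstrand\n")
        for g, s in order.order:
            fh.write(f"{g}\t{s}\n")


def read_gene_order_tsv(
    path: str | Path, taxon: str | None = None, circular: bool = True
) -> SignedGeneOrder:
    rows = Path(path).read_text().strip().splitlines()
    order = []
    for line in rows[1:]:
        g, s = line.split("\t")
        order.append((g, s))
    return SignedGeneOrder(
        taxon=taxon or Path(path).stem, order=tuple(order), circular=circular
    )
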