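"""Ortholog state matrices: the genes x taxa table of gene functional states.

The matrix is the substrate of every gene-content analysis in this package.
Each cell records whether an ortholog is intact, intact apart from a
frameshift inside a homopolymer tract (treated as functional, since such
frameshifts can be corrected by transcriptional polymerase slippage), a
pseudogene, or absent from the genome.

Files are plain tab-delimited tables: a header row of taxon ids and one row
per gene, first column the gene id.  Cell codes are configurable; the default
encoding is ``+`` / ``fs`` / ``psi`` / ``-``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GeneStatus",
    "OrthologMatrix",
    "DEFAULT_STATE_CODES",
    "read_ortholog_matrix",
    "write_ortholog_matrix",
    "read_matrix_config",
]


class GeneStatus(enum.Enum):
    """Functional state of one ortholog in one genome.

    ``AMBIGUOUS`` is produced only by the pseudogene classifier when the
    evidence does not support a confident call; it is not a valid matrix
    cell state.
    """

    INTACT = "intact"
    INTACT_FS_HOMOPOLYMER = "intact_fs_homopolymer"
    PSEUDOGENE = "pseudogene"
    ABSENT = "absent"
    AMBIGUOUS = "ambiguous"

    @property
    def functional(self) -> bool:
        """Whether the gene is treated as functional in content analyses."""
        return self in (GeneStatus.INTACT, GeneStatus.INTACT_FS_HOMOPOLYMER)


#: Default cell encoding; "fs" marks homopolymer-tract frameshifted genes,
#: which count as functional.
DEFAULT_STATE_CODES: dict[str, GeneStatus] = {
    "+": GeneStatus.INTACT,
    "fs": GeneStatus.INTACT_FS_HOMOPOLYMER,
    "psi": GeneStatus.PSEUDOGENE,
    "-": GeneStatus.ABSENT,
}

# Preference order when merging fused rows: the unit is functional if any
# member is, and the most-intact member state wins.
_MERGE_RANK = {
    GeneStatus.INTACT: 0,
    GeneStatus.INTACT_FS_HOMOPOLYMER: 1,
    GeneStatus.PSEUDOGENE: 2,
    GeneStatus.ABSENT: 3,
}


@dataclass(frozen=True)
class OrthologMatrix:
    """Complete genes x taxa table of :class:`GeneStatus` values.

    Parameters
    ----------
    states
        DataFrame indexed by gene id with one column per taxon; every cell
        a :class:`GeneStatus` other than ``AMBIGUOUS``.
    fusion_map
        Mapping of fused-unit id -> member gene ids that were merged into
        that single row (e.g. two domains of a bifunctional protein
        annotated separately in some genomes but counted as one gene).
    """

    states: pd.DataFrame
    fusion_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.states
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dups}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValueError(f"duplicate taxon ids: {dups}")
        members: list[str] = []
        for group in self.fusion_map.values():
            members.extend(group)
        if len(members) != len(set(members)):
            raise ValueError("fusion groups are not disjoint")
        for gene in df.index:
            for taxon in df.columns:
                value = df.at[gene, taxon]
                if not isinstance(value, GeneStatus) or value is GeneStatus.AMBIGUOUS:
                    raise ValueError(
                        f"invalid state for gene {gene!r} in taxon {taxon!r}: {value!r}"
                    )

    # -- basic accessors -------------------------------------------------

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.states.index)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.states.columns)

    def state(self, gene: str, taxon: str) -> GeneStatus:
        return self.states.at[gene, taxon]

    def functional(self) -> pd.DataFrame:
        """Boolean genes x taxa frame: True where the gene is functional."""
        return self.states.map(lambda s: s.functional)

    def functional_taxa(self, gene: str) -> frozenset[str]:
        row = self.states.loc[gene]
        return frozenset(t for t in self.taxa if row[t].functional)

    def pattern(self, gene: str) -> tuple[tuple[str, GeneStatus], ...]:
        """The tip-state pattern of one gene, in taxon order."""
        row = self.states.loc[gene]
        return tuple((t, row[t]) for t in self.taxa)

    # -- transformations -------------------------------------------------

    def rename_taxa(self, aliases: Mapping[str, str]) -> "OrthologMatrix":
        """Apply a taxon aliasing table (long organism name -> short id)."""
        return OrthologMatrix(self.states.rename(columns=dict(aliases)), self.fusion_map)

    def merge_fusions(self, fusion_map: Mapping[str, Iterable[str]]) -> "OrthologMatrix":
        """Collapse each fusion group to a single row.

        Per taxon the merged state is the most-intact member state, so a
        fused unit is functional wherever any member is.
        """
        fusion_map = {unit: tuple(genes) for unit, genes in fusion_map.items()}
        members: list[str] = [g for group in fusion_map.values() for g in group]
        if len(members) != len(set(members)):
            raise ValueError("fusion groups are not disjoint")
        df = self.states
        missing = set(members) - set(df.index)
        if missing:
            raise KeyError(f"fusion members not in matrix: {sorted(missing)}")
        rows = {}
        for unit, group in fusion_map.items():
            sub = df.loc[list(group)]
            rows[unit] = sub.apply(lambda col: min(col, key=_MERGE_RANK.__getitem__))
        merged = df.drop(index=members)
        if rows:
            merged = pd.concat([merged, pd.DataFrame(rows).T])
        return OrthologMatrix(merged, {**dict(self.fusion_map), **fusion_map})

    def subset_taxa(self, taxa: Iterable[str]) -> "OrthologMatrix":
        taxa = list(taxa)
        unknown = set(taxa) - set(self.taxa)
        if unknown:
            raise KeyError(f"unknown taxa: {sorted(unknown)}")
        return OrthologMatrix(self.states[taxa], self.fusion_map)


def read_ortholog_matrix(
    path: str | Path,
    state_codes: Mapping[str, GeneStatus] | None = None,
    fusion_map: Mapping[str, Iterable[str]] | None = None,
    aliases: Mapping[str, str] | None = None,
) -> OrthologMatrix:
    """Read a tab-delimited ortholog state table.

    The file must have a header row of taxon ids (first column the gene-id
    column) and one row per gene.  Unknown cell codes and empty cells are
    rejected with the offending gene and taxon named.
    """
    codes = dict(DEFAULT_STATE_CODES if state_codes is None else state_codes)
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene id(s) in {path}: {dups}")
    decoded = {}
    for gene, row in df.iterrows():
        states = []
        for taxon, cell in row.items():
            cell = cell.strip()
            if cell == "":
                raise ValueError(f"missing cell for gene {gene!r}, taxon {taxon!r}")
            if cell not in codes:
                raise ValueError(
                    f"unknown state code {cell!r} for gene {gene!r}, taxon {taxon!r}"
                )
            states.append(codes[cell])
        decoded[gene] = states
    matrix = OrthologMatrix(
        pd.DataFrame.from_dict(decoded, orient="index", columns=list(df.columns))
    )
    if aliases:
        matrix = matrix.rename_taxa(aliases)
    if fusion_map:
        matrix = matrix.merge_fusions(fusion_map)
    return matrix


def write_ortholog_matrix(
    matrix: OrthologMatrix,
    path: str | Path,
    state_codes: Mapping[str, GeneStatus] | None = None,
) -> None:
    """Write the matrix back to TSV with the given (default) cell encoding."""
    codes = dict(DEFAULT_STATE_CODES if state_codes is None else state_codes)
    rev = {status: code for code, status in codes.items()}
    out = matrix.states.map(rev.__getitem__)
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_matrix_config(path: str | Path) -> dict:
    """Read the JSON config holding state codes, fusion map and aliases.

    Keys (all optional): ``state_codes`` (code -> status name), ``fusion_map``
    (unit id -> member list), ``aliases`` (raw taxon name -> short id).
    """
    with open(path) as fh:
        raw = json.load(fh)
    config: dict = {}
    if "state_codes" in raw:
        config["state_codes"] = {
            code: GeneStatus[name.upper()] for code, name in raw["state_codes"].items()
        }
    if "fusion_map" in raw:
        config["fusion_map"] = {u: tuple(g) for u, g in raw["fusion_map"].items()}
    if "aliases" in raw:
        config["aliases"] = dict(raw["aliases"])
    return config
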