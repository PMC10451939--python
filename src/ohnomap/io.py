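"""Readers and writers for the standard tabular inputs.

All stages of the pipeline share three kinds of input: BLAST tabular
(``-outfmt 6``) similarity hits, gene location tables (TSV or BED6), and
small two-column maps (protein->gene, ohnolog pairs).  Everything is parsed
into plain frozen dataclasses; coordinates are stored 1-based inclusive
(the NCBI convention) with BED input converted on read.

Chromosome identifiers are opaque strings: ``"8"``, ``"chr8"`` and ``"41"``
are all legal and only exact string equality is used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneLocation",
    "HitRecord",
    "OhnologPair",
    "ParseError",
    "OUTFMT6_COLUMNS",
    "assign_ranks",
    "read_outfmt6",
    "write_outfmt6",
    "read_gene_table",
    "write_gene_table",
    "read_protein_gene_map",
    "read_ohnolog_pairs",
    "locations_by_gene",
]

#: Column order of BLAST tabular output, ``-outfmt 6``.
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

GENE_TABLE_HEADER = ("gene_id", "chromosome", "start", "end", "strand")


class ParseError(ValueError):
    """Raised for malformed input files; the message names the line."""


@dataclass(frozen=True, order=True)
class GeneLocation:
    """A gene's position in one genome.

    ``rank`` is the 0-based order index of the gene along its chromosome,
    assigned by sorting on (start, end, gene_id).
    """

    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class HitRecord:
    """One similarity-search hit, optionally resolved to gene ids."""

    query_protein: str
    subject_protein: str
    bit_score: float
    e_value: float
    query_gene: str | None = None
    subject_gene: str | None = None

    def __post_init__(self) -> None:
        if not (self.bit_score == self.bit_score and abs(self.bit_score) != float("inf")):
            raise ValueError("bit_score must be finite")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass(frozen=True)
class OhnologPair:
    """An unordered pair of WGD-derived duplicate genes, stored sorted."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"ohnolog pair members identical: {self.gene_a}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)


# ---------------------------------------------------------------------------
# rank assignment

def assign_ranks(locations: Iterable[GeneLocation]) -> list[GeneLocation]:
    """Recompute per-chromosome order ranks from coordinates.

    Genes are ordered by start coordinate; ties broken by end, then by
    gene_id, so the result is a deterministic function of the coordinate
    multiset regardless of input order.
    """
    by_chrom: dict[str, list[GeneLocation]] = {}
    for loc in locations:
        by_chrom.setdefault(loc.chromosome, []).append(loc)
    out: list[GeneLocation] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        for rank, g in enumerate(genes):
            out.append(dataclasses.replace(g, rank=rank))
    return out


def locations_by_gene(locations: Iterable[GeneLocation]) -> dict[str, GeneLocation]:
    index: dict[str, GeneLocation] = {}
    for loc in locations:
        if loc.gene_id in index:
            raise ParseError(f"duplicate gene_id {loc.gene_id!r}")
        index[loc.gene_id] = loc
    return index


# ---------------------------------------------------------------------------
# BLAST outfmt 6

def read_outfmt6(
    path: str | Path,
    protein_to_gene: Mapping[str, str] | None = None,
    strict: bool = True,
) -> list[HitRecord]:
    """Parse a 12-column BLAST tabular file into :class:`HitRecord` s.

    If *protein_to_gene* is given, query and subject protein ids are
    resolved to gene ids (isoform collapse itself happens later, in the
    classifier, so protein-level hits stay inspectable).  In strict mode a
    protein missing from the map is an error listing the offenders;
    otherwise the gene id is carried as the protein id.
    """
    path = Path(path)
    records: list[HitRecord] = []
    unmapped: set[str] = set()

    def resolve(protein: str) -> str:
        if protein_to_gene is None:
            return protein
        if protein in protein_to_gene:
            return protein_to_gene[protein]
        unmapped.add(protein)
        return protein

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric evalue/bitscore: {exc}"
                ) from None
            records.append(
                HitRecord(
                    query_protein=fields[0],
                    subject_protein=fields[1],
                    bit_score=bitscore,
                    e_value=evalue,
                    query_gene=resolve(fields[0]),
                    subject_gene=resolve(fields[1]),
                )
            )
    if strict and protein_to_gene is not None and unmapped:
        raise ParseError(
            "proteins missing from protein->gene map: "
            + ", ".join(sorted(unmapped))
        )
    return records


def write_outfmt6(records: Iterable[HitRecord], path: str | Path) -> None:
    """Serialize hits as BLAST outfmt 6.

    Alignment columns that the score-space model does not populate are
    written as the sentinel 0; pident is a monotone transform of the bit
    score capped at 100.
    """
    with Path(path).open("w") as fh:
        for r in records:
            pident = min(100.0, 100.0 * r.bit_score / (r.bit_score + 25.0))
            fh.write(
                "\t".join(
                    [
                        r.query_protein,
                        r.subject_protein,
                        f"{pident:.2f}",
                        "0", "0", "0", "0", "0", "0", "0",
                        f"{r.e_value:.3g}",
                        f"{r.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene location tables (TSV with header, or BED6)

def read_gene_table(path: str | Path) -> list[GeneLocation]:
    """Read gene locations from a header TSV or a BED6 file.

    The dialect is auto-detected: a first line starting with ``gene_id``
    is the native 5-column TSV (1-based inclusive coordinates); otherwise
    a 6-column line is treated as BED6 (0-based half-open, converted on
    read).  Ranks are always recomputed from the coordinates.
    """
    path = Path(path)
    raw: list[GeneLocation] = []
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        if not first:
            return []
        header_mode = first.split("\t")[0] == "gene_id"
        if header_mode:
            cols = tuple(first.split("\t"))
            if cols != GENE_TABLE_HEADER:
                raise ParseError(
                    f"{path.name}: bad header {cols}, expected {GENE_TABLE_HEADER}"
                )
            lines = enumerate(fh, start=2)
        else:
            lines = enumerate([first + "\n"] + fh.readlines(), start=1)
        for lineno, line in lines:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                if header_mode:
                    if len(fields) != 5:
                        raise ValueError(f"expected 5 columns, got {len(fields)}")
                    gene_id, chrom, start, end, strand = fields
                    loc = GeneLocation(gene_id, chrom, int(start), int(end), strand)
                else:
                    if len(fields) != 6:
                        raise ValueError(f"expected 6 BED columns, got {len(fields)}")
                    chrom, start, end, gene_id, _score, strand = fields
                    # BED is 0-based half-open
                    loc = GeneLocation(gene_id, chrom, int(start) + 1, int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
            raw.append(loc)
    ranked = assign_ranks(raw)
    locations_by_gene(ranked)  # raises on duplicate gene ids
    return ranked


def write_gene_table(
    locations: Iterable[GeneLocation], path: str | Path, dialect: str = "tsv"
) -> None:
    """Write locations as the native TSV or as BED6."""
    locs = sorted(locations, key=lambda g: (g.chromosome, g.rank))
    with Path(path).open("w") as fh:
        if dialect == "tsv":
            fh.write("\t".join(GENE_TABLE_HEADER) + "\n")
            for g in locs:
                fh.write(f"{g.gene_id}\t{g.chromosome}\t{g.start}\t{g.end}\t{g.strand}\n")
        elif dialect == "bed":
            for g in locs:
                fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# two-column maps

def _read_two_columns(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            pairs.append((fields[0], fields[1]))
    return pairs


def read_protein_gene_map(path: str | Path) -> dict[str, str]:
    """2-column TSV mapping protein id -> gene id (isoform collapse map)."""
    mapping: dict[str, str] = {}
    for protein, gene in _read_two_columns(path):
        if protein in mapping and mapping[protein] != gene:
            raise ParseError(f"protein {protein!r} mapped to two genes")
        mapping[protein] = gene
    return mapping


def read_ohnolog_pairs(path: str | Path) -> list[OhnologPair]:
    """2-column TSV of WGD-duplicate gene pairs; de-duplicated, canonical order."""
    seen: set[tuple[str, str]] = set()
    pairs: list[OhnologPair] = []
    for a, b in _read_two_columns(path):
        pair = OhnologPair(a, b)
        key = (pair.gene_a, pair.gene_b)
        if key not in seen:
            seen.add(key)
            pairs.append(pair)
    return pairs
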