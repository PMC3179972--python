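"""Identifier normalization: heterogeneous gene/protein IDs -> integer gene IDs.

Ortholog prediction tools publish their calls against different namespaces —
Ensembl protein accessions, NCBI gene/protein IDs, UniProt accessions, or
species-database IDs such as FlyBase FBgn numbers — and some report every
protein isoform of a gene separately.  Everything downstream works on a single
Entrez-style integer gene-ID namespace per species, so the first step is to
standardize identifiers through mapping tables and collapse isoform-level
records to gene level.

Symbols are matched case-insensitively (databases disagree on capitalisation
conventions across species); accessions are matched case-sensitively.  A raw
ID that maps to several genes fans out to all of them, each flagged
``ambiguous_source_id`` — inclusiveness is preferred over silently dropping a
gene that might matter to a downstream study.  Unmapped IDs never abort a run;
they are collected into a machine-readable report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from ._util import ParseError, TableSource, iter_tsv, write_tsv

SPECIES = ("human", "mouse", "zebrafish", "fly", "worm", "yeast")

ID_TYPES = (
    "symbol",
    "entrez",
    "ensembl_protein",
    "uniprot",
    "species_db",
    "refseq_protein",
)

#: id_types matched case-insensitively (gene symbols); accessions are exact.
_CASE_INSENSITIVE_TYPES = frozenset({"symbol"})

AMBIGUOUS_FLAG = "ambiguous_source_id"


@dataclass(frozen=True)
class GeneRef:
    """A gene in the integer gene-ID namespace of one species."""

    gene_id: int
    species: str
    symbol: Optional[str] = None
    source_db_id: Optional[str] = None

    def __post_init__(self):
        if self.gene_id <= 0:
            raise ValueError(f"gene_id must be positive, got {self.gene_id}")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")


@dataclass
class UnmappedRecord:
    raw_id: str
    species: str
    reason: str


class UnmappedReport:
    """Accumulates identifiers that could not be resolved to a gene."""

    def __init__(self):
        self.records: list[UnmappedRecord] = []

    def add(self, raw_id: str, species: str, reason: str = "no_match") -> None:
        self.records.append(UnmappedRecord(raw_id, species, reason))

    def __len__(self) -> int:
        return len(self.records)

    def write(self, path) -> None:
        write_tsv(
            path,
            ["raw_id", "species", "reason"],
            ((r.raw_id, r.species, r.reason) for r in self.records),
        )


class IdMap:
    """Lookup from raw identifier strings to sets of integer gene IDs.

    Entries are kept per id_type so that expert callers can restrict a lookup
    to a declared identifier type.  Protein accessions additionally carry the
    isoform length, used by the alignment module for longest-isoform
    selection.
    """

    def __init__(self, species: str):
        if species not in SPECIES:
            raise ValueError(f"unknown species {species!r}")
        self.species = species
        # (normalized_raw_id, id_type) -> set of gene_id
        self._entries: dict[tuple[str, str], set[int]] = {}
        # protein accession -> (gene_id, length in aa)
        self.isoform_lengths: dict[str, tuple[int, int]] = {}

    @staticmethod
    def _norm(raw_id: str, id_type: str) -> str:
        return raw_id.lower() if id_type in _CASE_INSENSITIVE_TYPES else raw_id

    def add(self, raw_id: str, id_type: str, gene_id: int, protein_length: int | None = None) -> None:
        if id_type not in ID_TYPES:
            raise ValueError(f"unknown id_type {id_type!r}; expected one of {ID_TYPES}")
        key = (self._norm(raw_id, id_type), id_type)
        self._entries.setdefault(key, set()).add(gene_id)
        if protein_length is not None:
            self.isoform_lengths[raw_id] = (gene_id, protein_length)

    def lookup(self, raw_id: str, declared_type: str | None = None) -> set[int]:
        """All gene IDs matching raw_id, optionally restricted to one id_type."""
        if declared_type is not None:
            if declared_type not in ID_TYPES:
                raise ValueError(f"unknown id_type {declared_type!r}")
            types: Iterable[str] = (declared_type,)
        else:
            types = ID_TYPES
        hits: set[int] = set()
        for t in types:
            hits |= self._entries.get((self._norm(raw_id, t), t), set())
        return hits

    def __len__(self) -> int:
        return len(self._entries)


def load_id_map(mapping_table_source: TableSource, species: str) -> IdMap:
    """Load a mapping table into an IdMap.

    Rows are tab-separated ``raw_id, id_type, gene_id[, protein_length]``;
    '#'-prefixed comment lines are ignored.  Duplicate rows deduplicate;
    conflicting rows (same raw_id, different genes) are retained as a
    multi-valued entry.
    """
    id_map = IdMap(species)
    for line_no, fields in iter_tsv(mapping_table_source):
        if len(fields) not in (3, 4):
            raise ParseError(
                f"expected 3 or 4 tab-separated columns, got {len(fields)}", line_no
            )
        raw_id, id_type, gene_id_str = fields[0], fields[1], fields[2]
        if id_type not in ID_TYPES:
            raise ParseError(f"unknown id_type {id_type!r}", line_no)
        try:
            gene_id = int(gene_id_str)
        except ValueError:
            raise ParseError(f"non-integer gene_id {gene_id_str!r}", line_no) from None
        length = None
        if len(fields) == 4 and fields[3] != "":
            try:
                length = int(fields[3])
            except ValueError:
                raise ParseError(f"non-integer protein_length {fields[3]!r}", line_no) from None
        id_map.add(raw_id, id_type, gene_id, length)
    return id_map


def normalize_identifier(
    raw_id: str,
    species: str,
    id_map: IdMap,
    declared_type: str | None = None,
    report: UnmappedReport | None = None,
) -> set[int]:
    """Resolve one raw identifier to gene IDs; unmatched IDs go to the report."""
    hits = id_map.lookup(raw_id, declared_type)
    if not hits and report is not None:
        report.add(raw_id, species, "no_match")
    return hits


@dataclass(frozen=True)
class GenePair:
    """A gene-level ortholog candidate pair, oriented input -> output species."""

    gene_a: int
    gene_b: int
    flags: frozenset[str] = field(default_factory=frozenset)

    def key(self) -> tuple[int, int]:
        return (self.gene_a, self.gene_b)


def collapse_to_gene_level(
    pairs: Iterable[tuple[str, str]],
    id_map_a: IdMap,
    id_map_b: IdMap,
    report: UnmappedReport | None = None,
) -> set[GenePair]:
    """Collapse raw (protein or gene) ID pairs to a set of gene-ID pairs.

    Isoform-level duplicates of the same gene pair merge into one record.  A
    raw ID resolving to several genes fans out to every combination, each
    flagged ambiguous_source_id.  Pairs with an unresolvable side are dropped
    and reported.
    """
    out: dict[tuple[int, int], set[str]] = {}
    for raw_a, raw_b in pairs:
        genes_a = id_map_a.lookup(raw_a)
        genes_b = id_map_b.lookup(raw_b)
        if not genes_a or not genes_b:
            if report is not None:
                if not genes_a:
                    report.add(raw_a, id_map_a.species, "no_match")
                if not genes_b:
                    report.add(raw_b, id_map_b.species, "no_match")
            continue
        ambiguous = len(genes_a) > 1 or len(genes_b) > 1
        for a in genes_a:
            for b in genes_b:
                flags = out.setdefault((a, b), set())
                if ambiguous:
                    flags.add(AMBIGUOUS_FLAG)
    return {GenePair(a, b, frozenset(flags)) for (a, b), flags in out.items()}
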