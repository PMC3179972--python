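"""Normalizing disease/trait terms to MeSH categories and joining orthologs.

Disease and trait descriptions in curated gene-disease sources are free
text: the same disease appears under many spellings, phrasings and
qualifiers.  To make them searchable they are normalized to MeSH disease
categories (C01-C27 plus F03, mental disorders), a controlled vocabulary
with entry-term synonyms, extended by two non-MeSH categories: Y01
"Disease risk factor, diagnosis or treatment" (e.g. HDL cholesterol,
telomere length) and Y02 "Trait" (e.g. hair color) for descriptions that are
not diseases at all.

A record is routed through a fixed precedence of mapping rules:

1. its clinical-synopsis (CS) heading, through a curated heading -> category
   map;
2. its simplified term, through the MeSH entry-term lookup (e.g. "breast
   cancer" is an entry term of "breast neoplasms") and then the term ->
   category table;
3. a curated manual-override table for terms mapped by hand;
4. configured keyword lists for Y01/Y02;
5. otherwise it lands in the unmapped report — never guessed.

Mapped human disease genes are then joined to their model-organism orthologs
through the integrated ortholog table, with the same score/best-match
filters available everywhere else, and compared against literature-derived
disease categories of the orthologs themselves.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from ._util import ParseError, TableSource, iter_tsv, write_tsv
from .integration import (
    OrthologPair,
    apply_best_match_filter,
    apply_score_filter,
    sort_canonical,
)

SOURCES = ("OMIM_phenotype", "OMIM_gene_locus", "GWAS")

FILTER_MODES = ("none", "score_ge2", "score_ge3", "best_match")

#: default disease-category table; callers may supply their own
DEFAULT_CATEGORIES: dict[str, str] = {
    "C04": "Neoplasms",
    "C10": "Nervous System Diseases",
    "C14": "Cardiovascular Diseases",
    "C16": "Congenital, Hereditary, and Neonatal Diseases and Abnormalities",
    "C18": "Nutritional and Metabolic Diseases",
    "C19": "Endocrine System Diseases",
    "F03": "Mental Disorders",
    "Y01": "Disease risk factor, diagnosis or treatment",
    "Y02": "Trait",
}

#: trailing comma-qualifiers stripped during term simplification
DEFAULT_QUALIFIERS: frozenset[str] = frozenset(
    {
        "susceptibility to",
        "resistance to",
        "protection against",
        "modifier of",
        "included",
        "formerly",
        "autosomal dominant",
        "autosomal recessive",
        "x-linked",
        "somatic",
        "digenic",
    }
)

#: keyword seeds for the two added categories
DEFAULT_Y01_KEYWORDS: tuple[str, ...] = (
    "cholesterol",
    "triglyceride",
    "telomere length",
    "bone size",
    "bone mineral density",
    "tanning",
    "blood pressure",
    "response to",
    "levels",
)
DEFAULT_Y02_KEYWORDS: tuple[str, ...] = (
    "color",
    "height",
    "body mass",
    "handedness",
    "freckl",
)

ROUTES = ("cs_heading", "entry_term", "manual_override", "y01_rule", "y02_rule", "unmapped")


@dataclass(frozen=True)
class MeshCategory:
    code: str
    label: str


@dataclass
class DiseaseRecord:
    source: str
    raw_term: str
    omim_id: Optional[int] = None
    cs_heading: Optional[str] = None
    human_genes: set[int] = field(default_factory=set)

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if not self.raw_term and self.omim_id is None:
            raise ValueError("record needs a raw term or an OMIM id")


_BRACKETED = re.compile(r"\[[^\]]*\]|\([^)]*\)|\{[^}]*\}")
_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")


def simplify_term(raw: str, qualifiers: frozenset[str] = DEFAULT_QUALIFIERS) -> str:
    """Canonicalize a free-text disease/trait term for lookup.

    Lower-cases, strips bracketed qualifiers and punctuation, collapses
    whitespace, and removes trailing comma-separated qualifier phrases such
    as ", susceptibility to".  Deterministic and idempotent.
    """
    text = _BRACKETED.sub(" ", raw).lower()
    segments = [s.strip() for s in text.split(",")]
    while len(segments) > 1 and _WS.sub(" ", _PUNCT.sub(" ", segments[-1])).strip() in qualifiers:
        segments.pop()
    text = " ".join(segments)
    text = _PUNCT.sub(" ", text)
    return _WS.sub(" ", text).strip()


@dataclass
class MeshLookup:
    """All the tables a record can be routed through, keyed by simplified text."""

    entry_terms: dict[str, str] = field(default_factory=dict)  # simplified -> MeSH term
    term_categories: dict[str, set[str]] = field(default_factory=dict)  # MeSH term -> codes
    cs_heading_map: dict[str, str] = field(default_factory=dict)  # heading -> code
    manual_overrides: dict[str, str] = field(default_factory=dict)  # simplified -> code
    y01_keywords: tuple[str, ...] = DEFAULT_Y01_KEYWORDS
    y02_keywords: tuple[str, ...] = DEFAULT_Y02_KEYWORDS
    categories: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CATEGORIES))

    def category(self, code: str) -> MeshCategory:
        if code not in self.categories:
            raise KeyError(f"unknown category code {code!r}; valid: {sorted(self.categories)}")
        return MeshCategory(code, self.categories[code])


def read_mesh_lookup(
    entry_term_source: TableSource,
    cs_heading_source: TableSource | None = None,
    manual_override_source: TableSource | None = None,
    categories: Mapping[str, str] | None = None,
) -> MeshLookup:
    """Entry-term table: (entry term, MeSH term, category codes comma-joined)."""
    lookup = MeshLookup()
    if categories is not None:
        lookup.categories = dict(categories)
    for line_no, fields in iter_tsv(entry_term_source):
        if len(fields) != 3:
            raise ParseError(f"expected 3 columns, got {len(fields)}", line_no)
        entry, mesh_term, codes = fields
        lookup.entry_terms[simplify_term(entry)] = mesh_term
        lookup.term_categories.setdefault(mesh_term, set()).update(
            c for c in codes.split(",") if c
        )
    if cs_heading_source is not None:
        for line_no, fields in iter_tsv(cs_heading_source):
            if len(fields) != 2:
                raise ParseError(f"expected 2 columns, got {len(fields)}", line_no)
            lookup.cs_heading_map[fields[0]] = fields[1]
    if manual_override_source is not None:
        for line_no, fields in iter_tsv(manual_override_source):
            if len(fields) != 2:
                raise ParseError(f"expected 2 columns, got {len(fields)}", line_no)
            lookup.manual_overrides[simplify_term(fields[0])] = fields[1]
    return lookup


def assign_category(record: DiseaseRecord, lookup: MeshLookup) -> tuple[set[MeshCategory], str]:
    """Map one record to its MeSH categories; returns (categories, route).

    A term may map to several categories (MeSH is poly-hierarchic); all are
    kept.  Exactly one route fires per record; unmapped is a reported
    outcome, not an error.
    """
    if record.cs_heading and record.cs_heading in lookup.cs_heading_map:
        code = lookup.cs_heading_map[record.cs_heading]
        return {lookup.category(code)}, "cs_heading"

    simplified = simplify_term(record.raw_term)
    mesh_term = lookup.entry_terms.get(simplified)
    if mesh_term is not None:
        codes = lookup.term_categories.get(mesh_term, set())
        if codes:
            return {lookup.category(c) for c in codes}, "entry_term"

    if simplified in lookup.manual_overrides:
        return {lookup.category(lookup.manual_overrides[simplified])}, "manual_override"

    if any(k in simplified for k in lookup.y01_keywords):
        return {lookup.category("Y01")}, "y01_rule"
    if any(k in simplified for k in lookup.y02_keywords):
        return {lookup.category("Y02")}, "y02_rule"

    return set(), "unmapped"


def read_omim_records(source: TableSource) -> list[DiseaseRecord]:
    """Tab-separated (omim_id, record_type, raw term, cs_heading, gene_ids)."""
    records = []
    for line_no, fields in iter_tsv(source):
        if len(fields) != 5:
            raise ParseError(f"expected 5 columns, got {len(fields)}", line_no)
        omim_id_s, record_type, raw_term, cs_heading, genes_s = fields
        source_name = {"phenotype": "OMIM_phenotype", "gene_locus": "OMIM_gene_locus"}.get(
            record_type
        )
        if source_name is None:
            raise ParseError(f"unknown OMIM record type {record_type!r}", line_no)
        try:
            omim_id = int(omim_id_s)
            genes = {int(g) for g in genes_s.split(",") if g}
        except ValueError:
            raise ParseError(f"non-integer id in {fields!r}", line_no) from None
        records.append(
            DiseaseRecord(source_name, raw_term, omim_id, cs_heading or None, genes)
        )
    return records


def read_gwas_records(source: TableSource) -> list[DiseaseRecord]:
    """Tab-separated (raw trait term, gene_ids comma-joined)."""
    records = []
    for line_no, fields in iter_tsv(source):
        if len(fields) != 2:
            raise ParseError(f"expected 2 columns, got {len(fields)}", line_no)
        try:
            genes = {int(g) for g in fields[1].split(",") if g}
        except ValueError:
            raise ParseError(f"non-integer gene id in {fields[1]!r}", line_no) from None
        records.append(DiseaseRecord("GWAS", fields[0], None, None, genes))
    return records


class GeneLiteratureMesh:
    """gene_id -> disease categories co-cited with the gene in the literature."""

    def __init__(self, categories: Mapping[int, set[str]] | None = None):
        self.categories: dict[int, set[str]] = {
            g: set(cs) for g, cs in (categories or {}).items()
        }

    def __getitem__(self, gene: int) -> set[str]:
        return self.categories.get(gene, set())

    @classmethod
    def read(cls, source: TableSource) -> "GeneLiteratureMesh":
        out: dict[int, set[str]] = {}
        for line_no, fields in iter_tsv(source):
            if len(fields) != 2:
                raise ParseError(f"expected 2 columns, got {len(fields)}", line_no)
            try:
                gene = int(fields[0])
            except ValueError:
                raise ParseError(f"non-integer gene id {fields[0]!r}", line_no) from None
            out.setdefault(gene, set()).add(fields[1])
        return cls(out)


def shared_disease_categories(
    gene: int, orthologs: Iterable[int], lit: GeneLiteratureMesh
) -> set[str]:
    """Categories a gene shares with any of its orthologs in the literature."""
    ortholog_cats: set[str] = set()
    for o in orthologs:
        ortholog_cats |= lit[o]
    return lit[gene] & ortholog_cats


@dataclass
class DiseaseJoinRow:
    raw_term: str
    categories: tuple[str, ...]
    omim_id: Optional[int]
    human_gene: int
    target_gene: Optional[int]  # None = no ortholog under the chosen filter
    simple_score: Optional[int]
    weighted_score: Optional[float]
    supporting_tools: tuple[str, ...]


def _apply_filter(pairs: Sequence[OrthologPair], filter_mode: str) -> list[OrthologPair]:
    if filter_mode == "none":
        return sort_canonical(pairs)
    if filter_mode == "score_ge2":
        return apply_score_filter(pairs, 2)
    if filter_mode == "score_ge3":
        return apply_score_filter(pairs, 3)
    if filter_mode == "best_match":
        return apply_best_match_filter(pairs)
    raise ValueError(f"unknown filter_mode {filter_mode!r}; valid: {FILTER_MODES}")


def join_disease_orthologs(
    records: Sequence[DiseaseRecord],
    ortholog_pairs: Sequence[OrthologPair],
    lookup: MeshLookup,
    filter_mode: str = "none",
    term_query: str | None = None,
    category_query: str | None = None,
    omim_ids: set[int] | None = None,
) -> list[DiseaseJoinRow]:
    """Select disease records, resolve their human genes, attach orthologs.

    Orthologs come from the integrated table (human genes on the query side)
    with the requested filter applied table-wide first, so join results obey
    the same monotonicity as the filters themselves.  Human genes left
    without a partner under the filter still produce a row with target_gene
    None so that "no ortholog" is an explicit outcome.
    """
    if category_query is not None and category_query not in lookup.categories:
        raise KeyError(
            f"unknown category code {category_query!r}; valid: {sorted(lookup.categories)}"
        )
    filtered = _apply_filter(ortholog_pairs, filter_mode)
    by_human: dict[int, list[OrthologPair]] = {}
    for p in filtered:
        by_human.setdefault(p.gene_a, []).append(p)

    rows: list[DiseaseJoinRow] = []
    for rec in records:
        if term_query is not None and term_query.lower() not in rec.raw_term.lower():
            continue
        if omim_ids is not None and rec.omim_id not in omim_ids:
            continue
        cats, _route = assign_category(rec, lookup)
        codes = tuple(sorted(c.code for c in cats))
        if category_query is not None and category_query not in codes:
            continue
        for gene in sorted(rec.human_genes):
            partners = by_human.get(gene, [])
            if not partners:
                rows.append(
                    DiseaseJoinRow(rec.raw_term, codes, rec.omim_id, gene, None, None, None, ())
                )
                continue
            for p in partners:
                rows.append(
                    DiseaseJoinRow(
                        rec.raw_term,
                        codes,
                        rec.omim_id,
                        gene,
                        p.gene_b,
                        p.simple_score,
                        p.weighted_score,
                        tuple(sorted(p.supporting_tools)),
                    )
                )
    return rows


def category_summary(rows: Sequence[DiseaseJoinRow]) -> dict[str, dict[str, int]]:
    """Per-category census of the join output: terms, human genes, target genes."""
    terms: dict[str, set[str]] = {}
    human: dict[str, set[int]] = {}
    target: dict[str, set[int]] = {}
    for row in rows:
        for code in row.categories:
            terms.setdefault(code, set()).add(row.raw_term)
            human.setdefault(code, set()).add(row.human_gene)
            if row.target_gene is not None:
                target.setdefault(code, set()).add(row.target_gene)
    return {
        code: {
            "n_terms": len(terms[code]),
            "n_human_genes": len(human[code]),
            "n_target_genes": len(target.get(code, set())),
        }
        for code in sorted(terms)
    }


def write_join_table(path, rows: Sequence[DiseaseJoinRow]) -> None:
    write_tsv(
        path,
        [
            "disease_term",
            "categories",
            "omim_id",
            "human_gene",
            "target_gene",
            "simple_score",
            "weighted_score",
            "supporting_tools",
        ],
        (
            (
                r.raw_term,
                ",".join(r.categories),
                "" if r.omim_id is None else r.omim_id,
                r.human_gene,
                "" if r.target_gene is None else r.target_gene,
                "" if r.simple_score is None else r.simple_score,
                "" if r.weighted_score is None else f"{r.weighted_score:.4f}",
                ",".join(r.supporting_tools),
            )
            for r in rows
        ),
    )
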