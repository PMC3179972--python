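"""Consensus integration of per-tool ortholog predictions.

Each source tool contributes a set of gene-level pairs for one ordered
species pair.  Integration takes the union over the selected tools and scores
every pair by the number of tools that support it (the *simple score*); the
GO-similarity module later adds a *weighted score* in which each supporting
tool counts by its functional-consistency weight.  Two filters mirror the
common usage patterns: a score threshold (drop pairs supported by fewer than
2 or 3 tools, rescuing a sub-threshold pair when it is a query gene's only
candidate) and a best-match filter (keep only each query gene's top-scoring
partner(s)).  Pairs are also classified as one-to-one / one-to-many /
many-to-one / many-to-many from partner counts, oriented input -> output
species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from ._util import ParseError, TableSource, iter_tsv, write_tsv
from .id_mapping import AMBIGUOUS_FLAG, GenePair, IdMap, UnmappedReport, collapse_to_gene_level

LOW_SCORE_ONLY_FLAG = "low_score_only_match"
BEST_MATCH_FLAG = "best_match"

RELATIONSHIP_CLASSES = ("one-to-one", "one-to-many", "many-to-one", "many-to-many")


class ConfigurationError(ValueError):
    pass


@dataclass
class ToolPairSet:
    """One tool's gene-level predictions for an ordered species pair."""

    tool_name: str
    species_pair: tuple[str, str]
    pairs: set[GenePair]
    original_scores: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def pair_keys(self) -> set[tuple[int, int]]:
        return {p.key() for p in self.pairs}


@dataclass
class OrthologPair:
    """An integrated gene pair with provenance and scores."""

    gene_a: int
    gene_b: int
    supporting_tools: frozenset[str]
    weighted_score: Optional[float] = None
    flags: frozenset[str] = field(default_factory=frozenset)
    original_scores: dict[str, str] = field(default_factory=dict)

    @property
    def simple_score(self) -> int:
        return len(self.supporting_tools)

    def key(self) -> tuple[int, int]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class ToolTableConfig:
    """Column layout of one tool's raw prediction table.

    col_a / col_b are 0-based column indices for the two identifiers;
    type_a / type_b their id_types (None = untyped lookup); col_score an
    optional column holding the tool's native score, preserved verbatim.
    """

    tool_name: str
    col_a: int = 0
    col_b: int = 1
    type_a: Optional[str] = None
    type_b: Optional[str] = None
    col_score: Optional[int] = None


def ingest_tool_predictions(
    config: ToolTableConfig,
    raw_table: TableSource,
    id_map_a: IdMap,
    id_map_b: IdMap,
    report: UnmappedReport | None = None,
) -> ToolPairSet:
    """Parse one tool's raw table, normalize IDs and collapse to gene level."""
    raw_pairs: list[tuple[str, str]] = []
    raw_scores: dict[tuple[str, str], str] = {}
    needed = max(
        config.col_a, config.col_b, config.col_score if config.col_score is not None else 0
    )
    for line_no, fields in iter_tsv(raw_table):
        if len(fields) <= needed:
            raise ParseError(
                f"expected at least {needed + 1} columns, got {len(fields)}", line_no
            )
        raw_a, raw_b = fields[config.col_a], fields[config.col_b]
        raw_pairs.append((raw_a, raw_b))
        if config.col_score is not None:
            raw_scores[(raw_a, raw_b)] = fields[config.col_score]

    pairs = collapse_to_gene_level(raw_pairs, id_map_a, id_map_b, report)

    # carry original scores through the gene-level collapse (last write wins
    # among isoform duplicates; tools report one score per isoform pair)
    original_scores: dict[tuple[int, int], str] = {}
    for (raw_a, raw_b), score in raw_scores.items():
        for a in id_map_a.lookup(raw_a):
            for b in id_map_b.lookup(raw_b):
                original_scores[(a, b)] = score

    return ToolPairSet(
        tool_name=config.tool_name,
        species_pair=(id_map_a.species, id_map_b.species),
        pairs=pairs,
        original_scores=original_scores,
    )


def integrate(
    tool_pair_sets: Sequence[ToolPairSet],
    selected_tools: Iterable[str] | None = None,
) -> list[OrthologPair]:
    """Union the selected tools' pair sets; simple score = supporting-tool count.

    Output order is canonical: by gene_a, then descending simple score, then
    gene_b.
    """
    if not tool_pair_sets:
        raise ConfigurationError("no tool pair sets given")
    species_pairs = {tps.species_pair for tps in tool_pair_sets}
    if len(species_pairs) > 1:
        raise ConfigurationError(f"mixed species pairs: {sorted(species_pairs)}")
    available = [tps.tool_name for tps in tool_pair_sets]
    if selected_tools is None:
        selected = set(available)
    else:
        selected = set(selected_tools)
        unknown = selected - set(available)
        if unknown:
            raise ConfigurationError(f"selected tools without data: {sorted(unknown)}")
    if not selected:
        raise ConfigurationError("selected_tools is empty")

    support: dict[tuple[int, int], set[str]] = {}
    flags: dict[tuple[int, int], set[str]] = {}
    originals: dict[tuple[int, int], dict[str, str]] = {}
    for tps in tool_pair_sets:
        if tps.tool_name not in selected:
            continue
        for pair in tps.pairs:
            k = pair.key()
            support.setdefault(k, set()).add(tps.tool_name)
            flags.setdefault(k, set()).update(pair.flags)
            if k in tps.original_scores:
                originals.setdefault(k, {})[tps.tool_name] = tps.original_scores[k]

    out = [
        OrthologPair(
            gene_a=a,
            gene_b=b,
            supporting_tools=frozenset(tools),
            flags=frozenset(flags[(a, b)]),
            original_scores=originals.get((a, b), {}),
        )
        for (a, b), tools in support.items()
    ]
    return sort_canonical(out)


def sort_canonical(pairs: Iterable[OrthologPair]) -> list[OrthologPair]:
    return sorted(pairs, key=lambda p: (p.gene_a, -p.simple_score, p.gene_b))


def apply_score_filter(
    pairs: Sequence[OrthologPair],
    threshold: int,
    rescue: str = "only_match",
    allow_any_threshold: bool = False,
) -> list[OrthologPair]:
    """Drop pairs supported by fewer than `threshold` tools, with a rescue.

    rescue="only_match" (default): a sub-threshold pair survives, flagged
    low_score_only_match, only when it is its query gene's single candidate.
    rescue="best_below_threshold": when none of a query gene's candidates
    pass, its top-scoring candidates survive, flagged likewise.
    """
    if threshold not in (2, 3) and not allow_any_threshold:
        raise ConfigurationError(
            f"score threshold {threshold} outside the supported {{2, 3}}; "
            "pass allow_any_threshold=True to override"
        )
    if rescue not in ("only_match", "best_below_threshold"):
        raise ConfigurationError(f"unknown rescue mode {rescue!r}")

    by_query: dict[int, list[OrthologPair]] = {}
    for p in pairs:
        by_query.setdefault(p.gene_a, []).append(p)

    kept: list[OrthologPair] = []
    for candidates in by_query.values():
        passing = [p for p in candidates if p.simple_score >= threshold]
        if passing:
            kept.extend(passing)
        elif rescue == "only_match" and len(candidates) == 1:
            p = candidates[0]
            kept.append(replace(p, flags=p.flags | {LOW_SCORE_ONLY_FLAG}))
        elif rescue == "best_below_threshold" and candidates:
            top = max(p.simple_score for p in candidates)
            kept.extend(
                replace(p, flags=p.flags | {LOW_SCORE_ONLY_FLAG})
                for p in candidates
                if p.simple_score == top
            )
    return sort_canonical(kept)


def apply_best_match_filter(pairs: Sequence[OrthologPair]) -> list[OrthologPair]:
    """Per query gene, keep the top-scoring partner(s); ties all kept."""
    by_query: dict[int, list[OrthologPair]] = {}
    for p in pairs:
        by_query.setdefault(p.gene_a, []).append(p)
    kept: list[OrthologPair] = []
    for candidates in by_query.values():
        top = max(p.simple_score for p in candidates)
        kept.extend(
            replace(p, flags=p.flags | {BEST_MATCH_FLAG})
            for p in candidates
            if p.simple_score == top
        )
    return sort_canonical(kept)


def classify_relationships(
    pairs: Sequence[OrthologPair],
) -> tuple[dict[tuple[int, int], str], dict[str, int]]:
    """Label every pair by partner counts on each side, input -> output.

    (a, b) is one-to-one when a is b's only partner and b is a's only
    partner; one-to-many when a has several partners; many-to-one when b
    does; many-to-many when both do.
    """
    partners_a: dict[int, int] = {}
    partners_b: dict[int, int] = {}
    for p in pairs:
        partners_a[p.gene_a] = partners_a.get(p.gene_a, 0) + 1
        partners_b[p.gene_b] = partners_b.get(p.gene_b, 0) + 1

    labels: dict[tuple[int, int], str] = {}
    counts = {c: 0 for c in RELATIONSHIP_CLASSES}
    for p in pairs:
        many_a = partners_a[p.gene_a] > 1
        many_b = partners_b[p.gene_b] > 1
        if not many_a and not many_b:
            label = "one-to-one"
        elif many_a and not many_b:
            label = "one-to-many"
        elif not many_a and many_b:
            label = "many-to-one"
        else:
            label = "many-to-many"
        labels[p.key()] = label
        counts[label] += 1
    return labels, counts


def transpose(pairs: Sequence[OrthologPair]) -> list[OrthologPair]:
    """Query the reverse species direction by transposing the stored table."""
    return sort_canonical(
        replace(p, gene_a=p.gene_b, gene_b=p.gene_a) for p in pairs
    )


INTEGRATED_COLUMNS = [
    "input_species",
    "gene_a",
    "symbol_a",
    "output_species",
    "gene_b",
    "symbol_b",
    "simple_score",
    "weighted_score",
    "supporting_tools",
    "original_scores",
    "relationship_class",
    "flags",
]


def write_integrated_table(
    path,
    pairs: Sequence[OrthologPair],
    species_pair: tuple[str, str],
    symbols_a: Mapping[int, str] | None = None,
    symbols_b: Mapping[int, str] | None = None,
) -> None:
    symbols_a = symbols_a or {}
    symbols_b = symbols_b or {}
    labels, _ = classify_relationships(pairs)
    rows = []
    for p in sort_canonical(pairs):
        originals = ",".join(f"{t}={s}" for t, s in sorted(p.original_scores.items()))
        rows.append(
            (
                species_pair[0],
                p.gene_a,
                symbols_a.get(p.gene_a, ""),
                species_pair[1],
                p.gene_b,
                symbols_b.get(p.gene_b, ""),
                p.simple_score,
                "" if p.weighted_score is None else f"{p.weighted_score:.4f}",
                ",".join(sorted(p.supporting_tools)),
                originals,
                labels[p.key()],
                ",".join(sorted(p.flags)),
            )
        )
    write_tsv(path, INTEGRATED_COLUMNS, rows)
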