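"""Benchmarking predictors against reference pair sets and negative gene sets.

Any predictor — a single tool's pair set or the integrated table under any
filter — is scored against (a) a curated reference set of high-confidence
ortholog pairs and (b) a lineage-specific negative gene set (genes asserted
to have no ortholog in the target species, so any predicted partner is a
false positive):

* sensitivity   = % of reference pairs the predictor recovers;
* specificity (vs reference) = % of the pairs the predictor returns, when
  queried with every gene appearing in the reference set (either side), that
  are themselves reference pairs;
* specificity (vs negatives) = % of negative-set genes for which the
  predictor returns no ortholog in the target species.

Reference pairs match unordered: a predicted (b, a) counts for reference
(a, b), since orthology is symmetric.  Coverage statistics count distinct
genes per species, and per-tool "increase" percentages compare the
integrated table's coverage with each individual tool's.  All percentages
are rounded half-up to integers at reporting interfaces; numerators and
denominators are kept so every ratio can be reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from ._util import ParseError, TableSource, iter_tsv, percent, write_tsv
from .integration import OrthologPair, ToolPairSet, classify_relationships


def _unordered(pairs: Iterable[tuple[int, int]]) -> set[frozenset[int]]:
    return {frozenset(p) for p in pairs}


@dataclass
class ReferencePairSet:
    """Curated high-confidence ortholog pairs, partitioned into subsets."""

    pairs: set[tuple[int, int]]
    subsets: dict[str, set[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        if self.subsets:
            union = set().union(*self.subsets.values())
            if union != self.pairs or sum(len(s) for s in self.subsets.values()) != len(self.pairs):
                raise ValueError("subsets must partition the reference pairs")

    @property
    def subset_sizes(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.subsets.items()}

    def genes(self) -> set[int]:
        out: set[int] = set()
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return out


@dataclass
class NegativeGeneSet:
    """Genes declared lineage-specific: no true ortholog outside the lineage."""

    genes: set[int]
    species: str

    def __post_init__(self):
        if not self.genes:
            raise ValueError("negative gene set is empty")


def read_reference_pairs(source: TableSource) -> ReferencePairSet:
    """Tab-separated (gene_a, gene_b, subset_label)."""
    pairs: set[tuple[int, int]] = set()
    subsets: dict[str, set[tuple[int, int]]] = {}
    for line_no, fields in iter_tsv(source):
        if len(fields) != 3:
            raise ParseError(f"expected 3 columns, got {len(fields)}", line_no)
        try:
            pair = (int(fields[0]), int(fields[1]))
        except ValueError:
            raise ParseError(f"non-integer gene ids {fields[:2]}", line_no) from None
        pairs.add(pair)
        subsets.setdefault(fields[2], set()).add(pair)
    return ReferencePairSet(pairs, subsets)


def read_negative_genes(source: TableSource, species: str) -> NegativeGeneSet:
    """One gene_id per line."""
    genes: set[int] = set()
    for line_no, fields in iter_tsv(source):
        try:
            genes.add(int(fields[0]))
        except ValueError:
            raise ParseError(f"non-integer gene id {fields[0]!r}", line_no) from None
    return NegativeGeneSet(genes, species)


@dataclass
class Ratio:
    numerator: int
    denominator: int

    @property
    def pct(self) -> int:
        return percent(self.numerator, self.denominator)

    @property
    def value(self) -> float:
        return 100.0 * self.numerator / self.denominator


class Predictor:
    """A queryable pair set: the interface every benchmark operation uses."""

    def __init__(self, pairs: Iterable[tuple[int, int]], name: str = "predictor"):
        self.name = name
        self.pairs = set(pairs)
        self._by_gene: dict[int, set[tuple[int, int]]] = {}
        for a, b in self.pairs:
            self._by_gene.setdefault(a, set()).add((a, b))
            self._by_gene.setdefault(b, set()).add((a, b))

    @classmethod
    def from_ortholog_pairs(cls, pairs: Sequence[OrthologPair], name: str = "integrated"):
        return cls({p.key() for p in pairs}, name)

    @classmethod
    def from_tool_pair_set(cls, tps: ToolPairSet):
        return cls(tps.pair_keys, tps.tool_name)

    def query(self, gene: int) -> set[tuple[int, int]]:
        """All stored pairs involving the gene, on either side."""
        return self._by_gene.get(gene, set())

    def partners(self, gene: int) -> set[int]:
        return {a if b == gene else b for a, b in self.query(gene)}


def sensitivity(predicted_pairs: Iterable[tuple[int, int]], reference: ReferencePairSet) -> Ratio:
    """Fraction of reference pairs recovered (unordered matching)."""
    if not reference.pairs:
        raise ValueError("empty reference set")
    ref = _unordered(reference.pairs)
    pred = _unordered(predicted_pairs)
    return Ratio(len(pred & ref), len(ref))


def specificity_vs_reference(predictor: Predictor, reference: ReferencePairSet) -> Optional[Ratio]:
    """Among pairs returned for every reference gene, the fraction in the
    reference set.  None when the predictor returns nothing (not computable)."""
    if not reference.pairs:
        raise ValueError("empty reference set")
    returned: set[frozenset[int]] = set()
    for gene in reference.genes():
        returned |= _unordered(predictor.query(gene))
    if not returned:
        return None
    ref = _unordered(reference.pairs)
    return Ratio(len(returned & ref), len(returned))


def specificity_vs_negative(
    predictor: Predictor, negatives: NegativeGeneSet, target_genes: set[int] | None = None
) -> Ratio:
    """Fraction of negative-set genes with no predicted ortholog.

    `target_genes`, when given, restricts which partners count as being in
    the target species (useful when gene-ID namespaces could overlap).
    """
    without = 0
    for gene in negatives.genes:
        partners = predictor.partners(gene)
        if target_genes is not None:
            partners &= target_genes
        if not partners:
            without += 1
    return Ratio(without, len(negatives.genes))


def coverage_increase_pct(integrated_count: int, tool_count: int) -> int:
    """100 * (integrated / tool - 1), rounded half-up."""
    if tool_count == 0:
        raise ZeroDivisionError("tool covers zero genes")
    from ._util import round_half_up

    return round_half_up(100.0 * (integrated_count / tool_count - 1.0))


@dataclass
class CoverageReport:
    genes_covered: dict[str, int]  # species -> distinct genes
    n_pairs: int
    relationship_counts: dict[str, int]
    per_tool_genes: dict[str, dict[str, int]]  # tool -> species -> genes
    per_tool_pairs: dict[str, int]
    increase_pct: dict[str, dict[str, Optional[int]]]  # tool -> species -> pct


def coverage_and_increase(
    integrated_pairs: Sequence[OrthologPair],
    per_tool_pair_sets: Sequence[ToolPairSet],
    species_pair: tuple[str, str],
) -> CoverageReport:
    sp_a, sp_b = species_pair
    genes_a = {p.gene_a for p in integrated_pairs}
    genes_b = {p.gene_b for p in integrated_pairs}
    _, rel_counts = classify_relationships(integrated_pairs)

    per_tool_genes: dict[str, dict[str, int]] = {}
    per_tool_pairs: dict[str, int] = {}
    increase: dict[str, dict[str, Optional[int]]] = {}
    for tps in per_tool_pair_sets:
        ta = {a for a, _ in tps.pair_keys}
        tb = {b for _, b in tps.pair_keys}
        per_tool_genes[tps.tool_name] = {sp_a: len(ta), sp_b: len(tb)}
        per_tool_pairs[tps.tool_name] = len(tps.pair_keys)
        increase[tps.tool_name] = {
            sp_a: coverage_increase_pct(len(genes_a), len(ta)) if ta else None,
            sp_b: coverage_increase_pct(len(genes_b), len(tb)) if tb else None,
        }
    return CoverageReport(
        genes_covered={sp_a: len(genes_a), sp_b: len(genes_b)},
        n_pairs=len({p.key() for p in integrated_pairs}),
        relationship_counts=rel_counts,
        per_tool_genes=per_tool_genes,
        per_tool_pairs=per_tool_pairs,
        increase_pct=increase,
    )


@dataclass
class EvaluationReport:
    """Sensitivity/specificity for a set of predictors plus coverage stats."""

    sensitivity: dict[str, Ratio]
    specificity_reference: dict[str, Optional[Ratio]]
    specificity_negative: dict[str, Ratio]
    coverage: Optional[CoverageReport] = None

    def summary_lines(self) -> list[str]:
        lines = ["predictor\tsensitivity%\tspec_ref%\tspec_neg%"]
        for name in sorted(self.sensitivity):
            sens = self.sensitivity[name].pct
            spec_r = self.specificity_reference.get(name)
            spec_n = self.specificity_negative.get(name)
            lines.append(
                f"{name}\t{sens}\t"
                f"{spec_r.pct if spec_r is not None else 'NA'}\t"
                f"{spec_n.pct if spec_n is not None else 'NA'}"
            )
        return lines

    def write(self, path) -> None:
        rows = []
        for name in sorted(self.sensitivity):
            sens = self.sensitivity[name]
            spec_r = self.specificity_reference.get(name)
            spec_n = self.specificity_negative.get(name)
            rows.append(
                (
                    name,
                    sens.pct,
                    sens.numerator,
                    sens.denominator,
                    spec_r.pct if spec_r else "NA",
                    spec_r.numerator if spec_r else "NA",
                    spec_r.denominator if spec_r else "NA",
                    spec_n.pct if spec_n else "NA",
                    spec_n.numerator if spec_n else "NA",
                    spec_n.denominator if spec_n else "NA",
                )
            )
        write_tsv(
            path,
            [
                "predictor",
                "sensitivity_pct",
                "recovered",
                "reference_total",
                "spec_ref_pct",
                "spec_ref_num",
                "spec_ref_den",
                "spec_neg_pct",
                "spec_neg_num",
                "spec_neg_den",
            ],
            rows,
        )


def evaluate_predictors(
    predictors: Mapping[str, Predictor],
    reference: ReferencePairSet,
    negatives: NegativeGeneSet | None = None,
    target_genes: set[int] | None = None,
) -> EvaluationReport:
    """Run the full benchmark for several predictors at once."""
    report = EvaluationReport({}, {}, {})
    for name, predictor in predictors.items():
        report.sensitivity[name] = sensitivity(predictor.pairs, reference)
        report.specificity_reference[name] = specificity_vs_reference(predictor, reference)
        if negatives is not None:
            report.specificity_negative[name] = specificity_vs_negative(
                predictor, negatives, target_genes
            )
    return report
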