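"""GO molecular-function semantic similarity and per-tool weights.

A consensus count treats all source tools as equal.  To weight them by the
functional consistency of what they predict, each tool's pairs are scored by
the GO molecular-function similarity of the two genes, computed from an
information-content measure over an annotation corpus:

    p(t)  = (annotations to t or any of its descendants) / (total annotations)
    ic(t) = -ln p(t)

Term-term similarity is the Lin measure, 2*ic(MICA) / (ic(t1) + ic(t2)) with
MICA the common ancestor of maximal IC; gene-gene similarity is the
best-match average (BMA) over the two genes' term sets.  Both are in [0, 1].
A Resnik option (raw ic(MICA), unbounded) is available behind a switch.

Because many annotations are themselves transferred from orthologs (IEA and
similar evidence), similarity can be computed on three nested evidence
subsets: MF1 (all codes), MF2 (experimental plus author/curator statements),
MF3 (experimental only).  Per-tool weights are each tool's mean pair
similarity divided by the median over tools, so the median tool has weight 1;
a pair's weighted score is the sum of its supporting tools' weights, which
reduces to the simple count when all weights are 1.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import obonet

from ._util import ParseError, TableSource, iter_tsv
from .integration import OrthologPair, ToolPairSet

MF_ROOT = "GO:0003674"

#: experimental evidence codes
_EXPERIMENTAL = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})
#: author/curator-statement codes
_CURATED = frozenset({"TAS", "NAS", "IC"})

EVIDENCE_SUBSETS: dict[str, frozenset[str] | None] = {
    "MF1": None,  # all evidence codes
    "MF2": _EXPERIMENTAL | _CURATED,
    "MF3": _EXPERIMENTAL,
}


class NotComputable(Exception):
    """A statistic with an empty basis (no annotated pairs, no means, ...)."""


class GoDag:
    """Molecular-function is_a DAG with memoized ancestor sets."""

    def __init__(self, parents: Mapping[str, set[str]], root: str = MF_ROOT):
        self.parents = {t: set(ps) for t, ps in parents.items()}
        self.root = root
        if root not in self.parents:
            self.parents[root] = set()
        self._ancestors: dict[str, frozenset[str]] = {}
        self._validate()

    def _validate(self) -> None:
        for term in self.parents:
            anc = self.ancestors(term)  # raises on cycles
            if term != self.root and self.root not in anc:
                raise ValueError(f"term {term} does not reach the root {self.root}")

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str, include_self: bool = True) -> frozenset[str]:
        """All terms reachable via is_a edges, including the term itself."""
        if term not in self.parents:
            raise KeyError(f"term {term} not in DAG")
        cached = self._ancestors.get(term)
        if cached is None:
            seen: set[str] = set()
            stack = [term]
            active = {term}
            while stack:
                t = stack[-1]
                remaining = self.parents[t] - seen
                if remaining:
                    p = remaining.pop()
                    if p in active:
                        raise ValueError(f"cycle through {p}")
                    if p not in self.parents:
                        raise KeyError(f"parent {p} of {t} not in DAG")
                    stack.append(p)
                    active.add(p)
                else:
                    stack.pop()
                    active.discard(t)
                    seen.add(t)
            cached = frozenset(seen)
            self._ancestors[term] = cached
        return cached if include_self else cached - {term}


def load_obo(source) -> GoDag:
    """Read an OBO 1.2 ontology, keeping molecular_function is_a edges only."""
    graph = obonet.read_obo(source)
    mf_nodes = {
        n for n, data in graph.nodes(data=True)
        if data.get("namespace", "molecular_function") == "molecular_function"
    }
    parents: dict[str, set[str]] = {n: set() for n in mf_nodes}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a" and child in mf_nodes and parent in mf_nodes:
            parents[child].add(parent)
    roots = [t for t, ps in parents.items() if not ps]
    if len(roots) != 1:
        raise ValueError(f"expected one molecular_function root, found {sorted(roots)}")
    return GoDag(parents, root=roots[0])


@dataclass
class GoAnnotationSet:
    """gene_id -> set of (GO term, evidence code), with its subset label."""

    assignments: dict[int, set[tuple[str, str]]]
    subset_selector: str = "MF1"

    def terms_for(self, gene_id: int) -> set[str]:
        return {t for t, _ in self.assignments.get(gene_id, set())}

    def genes(self) -> set[int]:
        return set(self.assignments)


def load_gaf(source: TableSource, dag: GoDag | None = None) -> GoAnnotationSet:
    """Read GAF 2.x annotations: columns 2 (gene), 5 (term), 7 (evidence),
    9 (aspect); only aspect F rows are kept.  '!' comment lines ignored."""
    assignments: dict[int, set[tuple[str, str]]] = {}
    for line_no, fields in iter_tsv(source, comment="!"):
        if len(fields) < 9:
            raise ParseError(f"GAF row with {len(fields)} columns (< 9)", line_no)
        if fields[8] != "F":
            continue
        try:
            gene_id = int(fields[1])
        except ValueError:
            raise ParseError(f"non-integer gene id {fields[1]!r}", line_no) from None
        term, evidence = fields[4], fields[6]
        if dag is not None and term not in dag:
            raise ParseError(f"term {term} not in ontology", line_no)
        assignments.setdefault(gene_id, set()).add((term, evidence))
    return GoAnnotationSet(assignments, "MF1")


def filter_by_evidence(annotations: GoAnnotationSet, subset: str) -> GoAnnotationSet:
    """Restrict to an evidence subset; genes left with no terms are dropped."""
    if subset not in EVIDENCE_SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {sorted(EVIDENCE_SUBSETS)}")
    allowed = EVIDENCE_SUBSETS[subset]
    if allowed is None:
        return GoAnnotationSet({g: set(ts) for g, ts in annotations.assignments.items() if ts}, subset)
    filtered = {
        g: kept
        for g, ts in annotations.assignments.items()
        if (kept := {(t, e) for t, e in ts if e in allowed})
    }
    return GoAnnotationSet(filtered, subset)


@dataclass
class TermIC:
    """Information content per term over an annotation corpus."""

    ic: dict[str, float]
    total_annotations: int

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __getitem__(self, term: str) -> float:
        return self.ic[term]


def compute_ic(annotations: GoAnnotationSet, dag: GoDag) -> TermIC:
    """IC from annotation frequencies, counting descendants.

    Each distinct (gene, term) assignment is one annotation instance and
    counts toward the term and all its ancestors.  Terms never reached have
    undefined IC and are excluded from similarity computations.
    """
    counts: dict[str, int] = {}
    total = 0
    for gene, terms in annotations.assignments.items():
        for term in {t for t, _ in terms}:
            total += 1
            for anc in dag.ancestors(term):
                counts[anc] = counts.get(anc, 0) + 1
    if total == 0:
        raise NotComputable("empty annotation corpus")
    ic = {t: -math.log(c / total) for t, c in counts.items()}
    return TermIC(ic, total)


def _mica_ic(t1: str, t2: str, dag: GoDag, ic: TermIC) -> float:
    common = dag.ancestors(t1) & dag.ancestors(t2)
    common_ic = [(ic[t], t) for t in common if t in ic]
    if not common_ic:
        return 0.0
    # ties in IC broken by term ID order (no numeric effect)
    return max(common_ic, key=lambda pair: (pair[0], pair[1]))[0]


def term_similarity(t1: str, t2: str, dag: GoDag, ic: TermIC, method: str = "lin") -> float:
    """Similarity between two MF terms; Lin (default, in [0,1]) or Resnik."""
    for t in (t1, t2):
        if t not in dag:
            raise KeyError(f"term {t} not in DAG")
        if t not in ic:
            raise ValueError(f"term {t} has undefined IC (never annotated)")
    if method == "resnik":
        return _mica_ic(t1, t2, dag, ic)
    if method != "lin":
        raise ValueError(f"unknown similarity method {method!r}")
    denom = ic[t1] + ic[t2]
    if denom == 0.0:
        return 0.0
    if t1 == t2:
        return 1.0
    return 2.0 * _mica_ic(t1, t2, dag, ic) / denom


def gene_pair_similarity(
    terms_a: Iterable[str],
    terms_b: Iterable[str],
    dag: GoDag,
    ic: TermIC,
    method: str = "lin",
) -> Optional[float]:
    """Best-match-average similarity of two term sets; None if not computable.

    Terms with undefined IC (annotation frequency zero in the corpus) are
    excluded; if either side ends up empty the pair is not computable.
    """
    a = sorted(t for t in set(terms_a) if t in dag and t in ic)
    b = sorted(t for t in set(terms_b) if t in dag and t in ic)
    if not a or not b:
        return None
    sim = [[term_similarity(ta, tb, dag, ic, method) for tb in b] for ta in a]
    row_max_mean = sum(max(row) for row in sim) / len(a)
    col_max_mean = sum(max(sim[i][j] for i in range(len(a))) for j in range(len(b))) / len(b)
    return (row_max_mean + col_max_mean) / 2.0


@dataclass
class ToolSimilarity:
    mean_sim: float
    n_pairs: int


def tool_mean_similarity(
    tool_pair_set: ToolPairSet,
    annotations: GoAnnotationSet,
    dag: GoDag,
    ic: TermIC,
    method: str = "lin",
) -> ToolSimilarity:
    """Mean gene-pair similarity over a tool's pairs with annotated genes."""
    values = []
    for pair in tool_pair_set.pairs:
        a, b = pair.key()
        s = gene_pair_similarity(
            annotations.terms_for(a), annotations.terms_for(b), dag, ic, method
        )
        if s is not None:
            values.append(s)
    if not values:
        raise NotComputable(f"tool {tool_pair_set.tool_name}: no annotated pairs")
    return ToolSimilarity(sum(values) / len(values), len(values))


@dataclass
class ToolWeights:
    """Per-tool weights, median-normalized to 1."""

    weight: dict[str, float]
    mean_sim: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, tool: str) -> float:
        return self.weight[tool]


def compute_tool_weights(mean_sims: Mapping[str, Optional[float]]) -> ToolWeights:
    """weight(tool) = mean_sim(tool) / median over tools (midpoint for even n)."""
    usable = {t: s for t, s in mean_sims.items() if s is not None}
    if not usable:
        raise NotComputable("no tool has a computable mean similarity")
    med = statistics.median(usable.values())
    if med <= 0:
        raise NotComputable("median mean-similarity is zero")
    return ToolWeights({t: s / med for t, s in usable.items()}, dict(usable))


def weighted_score(pair: OrthologPair, weights: ToolWeights) -> float:
    """Sum of the supporting tools' weights."""
    missing = [t for t in pair.supporting_tools if t not in weights.weight]
    if missing:
        raise KeyError(f"no weight for supporting tool(s) {sorted(missing)}")
    return sum(weights.weight[t] for t in pair.supporting_tools)


def add_weighted_scores(pairs: Sequence[OrthologPair], weights: ToolWeights) -> list[OrthologPair]:
    for p in pairs:
        p.weighted_score = weighted_score(p, weights)
    return list(pairs)
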