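# Methods

## Identifier normalization and gene-level collapsing

All inputs are standardized to one integer (Entrez-style) gene-ID namespace
per species via mapping tables (`raw_id, id_type, gene_id[, protein_length]`).
Gene symbols match case-insensitively (capitalisation conventions differ
across species databases); accessions match exactly. A raw identifier that
resolves to several genes fans out to every gene, each result flagged
`ambiguous_source_id`: inclusiveness is the deliberate default, since
silently picking one gene could drop a gene relevant to a downstream study.
Protein-isoform-level predictions collapse to gene level; any two isoform
pairs of the same gene pair become one record. Unmapped identifiers never
abort a run — they accumulate in a machine-readable report (`raw_id, species,
reason`).

## Consensus integration and filters

The integrated table over an ordered species pair (input → output) is the
set union of the selected tools' gene-level pair sets. Per pair:

* `simple_score` = number of supporting tools (1 … n_tools);
* provenance = the supporting tool names plus each tool's native score
  preserved verbatim;
* a relationship class from partner counts *within the table being
  classified*: one-to-one, one-to-many (query gene has several partners),
  many-to-one, many-to-many.

Filters, all grouped by the query-side gene:

* **score filter** (threshold 2 or 3; other values only via explicit
  override): keeps pairs at/above threshold. A sub-threshold pair survives,
  flagged `low_score_only_match`, only when it is its query gene's *single*
  candidate — that is the literal reading of the only-match rescue. The
  alternative reading (keep the best sub-threshold candidates whenever none
  pass) is available as `rescue="best_below_threshold"` but is not the
  default.
* **best-match filter**: keeps exactly the pairs achieving the query gene's
  maximum simple score; ties are all kept (flagged `best_match`).

Output order is canonical (query gene, descending score, partner gene), so
identical inputs give byte-identical outputs. Pairs are stored once per
ordered species pair; the reverse direction is served by transposing the
table rather than re-integrating.

The partner-count definition is applied per pair, not per connected
component: in the three-pair table {(a1,b1), (a1,b2), (a2,b1)}, (a1,b2) is
one-to-many and (a2,b1) many-to-one, and only (a1,b1) — whose both sides
have several partners — is many-to-many, even though all three pairs belong
to one connected cluster.

## GO semantic similarity and tool weights

Information content is computed from the annotation corpus itself:
`p(t)` = (annotation instances on t or any descendant) / (total annotation
instances), `IC(t) = −ln p(t)` (natural log). A distinct (gene, term) direct
assignment is one instance; terms never reached have undefined IC and are
excluded from similarity computations. Term-term similarity is Lin's
measure, `2·IC(MICA)/(IC(t1)+IC(t2))`, with MICA the common ancestor of
maximal IC (IC ties broken by term-ID order — no numeric effect); it is 1
for identical informative terms and 0 when the only shared information is
the root. Lin + best-match-average was chosen because it is self-normalizing
to [0, 1], matching the scale on which per-tool mean similarities in the
0.6–0.7 range produce weights near 1; Resnik (raw IC of the MICA, unbounded)
sits behind a `method="resnik"` switch.

Gene-pair similarity is the best-match average over the two term sets:
mean of each term's best match in the other set, computed in both directions
and averaged. Pairs where either gene has no informative term are
*not computable* and are excluded from means rather than scored 0.

Evidence subsets: MF1 = all codes; MF2 = {EXP, IDA, IPI, IMP, IGI, IEP, TAS,
NAS, IC} (experimental plus author/curator statements); MF3 = the six
experimental codes only. The named subsets come from the GO evidence-code
vocabulary's standard groupings; the point of MF2/MF3 is to limit circularity
from annotations that were themselves transferred between orthologs (IEA and
similar).

Tool weights: `weight(tool) = mean_sim(tool) / median over tools` (midpoint
median for even counts), so the median tool has weight exactly 1 and weights
are invariant under rescaling all means. A pair's weighted score is the sum
of its supporting tools' weights — chosen over alternatives (e.g. mean) so
that it reduces exactly to the simple count when all weights are 1 and stays
comparable with it.

## Protein alignment

Smith–Waterman local alignment under Gotoh's affine-gap recurrences: a gap
of length L costs `gap_open + (L−1)·gap_extend`, defaults BLOSUM62 /
10.0 / 0.5 — the classic protein defaults of the EMBOSS-style water
aligner. Residues absent from the matrix (e.g. selenocysteine U) are scored
through the wildcard X row. All cell values are multiples of 0.5, so the
traceback's floating-point equality tests are exact. Determinism is pinned
down fully: the best cell is the first in row-major order among ties; the
traceback prefers diagonal > up (gap in the second sequence) > left, and
closes a gap as early as possible; exactly one optimal alignment is
returned. For genes with several isoforms the longest represents the gene,
length ties broken by the lexicographically smallest accession.

Percent identity = `*` columns / full alignment length (gap columns count in
the denominator, the reporting convention of the cited aligner family);
percent similarity additionally counts `:` columns (positive substitution
score). Domain intervals (1-based inclusive on the source protein) map
through the alignment to the column span of their first and last aligned
residues; gap columns inside the span count in the denominator. A domain
wholly outside the locally aligned region yields an explicit not-aligned
record; partial overlaps are clipped to the aligned part. Interfaces report
percentages rounded half-up to integers; full precision is kept internally.

## Benchmarking

Reference pairs match unordered (orthology is symmetric). Sensitivity = %
of reference pairs recovered. Specificity against the reference = among the
de-duplicated pairs the predictor returns when queried with *every* gene
appearing in the reference set (both species' sides), the fraction that are
reference pairs. Specificity against a lineage-specific negative set = % of
negative genes for which the predictor returns no ortholog in the target
species. Coverage counts distinct genes per species; a tool's increase
percentage is `100·(integrated coverage / tool coverage − 1)`. Every
reported ratio keeps its numerator and denominator; percentages round
half-up at reporting interfaces only.

## The synthetic world

`fixtures.WorldSpec` defaults define the emulated study conditions: two
species (human → fly), 200 genes per side, 70% of human genes with a true
fly ortholog and 15% of those with a second fly partner (the fly side being
the less redundant genome), nine tools with recalls spread 0.45–0.90
(mirroring the 39–81% per-tool sensitivities seen on curated reference
sets) and false-positive rates 0.02–0.10 of the truth-set size, 30% of tool
rows emitted as protein isoforms to exercise collapsing, GO annotation on
85% of genes with an evidence mix that is 50% IEA, and disease records
spread over all mapping routes with half of ortholog pairs sharing a
planted literature category. One seed fixes everything; sub-generators draw
from named substreams so adding one does not perturb the others.

The GO fixture annotates both members of a true pair into the same branch of
a small 4-level DAG (same leaf with probability 0.8, else a sibling), while
genes appearing only in false pairs get a random branch — so true pairs are
functionally similar and false pairs usually are not, giving the consensus
score its planted correlation with similarity. The sequence fixture builds
equal-length pairs from common templates: the 40-residue domain block is
copied at `domain_conservation` (default 1.0), the flanks at 0.35 — high
enough that the local alignment extends through them, low enough that
overall identity sits far below the domain's. What passing tests on this
world do **not** show: robustness to realistic sequence evolution (indels,
composition bias), realistic GO topology, correlated tool errors, or
real-world identifier noise.

Problem sizes used by the default test run and the acceptance script
(200 genes/side, ≈150 true pairs, 25 sequence pairs, 60 disease records,
200 oracle-checked alignments of ≤30 residues, ≥100 oracle-checked GO pairs)
were chosen to exercise every score stratum and mapping route while keeping
the whole suite in the low seconds.

## Numerical and degenerate-input choices

* Percentages: round half-up at interfaces, full precision internally.
* Median of tool means: midpoint of the two central values for even counts.
* Empty annotation corpus, all-missing tool means, empty reference or
  negative sets: errors. Unmatched IDs, unannotated pairs, zero-pair tools:
  reported not-computable outcomes, never silent zeros.
* Score-filter thresholds outside {2, 3} require an explicit override flag.
* `weighted_score` requires a weight for every supporting tool; a missing
  weight is an error rather than an implicit 1.

## Known limitations

* The disease-term simplification rules and the Y01/Y02 keyword lists are
  seeded heuristics shipped as configuration; genuinely novel phrasings land
  in the unmapped report by design rather than being guessed.
* The aligner is a plain Python dynamic program, adequate for the intended
  per-pair display use (hundreds of residues), not for proteome-scale
  precomputation.
* Cross-release reconciliation of the source tools' genome builds is out of
  scope; disagreements caused by build skew appear as ordinary tool
  disagreement.
* The par-1/MARK4 worked-example check requires two external RefSeq records
  and stays unresolved until they are supplied.
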