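# orthomerge

Integrative ortholog prediction for functional and disease-focused studies.

Individual ortholog-prediction tools — phylogeny-based, sequence-cluster-based
and protein-interaction-based alike — disagree with each other, cover different
parts of each genome, and publish their calls in incompatible identifier
namespaces. `orthomerge` merges the gene-pair predictions of any set of such
tools into a single scored table for pairs of model organisms (human, mouse,
zebrafish, fly, worm, yeast), so that a biologist querying with a gene list can
cast a wide net or restrict to high-confidence calls, and so that human disease
genes can be tied to their model-organism orthologs.

## What it computes

* **Consensus score.** After standardizing all identifiers to integer
  (Entrez-style) gene IDs and collapsing protein isoforms to gene level, the
  integrated table is the union over the selected tools, and each gene pair
  carries a *simple score* = number of tools supporting it. Filters:
  score ≥ 2 / ≥ 3 (with a rescue for a query gene's *only* match) and a
  best-match filter that keeps each query gene's top-scoring partner(s).
* **Weighted score.** Each tool is weighted by the mean GO molecular-function
  semantic similarity of its predicted pairs — Lin similarity
  `sim(t1,t2) = 2·IC(MICA) / (IC(t1)+IC(t2))` with `IC(t) = −ln p(t)` over an
  annotation corpus, combined per gene pair by the best-match average —
  normalized so the median tool has weight 1. A pair's weighted score is the
  sum of its supporting tools' weights. Annotation evidence can be restricted
  to MF2 (experimental + author/curator statements) or MF3 (experimental only)
  to avoid circularity with electronically transferred annotations.
* **Protein alignment.** Smith–Waterman local alignment (affine gaps, BLOSUM62,
  gap open 10, extend 0.5) of each gene's longest isoform, with a per-column
  match line (`*` identical, `:` positive substitution score, `.` other,
  space = gap) and percent identity both overall and within annotated domain
  intervals mapped through the alignment.
* **Benchmarking.** Sensitivity against curated reference pair sets,
  specificity against both the reference sets and a lineage-specific negative
  gene set, plus genome-coverage and per-tool coverage-increase statistics.
* **Disease/trait mapping.** Free-text disease and trait terms (OMIM-like and
  GWAS-like records) normalized to MeSH disease categories (plus Y01 "disease
  risk factor, diagnosis or treatment" and Y02 "trait") through a fixed
  precedence of routes — clinical-synopsis heading, MeSH entry-term lookup,
  manual overrides, keyword rules, else an unmapped report — and joined to
  model-organism orthologs through the integrated table.

A fully synthetic "toy orthology world" generator (`orthomerge.fixtures`)
emits every input format the pipeline consumes — tool tables, ID maps, OBO +
GAF, FASTA + domain intervals, disease tables — with planted ground truth, so
the whole pipeline runs and is tested without any download.

## Worked example

Generate a world, query one human gene, and inspect its alignment:

```sh
$ orthomerge --quiet fixtures --seed 11 --n-genes 120 --out demo
$ orthomerge --quiet query --world demo --id HSYM10003 --out demo/hits.tsv
$ cat demo/hits.tsv
#input_species  gene_a  symbol_a  output_species  gene_b  symbol_b  simple_score  ...
human   10003       fly     50003       6       tool2,tool3,tool5,tool6,tool8,tool9 ... one-to-one
```

Human gene 10003 maps to fly gene 50003 with simple score 6: six of the nine
synthetic tools support the pair, and the pair is one-to-one (each side has
exactly one partner in the table). The planted truth
(`demo/ground_truth_pairs.tsv`) confirms 10003–50003 is a true pair.

```sh
$ orthomerge --quiet align --fasta demo/proteins.fasta --domains demo/domains.tsv \
      --gene-a 10003 --gene-b 50003 | head -5
# score=325.5 length=136 identity=54% similarity=60%
# domain planted_domain (a) cols 40-79 identity=100%
# domain planted_domain (b) cols 40-79 identity=100%
PSHGYEIICTNFEGHRFIAFCCM----QCTQDI--CSAKLFKAHGMLFMASPVCAAKMIE
*...:****...:.*      *.    :..*:*  ***.*********************
```

Overall identity is 54% while the planted conserved domain is 100% identical —
the typical shape of diverged orthologs, where the functionally critical
domain is far better conserved than the full-length protein.

```sh
$ orthomerge --quiet weights --world demo --obo demo/fixture.obo \
      --gaf demo/fixture.gaf --out demo/w.tsv && head -3 demo/w.tsv
#tool   mean_similarity n_pairs weight
tool1   0.8524  11      1.0574
tool2   0.8404  17      1.0426
```

Each tool's mean GO similarity over its predicted pairs, divided by the
median over tools, gives its weight (the median tool gets exactly 1).

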