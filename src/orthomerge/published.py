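"""Published fly-human benchmark counts for the nine integrated source tools.

These are the reported genome-coverage and benchmark counts for the nine
ortholog prediction tools and their integration over the Drosophila-human
species pair, used as worked-example inputs for the reporting arithmetic
(coverage-increase percentages, benchmark ratios).  They are inputs, not
computed results: reproducing the full-scale counts would require the nine
tools' genome-wide downloads.
"""

from __future__ import annotations

# tool -> (fly-human relationships, fly genes covered, human genes covered)
TOOL_COVERAGE: dict[str, tuple[int, int, int]] = {
    "Compara": (16880, 8416, 9826),
    "Homologene": (5423, 5015, 4762),
    "Inparanoid": (10204, 5855, 7441),
    "IsoBase": (9051, 8065, 7251),
    "OMA": (5673, 4499, 5222),
    "orthoMCL": (12853, 6435, 7890),
    "Phylome": (8690, 4560, 6251),
    "RoundUp": (7480, 5383, 6706),
    "TreeFam": (12894, 7156, 9106),
}

#: the integrated table over all nine tools
INTEGRATED_COVERAGE: tuple[int, int, int] = (28605, 9724, 12971)

#: curated reference-set subset sizes: transmembrane, kinase, oxphos pairs
REFERENCE_SUBSET_SIZES: dict[str, int] = {"transmembrane": 159, "kinase": 89, "oxphos": 71}

#: reference pairs recovered by the integrated table
INTEGRATED_RECOVERED: int = 301

#: human lineage-specific (negative-set) gene count
NEGATIVE_SET_SIZE: int = 1130

#: fly genes with >=1 literature disease category; of those, with a human ortholog
LITERATURE_FLY_GENES: int = 3557
LITERATURE_FLY_GENES_WITH_ORTHOLOG: int = 2739

#: fly disease genes (mapped from human disease/trait data) studied in disease
#: literature; of those, with the same disease category in the literature
OMIM_GWAS_FLY_GENES_IN_LITERATURE: int = 1534
OMIM_GWAS_FLY_GENES_CONFIRMED: int = 888
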