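"""A fully synthetic "toy orthology world" with known ground truth.

Every other module consumes standard files — per-tool prediction tables, ID
mapping tables, OBO/GAF ontology data, FASTA sequences with domain
intervals, disease/trait records — whose real counterparts are large
third-party downloads.  This module generates small, deterministic versions
of all of them with planted ground truth, so integration, scoring,
weighting, alignment, evaluation and disease mapping are all testable
end-to-end without any download.

The construction emulates the study conditions of a two-species
(human -> fly) integration of nine tools: per-tool recalls spread over
roughly 0.45-0.90 (mirroring the 39%-81% per-tool sensitivities seen on
curated reference sets), small per-tool false-positive rates, a minority of
one-to-many relationships (the fly genome is the less redundant side), and
annotation/evidence mixes in which roughly half of GO annotations are
electronically inferred.  Everything derives from one seed; sub-generators
draw from named substreams, so adding a generator does not perturb the
others.  What the generator does NOT emulate: real sequence evolution,
realistic GO topology, or tool-specific error correlations — tools err
independently here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .id_mapping import IdMap, load_id_map
from .integration import ToolPairSet, ToolTableConfig, ingest_tool_predictions

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# substream indices for the named random substreams
_S_TOPOLOGY, _S_TOOLS, _S_GO, _S_SEQ, _S_DISEASE = 0, 1, 2, 3, 4

_HUMAN_BASE = 10000
_FLY_BASE = 50000


def _rng(seed: int, stream: int, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream, sub)))


@dataclass
class WorldSpec:
    """Parameters of the synthetic orthology world; the seed fixes everything."""

    seed: int = 0
    n_genes_per_species: int = 200
    n_tools: int = 9
    tool_recalls: Optional[tuple[float, ...]] = None  # default: spread 0.45..0.90
    tool_fp_rates: Optional[tuple[float, ...]] = None  # default: spread 0.02..0.10
    pairable_fraction: float = 0.7  # human genes with a true fly ortholog
    frac_one_to_many: float = 0.15  # of pairable humans, with two fly partners
    isoform_fraction: float = 0.3  # tool rows emitted at protein (isoform) level
    annotation_density: float = 0.85  # genes receiving GO annotations
    annotation_tightness: float = 0.8  # ortholog partners annotated to the same leaf
    evidence_mix: tuple[tuple[str, float], ...] = (
        ("IEA", 0.50),
        ("IDA", 0.20),
        ("IMP", 0.10),
        ("TAS", 0.10),
        ("NAS", 0.05),
        ("IEP", 0.05),
    )
    n_go_branches: int = 8
    n_sequence_pairs: int = 25
    sequence_length_range: tuple[int, int] = (120, 300)
    domain_length: int = 40
    domain_conservation: float = 1.0  # planted identity within the domain block
    flank_conservation: float = 0.35  # planted identity within the flanks
    n_disease_records: int = 60
    route_mix: tuple[float, ...] = (0.25, 0.30, 0.10, 0.10, 0.10, 0.15)
    # (cs_heading, entry_term, manual_override, y01, y02, unmapped)
    shared_category_fraction: float = 0.5
    species_pair: tuple[str, str] = ("human", "fly")

    def __post_init__(self):
        if self.tool_recalls is None:
            self.tool_recalls = tuple(np.linspace(0.45, 0.90, self.n_tools))
        if self.tool_fp_rates is None:
            self.tool_fp_rates = tuple(np.linspace(0.02, 0.10, self.n_tools))
        if len(self.tool_recalls) != self.n_tools or len(self.tool_fp_rates) != self.n_tools:
            raise ValueError("tool_recalls/tool_fp_rates must have n_tools entries")
        for name, rates in (
            ("tool_recalls", self.tool_recalls),
            ("tool_fp_rates", self.tool_fp_rates),
        ):
            if any(not (0.0 <= r <= 1.0) for r in rates):
                raise ValueError(f"{name} outside [0, 1]")
        for name in (
            "pairable_fraction",
            "frac_one_to_many",
            "isoform_fraction",
            "annotation_density",
            "annotation_tightness",
            "domain_conservation",
            "flank_conservation",
            "shared_category_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.route_mix) - 1.0) > 1e-9 or len(self.route_mix) != 6:
            raise ValueError("route_mix must be 6 fractions summing to 1")

    @property
    def tool_names(self) -> tuple[str, ...]:
        return tuple(f"tool{i + 1}" for i in range(self.n_tools))


def _make_truth(spec: WorldSpec) -> tuple[list[int], list[int], set[tuple[int, int]]]:
    """Deterministic gene catalogs and true ortholog pairs (substream 0)."""
    rng = _rng(spec.seed, _S_TOPOLOGY)
    n = spec.n_genes_per_species
    humans = [_HUMAN_BASE + i for i in range(1, n + 1)]
    flies = [_FLY_BASE + i for i in range(1, n + 1)]
    n_pairable = int(round(spec.pairable_fraction * n))
    truth: set[tuple[int, int]] = set()
    next_fly = 0
    for k in range(n_pairable):
        if next_fly >= n:
            break
        h = humans[k]
        truth.add((h, flies[next_fly]))
        next_fly += 1
        if rng.random() < spec.frac_one_to_many and next_fly < n:
            truth.add((h, flies[next_fly]))
            next_fly += 1
    return humans, flies, truth


@dataclass
class GroundTruth:
    truth_pairs: set[tuple[int, int]]
    tool_true_pairs: dict[str, set[tuple[int, int]]]
    tool_false_pairs: dict[str, set[tuple[int, int]]]
    negative_human_genes: set[int]  # humans with no true fly ortholog

    def tool_pairs(self, tool: str) -> set[tuple[int, int]]:
        return self.tool_true_pairs[tool] | self.tool_false_pairs[tool]

    @property
    def all_emitted_pairs(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for t in self.tool_true_pairs:
            out |= self.tool_pairs(t)
        return out


@dataclass
class OrthologyWorld:
    spec: WorldSpec
    humans: list[int]
    flies: list[int]
    symbols_a: dict[int, str]
    symbols_b: dict[int, str]
    id_table_a: str  # mapping-table TSV text
    id_table_b: str
    tool_configs: dict[str, ToolTableConfig]
    tool_tables: dict[str, str]  # tool -> raw TSV text
    truth: GroundTruth

    def id_maps(self) -> tuple[IdMap, IdMap]:
        return (
            load_id_map(io.StringIO(self.id_table_a), self.spec.species_pair[0]),
            load_id_map(io.StringIO(self.id_table_b), self.spec.species_pair[1]),
        )

    def tool_pair_sets(self, report=None) -> list[ToolPairSet]:
        map_a, map_b = self.id_maps()
        return [
            ingest_tool_predictions(
                self.tool_configs[t], io.StringIO(self.tool_tables[t]), map_a, map_b, report
            )
            for t in self.spec.tool_names
        ]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "id_map_human.tsv").write_text(self.id_table_a)
        (outdir / "id_map_fly.tsv").write_text(self.id_table_b)
        for t, text in self.tool_tables.items():
            (outdir / f"{t}.tsv").write_text(text)
        truth_lines = ["#gene_a\tgene_b\n"] + [
            f"{a}\t{b}\n" for a, b in sorted(self.truth.truth_pairs)
        ]
        (outdir / "ground_truth_pairs.tsv").write_text("".join(truth_lines))
        (outdir / "negative_genes.tsv").write_text(
            "".join(f"{g}\n" for g in sorted(self.truth.negative_human_genes))
        )
        (outdir / "reference_pairs.tsv").write_text(
            "#gene_a\tgene_b\tsubset\n"
            + "".join(f"{a}\t{b}\tall\n" for a, b in sorted(self.truth.truth_pairs))
        )
        config_lines = ["#tool\tcol_a\tcol_b\ttype_a\ttype_b\tcol_score\n"]
        for t in self.spec.tool_names:
            c = self.tool_configs[t]
            config_lines.append(
                f"{t}\t{c.col_a}\t{c.col_b}\t{c.type_a or ''}\t{c.type_b or ''}\t"
                f"{'' if c.col_score is None else c.col_score}\n"
            )
        (outdir / "tools_config.tsv").write_text("".join(config_lines))
        symbol_lines = ["#species\tgene_id\tsymbol\n"]
        for g in self.humans:
            symbol_lines.append(f"{self.spec.species_pair[0]}\t{g}\t{self.symbols_a[g]}\n")
        for g in self.flies:
            symbol_lines.append(f"{self.spec.species_pair[1]}\t{g}\t{self.symbols_b[g]}\n")
        (outdir / "symbols.tsv").write_text("".join(symbol_lines))


def load_world_dir(path) -> tuple[IdMap, IdMap, dict[str, ToolTableConfig], dict[str, Path]]:
    """Read back a written world directory: ID maps, tool configs, table paths."""
    path = Path(path)
    map_a = load_id_map(path / "id_map_human.tsv", "human")
    map_b = load_id_map(path / "id_map_fly.tsv", "fly")
    configs: dict[str, ToolTableConfig] = {}
    tables: dict[str, Path] = {}
    from ._util import iter_tsv

    for _line, fields in iter_tsv(path / "tools_config.tsv"):
        tool, col_a, col_b, type_a, type_b, col_score = fields
        configs[tool] = ToolTableConfig(
            tool_name=tool,
            col_a=int(col_a),
            col_b=int(col_b),
            type_a=type_a or None,
            type_b=type_b or None,
            col_score=int(col_score) if col_score else None,
        )
        tables[tool] = path / f"{tool}.tsv"
    return map_a, map_b, configs, tables


def _symbols(genes: Sequence[int], prefix: str) -> dict[int, str]:
    return {g: f"{prefix}{g}" for g in genes}


def generate_orthology_world(spec: WorldSpec) -> OrthologyWorld:
    """Emit per-tool tables, ID maps, and the planted ground truth.

    Each tool's set is an independent Bernoulli sample of the truth at that
    tool's recall, plus false pairs at its false-positive rate (relative to
    the truth-set size), sampled among non-orthologous gene combinations.
    A configurable fraction of rows is emitted with isoform-level protein
    accessions to exercise gene-level collapsing.
    """
    humans, flies, truth = _make_truth(spec)
    truth_sorted = sorted(truth)
    symbols_a = _symbols(humans, "HSYM")
    symbols_b = _symbols(flies, "fsym")
    humans_with_ortholog = {a for a, _ in truth}
    negatives = set(humans) - humans_with_ortholog

    # mapping tables: entrez, symbol, species_db and two protein isoforms per gene
    def id_table(genes, symbols, db_prefix, acc_prefix, stream_sub):
        rng = _rng(spec.seed, _S_TOPOLOGY, stream_sub)
        lines = ["#raw_id\tid_type\tgene_id\tprotein_length\n"]
        for g in genes:
            length = int(rng.integers(150, 900))
            lines.append(f"{g}\tentrez\t{g}\t\n")
            lines.append(f"{symbols[g]}\tsymbol\t{g}\t\n")
            lines.append(f"{db_prefix}{g:07d}\tspecies_db\t{g}\t\n")
            lines.append(f"{acc_prefix}{g}.1\trefseq_protein\t{g}\t{length}\n")
            lines.append(f"{acc_prefix}{g}.2\trefseq_protein\t{g}\t{max(50, length - 80)}\n")
        return "".join(lines)

    id_table_a = id_table(humans, symbols_a, "HDB", "NP_H", 1)
    id_table_b = id_table(flies, symbols_b, "FBgn", "NP_F", 2)

    tool_true: dict[str, set[tuple[int, int]]] = {}
    tool_false: dict[str, set[tuple[int, int]]] = {}
    tool_tables: dict[str, str] = {}
    tool_configs: dict[str, ToolTableConfig] = {}

    # three raw-table dialects, cycled over the tools
    dialects = (
        ("entrez", "entrez", True),  # entrez/entrez with a native score column
        ("symbol", "species_db", False),  # symbol vs species-database ID, no score
        ("refseq_protein", "refseq_protein", True),  # isoform-level accessions
    )

    for idx, tool in enumerate(spec.tool_names):
        rng = _rng(spec.seed, _S_TOOLS, idx)
        recall, fp_rate = spec.tool_recalls[idx], spec.tool_fp_rates[idx]
        included = {p for p in truth_sorted if rng.random() < recall}
        n_false = int(round(fp_rate * len(truth_sorted)))
        false_pairs: set[tuple[int, int]] = set()
        guard = 0
        while len(false_pairs) < n_false and guard < 50 * (n_false + 1):
            guard += 1
            a = humans[int(rng.integers(len(humans)))]
            b = flies[int(rng.integers(len(flies)))]
            if (a, b) not in truth:
                false_pairs.add((a, b))
        tool_true[tool] = included
        tool_false[tool] = false_pairs

        type_a, type_b, has_score = dialects[idx % len(dialects)]
        lines = []
        for a, b in sorted(included | false_pairs):
            raw_as = _render_ids(a, type_a, symbols_a, "HDB", "NP_H", rng, spec.isoform_fraction)
            raw_bs = _render_ids(b, type_b, symbols_b, "FBgn", "NP_F", rng, spec.isoform_fraction)
            for raw_a in raw_as:
                for raw_b in raw_bs:
                    if has_score:
                        lines.append(f"{raw_a}\t{raw_b}\t{rng.random():.3f}\n")
                    else:
                        lines.append(f"{raw_a}\t{raw_b}\n")
        tool_tables[tool] = "".join(lines)
        tool_configs[tool] = ToolTableConfig(
            tool_name=tool,
            type_a=type_a,
            type_b=type_b,
            col_score=2 if has_score else None,
        )

    return OrthologyWorld(
        spec=spec,
        humans=humans,
        flies=flies,
        symbols_a=symbols_a,
        symbols_b=symbols_b,
        id_table_a=id_table_a,
        id_table_b=id_table_b,
        tool_configs=tool_configs,
        tool_tables=tool_tables,
        truth=GroundTruth(truth, tool_true, tool_false, negatives),
    )


def _render_ids(gene, id_type, symbols, db_prefix, acc_prefix, rng, isoform_fraction):
    if id_type == "entrez":
        return [str(gene)]
    if id_type == "symbol":
        return [symbols[gene]]
    if id_type == "species_db":
        return [f"{db_prefix}{gene:07d}"]
    # protein accessions: sometimes emit both isoforms (collapse exercise)
    if rng.random() < isoform_fraction:
        return [f"{acc_prefix}{gene}.1", f"{acc_prefix}{gene}.2"]
    return [f"{acc_prefix}{gene}.1"]


# ---------------------------------------------------------------- GO fixture


@dataclass
class GoFixture:
    obo_text: str
    gaf_text: str
    branch_of_pair: dict[tuple[int, int], int]
    gene_terms: dict[int, set[str]]  # planted direct annotations


def _go_term(branch: int, level: int, sibling: int = 0) -> str:
    return f"GO:1{branch:02d}{level:02d}{sibling:02d}"


def generate_go_fixture(spec: WorldSpec) -> GoFixture:
    """A rooted molecular-function DAG and a GAF annotating the world's genes.

    The DAG is `n_go_branches` chains of depth 4 under the root, each deep
    term with one sibling leaf.  Both members of a true ortholog pair are
    annotated into the same branch (usually the same leaf), so true pairs
    have high semantic similarity by construction; genes appearing only in
    false pairs are annotated into a random branch, so false pairs are
    usually split across branches and score low.
    """
    humans, flies, truth = _make_truth(spec)
    rng = _rng(spec.seed, _S_GO)
    root = "GO:0003674"

    terms: dict[str, Optional[str]] = {root: None}  # term -> is_a parent
    for b in range(spec.n_go_branches):
        parent = root
        for level in range(1, 5):
            t = _go_term(b, level)
            terms[t] = parent
            parent = t
        # sibling leaf under the level-3 term
        terms[_go_term(b, 4, 1)] = _go_term(b, 3)

    obo = ["format-version: 1.2", "ontology: fixture-go", ""]
    for t in sorted(terms):
        obo.append("[Term]")
        obo.append(f"id: {t}")
        obo.append(f"name: fixture term {t}")
        obo.append("namespace: molecular_function")
        if terms[t] is not None:
            obo.append(f"is_a: {terms[t]} ! parent")
        obo.append("")
    obo_text = "\n".join(obo)

    # branch assignment: one per true-ortholog component, keyed by human gene
    branch_of_human: dict[int, int] = {}
    for i, (a, _b) in enumerate(sorted(truth)):
        branch_of_human.setdefault(a, i % spec.n_go_branches)
    branch_of_fly: dict[int, int] = {}
    for a, b in sorted(truth):
        branch_of_fly.setdefault(b, branch_of_human[a])

    codes = [c for c, _ in spec.evidence_mix]
    probs = np.array([p for _, p in spec.evidence_mix])
    probs = probs / probs.sum()

    gene_terms: dict[int, set[str]] = {}
    gaf = ["!gaf-version: 2.1"]

    def annotate(gene: int, branch: Optional[int]):
        if rng.random() >= spec.annotation_density:
            return
        if branch is None:
            branch = int(rng.integers(spec.n_go_branches))
        # deep leaf, or its sibling when annotation is "loose"
        sibling = 0 if rng.random() < spec.annotation_tightness else 1
        chosen = {_go_term(branch, 4, sibling)}
        if rng.random() < 0.3:  # occasional extra shallower term
            chosen.add(_go_term(branch, int(rng.integers(1, 4))))
        gene_terms[gene] = chosen
        for t in sorted(chosen):
            ev = codes[int(rng.choice(len(codes), p=probs))]
            gaf.append(
                "\t".join(
                    [
                        "FIX",
                        str(gene),
                        f"G{gene}",
                        "",
                        t,
                        "FIX:0001",
                        ev,
                        "",
                        "F",
                        f"fixture gene {gene}",
                        "",
                        "protein",
                        "taxon:0000",
                        "20110831",
                        "FIX",
                    ]
                )
            )

    for g in humans:
        annotate(g, branch_of_human.get(g))
    for g in flies:
        annotate(g, branch_of_fly.get(g))

    branch_of_pair = {(a, b): branch_of_human[a] for a, b in truth}
    return GoFixture(obo_text, "\n".join(gaf) + "\n", branch_of_pair, gene_terms)


# ---------------------------------------------------------- sequence fixture


@dataclass
class PlantedSequencePair:
    gene_a: int
    gene_b: int
    accession_a: str
    accession_b: str
    domain_identity_planted: float  # realized identity within the domain block
    domain_a: tuple[int, int]  # 1-based inclusive on each longest isoform
    domain_b: tuple[int, int]


@dataclass
class SequenceFixture:
    fasta_text: str
    domain_table_text: str
    pairs: list[PlantedSequencePair]


def generate_sequence_fixture(spec: WorldSpec) -> SequenceFixture:
    """Protein pairs with a strongly conserved planted block in weakly
    conserved flanks — the typical shape of diverged orthologs.

    Each selected true ortholog pair gets two equal-length sequences built
    from common templates: within the domain block residues are copied with
    probability `domain_conservation`, within the flanks with
    `flank_conservation` (high enough that the local alignment extends
    through them, low enough that overall identity sits well below the
    domain's).  Every gene also gets a shorter second isoform so that
    longest-isoform selection is exercised.  The realized within-domain
    identity is recorded per pair.
    """
    _, _, truth = _make_truth(spec)
    rng = _rng(spec.seed, _S_SEQ)
    aa = np.array(list(AMINO_ACIDS))

    def random_seq(n: int) -> str:
        return "".join(aa[rng.integers(0, len(aa), n)])

    def mutate(template: str, keep_prob: float) -> tuple[str, int]:
        out = []
        matches = 0
        for ch in template:
            if rng.random() < keep_prob:
                out.append(ch)
                matches += 1
            else:
                alt = ch
                while alt == ch:
                    alt = aa[int(rng.integers(len(aa)))]
                out.append(alt)
        return "".join(out), matches

    lo, hi = spec.sequence_length_range
    pairs: list[PlantedSequencePair] = []
    fasta: list[str] = []
    domains: list[str] = ["#accession\tdomain\tstart\tend\n"]

    seen_genes: set[int] = set()
    for a, b in sorted(truth):
        if len(pairs) >= spec.n_sequence_pairs:
            break
        if a in seen_genes or b in seen_genes:
            continue  # one FASTA entry per gene; one-to-many extras skipped
        seen_genes.update((a, b))
        total = int(rng.integers(lo, hi + 1))
        flank_total = max(total - spec.domain_length, 10)
        left = int(rng.integers(0, flank_total + 1))
        right = flank_total - left

        block = random_seq(spec.domain_length)
        left_t, right_t = random_seq(left), random_seq(right)
        block_b, matches = mutate(block, spec.domain_conservation)
        left_b, _ = mutate(left_t, spec.flank_conservation)
        right_b, _ = mutate(right_t, spec.flank_conservation)

        seq_a = left_t + block + right_t
        seq_b = left_b + block_b + right_b
        a_start = b_start = left + 1
        a_end = b_end = left + spec.domain_length
        acc_a, acc_b = f"NP_H{a}.1", f"NP_F{b}.1"
        fasta.append(f">{acc_a} gene:{a}\n{seq_a}\n")
        fasta.append(f">{acc_b} gene:{b}\n{seq_b}\n")
        # shorter second isoforms: truncated forms of the main isoform
        fasta.append(f">NP_H{a}.2 gene:{a}\n{seq_a[: max(30, len(seq_a) // 2)]}\n")
        fasta.append(f">NP_F{b}.2 gene:{b}\n{seq_b[: max(30, len(seq_b) // 2)]}\n")
        domains.append(f"{acc_a}\tplanted_domain\t{a_start}\t{a_end}\n")
        domains.append(f"{acc_b}\tplanted_domain\t{b_start}\t{b_end}\n")
        pairs.append(
            PlantedSequencePair(
                a, b, acc_a, acc_b,
                100.0 * matches / spec.domain_length,
                (a_start, a_end), (b_start, b_end),
            )
        )
    return SequenceFixture("".join(fasta), "".join(domains), pairs)


# ----------------------------------------------------------- disease fixture


@dataclass
class PlantedDiseaseRecord:
    route: str  # planted mapping route
    category_code: Optional[str]  # None for unmapped


@dataclass
class DiseaseFixture:
    omim_text: str
    gwas_text: str
    entry_term_text: str
    cs_heading_text: str
    manual_override_text: str
    literature_text: str
    planted_records: list[PlantedDiseaseRecord]
    shared_fly_genes: set[int]  # fly genes planted to share a category
    unshared_fly_genes: set[int]


def generate_disease_fixture(spec: WorldSpec) -> DiseaseFixture:
    """Disease/trait records covering every mapping route, plus literature
    categories with a planted shared fraction between ortholog partners."""
    humans, flies, truth = _make_truth(spec)
    rng = _rng(spec.seed, _S_DISEASE)
    pairable_humans = sorted({a for a, _ in truth})
    disease_codes = ["C04", "C10", "C14", "C16", "C18", "C19", "F03"]

    routes = ["cs_heading", "entry_term", "manual_override", "y01_rule", "y02_rule", "unmapped"]
    counts = np.floor(np.array(spec.route_mix) * spec.n_disease_records).astype(int)
    counts[0] += spec.n_disease_records - counts.sum()

    cs_headings = {f"Heading_{c}": c for c in disease_codes}
    cs_lines = [f"{h}\t{c}\n" for h, c in sorted(cs_headings.items())]
    entry_lines: list[str] = []
    manual_lines: list[str] = []
    omim_lines: list[str] = []
    gwas_lines: list[str] = []
    planted: list[PlantedDiseaseRecord] = []

    def pick_genes() -> str:
        k = int(rng.integers(1, 4))
        idx = rng.choice(len(pairable_humans), size=min(k, len(pairable_humans)), replace=False)
        return ",".join(str(pairable_humans[i]) for i in sorted(idx))

    rec_id = 0
    for route, n in zip(routes, counts):
        for _ in range(int(n)):
            rec_id += 1
            code: Optional[str] = disease_codes[int(rng.integers(len(disease_codes)))]
            genes = pick_genes()
            if route == "cs_heading":
                heading = f"Heading_{code}"
                omim_lines.append(
                    f"{600000 + rec_id}\tphenotype\tSyndrome number {rec_id}\t{heading}\t{genes}\n"
                )
            elif route == "entry_term":
                entry = f"fixture disease {rec_id}"
                mesh = f"fixture neoplasm {rec_id}"
                entry_lines.append(f"{entry}\t{mesh}\t{code}\n")
                # raw term varies case and carries a strip-able qualifier
                omim_lines.append(
                    f"{600000 + rec_id}\tphenotype\tFixture Disease {rec_id}, susceptibility to\t\t{genes}\n"
                )
            elif route == "manual_override":
                term = f"rare disorder {rec_id}"
                manual_lines.append(f"{term}\t{code}\n")
                omim_lines.append(f"{600000 + rec_id}\tgene_locus\t{term}\t\t{genes}\n")
            elif route == "y01_rule":
                code = "Y01"
                gwas_lines.append(f"serum cholesterol measure {rec_id}\t{genes}\n")
            elif route == "y02_rule":
                code = "Y02"
                gwas_lines.append(f"hair color variant {rec_id}\t{genes}\n")
            else:  # unmapped
                code = None
                gwas_lines.append(f"zzq finding {rec_id}\t{genes}\n")
            planted.append(PlantedDiseaseRecord(route, code))

    # literature categories, grouped by human gene so one-to-many partners
    # stay consistent: a "shared" human and all its fly partners carry the
    # same category; an "unshared" human's partners carry a different one
    lit_lines: list[str] = []
    shared_fly: set[int] = set()
    unshared_fly: set[int] = set()
    flies_of_human: dict[int, list[int]] = {}
    for a, b in sorted(truth):
        flies_of_human.setdefault(a, []).append(b)
    partnered_humans = sorted(flies_of_human)
    n_shared_humans = int(round(spec.shared_category_fraction * len(partnered_humans)))
    for i, a in enumerate(partnered_humans):
        c1 = disease_codes[int(rng.integers(len(disease_codes)))]
        lit_lines.append(f"{a}\t{c1}\n")
        for b in flies_of_human[a]:
            if i < n_shared_humans:
                lit_lines.append(f"{b}\t{c1}\n")
                shared_fly.add(b)
            else:
                c2 = disease_codes[(disease_codes.index(c1) + 1) % len(disease_codes)]
                lit_lines.append(f"{b}\t{c2}\n")
                unshared_fly.add(b)

    return DiseaseFixture(
        omim_text="".join(omim_lines),
        gwas_text="".join(gwas_lines),
        entry_term_text="".join(entry_lines),
        cs_heading_text="".join(cs_lines),
        manual_override_text="".join(manual_lines),
        literature_text="".join(lit_lines),
        planted_records=planted,
        shared_fly_genes=shared_fly,
        unshared_fly_genes=unshared_fly,
    )
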