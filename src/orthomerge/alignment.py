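"""Pairwise local protein alignment with domain-region percent identity.

Predicted ortholog pairs are compared at the protein level with a
Smith-Waterman local alignment under an affine gap model (Gotoh's
algorithm): a gap of length L costs ``gap_open + (L - 1) * gap_extend``,
with the classic protein defaults of BLOSUM62, gap_open 10.0 and
gap_extend 0.5.  For genes with several protein isoforms, the longest
isoform represents the gene.

The rendered alignment carries a per-column match line: ``*`` identical
residues, ``:`` a positive substitution score, ``.`` any other aligned pair,
and a space where a gap was inserted.  Percent identity is the fraction of
``*`` columns over the full alignment length (gap columns included in the
denominator); percent similarity additionally counts ``:`` columns.  Domain
intervals given in protein coordinates are mapped through the alignment to
column spans and scored the same way — conserved domains typically show much
higher identity than the overall alignment, which is the point of reporting
them separately.

The traceback is deterministic: the highest-scoring cell (first in row-major
order on ties) is extended with the preference diagonal > up > left, and a
gap is closed as early as possible.  One optimal alignment is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Align import substitution_matrices

from ._util import ParseError, TableSource, iter_tsv, round_half_up

_NEG = float("-inf")

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "XBZU")


def blosum62():
    return substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class ProteinSeq:
    accession: str
    gene_id: int
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.residues.upper()) - VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.accession}: invalid residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainAnnotation:
    """A named domain interval, 1-based inclusive on the protein sequence."""

    accession: str
    name: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"domain {self.name} on {self.accession}: invalid interval "
                f"[{self.start}, {self.end}]"
            )


@dataclass
class DomainStat:
    name: str
    source: str  # 'a' or 'b'
    col_start: Optional[int]  # 0-based alignment column span, inclusive
    col_end: Optional[int]
    identity_pct: Optional[float]
    aligned: bool


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    match_line: str
    score: float
    identity_pct: float
    similarity_pct: float
    a_start: int  # 1-based first/last aligned residue on each sequence
    a_end: int
    b_start: int
    b_end: int
    domain_stats: list[DomainStat] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.aligned_a)

    def format(self, width: int = 60) -> str:
        """Three-row aligned block with a stats header."""
        lines = [
            f"# score={self.score:g} length={len(self)} "
            f"identity={round_half_up(self.identity_pct)}% "
            f"similarity={round_half_up(self.similarity_pct)}%"
        ]
        for d in self.domain_stats:
            if d.aligned:
                lines.append(
                    f"# domain {d.name} ({d.source}) cols {d.col_start + 1}-{d.col_end + 1} "
                    f"identity={round_half_up(d.identity_pct)}%"
                )
            else:
                lines.append(f"# domain {d.name} ({d.source}) not aligned")
        for off in range(0, len(self), width):
            lines.append(self.aligned_a[off : off + width])
            lines.append(self.match_line[off : off + width])
            lines.append(self.aligned_b[off : off + width])
        return "\n".join(lines)


def read_fasta(source, gene_ids: Mapping[str, int] | None = None) -> list[ProteinSeq]:
    """Read protein FASTA; accession is the first whitespace token.

    The gene for each accession comes from `gene_ids` or, failing that, from
    a ``gene:<int>`` token in the description line.
    """
    records = []
    for rec in SeqIO.parse(source, "fasta"):
        accession = rec.id
        gene_id = None
        if gene_ids and accession in gene_ids:
            gene_id = gene_ids[accession]
        else:
            for token in rec.description.split():
                if token.startswith("gene:"):
                    gene_id = int(token[5:])
                    break
        if gene_id is None:
            raise ParseError(f"no gene id for sequence {accession}")
        records.append(ProteinSeq(accession, gene_id, str(rec.seq).upper()))
    return records


def read_domain_table(source: TableSource) -> list[DomainAnnotation]:
    """Tab-separated (accession, name, start, end), 1-based inclusive."""
    domains = []
    for line_no, fields in iter_tsv(source):
        if len(fields) != 4:
            raise ParseError(f"expected 4 columns, got {len(fields)}", line_no)
        try:
            start, end = int(fields[2]), int(fields[3])
        except ValueError:
            raise ParseError(f"non-integer domain coordinates {fields[2:4]}", line_no) from None
        domains.append(DomainAnnotation(fields[0], fields[1], start, end))
    return domains


def select_longest_isoform(records: Sequence[ProteinSeq]) -> ProteinSeq:
    """Longest record; length ties broken by smallest accession."""
    if not records:
        raise ValueError("no isoforms given")
    gene_ids = {r.gene_id for r in records}
    if len(gene_ids) > 1:
        raise ValueError(f"isoforms of several genes: {sorted(gene_ids)}")
    return min(records, key=lambda r: (-r.length, r.accession))


def _score_fn(matrix):
    alphabet = set(matrix.alphabet)

    def score(x: str, y: str) -> float:
        if x not in alphabet:
            if "X" not in alphabet:
                raise KeyError(f"residue {x!r} not in matrix and no wildcard row")
            x = "X"
        if y not in alphabet:
            if "X" not in alphabet:
                raise KeyError(f"residue {y!r} not in matrix and no wildcard row")
            y = "X"
        return float(matrix[x, y])

    return score


def local_align(
    seq_a: ProteinSeq | str,
    seq_b: ProteinSeq | str,
    substitution_matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment with affine gaps.

    All cell values are multiples of 0.5 (integer substitution scores plus
    half-integer gap costs), so floating-point comparisons in the traceback
    are exact.
    """
    a = seq_a.residues if isinstance(seq_a, ProteinSeq) else seq_a
    b = seq_b.residues if isinstance(seq_b, ProteinSeq) else seq_b
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    matrix = substitution_matrix if substitution_matrix is not None else blosum62()
    s = _score_fn(matrix)

    n, m = len(a), len(b)
    # H: best local score ending at (i, j); E: ending in a gap in A
    # (consuming b_j); F: ending in a gap in B (consuming a_i).
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[_NEG] * (m + 1) for _ in range(n + 1)]
    F = [[_NEG] * (m + 1) for _ in range(n + 1)]

    best, best_i, best_j = 0.0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] - gap_open, Ei[j - 1] - gap_extend)
            f = max(Hi1[j] - gap_open, Fi1[j] - gap_extend)
            h = max(0.0, Hi1[j - 1] + s(ai, b[j - 1]), e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, best_i, best_j = h, i, j

    # traceback with the fixed preference diagonal > up > left; within a gap
    # the gap is closed (switch back to H) as early as possible
    cols_a: list[str] = []
    cols_b: list[str] = []
    i, j, state = best_i, best_j, "H"
    while True:
        if state == "H":
            if H[i][j] == 0.0:
                break
            diag = H[i - 1][j - 1] + s(a[i - 1], b[j - 1])
            if H[i][j] == diag:
                cols_a.append(a[i - 1])
                cols_b.append(b[j - 1])
                i, j = i - 1, j - 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            cols_a.append(a[i - 1])
            cols_b.append("-")
            if F[i][j] == H[i - 1][j] - gap_open:
                state = "H"
            i -= 1
        else:  # E
            cols_a.append("-")
            cols_b.append(b[j - 1])
            if E[i][j] == H[i][j - 1] - gap_open:
                state = "H"
            j -= 1

    aligned_a = "".join(reversed(cols_a))
    aligned_b = "".join(reversed(cols_b))
    match_line = render_match_line(aligned_a, aligned_b, matrix)
    identity, similarity = _stats_from_match_line(match_line)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        match_line=match_line,
        score=best,
        identity_pct=identity,
        similarity_pct=similarity,
        a_start=i + 1,
        a_end=best_i,
        b_start=j + 1,
        b_end=best_j,
    )


def render_match_line(aligned_a: str, aligned_b: str, substitution_matrix=None) -> str:
    """Per column: '*' identical, ':' positive score, '.' other pair, ' ' gap."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    matrix = substitution_matrix if substitution_matrix is not None else blosum62()
    s = _score_fn(matrix)
    out = []
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            out.append(" ")
        elif x == y:
            out.append("*")
        elif s(x, y) > 0:
            out.append(":")
        else:
            out.append(".")
    return "".join(out)


def _stats_from_match_line(match_line: str) -> tuple[float, float]:
    length = len(match_line)
    if length == 0:
        return 0.0, 0.0
    stars = match_line.count("*")
    colons = match_line.count(":")
    return 100.0 * stars / length, 100.0 * (stars + colons) / length


def alignment_identity_stats(result: AlignmentResult, rounded: bool = False):
    """(identity_pct, similarity_pct); integers (half-up) when rounded."""
    identity, similarity = _stats_from_match_line(result.match_line)
    if rounded:
        return round_half_up(identity), round_half_up(similarity)
    return identity, similarity


def domain_identity(
    result: AlignmentResult,
    domains: Iterable[DomainAnnotation],
    source: str = "a",
    sequence_length: int | None = None,
) -> list[DomainStat]:
    """Map domain intervals through the alignment and score their columns.

    A domain's residue interval becomes the alignment-column span from its
    first to its last aligned residue; gap columns inside the span count in
    the identity denominator.  Domains wholly outside the aligned region give
    a not-aligned record; partial overlaps are clipped to the aligned part.
    """
    if source not in ("a", "b"):
        raise ValueError("source must be 'a' or 'b'")
    aligned = result.aligned_a if source == "a" else result.aligned_b
    seq_start = result.a_start if source == "a" else result.b_start
    seq_end = result.a_end if source == "a" else result.b_end

    # residue position (1-based on the source sequence) -> alignment column
    pos_to_col: dict[int, int] = {}
    pos = seq_start - 1
    for col, ch in enumerate(aligned):
        if ch != "-":
            pos += 1
            pos_to_col[pos] = col

    stats = []
    for dom in domains:
        if sequence_length is not None and dom.end > sequence_length:
            raise ValueError(
                f"domain {dom.name} ends at {dom.end} beyond sequence length {sequence_length}"
            )
        lo, hi = max(dom.start, seq_start), min(dom.end, seq_end)
        if lo > hi:
            stats.append(DomainStat(dom.name, source, None, None, None, False))
            continue
        c0, c1 = pos_to_col[lo], pos_to_col[hi]
        span = result.match_line[c0 : c1 + 1]
        identity = 100.0 * span.count("*") / len(span)
        stats.append(DomainStat(dom.name, source, c0, c1, identity, True))
    result.domain_stats.extend(stats)
    return stats


def align_gene_pair(
    records_a: Sequence[ProteinSeq],
    records_b: Sequence[ProteinSeq],
    domains: Iterable[DomainAnnotation] = (),
    **align_kwargs,
) -> AlignmentResult:
    """Longest-isoform alignment for a gene pair, with domain stats attached."""
    rep_a = select_longest_isoform(records_a)
    rep_b = select_longest_isoform(records_b)
    result = local_align(rep_a, rep_b, **align_kwargs)
    by_acc: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        by_acc.setdefault(d.accession, []).append(d)
    if rep_a.accession in by_acc:
        domain_identity(result, by_acc[rep_a.accession], "a", rep_a.length)
    if rep_b.accession in by_acc:
        domain_identity(result, by_acc[rep_b.accession], "b", rep_b.length)
    return result
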