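"""Small shared helpers: rounding convention and TSV plumbing."""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Iterator, TextIO, Union

TableSource = Union[str, Path, TextIO, Iterable[str]]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    All percentages are reported as integers at the interfaces; Python's
    builtin round() rounds halves to even, which is not the convention used
    for the reported figures.
    """
    if x >= 0:
        return int(x + 0.5)
    return -int(-x + 0.5)


def percent(numerator: float, denominator: float) -> int:
    """100 * numerator / denominator, rounded half-up to an integer."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator)


class ParseError(ValueError):
    """A malformed row in a tabular input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def iter_tsv(source: TableSource, *, comment: str = "#") -> Iterator[tuple[int, list[str]]]:
    """Yield (line_number, fields) for each non-comment, non-blank TSV line.

    Accepts a path, an open text handle, or any iterable of lines, so tests
    and fixtures can feed in-memory tables without touching disk.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as handle:
            yield from _iter_lines(handle, comment)
    else:
        yield from _iter_lines(source, comment)


def _iter_lines(lines: Iterable[str], comment: str) -> Iterator[tuple[int, list[str]]]:
    for i, line in enumerate(lines, start=1):
        stripped = line.rstrip("\n").rstrip("\r")
        if not stripped.strip() or stripped.lstrip().startswith(comment):
            continue
        yield i, stripped.split("\t")


def write_tsv(path: str | Path, header: list[str], rows: Iterable[Iterable[object]]) -> None:
    """Write a TSV with a single '#'-prefixed header line naming the columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt", encoding="utf-8") as out:
        out.write("#" + "\t".join(header) + "\n")
        for row in rows:
            out.write("\t".join(str(c) for c in row) + "\n")


def as_text(table: str) -> io.StringIO:
    """Wrap an inline table literal as a file-like object."""
    return io.StringIO(table)
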