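"""Tab-delimited gene-centric annotation files.

The input dialect is deliberately minimal so that any upstream pipeline can
produce it: one row per record, tab-separated, the gene symbol in the first
column, any further columns free-form. If the first line starts with ``#`` it
is the header (the ``#`` is stripped); otherwise columns are auto-named
``col1..colK``. Lines after the first that start with ``#`` are data, not
comments.

Each parsed table becomes an :class:`AnnotationSet` once an icon is attached;
the set is the unit that gets normalized against HGNC and joined onto
pathways. Normalization produces an :class:`UnmatchedReport` partitioning the
misses into symbols with no HGNC match versus valid genes that simply belong
to no loaded pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from ._io import atomic_write_text
from .errors import FormatError
from .normalize import Normalizer, normalize_symbols

__all__ = [
    "AnnotationRow",
    "AnnotationTable",
    "AnnotationSet",
    "UnmatchedReport",
    "parse_annotation_file",
    "preview_annotation_file",
    "write_annotation",
    "attach_icon",
    "normalize_annotation",
    "write_unmatched_report",
    "read_unmatched_report",
]

DEFAULT_PREVIEW_LINES = 10

NO_HGNC_MATCH = "no-HGNC-match"
OUT_OF_PATHWAY = "out-of-pathway"


@dataclass(frozen=True)
class AnnotationRow:
    gene_symbol: str
    values: tuple[str, ...]

    def fields(self) -> tuple[str, ...]:
        return (self.gene_symbol,) + self.values


@dataclass(frozen=True)
class AnnotationTable:
    name: str
    columns: tuple[str, ...]
    rows: tuple[AnnotationRow, ...]
    header_present: bool

    def __post_init__(self):
        for i, row in enumerate(self.rows):
            if len(row.values) + 1 != len(self.columns):
                raise FormatError(
                    f"{self.name}: row {i + 1} has {len(row.values) + 1} fields, "
                    f"expected {len(self.columns)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class AnnotationSet:
    """One annotation table plus its display icon.

    ``gene_index`` maps gene symbol -> row indices (a gene may recur across
    rows, e.g. one row per variant). After :func:`normalize_annotation` the
    keys are approved symbols and ``invalid_rows`` marks rows whose symbol
    had no HGNC match; those rows are retained but unindexed.
    """

    table: AnnotationTable
    icon: str
    gene_index: dict[str, tuple[int, ...]] = field(default_factory=dict)
    normalized: bool = False
    invalid_rows: frozenset[int] = field(default_factory=frozenset)

    @property
    def name(self) -> str:
        return self.table.name

    @property
    def genes(self) -> frozenset[str]:
        """Distinct indexed genes (the counting unit for enrichment)."""
        return frozenset(self.gene_index)


@dataclass(frozen=True)
class UnmatchedReport:
    """Post-upload report: which input symbols failed and why.

    ``invalid_symbols`` lists (input symbol, reason) for symbols with no HGNC
    match; ``out_of_pathway`` lists approved symbols absent from every loaded
    pathway. The two partitions are disjoint by construction.
    """

    invalid_symbols: tuple[tuple[str, str], ...] = ()
    out_of_pathway: tuple[str, ...] = ()

    @property
    def n_entries(self) -> int:
        return len(self.invalid_symbols) + len(self.out_of_pathway)


def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8-sig")
    return text.splitlines()


def parse_annotation_file(path: str | Path, name: str | None = None) -> AnnotationTable:
    """Parse one tab-delimited annotation file.

    Blank lines are skipped. Short rows (fewer fields than the header) are
    right-padded with empty strings and reported via a single warning; a row
    with more fields than the header is a format error naming the line.
    """
    path = Path(path)
    name = name if name is not None else path.stem
    raw = [(i, line) for i, line in enumerate(_read_lines(path), start=1) if line.strip()]
    if not raw:
        raise FormatError(f"{path}: empty annotation file")

    first_lineno, first = raw[0]
    if first.startswith("#"):
        columns = tuple(c.strip() for c in first[1:].split("\t"))
        header_present = True
        data = raw[1:]
    else:
        columns = tuple(f"col{i + 1}" for i in range(len(first.split("\t"))))
        header_present = False
        data = raw

    rows: list[AnnotationRow] = []
    padded: list[int] = []
    for lineno, line in data:
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) > len(columns):
            raise FormatError(
                f"{path}: line {lineno}: {len(fields)} fields exceed the "
                f"{len(columns)}-column header")
        if len(fields) < len(columns):
            padded.append(lineno)
            fields += [""] * (len(columns) - len(fields))
        rows.append(AnnotationRow(fields[0], tuple(fields[1:])))
    if padded:
        warnings.warn(
            f"{path}: {len(padded)} line(s) right-padded to {len(columns)} "
            f"columns (lines {', '.join(map(str, padded[:5]))}"
            f"{', ...' if len(padded) > 5 else ''})",
            stacklevel=2)
    return AnnotationTable(name, columns, tuple(rows), header_present)


def preview_annotation_file(path: str | Path, n_lines: int = DEFAULT_PREVIEW_LINES) -> list[AnnotationRow]:
    """First ``n_lines`` data rows in file order (default 10), for upload
    validation: the user checks that column 1 really is the gene symbol."""
    if n_lines <= 0:
        raise FormatError(f"preview length must be positive, got {n_lines}")
    table = parse_annotation_file(path)
    return list(table.rows[:n_lines])


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    lines: list[str] = []
    if table.header_present:
        lines.append("#" + "\t".join(table.columns))
    for row in table.rows:
        lines.append("\t".join(row.fields()))
    atomic_write_text(path, "\n".join(lines) + "\n")


def attach_icon(table: AnnotationTable, icon: str, registry) -> AnnotationSet:
    """Bind exactly one icon to an annotation table.

    The icon must already exist in *registry* (an
    :class:`~pathannot.icons.IconRegistry`); re-attaching replaces the icon,
    it never accumulates. The raw gene index is built from the symbols as
    written; normalization rewrites it.
    """
    registry.get(icon)  # raises ConfigError for unknown icons
    index: dict[str, list[int]] = {}
    for i, row in enumerate(table.rows):
        index.setdefault(row.gene_symbol, []).append(i)
    return AnnotationSet(table=table, icon=icon,
                         gene_index={g: tuple(ix) for g, ix in index.items()})


def normalize_annotation(
    aset: AnnotationSet,
    norm: Normalizer,
    pathway_universe: Iterable[str],
) -> tuple[AnnotationSet, UnmatchedReport]:
    """Normalize a set's gene symbols and produce the unmatched report.

    Matched symbols are rewritten to their approved form and indexed;
    unmatched symbols stay in their rows (flagged invalid) but drop out of
    the gene index. Matched genes absent from *pathway_universe* remain
    indexed — they count for enrichment margins only through the universe
    intersection — and are reported as out-of-pathway.
    """
    universe = set(pathway_universe)
    results = normalize_symbols(norm, [r.gene_symbol for r in aset.table.rows])

    new_rows: list[AnnotationRow] = []
    index: dict[str, list[int]] = {}
    invalid_rows: set[int] = set()
    invalid_seen: dict[str, None] = {}
    out_seen: dict[str, None] = {}
    for i, (row, res) in enumerate(zip(aset.table.rows, results)):
        if res.status == "unmatched":
            new_rows.append(row)
            invalid_rows.add(i)
            invalid_seen.setdefault(row.gene_symbol, None)
        else:
            new_rows.append(replace(row, gene_symbol=res.approved_symbol))
            index.setdefault(res.approved_symbol, []).append(i)
            if res.approved_symbol not in universe:
                out_seen.setdefault(res.approved_symbol, None)

    table = AnnotationTable(aset.table.name, aset.table.columns,
                            tuple(new_rows), aset.table.header_present)
    new_set = AnnotationSet(
        table=table, icon=aset.icon,
        gene_index={g: tuple(ix) for g, ix in index.items()},
        normalized=True, invalid_rows=frozenset(invalid_rows))
    report = UnmatchedReport(
        invalid_symbols=tuple((s, NO_HGNC_MATCH) for s in invalid_seen),
        out_of_pathway=tuple(out_seen))
    return new_set, report


def write_unmatched_report(report: UnmatchedReport, path: str | Path) -> None:
    """Serialize the report as a two-column TSV (symbol, category), in file
    order of first occurrence."""
    lines = ["symbol\tcategory"]
    for symbol, reason in report.invalid_symbols:
        lines.append(f"{symbol}\t{reason}")
    for symbol in report.out_of_pathway:
        lines.append(f"{symbol}\t{OUT_OF_PATHWAY}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_unmatched_report(path: str | Path) -> UnmatchedReport:
    lines = _read_lines(path)
    if not lines or lines[0] != "symbol\tcategory":
        raise FormatError(f"{path}: not an unmatched report (bad header)")
    invalid: list[tuple[str, str]] = []
    out: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns")
        symbol, category = fields
        if category == OUT_OF_PATHWAY:
            out.append(symbol)
        else:
            invalid.append((symbol, category))
    return UnmatchedReport(tuple(invalid), tuple(out))
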