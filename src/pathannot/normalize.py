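"""Two-phase HGNC gene-symbol normalization.

Human gene symbols in user files are noisy: deprecated aliases, lowercase
variants, or plain typos. Normalization maps every input symbol to the HGNC
*approved symbol* in two phases:

1. the symbol (case-insensitively, whitespace-stripped) matches an approved
   symbol directly, or
2. it matches an HGNC synonym that maps to exactly one approved symbol.

Synonyms shared by two or more approved symbols are ambiguous and are removed
from the lookup table entirely: an ambiguous alias never resolves, because a
wrong gene is worse than no gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._io import atomic_write_text
from .errors import ConfigError, FormatError, InputError

__all__ = [
    "HgncTable",
    "Normalizer",
    "NormalizationResult",
    "build_normalizer",
    "normalize_symbol",
    "normalize_symbols",
    "read_hgnc_table",
    "write_hgnc_table",
    "canonical",
]


def canonical(symbol: str) -> str:
    """Canonical matching form: surrounding whitespace stripped, uppercased."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class HgncTable:
    """A reference table of (approved symbol, synonyms) pairs.

    Approved symbols must be unique (in canonical form) and non-empty.
    """

    rows: tuple[tuple[str, tuple[str, ...]], ...]

    def __init__(self, rows: Iterable[tuple[str, Sequence[str]]]):
        frozen = tuple((a, tuple(s)) for a, s in rows)
        object.__setattr__(self, "rows", frozen)
        seen: set[str] = set()
        for approved, _ in frozen:
            if not approved.strip():
                raise ConfigError("approved symbol must not be empty")
            c = canonical(approved)
            if c in seen:
                raise ConfigError(f"duplicate approved symbol in HGNC table: {approved!r}")
            seen.add(c)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class Normalizer:
    """Compiled lookup structure built from an :class:`HgncTable`.

    ``approved`` maps canonical form -> HGNC display casing;
    ``synonym_map`` maps canonical synonym -> approved symbol (display casing);
    ``dropped_ambiguous`` holds canonical synonyms removed for multi-mapping.
    """

    approved: dict[str, str] = field(default_factory=dict)
    synonym_map: dict[str, str] = field(default_factory=dict)
    dropped_ambiguous: frozenset[str] = field(default_factory=frozenset)

    @property
    def approved_symbols(self) -> frozenset[str]:
        """The set of approved symbols in HGNC display casing."""
        return frozenset(self.approved.values())


@dataclass(frozen=True)
class NormalizationResult:
    input_symbol: str
    approved_symbol: str | None
    status: str  # one of {"approved", "synonym", "unmatched"}
    invalid_input: bool = False

    def __post_init__(self):
        if (self.status == "unmatched") != (self.approved_symbol is None):
            raise ValueError("status 'unmatched' iff approved_symbol is absent")


def build_normalizer(table: HgncTable) -> Normalizer:
    """Compile an HGNC table into the two-phase lookup structure.

    Synonyms occurring under two or more approved symbols are dropped as
    ambiguous. A synonym whose canonical form equals any approved symbol is
    excluded from the synonym map: phase-1 (approved) matching takes
    precedence. Duplicate listings of a synonym under the same approved
    symbol carry no information and count once.
    """
    approved: dict[str, str] = {}
    for approved_symbol, _ in table.rows:
        approved[canonical(approved_symbol)] = approved_symbol.strip()

    owners: dict[str, set[str]] = {}
    for approved_symbol, synonyms in table.rows:
        owner = canonical(approved_symbol)
        for syn in {canonical(s) for s in synonyms if s.strip()}:
            owners.setdefault(syn, set()).add(owner)

    synonym_map: dict[str, str] = {}
    dropped: set[str] = set()
    for syn, owner_set in owners.items():
        if len(owner_set) >= 2:
            dropped.add(syn)
        elif syn not in approved:
            synonym_map[syn] = approved[next(iter(owner_set))]

    return Normalizer(approved=approved, synonym_map=synonym_map,
                      dropped_ambiguous=frozenset(dropped))


def normalize_symbol(norm: Normalizer, symbol: str) -> NormalizationResult:
    """Resolve one symbol: phase 1 against approved symbols, phase 2 against
    unambiguous synonyms; otherwise unmatched."""
    if not symbol or not symbol.strip():
        raise InputError("gene symbol is empty or whitespace-only")
    c = canonical(symbol)
    if c in norm.approved:
        return NormalizationResult(symbol, norm.approved[c], "approved")
    if c in norm.synonym_map:
        return NormalizationResult(symbol, norm.synonym_map[c], "synonym")
    return NormalizationResult(symbol, None, "unmatched")


def normalize_symbols(norm: Normalizer, symbols: Iterable[str]) -> list[NormalizationResult]:
    """Elementwise :func:`normalize_symbol`, order-preserving.

    Per-element input errors (empty symbols) do not abort the batch; they
    yield an unmatched result flagged ``invalid_input``.
    """
    out: list[NormalizationResult] = []
    for s in symbols:
        try:
            out.append(normalize_symbol(norm, s))
        except InputError:
            out.append(NormalizationResult(s, None, "unmatched", invalid_input=True))
    return out


def read_hgnc_table(path: str | Path) -> HgncTable:
    """Read the two-column TSV dialect: ``approved_symbol<TAB>synonyms``.

    The synonym list accepts comma or pipe separators (real HGNC exports use
    pipes). A header line is required and skipped.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8-sig").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty HGNC table")
    rows: list[tuple[str, tuple[str, ...]]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) > 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
        approved = fields[0].strip()
        if not approved:
            raise FormatError(f"{path}: line {lineno}: empty approved symbol")
        raw = fields[1] if len(fields) == 2 else ""
        sep = "|" if "|" in raw else ","
        synonyms = tuple(s.strip() for s in raw.split(sep) if s.strip())
        rows.append((approved, synonyms))
    return HgncTable(rows)


def write_hgnc_table(table: HgncTable, path: str | Path) -> None:
    lines = ["approved_symbol\tsynonyms"]
    for approved, synonyms in table.rows:
        lines.append(f"{approved}\t{','.join(synonyms)}")
    atomic_write_text(path, "\n".join(lines) + "\n")
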