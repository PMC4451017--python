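"""Per-pathway annotation counts and Fisher's-exact enrichment.

For each pathway and each annotation set, the summary table reports k, the
number of *distinct* annotated genes in the pathway (a gene with five variant
rows counts once). Optionally, each (pathway, set) pair gets a one-sided
Fisher's exact p-value for over-representation: with N genes in the universe
(the union of genes across loaded pathways), K of them annotated, and an
n-gene pathway, the p-value is the upper hypergeometric tail

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n).

The tail is computed with exact integer arithmetic (math.comb over a single
rational), so the result is correct to full double precision — no log-gamma
cancellation. Raw p-values are the primary output; Benjamini–Hochberg
adjustment (per set, across pathways) is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from math import comb
from pathlib import Path

import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._io import atomic_write_text
from .annotations import AnnotationSet
from .errors import InputError
from .pathways import Pathway, PathwayCollection

__all__ = [
    "ContingencyInputs",
    "SummaryRow",
    "SummaryTable",
    "count_annotated",
    "fisher_enrichment_p",
    "build_summary_table",
    "sort_table",
]


@dataclass(frozen=True)
class ContingencyInputs:
    """2x2 margins for one (pathway, annotation set) pair.

    k: annotated genes in the pathway; K: annotated genes in the universe;
    n: pathway size; N: universe size.
    """

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self):
        if self.N < 0:
            raise InputError(f"N must be non-negative, got N={self.N}")
        if not (0 <= self.n <= self.N):
            raise InputError(f"require 0 <= n <= N, got n={self.n}, N={self.N}")
        if not (0 <= self.K <= self.N):
            raise InputError(f"require 0 <= K <= N, got K={self.K}, N={self.N}")
        if not (0 <= self.k <= min(self.n, self.K)):
            raise InputError(
                f"require 0 <= k <= min(n, K), got k={self.k}, "
                f"min(n, K)={min(self.n, self.K)}")


def fisher_enrichment_p(c: ContingencyInputs) -> float:
    """One-sided (over-representation) Fisher's exact p-value.

    Exact rational tail sum; the only rounding is the final conversion to
    float, so agreement with brute-force enumeration holds to machine
    precision for any margins that fit in memory.
    """
    k, K, n, N = c.k, c.K, c.n, c.N
    lo = max(0, n - (N - K))  # minimum possible overlap
    hi = min(n, K)
    if k <= lo:
        return 1.0
    numerator = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, hi + 1))
    return float(Fraction(numerator, comb(N, n)))


def count_annotated(pathway: Pathway, aset: AnnotationSet) -> int:
    """Distinct annotated genes in the pathway (genes, never rows)."""
    return len(pathway.genes & aset.genes)


@dataclass(frozen=True)
class SummaryRow:
    pathway_id: str
    display_name: str
    source: str
    n_genes: int
    counts: dict[str, int] = field(default_factory=dict)  # set name -> k
    p_values: dict[str, float] = field(default_factory=dict)
    p_adjusted: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SummaryTable:
    rows: tuple[SummaryRow, ...]
    set_names: tuple[str, ...]
    sort_state: tuple[str, str] | None = None  # (column, direction)

    def columns(self) -> list[str]:
        cols = ["pathway_id", "name", "source", "n_genes"]
        for s in self.set_names:
            cols.append(f"{s}_count")
        for s in self.set_names:
            if any(s in r.p_values for r in self.rows):
                cols.append(f"{s}_p")
            if any(s in r.p_adjusted for r in self.rows):
                cols.append(f"{s}_p_adj")
        return cols

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec: dict[str, object] = {"pathway_id": r.pathway_id, "name": r.display_name,
                                      "source": r.source, "n_genes": r.n_genes}
            for s in self.set_names:
                rec[f"{s}_count"] = r.counts.get(s, 0)
                if s in r.p_values:
                    rec[f"{s}_p"] = r.p_values[s]
                if s in r.p_adjusted:
                    rec[f"{s}_p_adj"] = r.p_adjusted[s]
            records.append(rec)
        return pd.DataFrame.from_records(records, columns=self.columns())

    def write_tsv(self, path: str | Path) -> None:
        atomic_write_text(path, self.to_frame().to_csv(sep="\t", index=False))


def build_summary_table(collection: PathwayCollection, sets: list[AnnotationSet],
                        with_enrichment: bool = False,
                        adjust: str | None = None) -> SummaryTable:
    """One row per pathway: size, per-set overlap counts, optional p-values.

    The universe is the union of genes across the collection's pathways;
    annotation genes outside it are excluded from the margin K. A set with
    zero genes in the universe yields p = 1 everywhere, with a warning.
    """
    if len(collection) == 0:
        raise InputError("cannot summarize an empty pathway collection")
    if adjust not in (None, "bh"):
        raise InputError(f"unknown adjustment method {adjust!r} (supported: 'bh')")

    universe = collection.universe
    N = len(universe)
    set_genes = {s.name: s.genes & universe for s in sets}

    rows: list[SummaryRow] = []
    for p in collection:
        counts = {s.name: count_annotated(p, s) for s in sets}
        p_values: dict[str, float] = {}
        if with_enrichment:
            for s in sets:
                K = len(set_genes[s.name])
                k = len(p.genes & set_genes[s.name])
                p_values[s.name] = fisher_enrichment_p(
                    ContingencyInputs(k=k, K=K, n=p.n_genes, N=N))
        rows.append(SummaryRow(p.id, p.display_name, p.source, p.n_genes,
                               counts=counts, p_values=p_values))

    if with_enrichment:
        for s in sets:
            if not set_genes[s.name]:
                warnings.warn(f"annotation set {s.name!r} has no genes in the "
                              f"pathway universe; all p-values are 1", stacklevel=2)

    if with_enrichment and adjust == "bh" and rows:
        for s in sets:
            pvals = [r.p_values[s.name] for r in rows]
            adjusted = multipletests(pvals, method="fdr_bh")[1]
            rows = [replace(r, p_adjusted={**r.p_adjusted, s.name: float(q)})
                    for r, q in zip(rows, adjusted)]

    return SummaryTable(tuple(rows), tuple(s.name for s in sets))


def _sort_key(table: SummaryTable, column: str):
    if column == "pathway_id":
        return lambda r: r.pathway_id
    if column == "name":
        return lambda r: r.display_name
    if column == "source":
        return lambda r: r.source
    if column == "n_genes":
        return lambda r: r.n_genes
    for s in table.set_names:
        if column == f"{s}_count":
            return lambda r, s=s: r.counts.get(s, 0)
        if column == f"{s}_p":
            return lambda r, s=s: r.p_values.get(s, float("inf"))
        if column == f"{s}_p_adj":
            return lambda r, s=s: r.p_adjusted.get(s, float("inf"))
    raise InputError(f"unknown sort column {column!r}")


def sort_table(table: SummaryTable, column: str, direction: str = "asc") -> SummaryTable:
    """Stable sort by one column; ties keep their current relative order."""
    if direction not in ("asc", "desc"):
        raise InputError(f"direction must be 'asc' or 'desc', got {direction!r}")
    key = _sort_key(table, column)
    rows = tuple(sorted(table.rows, key=key, reverse=(direction == "desc")))
    return SummaryTable(rows, table.set_names, sort_state=(column, direction))
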