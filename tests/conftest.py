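"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import Counter
from fractions import Fraction
from itertools import combinations

import pytest
from hypothesis import HealthCheck, settings

from pathannot import (
    HgncTable,
    IconRegistry,
    Pathway,
    PathwayCollection,
    build_normalizer,
    default_registry,
)
from pathannot.normalize import canonical

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# independent oracles

def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> Fraction:
    """Brute-force P(overlap >= k): enumerate every size-n subset of an
    N-element universe whose first K elements are 'annotated'."""
    annotated = set(range(K))
    total = 0
    ge = 0
    for subset in combinations(range(N), n):
        total += 1
        if len(annotated.intersection(subset)) >= k:
            ge += 1
    return Fraction(ge, total)


def overlap_distribution(K: int, n: int, N: int) -> Counter:
    """Exact distribution of |annotated ∩ subset| by enumeration."""
    annotated = set(range(K))
    return Counter(len(annotated.intersection(c)) for c in combinations(range(N), n))


def naive_normalize(table: HgncTable, symbol: str) -> tuple[str | None, str]:
    """Full-table-scan reference for the two-phase normalizer."""
    c = canonical(symbol)
    for approved, _ in table.rows:
        if canonical(approved) == c:
            return approved.strip(), "approved"
    owners: set[str] = set()
    display: dict[str, str] = {}
    for approved, synonyms in table.rows:
        if c in {canonical(s) for s in synonyms}:
            owners.add(canonical(approved))
            display[canonical(approved)] = approved.strip()
    if len(owners) == 1:
        return display[next(iter(owners))], "synonym"
    return None, "unmatched"


# ---------------------------------------------------------------------------
# small shared inputs

@pytest.fixture
def tiny_hgnc() -> HgncTable:
    return HgncTable([
        ("TP53", ("p53", "LFS1")),
        ("BRCA2", ("FACD", "FANCD1")),
        ("KRAS", ("KRAS2", "c-K-ras")),
        ("CDK4", ("PSK-J3",)),
        ("CDK6", ("PLSTIRE",)),
        # 'SHARED' is ambiguous between MYC and MYCN
        ("MYC", ("c-Myc", "SHARED")),
        ("MYCN", ("N-myc", "SHARED")),
    ])


@pytest.fixture
def tiny_normalizer(tiny_hgnc):
    return build_normalizer(tiny_hgnc)


@pytest.fixture
def tiny_collection() -> PathwayCollection:
    return PathwayCollection([
        Pathway("pw_apoptosis", "Apoptosis", "test",
                frozenset({"TP53", "MYC", "BRCA2"})),
        Pathway("pw_cellcycle", "Cell cycle", "test",
                frozenset({"TP53", "CDK4", "CDK6"})),
        Pathway("pw_ras", "RAS signaling", "test",
                frozenset({"KRAS", "MYC"})),
    ])


@pytest.fixture
def registry() -> IconRegistry:
    return default_registry()
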