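"""Normalize messy gene symbols against an HGNC reference.

Builds a tiny HGNC table, compiles the two-phase normalizer, and resolves a
mixed list of approved symbols, case variants, synonyms, an ambiguous
synonym, and a typo.
"""

from pathannot import HgncTable, build_normalizer, normalize_symbols

table = HgncTable([
    ("TP53", ["p53", "LFS1"]),
    ("BRCA2", ["FACD", "FANCD1"]),
    ("MYC", ["c-Myc", "bHLHe39", "SHARED"]),
    ("MYCN", ["N-myc", "SHARED"]),   # 'SHARED' maps to two genes -> dropped
])
norm = build_normalizer(table)

queries = ["TP53", "tp53", "p53", "FANCD1", "SHARED", "NOT_A_GENE"]
print(f"{'input':<12} {'approved':<10} status")
for res in normalize_symbols(norm, queries):
    print(f"{res.input_symbol:<12} {res.approved_symbol or '-':<10} {res.status}")

# 'tp53' and 'p53' both resolve to TP53 (phase 1 is case-insensitive; phase 2
# consults unambiguous synonyms). 'SHARED' belongs to both MYC and MYCN, so
# it is unmatched by design, as is the typo.
print(f"\nambiguous synonyms dropped from the lookup: {sorted(norm.dropped_ambiguous)}")
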