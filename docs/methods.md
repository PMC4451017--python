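# Methods

## Scope and data model

`pathannot` treats an *annotation set* as one uploaded tab-delimited table:
gene symbol in column 1, free-form value columns after it, an optional single
`#`-prefixed header line, and exactly one display icon. A *pathway* is a named
gene set (from a GMT file or derived from a Cytoscape XGMML topology); a
*collection* is an ordered list of pathways whose gene union defines the
analysis universe. Everything downstream — counting, enrichment, rendering —
is a join between these two objects keyed on HGNC approved symbols.

## Gene-symbol normalization

The normalizer is compiled once from a two-column HGNC reference
(`approved_symbol`, synonym list; comma or pipe separated). Matching is
case-insensitive on whitespace-stripped symbols; output uses HGNC casing.
Resolution is strictly two-phase:

1. **approved**: the canonical form equals an approved symbol;
2. **synonym**: it equals a synonym that maps to exactly one approved symbol.

Synonyms shared by ≥2 approved symbols are removed from the lookup at build
time (`dropped_ambiguous`) — resolving to the wrong gene is strictly worse
than failing, so an ambiguous alias always returns *unmatched*. A synonym
whose canonical form collides with an approved symbol is likewise excluded
from the synonym map: phase 1 wins. HGNC "previous symbols" and "aliases" are
folded into a single synonym list; the reference dialect carries no
distinction, and the resolution rule would be identical for both.

During annotation upload, unmatched symbols stay in their rows (flagged) but
leave the gene index; the unmatched report partitions misses into
*no-HGNC-match* and *out-of-pathway* (valid genes in no loaded pathway), in
file order of first occurrence.

## Counting and enrichment

The counting unit is the distinct gene, never the row: per-sample variant
tables legitimately repeat a gene, and a pathway overlap of k means k genes.
For enrichment, each (pathway, set) pair forms a 2×2 table with margins
N = |universe|, K = |set genes ∩ universe|, n = |pathway|, k = |overlap|; the
reported p-value is the one-sided upper hypergeometric tail
Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n). Two deliberate choices, both configurable in
principle but fixed as defaults:

- **Sidedness**: over-representation only. Enrichment asks whether a pathway
  holds more annotated genes than chance; the lower tail answers a different
  question.
- **Universe**: the union of genes over loaded pathways, not the genome.
  Genes outside every pathway cannot contribute to any overlap, and the
  unmatched report already treats them as non-participating; including them
  would only deflate every p-value by a constant margin inflation.

The tail is evaluated with exact integer binomials over a single rational
(`math.comb` + `fractions.Fraction`), so the only rounding is the final
conversion to float. This costs microseconds at the N ≈ 10²–10⁴ typical of
pathway universes and removes any question of log-gamma cancellation; the
test suite cross-checks against `scipy.stats.hypergeom.sf` and against
brute-force subset enumeration. Raw p-values are primary; Benjamini–Hochberg
(via `statsmodels`) is applied per set across pathways when requested, off by
default. Sorting of the summary table is a stable sort, so repeated or
tied-key sorts never reorder equal rows.

## Topology parsing and rendering

XGMML nodes supply a label, coordinates (from the `graphics` child, falling
back to node-level `att` elements) and box extents; coordinates are continuous
screen units, y-down, taken as-is from the Cytoscape export. Nodes without
coordinates are placed on a deterministic row-major grid (4 columns,
150×80-unit cells) so rendering never fails on a coordinate gap. A node's
genes come from its label, split on `/` and `,` and normalized per token;
family shorthand such as `CDK4/6` expands the bare numeric token against the
first token's alphabetic stem (`CDK` + `6`). Unresolvable labels (compounds,
processes) keep their node but carry no genes.

The overlay join emits one *hit* per (gene-bearing node, set) pair whose
intersection is non-empty; all matching rows aggregate into that hit's single
tooltip (header names from the `#` line plus the row values). Geometry: icons
are 14×14 units in a horizontal strip anchored at the node's top-right
corner, in set load order, wrapping after four — the adjacency convention is
ours, chosen so multiple data types on one gene remain individually visible.
Gene labels hyperlink to a configurable URL template (GeneCards search by
default). SVG is emitted via `xml.etree` with fixed attribute order, no
timestamps and no randomness, making byte-identical reruns a testable
contract; the HTML variant adds per-hit tooltip boxes shown by a
`:hover` CSS rule only, so files open offline in any browser. Icon images are
restricted to png/jpg/gif and embedded as base64 data URIs.

## Synthetic data generator

The fixture module emulates a small interpretation study and is the input
source for tests and the acceptance script. Defaults: a 60-gene reference
(`GENE0001…`) with 1–3 synonyms per gene (lowercase variants and
`ALT_`-prefixed strings, exercising case-insensitive matching) and 2
synonyms deliberately shared between gene pairs; 10 pathways of 4–12 genes
drawn without replacement, each with an XGMML topology (grid coordinates, one
non-gene "ATP" node, chained activation edges); annotation files sampling
genes at rate 0.3 with 3 injected invalid symbols, 2 value columns,
occasional duplicate gene rows, and symbols spelled as a mix of approved
forms, case variants and resolvable synonyms. Approved genes *outside* the
pathway universe are sampled at the same rate so the out-of-pathway report
partition is non-trivially exercised. Every generator consumes one seeded
`random.Random`; a seed determines the outputs byte-for-byte, and each
annotation fixture returns a ground-truth manifest (per-pathway overlap
counts, both unmatched partitions) computed independently of the parsing
pipeline, which end-to-end tests must reproduce exactly.

What the generator does **not** emulate: realistic pathway topology (hubs,
cross-talk), skewed pathway-size distributions, biologically structured
annotation overlap, or real HGNC content with its historical symbol
collisions. Passing tests therefore demonstrate correctness of the
counting/normalization/rendering machinery, not robustness to the full mess
of real nomenclature.

## Numerical and degenerate-input conventions

- k at the distribution's minimum support point (including k = 0, or K = N)
  gives p = 1 exactly.
- An annotation set with no genes in the universe yields k = 0 and p = 1 for
  every pathway, with a warning rather than an error.
- An empty pathway collection, a pathway with no genes, and a topology with
  zero gene nodes are errors: each would make counting meaningless.
- Short annotation rows are right-padded with empty fields (warned); overlong
  rows are format errors naming the line — padding tolerates ragged
  spreadsheet exports while column drift stays loud.
- All output files are written atomically (temp file + rename); no error path
  leaves a partial artifact.

## Problem sizes

Tests and the acceptance script run the study at the generator defaults above
(60 genes, 10 pathways, 3 annotation sets); the exhaustive enrichment check
enumerates every valid margin configuration with N ≤ 12 against subset
enumeration, and normalization properties are verified across 100 seeded
references of 25 genes.

## Known limitations

- GMT descriptions double as display names; there is no separate metadata
  carrier.
- The background-image option trusts XGMML coordinates; no registration or
  scaling against the raster is attempted.
- No KGML/SBML/BioPAX ingestion, no rank-based (GSEA-style) or
  topology-aware enrichment, and no streaming parser for multi-GB files.
- Tooltip box sizing in HTML output is a character-count heuristic, not a
  text-measurement layout.
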