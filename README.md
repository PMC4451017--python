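# pathannot

Overlay gene-centric annotations on biological pathways — headless.

Clinical and research genomics produces *gene-keyed* tables from disparate
assays: somatic variants, copy-number calls, differential expression, drug–gene
relationships, phenotype links. Interpreting them requires seeing the genes in
the topological context of their pathways, not as isolated lists. `pathannot`
is a library (plus a thin CLI) for bioinformaticians who need to assemble that
view reproducibly: it ingests simple tab-delimited annotation files, normalizes
gene symbols against an HGNC reference, joins the annotations onto pathway gene
sets and Cytoscape topologies, computes per-pathway counts and enrichment, and
renders static SVG/HTML pathway diagrams in which each annotation set appears
as an icon next to its genes, with the full annotated rows available as hover
tooltips and each gene linked to its GeneCards page.

## What it computes

**Symbol normalization** is two-phase: an input symbol is matched
(case-insensitively) against HGNC *approved symbols* first, then against HGNC
*synonyms*; a synonym associated with more than one approved symbol is removed
from the lookup entirely, so an ambiguous alias never resolves. Symbols that
fail both phases, and valid genes that belong to no loaded pathway, are
partitioned into a downloadable unmatched report.

**Enrichment** is the one-sided Fisher's exact test for over-representation.
With N genes in the universe (the union of genes across loaded pathways), K of
them annotated, and a pathway of n genes containing k annotated genes:

    p = Σ_{i=k}^{min(n,K)}  C(K,i) · C(N−K, n−i) / C(N,n)

computed with exact integer/rational arithmetic, so the reported p-value is
the mathematically exact tail up to one final float rounding. Counts are per
*gene*, never per row: a gene with five variant rows counts once.
Benjamini–Hochberg adjustment is available behind a flag.

**Rendering** is deterministic: identical inputs produce byte-identical SVG.
Each (node, set) hit draws one icon in a strip at the node's top-right corner;
a legend lists each loaded set once; HTML output embeds declarative
CSS-hover tooltips and needs no scripts or network.

## Worked example

`examples/02_enrichment_table.py` generates a seeded synthetic study (60-gene
HGNC reference, 10 pathways, one "mutations" annotation set) and prints the
summary table sorted by p-value:

```
loaded mutations: 20 genes (3 symbols had no HGNC match)

pathway  n_genes   k  p (one-sided Fisher)
PW003         10   6  0.0912
PW007         11   6  0.1502
PW006         12   6  0.2243
PW002          5   3  0.2532
...
PW005          7   1  0.9694
```

`n_genes` is the pathway size, `k` the number of distinct annotated genes it
contains, and `p` the exact upper hypergeometric tail against the
union-of-pathways universe: PW003 holds 6 of the 20 annotated genes in only 10
members, the strongest (though here unremarkable) over-representation.

The other examples show symbol normalization (`01_normalize_symbols.py`) and
overlay rendering (`03_render_overlay.py`), where a gene present in two
annotation sets — e.g. a mutated gene that is also druggable — receives two
icons next to its node.

The same operations are scriptable from the shell:

```sh
pathannot fixtures --seed 1 --out fx/
pathannot summarize --gmt fx/pathways.gmt --hgnc fx/hgnc.tsv \
    --annot fx/annot_1.tsv:cross --annot fx/annot_2.tsv:pill \
    --enrich --out table.tsv
pathannot render --xgmml fx/pathway_PW001.xgmml --hgnc fx/hgnc.tsv \
    --annot fx/annot_1.tsv:cross --out pathway.html
```

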