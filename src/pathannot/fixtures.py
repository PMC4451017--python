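"""Deterministic synthetic inputs: HGNC tables, pathway collections, and
annotation files with a ground-truth manifest.

Every module in this package is testable offline: the generators here emit an
HGNC reference (approved symbols ``GENE0001..`` with lowercase and
``ALT_``-prefixed synonyms, plus a controlled number of ambiguous synonyms
shared between gene pairs), a pathway collection (GMT membership drawn
without replacement, plus one XGMML topology per pathway with grid
coordinates and one non-gene compound node), and annotation files whose rows
mix approved symbols, case variants and resolvable synonyms, with a known
number of injected invalid symbols.

The manifest returned with each annotation fixture records the ground truth —
per-pathway overlap counts, the invalid-symbol list, and the genes that are
valid but outside the pathway universe — so end-to-end pipeline outputs can
be checked exactly. All randomness flows through one seeded
``random.Random`` instance; the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from ._io import atomic_write_text
from .errors import InputError
from .normalize import HgncTable, write_hgnc_table
from .pathways import PathwayNode, PathwayEdge, PathwayTopology, write_xgmml

__all__ = [
    "FixtureSpec",
    "HgncFixture",
    "PathwayFixture",
    "AnnotationFixture",
    "make_hgnc_fixture",
    "make_pathway_fixture",
    "make_annotation_fixture",
    "make_icon_fixture",
    "make_all_fixtures",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for one reproducible fixture family.

    Defaults emulate a small study: a 60-gene reference, 10 pathways of 4-12
    genes, annotation files covering ~30% of genes with a few typos.
    """

    seed: int = 0
    n_genes: int = 60
    n_synonyms_per_gene: tuple[int, int] = (1, 3)
    ambiguous_synonym_count: int = 2
    n_pathways: int = 10
    pathway_size: tuple[int, int] = (4, 12)
    hit_rate: float = 0.3
    invalid_symbol_count: int = 3
    extra_column_count: int = 2

    def __post_init__(self):
        for name in ("n_genes", "ambiguous_synonym_count", "n_pathways",
                     "invalid_symbol_count", "extra_column_count"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if not (0.0 <= self.hit_rate <= 1.0):
            raise InputError(f"hit_rate must be in [0, 1], got {self.hit_rate}")
        lo, hi = self.n_synonyms_per_gene
        if lo < 0 or hi < lo:
            raise InputError("n_synonyms_per_gene must be a non-negative (lo, hi) range")
        lo, hi = self.pathway_size
        if lo < 1 or hi < lo:
            raise InputError("pathway_size must be a positive (lo, hi) range")
        if self.n_genes >= 2:
            feasible_pairs = self.n_genes * (self.n_genes - 1) // 2
        else:
            feasible_pairs = 0
        if self.ambiguous_synonym_count > feasible_pairs:
            raise InputError(
                f"ambiguous_synonym_count={self.ambiguous_synonym_count} exceeds "
                f"the {feasible_pairs} feasible gene pairs for n_genes={self.n_genes}")
        if self.n_pathways > 0 and self.pathway_size[0] > self.n_genes:
            raise InputError(
                f"pathway_size lower bound {self.pathway_size[0]} exceeds "
                f"n_genes={self.n_genes}")


@dataclass(frozen=True)
class HgncFixture:
    table: HgncTable
    path: Path | None
    ambiguous_synonyms: tuple[str, ...]

    @property
    def approved(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.table.rows)


@dataclass(frozen=True)
class PathwayFixture:
    membership: dict[str, tuple[str, ...]]  # pathway id -> member genes
    gmt_path: Path | None
    xgmml_paths: dict[str, Path] = field(default_factory=dict)

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(g for genes in self.membership.values() for g in genes)


@dataclass(frozen=True)
class AnnotationFixture:
    path: Path | None
    text: str
    manifest: dict


def _rng(spec: FixtureSpec, rng: random.Random | None) -> random.Random:
    return rng if rng is not None else random.Random(spec.seed)


def make_hgnc_fixture(spec: FixtureSpec, out_path: str | Path | None = None,
                      rng: random.Random | None = None) -> HgncFixture:
    """Generate the HGNC reference: unique approved symbols, per-gene synonym
    lists, and exactly ``ambiguous_synonym_count`` synonyms each shared by two
    distinct genes."""
    rng = _rng(spec, rng)
    approved = [f"GENE{i + 1:04d}" for i in range(spec.n_genes)]
    synonyms: dict[str, list[str]] = {a: [] for a in approved}
    lo, hi = spec.n_synonyms_per_gene
    for a in approved:
        for j in range(rng.randint(lo, hi)):
            if rng.random() < 0.5:
                synonyms[a].append(f"{a.lower()}v{j + 1}")
            else:
                synonyms[a].append(f"ALT_{a}_{j + 1}")

    pairs: list[tuple[str, str]] = []
    seen_pairs: set[tuple[str, str]] = set()
    while len(pairs) < spec.ambiguous_synonym_count:
        g1, g2 = rng.sample(approved, 2)
        key = (min(g1, g2), max(g1, g2))
        if key not in seen_pairs:
            seen_pairs.add(key)
            pairs.append(key)
    ambiguous = []
    for i, (g1, g2) in enumerate(pairs):
        syn = f"AMBIG{i + 1:04d}"
        synonyms[g1].append(syn)
        synonyms[g2].append(syn)
        ambiguous.append(syn)

    table = HgncTable([(a, tuple(synonyms[a])) for a in approved])
    path = None
    if out_path is not None:
        path = Path(out_path)
        write_hgnc_table(table, path)
    return HgncFixture(table=table, path=path, ambiguous_synonyms=tuple(ambiguous))


def make_pathway_fixture(spec: FixtureSpec, hgnc: HgncFixture,
                         out_dir: str | Path | None = None,
                         rng: random.Random | None = None) -> PathwayFixture:
    """Generate GMT membership and one XGMML topology per pathway.

    Membership is drawn without replacement; each topology places the
    pathway's genes on a row-major grid, adds one non-gene compound node
    ("ATP"), and chains the nodes with activation edges.
    """
    rng = _rng(spec, rng)
    approved = list(hgnc.approved)
    lo, hi = spec.pathway_size
    membership: dict[str, tuple[str, ...]] = {}
    for i in range(spec.n_pathways):
        size = rng.randint(lo, min(hi, len(approved)))
        membership[f"PW{i + 1:03d}"] = tuple(rng.sample(approved, size))

    gmt_path = None
    xgmml_paths: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        lines = [f"{pid}\tsynthetic pathway {pid}\t" + "\t".join(genes)
                 for pid, genes in membership.items()]
        gmt_path = out_dir / "pathways.gmt"
        atomic_write_text(gmt_path, "\n".join(lines) + ("\n" if lines else ""))
        for pid, genes in membership.items():
            nodes = []
            for j, gene in enumerate(genes):
                row, col = divmod(j, 4)
                nodes.append(PathwayNode(node_id=f"n{j + 1}", label=gene,
                                         x=30.0 + col * 150.0, y=30.0 + row * 80.0))
            row, col = divmod(len(genes), 4)
            nodes.append(PathwayNode(node_id="cmpd1", label="ATP",
                                     x=30.0 + col * 150.0, y=30.0 + row * 80.0))
            edges = [PathwayEdge(nodes[j].node_id, nodes[j + 1].node_id, "activates")
                     for j in range(len(nodes) - 1)]
            topo = PathwayTopology(tuple(nodes), tuple(edges))
            xgmml_paths[pid] = out_dir / f"pathway_{pid}.xgmml"
            write_xgmml(topo, xgmml_paths[pid], label=pid)
    return PathwayFixture(membership=membership, gmt_path=gmt_path,
                          xgmml_paths=xgmml_paths)


def _symbol_variant(gene: str, synonyms: dict[str, tuple[str, ...]],
                    ambiguous: frozenset[str], rng: random.Random) -> str:
    """A resolvable spelling of *gene*: approved, case variant, or synonym."""
    u = rng.random()
    if u < 0.5:
        return gene
    if u < 0.75:
        return gene.lower()
    usable = [s for s in synonyms.get(gene, ()) if s not in ambiguous]
    return rng.choice(usable) if usable else gene


def make_annotation_fixture(spec: FixtureSpec, hgnc: HgncFixture,
                            pathways: PathwayFixture,
                            name: str = "annot_1",
                            out_path: str | Path | None = None,
                            rng: random.Random | None = None) -> AnnotationFixture:
    """Generate one annotation file plus its ground-truth manifest.

    Genes are sampled at ``hit_rate`` from the pathway universe (true hits)
    and from the approved symbols outside it (out-of-pathway entries);
    ``invalid_symbol_count`` bogus symbols and ``extra_column_count`` value
    columns are injected. Some genes get duplicate rows to exercise the
    genes-not-rows counting rule. The manifest records per-pathway overlap
    counts and both unmatched-report partitions.
    """
    rng = _rng(spec, rng)
    universe = sorted(pathways.universe)
    outside = sorted(set(hgnc.approved) - pathways.universe)
    synonyms = {a: syns for a, syns in hgnc.table.rows}
    ambiguous = frozenset(hgnc.ambiguous_synonyms)

    selected_in = [g for g in universe if rng.random() < spec.hit_rate]
    selected_out = [g for g in outside if rng.random() < spec.hit_rate]
    invalid = [f"NOTAGENE{i + 1:03d}" for i in range(spec.invalid_symbol_count)]

    columns = ["Gene"] + [f"ann_{j + 1}" for j in range(spec.extra_column_count)]
    rows: list[list[str]] = []
    for gene in selected_in + selected_out:
        n_rows = 2 if rng.random() < 0.15 else 1  # occasional duplicate gene rows
        for _ in range(n_rows):
            symbol = _symbol_variant(gene, synonyms, ambiguous, rng)
            values = [f"v{rng.randrange(10_000)}" for _ in range(spec.extra_column_count)]
            rows.append([symbol] + values)
    for symbol in invalid:
        values = [f"v{rng.randrange(10_000)}" for _ in range(spec.extra_column_count)]
        rows.append([symbol] + values)
    rng.shuffle(rows)

    lines = ["#" + "\t".join(columns)] + ["\t".join(r) for r in rows]
    text = "\n".join(lines) + "\n"
    path = None
    if out_path is not None:
        path = Path(out_path)
        atomic_write_text(path, text)

    counts = {pid: len(set(genes) & set(selected_in))
              for pid, genes in pathways.membership.items()}
    manifest = {
        "set_name": name,
        "n_rows": len(rows),
        "genes_in_universe": selected_in,
        "out_of_pathway": selected_out,
        "invalid_symbols": invalid,
        "pathway_counts": counts,
    }
    return AnnotationFixture(path=path, text=text, manifest=manifest)


def make_icon_fixture(out_dir: str | Path, name: str = "usericon",
                      fmt: str = "png", color: tuple[int, int, int] = (200, 40, 40),
                      size: int = 12) -> Path:
    """Write a small solid-color raster icon (needs Pillow)."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.{fmt}"
    img = Image.new("RGB", (size, size), color)
    img.save(path, format="JPEG" if fmt == "jpg" else fmt.upper())
    return path


def make_all_fixtures(spec: FixtureSpec, out_dir: str | Path,
                      n_annotation_sets: int = 2) -> dict:
    """Emit the whole fixture family into *out_dir* with one threaded RNG.

    Writes hgnc.tsv, pathways.gmt, pathway_*.xgmml, annot_*.tsv and
    manifest.json; returns the paths and manifests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    hgnc = make_hgnc_fixture(spec, out_dir / "hgnc.tsv", rng=rng)
    pathways = make_pathway_fixture(spec, hgnc, out_dir, rng=rng)
    annotations = []
    for i in range(n_annotation_sets):
        name = f"annot_{i + 1}"
        annotations.append(make_annotation_fixture(
            spec, hgnc, pathways, name=name,
            out_path=out_dir / f"{name}.tsv", rng=rng))
    manifest = {
        "spec": {"seed": spec.seed, "n_genes": spec.n_genes,
                 "n_pathways": spec.n_pathways, "hit_rate": spec.hit_rate,
                 "invalid_symbol_count": spec.invalid_symbol_count},
        "hgnc": str(hgnc.path),
        "gmt": str(pathways.gmt_path),
        "xgmml": {pid: str(p) for pid, p in pathways.xgmml_paths.items()},
        "annotations": [a.manifest for a in annotations],
    }
    atomic_write_text(out_dir / "manifest.json",
                      json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"hgnc": hgnc, "pathways": pathways, "annotations": annotations,
            "manifest_path": out_dir / "manifest.json"}
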