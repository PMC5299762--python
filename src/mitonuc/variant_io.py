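"""Readers and writers for the formats the pipeline touches.

VCF v4.2 (bi-allelic SNVs, haploid or diploid GT), 1000 Genomes-style panel
files (whitespace-delimited sample / population / continental group),
haplogroup definition tables (TSV: parent, child, comma-separated pos:alt
variants, origin, macro) and Newick trees.

Coordinates are 1-based in VCF; in-memory site indexing is 0-based.
Genotype phase is ignored throughout: only allele dosage is retained, which
is all the allele-sharing distance needs.  Missing genotypes are stored as
NaN in the dosage matrix; how they are handled statistically is decided by
the distance layer, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import pysam

from .haplocall import HaplogroupTree, Variant

if TYPE_CHECKING:  # pragma: no cover
    from .njtree import PhyloTree

__all__ = [
    "Site",
    "GenotypeMatrix",
    "PopulationPanel",
    "read_vcf",
    "write_vcf",
    "read_panel",
    "write_panel",
    "read_haplogroup_table",
    "load_default_haplogroup_tree",
    "load_kgp_population_sizes",
    "write_newick",
]


@dataclass(frozen=True)
class Site:
    """One bi-allelic variant site (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Samples × sites allele-dosage matrix.

    ``dosage[i, j]`` is the count of alternate alleles carried by sample
    ``i`` at site ``j``: 0..ploidy, or NaN for a missing genotype.
    """

    samples: list[str]
    sites: list[Site]
    dosage: np.ndarray  # float array, NaN = missing
    ploidy: int

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise ValueError(f"duplicate sample labels: {dupes}")
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > self.ploidy)
        if np.any(bad & ~np.isnan(self.dosage)):
            raise ValueError(f"dosages outside 0..{self.ploidy}")
        last: dict[str, int] = {}
        for s in self.sites:
            if s.chrom in last and s.pos <= last[s.chrom]:
                raise ValueError(
                    f"positions not strictly increasing on {s.chrom} at {s.pos}"
                )
            last[s.chrom] = s.pos

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to site indices ``keep`` (order preserved)."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[self.sites[j] for j in keep],
            dosage=self.dosage[:, keep].copy(),
            ploidy=self.ploidy,
        )


@dataclass
class PopulationPanel:
    """Sample → (population code, continental group) mapping."""

    pop_of: dict[str, str]
    group_of: dict[str, str]
    pop_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.pop_of) != set(self.group_of):
            raise ValueError("pop_of and group_of cover different samples")
        if not self.pop_order:
            seen: list[str] = []
            for pop in self.pop_of.values():
                if pop not in seen:
                    seen.append(pop)
            self.pop_order = seen

    @property
    def samples(self) -> list[str]:
        return list(self.pop_of)

    def group_of_pop(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for s, pop in self.pop_of.items():
            g = self.group_of[s]
            if pop in out and out[pop] != g:
                raise ValueError(f"population {pop!r} assigned to two groups")
            out[pop] = g
        return out

    def population_sizes(self) -> pd.Series:
        counts = pd.Series(list(self.pop_of.values())).value_counts()
        return counts.reindex(self.pop_order).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": list(self.pop_of),
                "pop": [self.pop_of[s] for s in self.pop_of],
                "group": [self.group_of[s] for s in self.pop_of],
            }
        )


# ---------------------------------------------------------------------------
# VCF


def _dosage_from_gt(gt: tuple, ploidy: int, where: str) -> float:
    alleles = [a for a in gt if a is not None]
    if len(alleles) != len(gt) and alleles:
        raise ValueError(f"partially missing genotype at {where}")
    if not alleles:
        return math.nan
    if len(gt) != ploidy:
        raise ValueError(
            f"GT arity {len(gt)} does not match declared ploidy {ploidy} at {where}"
        )
    if any(a not in (0, 1) for a in alleles):
        raise ValueError(f"non-biallelic allele index in GT at {where}")
    return float(sum(alleles))


def read_vcf(path: str | Path, ploidy: int) -> GenotypeMatrix:
    """Read an uncompressed VCF into a :class:`GenotypeMatrix`.

    Only bi-allelic SNV records are accepted; a multi-allelic ALT raises
    with the offending site named.  ``./.`` (or ``.``) becomes NaN.
    """
    if ploidy not in (1, 2):
        raise ValueError(f"ploidy must be 1 or 2, got {ploidy}")
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        sites: list[Site] = []
        rows: list[np.ndarray] = []
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                raise ValueError(
                    f"multi-allelic or ALT-less site {rec.chrom}:{rec.pos} "
                    f"(ALT={','.join(alts) if alts else '.'}) is not supported"
                )
            sites.append(Site(rec.chrom, rec.pos, rec.ref, alts[0]))
            where = f"{rec.chrom}:{rec.pos}"
            rows.append(
                np.array(
                    [
                        _dosage_from_gt(rec.samples[s]["GT"], ploidy, where)
                        for s in samples
                    ]
                )
            )
    dosage = (
        np.array(rows).T if rows else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples=samples, sites=sites, dosage=dosage, ploidy=ploidy)


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal, byte-deterministic VCF v4.2.

    Unphased GT fields: ``0/1``-style for diploid, single-allele for
    haploid; missing genotypes as ``./.`` or ``.``.
    """
    for s in G.sites:
        if not s.ref or not s.alt:
            raise ValueError(f"site {s.chrom}:{s.pos} lacks ref/alt alleles")
    contigs: list[str] = []
    for s in G.sites:
        if s.chrom not in contigs:
            contigs.append(s.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(G.samples)
    )
    for j, s in enumerate(G.sites):
        gts = []
        for i in range(G.n_samples):
            d = G.dosage[i, j]
            if math.isnan(d):
                gts.append("./." if G.ploidy == 2 else ".")
            elif G.ploidy == 2:
                d = int(d)
                gts.append(["0/0", "0/1", "1/1"][d])
            else:
                gts.append(str(int(d)))
        fields = [s.chrom, str(s.pos), ".", s.ref, s.alt, ".", "PASS", ".", "GT"] + gts
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Panel files


def read_panel(path: str | Path) -> PopulationPanel:
    """Read a whitespace-delimited sample/pop/group panel file (with header)."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"panel file needs >= 3 columns, got {df.shape[1]}")
    df = df.iloc[:, :3]
    df.columns = ["sample", "pop", "group"]
    if df["sample"].duplicated().any():
        dupes = sorted(df.loc[df["sample"].duplicated(), "sample"].unique())
        raise ValueError(f"duplicate samples in panel: {dupes}")
    pop_of = dict(zip(df["sample"], df["pop"]))
    group_of = dict(zip(df["sample"], df["group"]))
    return PopulationPanel(pop_of=pop_of, group_of=group_of)


def write_panel(panel: PopulationPanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Haplogroup definition tables


def _parse_variants(cell: str) -> frozenset[Variant]:
    cell = (cell or "").strip()
    if not cell:
        return frozenset()
    out: set[Variant] = set()
    for tok in cell.split(","):
        pos_s, _, alt = tok.strip().partition(":")
        if not alt:
            raise ValueError(f"malformed variant token {tok!r} (want pos:alt)")
        out.add((int(pos_s), alt))
    return frozenset(out)


def read_haplogroup_table(path: str | Path) -> HaplogroupTree:
    """Load a haplogroup tree from its TSV definition.

    Columns: parent, child, variants (comma-separated ``pos:alt``), origin,
    macro.  The root row has parent ``-`` and an empty variant list.  Rows
    may appear in any order.  Cycles, duplicate labels and orphan nodes are
    rejected by :class:`HaplogroupTree` validation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"parent", "child", "variants", "origin", "macro"}
    if not required.issubset(df.columns):
        raise ValueError(f"haplogroup table missing columns {required - set(df.columns)}")
    if df["child"].duplicated().any():
        dupes = sorted(df.loc[df["child"].duplicated(), "child"].unique())
        raise ValueError(f"duplicate haplogroup labels: {dupes}")
    roots = df[df["parent"].isin(["-", "", "."])]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root row, found {len(roots)}")
    root = roots.iloc[0]["child"]
    parent = {
        r.child: r.parent for r in df.itertuples() if r.child != root
    }
    edge_variants = {r.child: _parse_variants(r.variants) for r in df.itertuples()}
    macro_map = {r.child: r.macro for r in df.itertuples()}
    origin_map = {r.child: r.origin for r in df.itertuples()}
    return HaplogroupTree(
        root=root,
        parent=parent,
        edge_variants=edge_variants,
        macro_map=macro_map,
        origin_map=origin_map,
    )


def load_default_haplogroup_tree() -> HaplogroupTree:
    """The bundled synthetic haplogroup fixture tree.

    Topology mirrors the canonical human mtDNA macro-structure — ancient
    African clades (L0, L1, L5) splitting from (L2, L3'4), with M, N and R
    nested under L3 — but the defining-variant positions are invented
    fixture data, not real PhyloTree coordinates.
    """
    ref = resources.files("mitonuc.data").joinpath("haplogroup_tree.tsv")
    with resources.as_file(ref) as p:
        return read_haplogroup_table(p)


def load_kgp_population_sizes() -> pd.DataFrame:
    """1000 Genomes Phase 3 population sizes (pop, continental group, n)."""
    ref = resources.files("mitonuc.data").joinpath("kgp_population_sizes.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# Newick


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: "PhyloTree", path: str | Path | None = None) -> str:
    """Serialize a :class:`~mitonuc.njtree.PhyloTree` to Newick.

    Returns the Newick string; writes it to ``path`` when given.  Every leaf
    must be labelled.  Node traversal order is deterministic (children by
    node id), so equal trees serialize byte-identically.
    """
    g = tree.graph
    labels = tree.leaf_labels
    leaves = [n for n in g.nodes if g.degree(n) == 1]
    for n in leaves:
        if n not in labels or not labels[n]:
            raise ValueError(f"unlabeled leaf node {n}")
    if len(g.nodes) == 1:
        (n,) = g.nodes
        s = f"{labels[n]}:0;"
    else:
        root = tree.root if tree.root is not None else max(
            (n for n in g.nodes if g.degree(n) > 1), default=leaves[0]
        )

        def sub(node: int, parent: int | None) -> str:
            kids = sorted(n for n in g.neighbors(node) if n != parent)
            if not kids:
                return labels[node]
            inner = ",".join(
                f"{sub(k, node)}:{_fmt_len(g.edges[node, k]['length'])}"
                for k in kids
            )
            lbl = labels.get(node, "")
            return f"({inner}){lbl}"

        s = sub(root, None) + ";"
    if path is not None:
        Path(path).write_text(s + "\n")
    return s
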