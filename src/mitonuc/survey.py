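"""Population-level haplogroup census and mismatch classification.

Cross-tabulates haplogroup calls by population, hierarchically clusters the
composition profiles (average linkage, Euclidean metric on row proportions
so population size does not drive the dendrogram), classifies each
(population, haplogroup) cell as matched or mismatched by comparing the
haplogroup's continental origin with the population's continental group,
and extracts phylogenetically discordant sister pairs: cherries of the
nuclear NJ tree whose members carry haplogroups far apart on the
haplogroup tree.

Continental groups of admixed ancestry (e.g. an American group formed from
European, African and Native American sources) can be declared with their
source-origin set; any source origin then counts as matched at the cell
level, while per-sample records still log every origin≠group case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage

from .haplocall import (
    HaplogroupTree,
    HaplotypeCall,
    haplogroup_path_distance,
    macro_and_origin,
)
from .njtree import PhyloTree, sister_pairs
from .variant_io import PopulationPanel

__all__ = [
    "CountMatrix",
    "MismatchTable",
    "haplogroup_counts",
    "cluster_counts",
    "classify_matches",
    "discordant_sisters",
]

#: default haplogroup-tree path distance for "divergent" sister haplotypes
DEFAULT_MIN_HG_DISTANCE = 4


@dataclass
class CountMatrix:
    """Populations × haplogroups integer count table with annotations."""

    table: pd.DataFrame  # index = populations, columns = haplogroup labels
    group_of_pop: dict[str, str]

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [p for p in self.table.index if p not in self.group_of_pop]
        if missing:
            raise ValueError(f"populations without group annotation: {missing}")

    def proportions(self) -> pd.DataFrame:
        sums = self.table.sum(axis=1)
        return self.table.div(sums.replace(0, 1), axis=0)

    def to_tsv(self, path: str | Path, tree: HaplogroupTree | None = None) -> None:
        df = self.table.copy()
        df.insert(0, "group", [self.group_of_pop[p] for p in df.index])
        df.index.name = "pop"
        if tree is not None:
            macro = ["" ] + [tree.macro_map.get(h, "?") for h in self.table.columns]
            origin = [""] + [tree.origin_map.get(h, "?") for h in self.table.columns]
            header = pd.DataFrame(
                [macro, origin], columns=df.columns, index=["#macro", "#origin"]
            )
            df = pd.concat([header, df])
        df.to_csv(path, sep="\t")


@dataclass
class MismatchTable:
    """Matched/mismatched status per cell plus per-sample records."""

    cells: pd.DataFrame  # pop, haplogroup, count, origin, status
    per_sample: pd.DataFrame  # sample, pop, group, haplogroup, origin, status
    mismatch_fraction: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_sample.empty:
            return
        cell_total = (
            self.cells.groupby(["pop", "haplogroup"])["count"].sum().sort_index()
        )
        rec_total = (
            self.per_sample.groupby(["pop", "haplogroup"]).size().sort_index()
        )
        if not cell_total[cell_total > 0].equals(rec_total.astype(cell_total.dtype)):
            raise ValueError("per-sample records do not sum to cell counts")

    def to_tsv(self, path: str | Path) -> None:
        self.per_sample.to_csv(path, sep="\t", index=False)


def haplogroup_counts(
    calls: list[HaplotypeCall],
    panel: PopulationPanel,
    keep_zero_columns: bool = False,
    all_haplogroups: list[str] | None = None,
) -> CountMatrix:
    """Cross-tabulate haplogroup calls by population."""
    missing = [c.sample for c in calls if c.sample not in panel.pop_of]
    if missing:
        raise KeyError(f"called samples absent from panel: {missing[:5]}")
    df = pd.DataFrame(
        {
            "pop": [panel.pop_of[c.sample] for c in calls],
            "haplogroup": [c.haplogroup for c in calls],
        }
    )
    table = pd.crosstab(df["pop"], df["haplogroup"])
    pops = [p for p in panel.pop_order if p in table.index] + [
        p for p in table.index if p not in panel.pop_order
    ]
    cols = sorted(table.columns)
    if keep_zero_columns and all_haplogroups is not None:
        cols = sorted(set(cols) | set(all_haplogroups))
    table = table.reindex(index=pops, columns=cols, fill_value=0)
    table.index.name = "pop"
    table.columns.name = "haplogroup"
    return CountMatrix(table=table, group_of_pop=panel.group_of_pop())


def cluster_counts(
    M: CountMatrix,
) -> dict:
    """Average-linkage hierarchical clustering of rows and columns.

    Operates on proportion-normalized profiles (rows: haplogroup
    composition per population; columns: population profile per
    haplogroup).  Returns leaf orders and scipy linkage matrices.
    Deterministic: scipy's tie-breaking is by input order.
    """
    if len(M.table) < 2:
        warnings.warn("single-row count matrix; identity ordering returned")
        return {
            "row_order": list(M.table.index),
            "col_order": list(M.table.columns),
            "row_linkage": None,
            "col_linkage": None,
        }
    P = M.proportions().to_numpy()
    row_Z = linkage(P, method="average", metric="euclidean")
    row_order = [
        M.table.index[i] for i in dendrogram(row_Z, no_plot=True)["leaves"]
    ]
    counts = M.table.to_numpy().astype(float)
    col_sums = counts.sum(axis=0)
    col_profiles = (counts / np.where(col_sums == 0, 1, col_sums)).T
    if len(M.table.columns) >= 2:
        col_Z = linkage(col_profiles, method="average", metric="euclidean")
        col_order = [
            M.table.columns[i] for i in dendrogram(col_Z, no_plot=True)["leaves"]
        ]
    else:
        col_Z = None
        col_order = list(M.table.columns)
    return {
        "row_order": row_order,
        "col_order": col_order,
        "row_linkage": row_Z,
        "col_linkage": col_Z,
    }


def classify_matches(
    M: CountMatrix,
    tree: HaplogroupTree,
    admixed_sources: dict[str, set[str]] | None = None,
    calls: list[HaplotypeCall] | None = None,
    panel: PopulationPanel | None = None,
) -> MismatchTable:
    """Classify each (population, haplogroup) cell as matched or mismatched.

    A cell is matched iff the haplogroup's continental origin equals the
    population's continental group, or the group is declared admixed and
    the origin is one of its declared sources.  Per-sample records (and the
    cohort mismatch fraction) use the strict origin == group rule so that
    expected admixed-population mismatches are still recorded; they are
    filled when ``calls`` and ``panel`` are provided.
    """
    admixed_sources = admixed_sources or {}
    origin_universe = set(tree.origin_map.values())
    for h in M.table.columns:
        if h not in tree.origin_map:
            raise KeyError(f"haplogroup {h!r} has no origin mapping")

    def cell_status(group: str, origin: str) -> str:
        if group in admixed_sources:
            return "matched" if origin in admixed_sources[group] else "mismatched"
        if group not in origin_universe:
            raise ValueError(
                f"continental group {group!r} is neither an mtDNA origin nor "
                "declared admixed; declare its source origins"
            )
        return "matched" if origin == group else "mismatched"

    rows = []
    for pop in M.table.index:
        group = M.group_of_pop[pop]
        for hg in M.table.columns:
            count = int(M.table.loc[pop, hg])
            origin = tree.origin_map[hg]
            rows.append(
                {
                    "pop": pop,
                    "group": group,
                    "haplogroup": hg,
                    "origin": origin,
                    "count": count,
                    "status": cell_status(group, origin),
                }
            )
    cells = pd.DataFrame(rows)

    if calls is not None and panel is not None:
        recs = []
        for c in calls:
            pop = panel.pop_of[c.sample]
            group = panel.group_of[c.sample]
            macro, origin = macro_and_origin(c, tree)
            recs.append(
                {
                    "sample": c.sample,
                    "pop": pop,
                    "group": group,
                    "haplogroup": c.haplogroup,
                    "macro": macro,
                    "origin": origin,
                    "status": "matched" if origin == group else "mismatched",
                }
            )
        per_sample = pd.DataFrame(recs)
        frac = float((per_sample["status"] == "mismatched").mean())
    else:
        per_sample = pd.DataFrame(
            columns=["sample", "pop", "group", "haplogroup", "macro", "origin", "status"]
        )
        weights = cells["count"].to_numpy()
        mism = (cells["status"] == "mismatched").to_numpy()
        frac = float((weights * mism).sum() / weights.sum()) if weights.sum() else 0.0

    return MismatchTable(
        cells=cells,
        per_sample=per_sample,
        mismatch_fraction=frac,
        meta={"admixed_sources": {k: sorted(v) for k, v in admixed_sources.items()}},
    )


def discordant_sisters(
    tree: PhyloTree,
    calls: list[HaplotypeCall],
    hg_tree: HaplogroupTree,
    min_hg_distance: int = DEFAULT_MIN_HG_DISTANCE,
) -> pd.DataFrame:
    """Cherries of the nuclear tree whose haplogroups are tree-distant.

    For every sister pair, the path distance between the two members'
    haplogroups on the haplogroup tree is computed; pairs at or above
    ``min_hg_distance`` edges are reported with their pendant branch
    lengths and haplogroup pair.
    """
    call_of = {c.sample: c for c in calls}
    uncalled = sorted(tree.leaf_set() - set(call_of))
    if uncalled:
        raise KeyError(f"tree leaves without a haplogroup call: {uncalled[:5]}")
    inv = {lab: n for n, lab in tree.leaf_labels.items()}
    rows = []
    for a, b in sister_pairs(tree):
        ha, hb = call_of[a].haplogroup, call_of[b].haplogroup
        dist = haplogroup_path_distance(hg_tree, ha, hb)
        if dist >= min_hg_distance:
            na, nb = inv[a], inv[b]
            (pa,) = tree.graph.neighbors(na)
            (pb,) = tree.graph.neighbors(nb)
            rows.append(
                {
                    "sample_i": a,
                    "sample_j": b,
                    "haplogroup_i": ha,
                    "haplogroup_j": hb,
                    "hg_distance": dist,
                    "pendant_i": tree.graph.edges[na, pa]["length"],
                    "pendant_j": tree.graph.edges[nb, pb]["length"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_i",
            "sample_j",
            "haplogroup_i",
            "haplogroup_j",
            "hg_distance",
            "pendant_i",
            "pendant_j",
        ],
    )
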