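"""Allele-sharing distances between all pairs of individuals.

The distance between two individuals is the number of allele differences
``d`` divided by the number of alleles compared: for unphased diploid
genotypes the per-site contribution is ``|dosage_a - dosage_b|`` (the
minimal number of mismatched alleles over all pairings of the four
alleles), normalized by ``2n``; for haploid data it is ``1[a != b]``
normalized by ``n``.  Missing genotypes are handled by pairwise-complete
deletion: a site where either member of the pair is missing is dropped from
both numerator and denominator (PLINK-like behaviour).

Note the resulting dissimilarity need not satisfy the triangle inequality
when different pairs use different site subsets; no metric property is
assumed downstream (classical MDS and NJ both operate on it regardless).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pathlib import Path

from .variant_io import GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "allele_sharing_distance",
    "pairwise_distance_matrix",
    "mean_population_distances",
]


@dataclass
class DistanceMatrix:
    """Labelled symmetric pairwise distance matrix with per-pair site counts."""

    labels: list[str]
    values: np.ndarray
    sites_used: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sites_used = np.asarray(self.sites_used)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("distance matrix must be exactly symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("allele-sharing distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def pair_index(self) -> list[tuple[str, str]]:
        """Unordered pairs in condensed (row-major upper-triangle) order."""
        return [
            (self.labels[i], self.labels[j])
            for i in range(self.n)
            for j in range(i + 1, self.n)
        ]

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in the same order as :meth:`pair_index`."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        """Same matrix with rows/columns permuted to the given label order."""
        if sorted(labels) != sorted(self.labels):
            raise ValueError("label sets differ")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)],
            sites_used=self.sites_used[np.ix_(idx, idx)],
            meta=dict(self.meta),
        )

    def to_square_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    def to_pair_tsv(self, path: str | Path) -> None:
        iu = np.triu_indices(self.n, k=1)
        pd.DataFrame(
            {
                "sample_i": [self.labels[i] for i in iu[0]],
                "sample_j": [self.labels[j] for j in iu[1]],
                "distance": self.values[iu],
                "sites_used": self.sites_used[iu],
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def allele_sharing_distance(a: np.ndarray, b: np.ndarray, ploidy: int) -> float:
    """Allele-sharing distance between two dosage vectors (NaN = missing)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if ploidy not in (1, 2):
        raise ValueError(f"ploidy must be 1 or 2, got {ploidy}")
    valid = ~np.isnan(a) & ~np.isnan(b)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no sites with genotypes present in both samples")
    if ploidy == 2:
        d = float(np.abs(a[valid] - b[valid]).sum())
        return d / (2 * n_valid)
    d = float((a[valid] != b[valid]).sum())
    return d / n_valid


def pairwise_distance_matrix(G: GenotypeMatrix) -> DistanceMatrix:
    """All-pairs allele-sharing distances for a genotype matrix.

    Vectorized one row at a time: O(n^2 p) work, O(n p) memory.
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    X = G.dosage
    n = G.n_samples
    valid = ~np.isnan(X)
    counts = (valid.astype(np.int64) @ valid.T.astype(np.int64))
    Xz = np.where(valid, X, 0.0)
    num = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        if G.ploidy == 2:
            num[i] = np.abs(np.where(both, Xz[i] - Xz, 0.0)).sum(axis=1)
        else:
            num[i] = ((Xz[i] != Xz) & both).sum(axis=1)
    off_diag_empty = (counts == 0) & ~np.eye(n, dtype=bool)
    if np.any(off_diag_empty):
        i, j = np.argwhere(off_diag_empty)[0]
        raise ValueError(
            f"distance undefined for pair ({G.samples[i]}, {G.samples[j]}): "
            "no sites with genotypes present in both"
        )
    denom = (2 if G.ploidy == 2 else 1) * np.maximum(counts, 1)
    D = num / denom
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(
        labels=list(G.samples),
        values=D,
        sites_used=counts,
        meta={
            "ploidy": G.ploidy,
            "normalization": "2n" if G.ploidy == 2 else "n",
            "missing_policy": "pairwise-complete",
        },
    )


def mean_population_distances(D: DistanceMatrix, panel) -> DistanceMatrix:
    """Aggregate a per-sample matrix to mean between-population distances.

    The (P, Q) entry is the mean distance over all sample pairs with one
    member in P and one in Q (within-population means on the off-diagonal
    never mix in: the diagonal is forced to zero as for any distance
    matrix).  Useful for population-level trees when a full n-leaf NJ run
    is too large.
    """
    pops = [p for p in panel.pop_order]
    idx_of = {p: [] for p in pops}
    for i, s in enumerate(D.labels):
        idx_of[panel.pop_of[s]].append(i)
    k = len(pops)
    out = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=np.int64)
    for a in range(k):
        for b in range(a + 1, k):
            block = D.values[np.ix_(idx_of[pops[a]], idx_of[pops[b]])]
            out[a, b] = out[b, a] = block.mean()
            counts[a, b] = counts[b, a] = block.size
    return DistanceMatrix(
        labels=pops,
        values=out,
        sites_used=counts,
        meta=dict(D.meta, level="population-mean"),
    )
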