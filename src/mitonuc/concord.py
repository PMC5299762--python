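"""Nuclear-vs-mitochondrial distance concordance statistics.

Given the nuclear and mtDNA allele-sharing distance matrices over the same
cohort, the two condensed pair vectors are compared three ways:

- Spearman rank correlation (rho) with a t-approximation p-value (exact
  permutation p for n <= 8).  Pairs of a distance matrix are not
  independent observations; the plain coefficient is the primary output,
  and an optional Mantel-style permutation test (permuting the sample
  labels of one matrix) is provided for a permutation p-value.
- Per-pair rank distance-differences: both pair vectors are ranked
  (average ranks under ties) and the difference, normalized by the pair
  count P so cohorts of different sizes are comparable, is reported per
  pair.  The raw rank differences sum to exactly zero.
- Outlier pairs: rank differences standardized by their own mean/SD;
  pairs with |z| above a threshold (default 3) are flagged, with the
  direction recording whether the pair is nuclear-close/mito-far or the
  converse.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from .gendist import DistanceMatrix

__all__ = [
    "ConcordanceResult",
    "spearman",
    "rank_distance_difference",
    "outlier_pairs",
    "concordance",
    "mantel_permutation_p",
]

#: above this length, exact-permutation p is infeasible; t-approximation used
EXACT_PERMUTATION_MAX_N = 8


def _rank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and p-value.

    Average-rank tie handling; rho is the Pearson correlation of the
    ranks.  p is two-sided: exact by permutation for n <= 8, otherwise
    from the t-approximation t = rho * sqrt((n-2) / (1-rho^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError(f"length mismatch: {n} vs {y.size}")
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho undefined for a constant vector")
    rho = _rank_pearson(x, y)
    if n <= EXACT_PERMUTATION_MAX_N:
        count = 0
        total = 0
        for perm in _permutations(range(n)):
            r = _rank_pearson(x, y[list(perm)])
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    elif abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * float(t_dist.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def rank_distance_difference(Dn: DistanceMatrix, Dm: DistanceMatrix) -> pd.DataFrame:
    """Per-pair normalized rank differences between two distance matrices.

    Returns a DataFrame keyed by unordered pair with columns d_nuclear,
    d_mito, rank_n, rank_m, diff (= (rank_n - rank_m) / P).
    """
    if set(Dn.labels) != set(Dm.labels):
        only_n = sorted(set(Dn.labels) - set(Dm.labels))
        only_m = sorted(set(Dm.labels) - set(Dn.labels))
        raise ValueError(
            f"label sets differ: only in nuclear {only_n}, only in mito {only_m}"
        )
    Dm = Dm.reorder(Dn.labels)
    xn = Dn.condensed()
    xm = Dm.condensed()
    P = xn.size
    rank_n = rankdata(xn, method="average")
    rank_m = rankdata(xm, method="average")
    pairs = Dn.pair_index()
    return pd.DataFrame(
        {
            "sample_i": [p[0] for p in pairs],
            "sample_j": [p[1] for p in pairs],
            "d_nuclear": xn,
            "d_mito": xm,
            "rank_n": rank_n,
            "rank_m": rank_m,
            "diff": (rank_n - rank_m) / P,
        }
    )


def outlier_pairs(diffs: pd.DataFrame, z_threshold: float = 3.0) -> pd.DataFrame:
    """Flag pairs whose normalized rank difference is a z-score outlier.

    Standardizes ``diff`` by its own mean and SD.  Positive z means the
    pair ranks farther apart in nuclear than in mtDNA distance
    (nuclear-far/mito-close); negative the converse.
    """
    if len(diffs) < 10:
        raise ValueError(f"need at least 10 pairs, got {len(diffs)}")
    d = diffs["diff"].to_numpy()
    sd = d.std(ddof=0)
    out = diffs.copy()
    # rounding noise on a constant vector is not variance
    if sd <= 1e-14 * max(1.0, float(np.abs(d).max(initial=0.0))):
        warnings.warn("rank differences have zero variance; no outliers defined")
        out["z"] = 0.0
        out["outlier"] = False
        out["direction"] = "none"
        return out.loc[out["outlier"]]
    out["z"] = (d - d.mean()) / sd
    out["outlier"] = out["z"].abs() > z_threshold
    out["direction"] = np.where(
        out["z"] > 0, "nuclear_far_mito_close", "nuclear_close_mito_far"
    )
    return out.loc[out["outlier"]].reset_index(drop=True)


def mantel_permutation_p(
    Dn: DistanceMatrix,
    Dm: DistanceMatrix,
    permutations: int = 999,
    seed: int = 0,
) -> float:
    """Mantel-style permutation p for the Spearman rho of two matrices.

    Permutes the sample labels of the second matrix; two-sided on |rho|.
    """
    Dm = Dm.reorder(Dn.labels)
    xn = Dn.condensed()
    rho_obs = _rank_pearson(xn, Dm.condensed())
    rng = np.random.default_rng(seed)
    n = Dn.n
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        xm = Dm.values[np.ix_(perm, perm)][np.triu_indices(n, k=1)]
        if abs(_rank_pearson(xn, xm)) >= abs(rho_obs) - 1e-12:
            hits += 1
    return (hits + 1) / (permutations + 1)


@dataclass
class ConcordanceResult:
    """Bundle of concordance statistics for one cohort."""

    rho: float
    p_value: float
    n_pairs: int
    diffs: pd.DataFrame
    outliers: pd.DataFrame
    z_threshold: float
    mantel_p: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho out of range: {self.rho}")

    def summary(self) -> dict:
        out = {
            "rho": self.rho,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
            "z_threshold": self.z_threshold,
            "n_outliers": int(len(self.outliers)),
        }
        if self.mantel_p is not None:
            out["mantel_p"] = self.mantel_p
        return out

    def write(self, pairs_path: str | Path, summary_path: str | Path) -> None:
        df = self.diffs.copy()
        d = df["diff"].to_numpy()
        sd = d.std(ddof=0)
        df["z"] = 0.0 if sd == 0 else (d - d.mean()) / sd
        df["outlier"] = df["z"].abs() > self.z_threshold
        df.to_csv(pairs_path, sep="\t", index=False, float_format="%.10g")
        Path(summary_path).write_text(
            json.dumps(self.summary(), indent=2, sort_keys=True) + "\n"
        )


def concordance(
    Dn: DistanceMatrix,
    Dm: DistanceMatrix,
    z_threshold: float = 3.0,
    permutations: int = 0,
    seed: int = 0,
) -> ConcordanceResult:
    """Full concordance analysis of nuclear vs mtDNA distance matrices."""
    diffs = rank_distance_difference(Dn, Dm)
    rho, p = spearman(diffs["d_nuclear"], diffs["d_mito"])
    outliers = outlier_pairs(diffs, z_threshold=z_threshold)
    mp = (
        mantel_permutation_p(Dn, Dm, permutations=permutations, seed=seed)
        if permutations
        else None
    )
    return ConcordanceResult(
        rho=rho,
        p_value=p,
        n_pairs=len(diffs),
        diffs=diffs,
        outliers=outliers,
        z_threshold=z_threshold,
        mantel_p=mp,
    )
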