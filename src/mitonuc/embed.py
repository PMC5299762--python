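"""Classical (Torgerson) multidimensional scaling of a distance matrix.

Double-center the squared distances, B = -1/2 J D^2 J with J = I - 11'/n,
eigendecompose B, and take the top-k eigenvectors scaled by the square root
of their eigenvalues.  For a Euclidean-embeddable D this reproduces the
original distances exactly at k = n - 1.  Allele-sharing distances are not
guaranteed Euclidean; negative eigenvalues among the top k yield zero
coordinates and set a warning flag rather than imaginary axes.

Deterministic up to per-axis sign; :func:`canonicalize_signs` fixes each
axis so its first nonzero coordinate is positive, which keeps plots and
regression tests stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .gendist import DistanceMatrix

__all__ = ["Embedding", "classical_mds", "canonicalize_signs"]


@dataclass
class Embedding:
    """MDS coordinates with the spectrum they came from."""

    labels: list[str]
    coords: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # all n, descending
    positive_mass_captured: float
    negative_axes: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coords.shape[0] != len(self.labels):
            raise ValueError("coordinate rows do not match labels")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def to_tsv(self, path: str | Path, panel=None) -> None:
        df = pd.DataFrame(
            self.coords,
            index=pd.Index(self.labels, name="sample"),
            columns=[f"C{i + 1}" for i in range(self.k)],
        )
        if panel is not None:
            df.insert(0, "pop", [panel.pop_of[s] for s in self.labels])
            df.insert(1, "group", [panel.group_of[s] for s in self.labels])
        df.to_csv(path, sep="\t", float_format="%.10g")


def classical_mds(D: DistanceMatrix, k: int) -> Embedding:
    """Embed a distance matrix in k dimensions by classical MDS."""
    n = D.n
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    sq = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    B = (B + B.T) / 2.0  # average away numerical asymmetry
    w, V = eigh(B)  # ascending
    w = w[::-1]
    V = V[:, ::-1]
    lam = w[:k].copy()
    # only meaningfully negative eigenvalues flag non-Euclidean structure;
    # eigensolver noise around zero is clipped silently
    tol = 1e-9 * max(1.0, float(np.abs(w).max()))
    neg = lam < -tol
    coords = V[:, :k] * np.sqrt(np.clip(lam, 0.0, None))
    if np.any(neg):
        coords[:, neg] = 0.0
    pos = w[w > 0]
    mass = float(np.clip(lam, 0.0, None).sum() / pos.sum()) if pos.size else 0.0
    return Embedding(
        labels=list(D.labels),
        coords=coords,
        eigenvalues=w,
        positive_mass_captured=mass,
        negative_axes=bool(np.any(neg)),
    )


def canonicalize_signs(coords: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip each axis so its first coordinate of magnitude > tol is positive."""
    out = np.array(coords, dtype=float, copy=True)
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.nonzero(np.abs(col) > tol)[0]
        if nz.size and col[nz[0]] < 0:
            out[:, j] = -col
    return out
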