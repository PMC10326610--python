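"""Beta diversity: Bray–Curtis distances, PCoA and UPGMA clustering.

Community dissimilarity between samples is measured with the Bray–Curtis
index ``d(x, y) = 1 - 2 * sum_i min(x_i, y_i) / (sum x + sum y)``, computed
on per-sample relative abundances (the read-ratio basis) or on raw counts.
The distance matrix is embedded with principal coordinates analysis
(Gower double-centering of ``-d^2/2`` followed by a symmetric
eigendecomposition) and summarized as a dendrogram with average-linkage
(UPGMA) agglomerative clustering.

Bray–Curtis matrices are generally non-Euclidean, so some PCoA
eigenvalues may be negative. By default they are reported, not
corrected, and proportions of explained variation are taken over the
positive eigenvalues only; Lingoes and Cailliez corrections are
available via ``correction=``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .community import CommunityMatrix

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "bray_curtis",
    "pcoa",
    "upgma",
    "nearest_neighbors",
    "sister_pairs",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "values", d)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def write_tsv(self, path: str | Path, *, header_lines=()) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t")


def _as_frame(
    matrix: CommunityMatrix | pd.DataFrame, use_relative: bool
) -> pd.DataFrame:
    if isinstance(matrix, CommunityMatrix):
        frame = matrix.counts.astype(float)
    else:
        frame = matrix.astype(float)
    totals = frame.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {zero.index.tolist()}")
    if use_relative:
        frame = frame / totals
    return frame


def bray_curtis(
    matrix: CommunityMatrix | pd.DataFrame, *, use_relative: bool = True
) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between sample columns.

    ``use_relative=True`` (default) converts each column to relative
    abundances first, the read-ratio basis used throughout the survey
    analysis; on columns with equal totals the two bases coincide.
    """
    frame = _as_frame(matrix, use_relative)
    x = frame.to_numpy()
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = np.minimum(x[:, i], x[:, j]).sum()
            total = x[:, i].sum() + x[:, j].sum()
            d[i, j] = d[j, i] = 1.0 - 2.0 * shared / total
    return DistanceMatrix(tuple(str(c) for c in frame.columns), d)


@dataclass(frozen=True)
class PCoAResult:
    """Eigenvalues, explained proportions and sample coordinates."""

    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportions: np.ndarray  # positive axes / sum of positive eigenvalues
    coordinates: pd.DataFrame  # samples x retained axes
    n_negative: int

    def proportion_explained(self, n_axes: int) -> float:
        """Summed proportion of the first ``n_axes`` positive axes."""
        return float(self.proportions[:n_axes].sum())


def pcoa(
    dist: DistanceMatrix,
    n_axes: int | None = None,
    *,
    correction: Literal[None, "lingoes", "cailliez"] = None,
    eps: float = 1e-10,
) -> PCoAResult:
    """Principal coordinates analysis of a distance matrix.

    Double-centers ``-d^2/2``, eigendecomposes, and scales each retained
    axis by the square root of its eigenvalue. Axes are ordered by
    descending eigenvalue; each axis's sign is fixed by making its
    largest-magnitude coordinate positive so output is reproducible.
    Negative eigenvalues are counted and reported; ``correction`` adds
    the Lingoes (on squared distances) or Cailliez (on distances)
    constant that makes the matrix Euclidean.
    """
    d = dist.values
    n = d.shape[0]
    if n_axes is None:
        n_axes = n - 1
    if not 1 <= n_axes <= n - 1:
        raise ValueError(f"n_axes must be in [1, {n - 1}]")

    if correction == "lingoes":
        w = _gower_eigvals(d)
        c = max(0.0, -w.min())
        if c > 0:
            d2 = d**2 + 2.0 * c
            np.fill_diagonal(d2, 0.0)
            d = np.sqrt(d2)
    elif correction == "cailliez":
        d = d + _cailliez_constant(d)
        np.fill_diagonal(d, 0.0)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")

    b = _gower_center(d)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    pos = eigvals > eps
    n_negative = int((eigvals < -eps).sum())
    pos_sum = eigvals[pos].sum()
    proportions = eigvals[pos] / pos_sum

    k = min(n_axes, int(pos.sum()))
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    for j in range(k):  # deterministic axis orientation
        i_max = np.argmax(np.abs(coords[:, j]))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    frame = pd.DataFrame(
        coords,
        index=list(dist.labels),
        columns=[f"PCo{j + 1}" for j in range(k)],
    )
    return PCoAResult(
        eigenvalues=eigvals,
        proportions=proportions,
        coordinates=frame,
        n_negative=n_negative,
    )


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _gower_eigvals(d: np.ndarray) -> np.ndarray:
    return np.linalg.eigvalsh(_gower_center(d))


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest c so that d + c (off-diagonal) is Euclidean."""
    n = d.shape[0]
    delta1 = _gower_center(d)
    delta2 = _gower_center_linear(d)
    zero = np.zeros((n, n))
    upper = np.hstack([zero, 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    sp = np.vstack([upper, lower])
    eigs = np.linalg.eigvals(sp)
    return float(max(np.real(eigs).max(), 0.0))


def _gower_center_linear(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def upgma(
    dist: DistanceMatrix, *, method: str = "average", digits: int = 6
) -> str:
    """Agglomerative dendrogram in Newick text (UPGMA by default).

    Node heights are half the merge distance, so the tree is ultrametric
    under average linkage; branch lengths are height differences.
    ``method`` may be any scipy linkage method (``complete``, ``ward``,
    ...) for sensitivity checks.
    """
    if len(dist.labels) < 2:
        raise ValueError("need at least 2 labels")
    link = hierarchy.linkage(dist.condensed(), method=method)
    labels = dist.labels
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(link):
        a, b = int(a), int(b)
        height = h / 2.0
        la = height - heights[a]
        lb = height - heights[b]
        node = n + k
        heights[node] = height
        newick[node] = (
            f"({newick[a]}:{la:.{digits}f},{newick[b]}:{lb:.{digits}f})"
        )
    return newick[2 * n - 2] + ";"


def linkage_matrix(dist: DistanceMatrix, *, method: str = "average") -> np.ndarray:
    """Raw scipy linkage matrix for plotting or further inspection."""
    return hierarchy.linkage(dist.condensed(), method=method)


def nearest_neighbors(dist: DistanceMatrix) -> dict[str, str]:
    """Nearest neighbor of every label."""
    d = dist.values.copy()
    np.fill_diagonal(d, np.inf)
    return {
        lab: dist.labels[int(np.argmin(d[i]))]
        for i, lab in enumerate(dist.labels)
    }


def sister_pairs(dist: DistanceMatrix, *, method: str = "average") -> list[tuple[str, str]]:
    """Leaf pairs that merge directly with each other in the dendrogram."""
    link = hierarchy.linkage(dist.condensed(), method=method)
    n = len(dist.labels)
    out = []
    for a, b, _, _ in link:
        if a < n and b < n:
            out.append((dist.labels[int(a)], dist.labels[int(b)]))
    return out
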