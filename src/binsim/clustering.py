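"""Agglomerative centroid-linkage clustering of equations.

Each equation is represented by its vector of per-pair coefficients over a
dataset, mean-centered and scaled to unit sample variance.  The distance
between two equations is the Euclidean distance between those standardized
vectors; clusters merge greedily by minimum distance between their centroids
(arithmetic means of member columns).  Centroid linkage is not monotone, so
merge-height inversions may occur; they are reported, never repaired.

Because standardization maps v and alpha*v + beta (alpha > 0) to the same
z-scores, affine families of equations merge at height ~0 before anything
else — the basis of the zero-distance elimination stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .measures import CoefficientMatrix

__all__ = [
    "EquationDistanceMatrix",
    "Dendrogram",
    "standardize",
    "equation_distances",
    "centroid_cluster",
]


def standardize(coeffs) -> np.ndarray:
    """Mean-center and scale each coefficient column to unit sample variance.

    Accepts a :class:`CoefficientMatrix` or a plain (pairs × equations)
    array.  Raises for fewer than 2 rows or a zero-variance column (naming
    the offending equation when ids are available).
    """
    if isinstance(coeffs, CoefficientMatrix):
        values, eq_ids = coeffs.values, coeffs.eq_ids
    else:
        values, eq_ids = np.asarray(coeffs, dtype=np.float64), None
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("standardization needs >= 2 pair rows")
    if not np.isfinite(values).all():
        bad_cols = np.flatnonzero(~np.isfinite(values).all(axis=0))
        label = [eq_ids[k] for k in bad_cols] if eq_ids else bad_cols.tolist()
        raise ValueError(f"non-finite values in column(s) {label}")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        label = [eq_ids[k] for k in zero] if eq_ids else zero.tolist()
        raise ValueError(f"zero-variance column(s) for eq_id(s) {label}")
    return (values - mean) / sd


@dataclass
class EquationDistanceMatrix:
    """Symmetric matrix of Euclidean distances between standardized columns."""

    eq_ids: list[int]
    d_kl: np.ndarray

    def to_csv(self, path, delimiter: str = ",") -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
            writer.writerow(["eq_id", *self.eq_ids])
            for eq_id, row in zip(self.eq_ids, self.d_kl):
                writer.writerow([eq_id, *(f"{v:.12g}" for v in row)])


def equation_distances(z: np.ndarray,
                       eq_ids: list[int] | None = None) -> EquationDistanceMatrix:
    """Pairwise Euclidean distances between standardized coefficient columns."""
    z = np.asarray(z, dtype=np.float64)
    if eq_ids is None:
        eq_ids = list(range(1, z.shape[1] + 1))
    return EquationDistanceMatrix(list(eq_ids),
                                  squareform(pdist(z.T, metric="euclidean")))


@dataclass
class Dendrogram:
    """Merge sequence of an agglomerative clustering.

    ``merges[t] = (left, right, height, size)`` with cluster indexing as in
    a linkage matrix: leaves are 0..n-1 (positionally matching ``eq_ids``),
    and merge t creates cluster n+t.  ``height`` is the Euclidean distance
    between the merged clusters' centroids.
    """

    eq_ids: list[int]
    merges: list[tuple[int, int, float, int]]

    @property
    def n_leaves(self) -> int:
        return len(self.eq_ids)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def inversions(self) -> list[int]:
        """Merge steps whose height is below an earlier constituent merge."""
        n = self.n_leaves
        out = []
        for t, (left, right, height, _) in enumerate(self.merges):
            for child in (left, right):
                if child >= n and self.merges[child - n][2] > height + 1e-15:
                    out.append(t)
                    break
        return out

    def to_linkage(self) -> np.ndarray:
        """A scipy-style (n-1, 4) linkage array."""
        return np.array([[l, r, h, s] for l, r, h, s in self.merges],
                        dtype=np.float64)

    def to_newick(self, labels: list[str] | None = None) -> str:
        """Newick string; branch length = parent height − child height.

        Inverted merges yield negative branch lengths, kept as-is.
        """
        if labels is None:
            labels = [f"Eq{eq_id}" for eq_id in self.eq_ids]
        n = self.n_leaves

        def height_of(node: int) -> float:
            return 0.0 if node < n else self.merges[node - n][2]

        def render(node: int, parent_height: float) -> str:
            length = parent_height - height_of(node)
            if node < n:
                return f"{labels[node]}:{length:.10g}"
            left, right, height, _ = self.merges[node - n]
            return (f"({render(left, height)},{render(right, height)})"
                    f":{length:.10g}")

        root = n + len(self.merges) - 1
        left, right, height, _ = self.merges[-1]
        return (f"({render(left, height)},{render(right, height)});")


def centroid_cluster(z: np.ndarray,
                     eq_ids: list[int] | None = None) -> Dendrogram:
    """Greedy centroid-linkage agglomeration of standardized columns.

    At every step the two active clusters with minimum distance between
    their centroids (arithmetic means of member columns) are merged.  Ties
    are broken by the lexicographically smallest pair of smallest member
    eq_ids, making the merge sequence deterministic.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.ndim != 2 or z.shape[1] < 2:
        raise ValueError("need >= 2 equations to cluster")
    n = z.shape[1]
    if eq_ids is None:
        eq_ids = list(range(1, n + 1))
    if len(eq_ids) != n:
        raise ValueError("eq_ids length must match the number of columns")

    centroids = {k: z[:, k].copy() for k in range(n)}
    sizes = {k: 1 for k in range(n)}
    min_member = {k: eq_ids[k] for k in range(n)}  # tie-break key
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        active = sorted(centroids)
        for i_pos, i in enumerate(active):
            for j in active[i_pos + 1:]:
                dist = float(np.linalg.norm(centroids[i] - centroids[j]))
                pair_key = tuple(sorted((min_member[i], min_member[j])))
                cand = (dist, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        dist, _, i, j = best
        size = sizes[i] + sizes[j]
        merges.append((i, j, dist, size))
        centroids[next_id] = (sizes[i] * centroids[i]
                              + sizes[j] * centroids[j]) / size
        sizes[next_id] = size
        min_member[next_id] = min(min_member[i], min_member[j])
        for k in (i, j):
            del centroids[k], sizes[k], min_member[k]
        next_id += 1
    return Dendrogram(list(eq_ids), merges)
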