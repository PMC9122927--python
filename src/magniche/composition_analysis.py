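"""Gene-repertoire dissimilarity: Bray-Curtis, hierarchical clustering, NMDS.

Genome × family count profiles (CAZymes, sulfatases, peptidases, TBDTs) are
converted to a Bray-Curtis dissimilarity matrix, clustered agglomeratively
(average linkage by default) and embedded by non-metric multidimensional
scaling with Kruskal stress-1 as the quality measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.manifold import MDS

__all__ = ["bray_curtis", "hierarchical_cluster", "Dendrogram", "nmds",
           "Ordination"]


def bray_curtis(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between profile rows.

    BC(x, y) = 1 − 2 Σ min(x_i, y_i) / (Σ x_i + Σ y_i). Counts are used raw
    (no relative-abundance standardisation). A pair of all-zero profiles has
    an undefined quotient and is reported as 0 with a warning.
    """
    x = profiles.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts in profile matrix")
    totals = x.sum(axis=1)
    n = x.shape[0]
    d = np.zeros((n, n))
    empty_pair = False
    for i in range(n):
        mins = np.minimum(x[i], x[i + 1:]).sum(axis=1)
        denom = totals[i] + totals[i + 1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = 1.0 - 2.0 * mins / denom
        zero = denom == 0
        if zero.any():
            empty_pair = True
            vals[zero] = 0.0
        d[i, i + 1:] = vals
        d[i + 1:, i] = vals
    if empty_pair:
        warnings.warn("all-zero profile pair(s); dissimilarity defined as 0",
                      stacklevel=2)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


@dataclass
class Dendrogram:
    """Agglomerative clustering result: item ids (lexicographic) and the
    scipy linkage matrix."""

    ids: list
    linkage: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> dict:
        """item id -> flat cluster label for a cut into n_clusters groups."""
        labels = hierarchy.fcluster(self.linkage, t=n_clusters,
                                    criterion="maxclust")
        return dict(zip(self.ids, (int(l) for l in labels)))

    def to_newick(self) -> str:
        """Export the dendrogram as a rooted newick string with branch
        lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def hierarchical_cluster(matrix: pd.DataFrame,
                         linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a dissimilarity matrix.

    Items are sorted lexicographically before linkage so that equal-distance
    ties resolve deterministically.
    """
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    ids = sorted(str(i) for i in matrix.index)
    m = matrix.loc[ids, ids].to_numpy(dtype=float)
    z = hierarchy.linkage(squareform(m, checks=False), method=linkage)
    return Dendrogram(ids=ids, linkage=z)


@dataclass(frozen=True)
class Ordination:
    ids: tuple
    coordinates: np.ndarray  # n × k
    stress: float  # Kruskal stress-1
    seed: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.ids), columns=cols)


def nmds(matrix: pd.DataFrame, k: int = 2, seed: int = 0,
         max_iter: int = 300, tol: float = 1e-6, restarts: int = 4,
         ) -> Ordination:
    """Non-metric MDS of a dissimilarity matrix into k dimensions.

    Minimises Kruskal stress-1 by SMACOF iterations with monotone (isotonic)
    regression on the disparities; the best of ``restarts`` seeded starts is
    returned, making results reproducible given (seed, restarts).
    """
    n = matrix.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of items {n}")
    ids = tuple(str(i) for i in matrix.index)
    d = matrix.to_numpy(dtype=float)
    model = MDS(n_components=k, metric=False, dissimilarity="precomputed",
                n_init=restarts, max_iter=max_iter, eps=tol,
                random_state=seed, normalized_stress=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn chat about n_init defaults
        coords = model.fit_transform(d)
    return Ordination(ids=ids, coordinates=coords, stress=float(model.stress_),
                      seed=seed, converged=model.n_iter_ < max_iter)
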