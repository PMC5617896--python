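"""Complete-linkage hierarchical clustering with deterministic tie-breaking.

Matches the heatmap methodology of the expression analysis: Euclidean
distances between gene rows of the averaged-log expression matrix,
agglomerated with complete linkage.  The agglomeration is implemented
directly (rather than delegated) so that ties are broken reproducibly:
among all minimum-distance cluster pairs, the pair whose clusters contain
the smallest original row indices (lexicographic on (min-index, max-index))
is merged first.  Rows are clustered as provided — no scaling or centering.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


@dataclass
class Dendrogram:
    """Merge tree in SciPy linkage-matrix form.

    ``merges`` is the (n-1, 4) linkage matrix: each row holds the two merged
    node ids (leaves are 0..n-1, internal nodes n, n+1, ...), the merge
    height (complete-linkage Euclidean distance) and the new cluster size.
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Flat assignment into k clusters (cluster ids 1..k)."""
        flat = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def cophenetic_matrix(self) -> np.ndarray:
        return squareform(hierarchy.cophenet(self.merges))

    def merge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["node_a", "node_b", "height", "size"]
        )


def hclust_complete(
    matrix: pd.DataFrame | np.ndarray, k: int | None = None
) -> Dendrogram | tuple[Dendrogram, pd.Series]:
    """Complete-linkage agglomeration on Euclidean row distances.

    Returns the dendrogram, or ``(dendrogram, assignments)`` when ``k`` is
    given.  Raises on NaNs or fewer than two rows.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(x) for x in matrix.index]
        X = matrix.values.astype(float)
    else:
        X = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(X.shape[0])]
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two rows to cluster")
    if np.isnan(X).any():
        raise ValueError("matrix contains NaN")

    D = squareform(pdist(X, metric="euclidean"))
    np.fill_diagonal(D, np.inf)
    # active cluster slots, always ordered by their smallest original index
    node_id = list(range(n))  # linkage node id per slot
    sizes = [1] * n
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        # row-major argmin over the symmetric matrix picks, among ties, the
        # smallest slot i then smallest slot j: the documented tie-break,
        # because slots stay sorted by smallest original member index
        flat = int(np.argmin(D))
        i, j = divmod(flat, D.shape[0])
        if i > j:
            i, j = j, i
        h = D[i, j]
        a, b = node_id[i], node_id[j]
        merges[step] = (min(a, b), max(a, b), h, sizes[i] + sizes[j])
        # complete linkage: new cluster distance = max of the two rows
        new_row = np.maximum(D[i], D[j])
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = np.inf
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        node_id[i] = n + step
        sizes[i] = sizes[i] + sizes[j]
        del node_id[j], sizes[j]
    dendro = Dendrogram(merges, labels)
    if k is None:
        return dendro
    return dendro, dendro.cut(k)


def write_dendrogram_tsv(dendro: Dendrogram, path) -> None:
    dendro.merge_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
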