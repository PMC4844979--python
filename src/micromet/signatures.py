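"""Phenotypic subpopulation signatures by hierarchical clustering.

Group parameter sets are log10-transformed and normalized per parameter to
[-1, 1], clustered with Euclidean distance and average (UPGMA) linkage, and
the leaves reordered by optimal leaf ordering — columns clustered first,
then rows. Subpopulations are maximal dendrogram subtrees in which, for
every parameter, at least a fixed fraction (default 75%) of members share
the sign of the normalized value (red vs cyan in the conventional diverging
heat map); a value of exactly 0 counts toward neither side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SignatureCluster",
    "HClusterResult",
    "log_normalize",
    "hcluster",
    "optimal_leaf_order",
    "extract_subpopulations",
    "mean_signature",
    "signature_table",
]


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])


def log_normalize(matrix) -> pd.DataFrame:
    """Per column: log10-transform, then map the column range affinely onto
    [-1, 1] (min -> -1, max -> +1). Constant columns map to 0.

    All entries must be strictly positive.
    """
    frame = _as_frame(matrix)
    values = frame.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("log_normalize requires strictly positive finite entries")
    logs = np.log10(values)
    lo = logs.min(axis=0)
    hi = logs.max(axis=0)
    span = hi - lo
    out = np.zeros_like(logs)
    nondeg = span > 0
    out[:, nondeg] = 2.0 * (logs[:, nondeg] - lo[nondeg]) / span[nondeg] - 1.0
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


@dataclass
class HClusterResult:
    """Row/column dendrograms with optimally ordered leaves."""

    row_linkage: np.ndarray
    row_order: np.ndarray
    col_linkage: np.ndarray | None
    col_order: np.ndarray
    index: pd.Index
    columns: pd.Index

    def ordered(self, frame: pd.DataFrame) -> pd.DataFrame:
        return frame.iloc[self.row_order, :].iloc[:, self.col_order]


def _minplus(A: np.ndarray, B: np.ndarray, chunk: int = 64):
    """Min-plus matrix product with argmin: C[i,j] = min_k A[i,k]+B[k,j]."""
    nI, nJ = A.shape[0], B.shape[1]
    C = np.empty((nI, nJ))
    arg = np.empty((nI, nJ), dtype=np.intp)
    for s in range(0, nI, chunk):
        block = A[s:s + chunk, :, None] + B[None, :, :]
        a = block.argmin(axis=1)
        arg[s:s + chunk] = a
        C[s:s + chunk] = np.take_along_axis(block, a[:, None, :], axis=1)[:, 0, :]
    return C, arg


def optimal_leaf_order(linkage: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Exact optimal leaf ordering: among all 2^(n-1) leaf orders consistent
    with the dendrogram, return one minimizing the total distance between
    adjacent leaves (exact dynamic program over subtree endpoint pairs)."""
    n = linkage.shape[0] + 1
    if n == 1:
        return np.array([0])
    dist = np.asarray(dist, dtype=float)
    # per node: leaves (A-block then B-block), size of A, cost matrix over
    # (start, end) leaf positions, and argmin tables for traceback
    leaves: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    M: dict[int, np.ndarray] = {i: np.zeros((1, 1)) for i in range(n)}
    nA: dict[int, int] = {}
    K1: dict[int, np.ndarray] = {}
    L2: dict[int, np.ndarray] = {}

    for row in range(n - 1):
        a, b = int(linkage[row, 0]), int(linkage[row, 1])
        node = n + row
        la, lb = leaves[a], leaves[b]
        D = dist[np.ix_(la, lb)]
        R1, K1[node] = _minplus(M[a], D)
        cross, L2[node] = _minplus(R1, M[b])
        size = len(la) + len(lb)
        full = np.full((size, size), np.inf)
        full[:len(la), len(la):] = cross
        full[len(la):, :len(la)] = cross.T
        leaves[node] = np.concatenate([la, lb])
        nA[node] = len(la)
        M[node] = full
        del M[a], M[b]  # children cost matrices no longer needed

    root = 2 * n - 2
    cross = M[root][:nA[root], nA[root]:]
    i0, j0 = np.unravel_index(np.argmin(cross), cross.shape)

    # iterative traceback (dendrograms can be deep); (node, start, end) in
    # node-local leaf positions, start >= split meaning reversed orientation
    order: list[int] = []
    stack: list[tuple[int, int, int]] = [(root, int(i0), int(j0) + nA[root])]
    while stack:
        node, s, e = stack.pop()
        ids = leaves[node]
        if len(ids) == 1:
            order.append(int(ids[0]))
            continue
        split = nA[node]
        a, b = int(linkage[node - n, 0]), int(linkage[node - n, 1])
        if s < split:  # forward: A-block (i -> k) then B-block (l -> j)
            i, j = s, e - split
            l = int(L2[node][i, j])
            k = int(K1[node][i, l])
            stack.append((b, l, j))
            stack.append((a, i, k))
        else:  # reversed: B-block (j -> l) then A-block (k -> i)
            i, j = e, s - split
            l = int(L2[node][i, j])
            k = int(K1[node][i, l])
            stack.append((a, k, i))
            stack.append((b, j, l))
    return np.array(order)


def _olo_linkage(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    link = hierarchy.linkage(data, method="average", metric="euclidean")
    dist = squareform(pdist(data))
    return link, optimal_leaf_order(link, dist)


def hcluster(matrix) -> HClusterResult:
    """Agglomerative clustering (Euclidean metric, average linkage) with
    optimal leaf ordering, clustering first along the columns and then the
    rows. Requires at least 2 rows."""
    frame = _as_frame(matrix)
    data = frame.to_numpy(dtype=float)
    if data.shape[0] < 2:
        raise ValueError("hcluster requires at least 2 rows")
    if data.shape[1] >= 2:
        col_linkage, col_order = _olo_linkage(data.T)
    else:
        col_linkage, col_order = None, np.arange(data.shape[1])
    row_linkage, row_order = _olo_linkage(data)
    return HClusterResult(row_linkage, row_order, col_linkage, col_order,
                          frame.index, frame.columns)


@dataclass
class SignatureCluster:
    """A subpopulation: dendrogram subtree whose members agree in sign.

    ``indices`` are positional row indices into the clustered matrix;
    ``mean`` is the per-parameter mean of normalized values; ``purity`` the
    per-parameter fraction of members sharing the majority sign.
    """

    indices: np.ndarray
    mean: pd.Series
    purity: pd.Series

    def __len__(self) -> int:
        return len(self.indices)


def _sign_purity(block: np.ndarray) -> np.ndarray:
    n = block.shape[0]
    pos = (block > 0).sum(axis=0)
    neg = (block < 0).sum(axis=0)
    return np.maximum(pos, neg) / n


def mean_signature(rows) -> pd.Series:
    """Arithmetic mean per parameter of a (non-empty) block of normalized
    rows."""
    frame = _as_frame(rows)
    if len(frame) == 0:
        raise ValueError("mean_signature of an empty cluster")
    return frame.mean(axis=0)


def extract_subpopulations(
    normalized,
    clustering: HClusterResult | np.ndarray,
    purity: float = 0.75,
    min_fraction: float = 0.05,
) -> list[SignatureCluster]:
    """Maximal dendrogram subtrees of size >= ``min_fraction * n`` whose
    per-parameter sign purity reaches the ``purity`` threshold.

    The tree is walked from the root; a qualifying subtree is reported and
    not descended further, so no reported subtree contains another. Values
    of exactly 0 count toward neither sign.
    """
    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must lie in (0.5, 1]")
    frame = _as_frame(normalized)
    data = frame.to_numpy(dtype=float)
    linkage = clustering.row_linkage if isinstance(clustering, HClusterResult) else clustering
    n = data.shape[0]
    if linkage.shape[0] != n - 1:
        raise ValueError("dendrogram does not match the matrix")
    min_size = min_fraction * n

    root = hierarchy.to_tree(linkage)
    found: list[SignatureCluster] = []

    def qualify(node) -> SignatureCluster | None:
        members = np.array(node.pre_order(lambda leaf: leaf.id))
        if len(members) < min_size:
            return None
        block = data[members]
        pur = _sign_purity(block)
        if np.all(pur >= purity):
            return SignatureCluster(
                indices=np.sort(members),
                mean=pd.Series(block.mean(axis=0), index=frame.columns),
                purity=pd.Series(pur, index=frame.columns),
            )
        return None

    def walk(node):
        cluster = qualify(node)
        if cluster is not None:
            found.append(cluster)
            return
        if not node.is_leaf():
            walk(node.get_left())
            walk(node.get_right())

    walk(root)
    return found


def signature_table(clusters: list[SignatureCluster]) -> pd.DataFrame:
    """Mean signatures of the extracted subpopulations, one row per cluster
    (labelled a, b, c, ... in extraction order)."""
    if not clusters:
        return pd.DataFrame()
    labels = [chr(ord("a") + i) for i in range(len(clusters))]
    return pd.DataFrame([c.mean for c in clusters], index=labels)
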