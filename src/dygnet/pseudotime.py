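"""Developmental pseudotime: embed, cluster, span, root, and order.

Cells are embedded in a low-dimensional space (PCA by default; t-SNE is
the documented option), clustered by partition-around-medoids (PAM), and
a minimum spanning tree is fitted to the cluster medoids.  One end of
the tree is identified as the stem-cell population by marker-gene
expression; hop distance from that root along a chosen root->leaf path
becomes the integer time bin t_hat in {1..T}.  Cells in clusters off the
chosen path belong to other branches of the lineage and are excluded
from that trajectory's assignment (reported, never silent).

PAM is implemented directly (build + swap on Euclidean distances) so the
algorithm is deterministic and the no-improving-swap optimality check is
testable; the MST uses Kruskal with lexicographic tie-breaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .io import ExpressionMatrix, GeneSet


@dataclass
class Embedding:
    coords: np.ndarray          # cells x d, rows aligned with expression cells
    method: str
    seed: int


@dataclass
class Clustering:
    labels: np.ndarray          # per-cell cluster index in {0..k-1}
    medoid_cells: np.ndarray    # one cell index per cluster

    @property
    def k(self) -> int:
        return len(self.medoid_cells)

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


@dataclass
class TrajectoryTree:
    """Undirected tree over cluster indices with Euclidean edge lengths."""

    n_nodes: int
    edges: list[tuple[int, int, float]]
    root: int | None = None

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError(
                f"tree on {self.n_nodes} nodes needs {self.n_nodes - 1} edges, "
                f"got {len(self.edges)}"
            )
        if not self._connected():
            raise ValueError("tree edges do not form a connected graph")

    def _connected(self) -> bool:
        if self.n_nodes == 1:
            return True
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_nodes

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for a, b, _ in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def leaves(self) -> list[int]:
        adj = self.adjacency()
        return [n for n, nbs in adj.items() if len(nbs) == 1]

    def hop_distances(self, source: int) -> dict[int, int]:
        adj = self.adjacency()
        dist = {source: 0}
        frontier = [source]
        while frontier:
            nxt = []
            for n in frontier:
                for nb in adj[n]:
                    if nb not in dist:
                        dist[nb] = dist[n] + 1
                        nxt.append(nb)
            frontier = nxt
        return dist

    def path(self, a: int, b: int) -> list[int]:
        """Unique path between two nodes."""
        adj = self.adjacency()
        prev = {a: None}
        stack = [a]
        while stack:
            n = stack.pop()
            if n == b:
                break
            for nb in adj[n]:
                if nb not in prev:
                    prev[nb] = n
                    stack.append(nb)
        out = [b]
        while prev[out[-1]] is not None:
            out.append(prev[out[-1]])
        return out[::-1]


@dataclass
class CellTimeAssignment:
    """Integer time bins along one root->leaf trajectory.

    t_hat is -1 for cells in clusters off the trajectory path; T equals
    the number of clusters on the path (1 + max hop distance).
    """

    cell_ids: list[str]
    t_hat: np.ndarray
    T: int
    trajectory: list[int]
    excluded_cells: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------


def reduce_dimensions(
    expr: ExpressionMatrix, d: int = 3, method: str = "pca", seed: int = 0
) -> Embedding:
    """Embed cells into d dimensions; deterministic given (method, seed).

    The reducer is a pluggable contract: PCA (exact, deterministic) is
    the default used throughout testing; t-SNE, the usual choice for
    visualising single-cell manifolds, is delegated to scikit-learn.
    """
    if expr.state != "standardized":
        raise ValueError("reduce_dimensions requires standardized expression")
    if d < 2:
        raise ValueError("d must be >= 2")
    if d >= expr.n_genes:
        raise ValueError(f"d={d} must be smaller than the number of genes ({expr.n_genes})")
    if method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=d, svd_solver="full", random_state=seed).fit_transform(
            expr.values
        )
    elif method == "tsne":
        from sklearn.manifold import TSNE

        tsne_method = "barnes_hut" if d < 4 else "exact"
        coords = TSNE(
            n_components=d, random_state=seed, init="pca", method=tsne_method
        ).fit_transform(expr.values)
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    return Embedding(coords=np.asarray(coords, float), method=method, seed=seed)


def cluster_pam(emb: Embedding, k: int, seed: int = 0) -> Clustering:
    """Partition around medoids on Euclidean distances (build + swap).

    BUILD greedily picks medoids minimizing total dissimilarity; SWAP
    repeatedly applies the single best cost-reducing (medoid, non-medoid)
    exchange until none exists.  Ties break toward the lowest point
    index, so the result is deterministic; ``seed`` is accepted for
    interface uniformity but unused.
    """
    X = emb.coords
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells ({n})")
    dist = squareform(pdist(X))
    if k > len(np.unique(X, axis=0)):
        raise ValueError("k exceeds the number of distinct points")

    # BUILD
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        cur = dist[:, medoids].min(axis=1)
        gain = np.maximum(cur[None, :] - dist, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))

    # SWAP: best-improvement until convergence
    medoids = sorted(medoids)
    cost = dist[:, medoids].min(axis=1).sum()
    while True:
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            base = dist[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in range(n):
                if h in medoids:
                    continue
                new_cost = np.minimum(base, dist[:, h]).sum()
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)
        cost = dist[:, medoids].min(axis=1).sum()

    med = np.array(medoids, dtype=int)
    labels = np.argmin(dist[:, med], axis=1)
    labels[med] = np.arange(k)  # a medoid always belongs to its own cluster
    return Clustering(labels=labels, medoid_cells=med)


def build_mst(clust: Clustering, emb: Embedding) -> TrajectoryTree:
    """Minimum spanning tree over cluster medoids (Kruskal, Euclidean).

    Ties between equal-length edges break lexicographically on the edge
    index (i, j), making the tree deterministic.
    """
    k = clust.k
    if k < 2:
        raise ValueError("need at least 2 clusters")
    coords = emb.coords[clust.medoid_cells]
    cand = sorted(
        (float(np.linalg.norm(coords[i] - coords[j])), i, j)
        for i in range(k)
        for j in range(i + 1, k)
    )
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int, float]] = []
    for w, i, j in cand:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j, w))
            if len(edges) == k - 1:
                break
    return TrajectoryTree(n_nodes=k, edges=edges)


def choose_root(
    clust: Clustering, expr: ExpressionMatrix, stem_markers: GeneSet
) -> int:
    """Cluster with highest mean marker expression (stem-cell end).

    The mean pools over member cells and all markers present in the
    expression matrix; missing markers warn, an empty overlap errors.
    Ties break toward the lowest cluster index.
    """
    present = [g for g in stem_markers if g in expr.gene_ids]
    missing = [g for g in stem_markers if g not in expr.gene_ids]
    if missing:
        warnings.warn(f"markers not in expression matrix: {missing}")
    if not present:
        raise ValueError("no stem marker overlaps the expression genes")
    cols = [expr.gene_index(g) for g in present]
    means = np.array(
        [expr.values[np.ix_(clust.members(c), cols)].mean() for c in range(clust.k)]
    )
    return int(np.argmax(means))  # argmax takes the first (lowest) index on ties


def assign_pseudotime(
    tree: TrajectoryTree,
    root: int,
    clust: Clustering,
    cell_ids: list[str],
    leaf: int | str = "auto",
) -> CellTimeAssignment:
    """Time-stamp cells by hop distance from the root along one path.

    ``leaf='auto'`` picks the node farthest from the root by hop count
    (lowest index on ties).  Clusters off the root->leaf path belong to
    other branches; their cells get t_hat = -1 and are reported in
    ``excluded_cells``.
    """
    hops = tree.hop_distances(root)
    if leaf == "auto":
        far = max(hops.values())
        leaf = min(n for n, h in hops.items() if h == far)
    leaf = int(leaf)
    if leaf == root:
        raise ValueError("leaf must differ from root")
    if leaf not in tree.leaves():
        raise ValueError(f"node {leaf} is not a leaf of the tree")
    path = tree.path(root, leaf)
    on_path = {c: h + 1 for h, c in enumerate(path)}
    t_hat = np.array([on_path.get(int(c), -1) for c in clust.labels], dtype=int)
    excluded = [cid for cid, t in zip(cell_ids, t_hat) if t < 0]
    if excluded:
        warnings.warn(
            f"{len(excluded)} cell(s) in off-path clusters excluded from trajectory"
        )
    return CellTimeAssignment(
        cell_ids=list(cell_ids),
        t_hat=t_hat,
        T=len(path),
        trajectory=path,
        excluded_cells=excluded,
    )


def suggest_k(emb: Embedding, k_range: range = range(2, 11)) -> int:
    """Silhouette-based suggestion for the number of clusters."""
    from sklearn.metrics import silhouette_score

    best_k, best_s = None, -np.inf
    for k in k_range:
        if k >= emb.coords.shape[0]:
            break
        labels = cluster_pam(emb, k).labels
        s = silhouette_score(emb.coords, labels)
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no feasible k in range")
    return best_k
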