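"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths under test:

* ``gen_lasso_dual_oracle`` solves min ||y - X b||^2 + lam ||D b||_1 via
  the Lagrange dual, which for full-column-rank X is a box-constrained
  least-squares problem handled by scipy's BVLS solver.
* ``weighted_lasso_cd`` is plain cyclic coordinate descent for the T=1
  weighted-lasso special case.
* ``mst_weight_bruteforce`` enumerates every spanning tree via Pruefer
  sequences (k <= 7).
* ``pam_cost`` / ``no_improving_swap`` verify PAM local optimality by
  exhaustive swap search.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse


def gen_lasso_dual_oracle(X: np.ndarray, y: np.ndarray, D, lam: float):
    """High-precision generalized-lasso solution via the dual BVLS problem.

    For min_b ||y - Xb||^2 + lam ||Db||_1 with X of full column rank:
    writing the problem as 2 * (0.5||y-Xb||^2 + (lam/2)||Db||_1), the dual
    of the half-scaled problem is min_u (X^T y - D^T u)^T (X^T X)^{-1}
    (X^T y - D^T u) subject to |u_i| <= lam/2, and the primal solution is
    b = (X^T X)^{-1} (X^T y - D^T u).
    """
    if scipy.sparse.issparse(D):
        D = D.toarray()
    D = np.asarray(D, float)
    XtX = X.T @ X
    Xty = X.T @ y
    # (X^T X)^{-1} = L L^T via Cholesky of the inverse
    L = scipy.linalg.cholesky(np.linalg.inv(XtX), lower=True)
    A = L.T @ D.T
    c = L.T @ Xty
    bound = lam / 2.0
    res = scipy.optimize.lsq_linear(
        A, c, bounds=(-bound, bound), method="bvls", tol=1e-15, max_iter=2000
    )
    u = res.x
    b = np.linalg.solve(XtX, Xty - D.T @ u)
    obj = float(np.sum((y - X @ b) ** 2) + lam * np.abs(D @ b).sum())
    return b, obj


def weighted_lasso_cd(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: float,
    tol: float = 1e-14,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Cyclic coordinate descent for min ||y - Xb||^2 + lam sum_j w_j |b_j|."""
    n, p = X.shape
    b = np.zeros(p)
    col_sq = (X ** 2).sum(axis=0)
    r = y.copy()
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            old = b[j]
            rho = X[:, j] @ r + col_sq[j] * old   # X_j^T (y - X b_{-j})
            z = 2.0 * rho
            thr = lam * w[j]
            bj = np.sign(z) * max(abs(z) - thr, 0.0) / (2.0 * col_sq[j])
            if bj != old:
                r += X[:, j] * (old - bj)
                b[j] = bj
                delta = max(delta, abs(bj - old))
        if delta < tol:
            break
    return b


def mst_weight_bruteforce(dist: np.ndarray) -> float:
    """Minimum spanning-tree weight by Pruefer-sequence enumeration (k <= 7)."""
    k = dist.shape[0]
    if k == 2:
        return float(dist[0, 1])
    best = np.inf
    for seq in itertools.product(range(k), repeat=k - 2):
        edges = _pruefer_to_edges(list(seq), k)
        w = sum(dist[i, j] for i, j in edges)
        best = min(best, w)
    return float(best)


def _pruefer_to_edges(seq: list[int], k: int) -> list[tuple[int, int]]:
    degree = [1] * k
    for s in seq:
        degree[s] += 1
    edges = []
    for s in seq:
        leaf = min(i for i in range(k) if degree[i] == 1)
        edges.append((leaf, s))
        degree[leaf] -= 1
        degree[s] -= 1
    u, v = [i for i in range(k) if degree[i] == 1]
    edges.append((u, v))
    return edges


def pam_cost(dist: np.ndarray, medoids: list[int]) -> float:
    return float(dist[:, medoids].min(axis=1).sum())


def no_improving_swap(dist: np.ndarray, medoids: list[int]) -> bool:
    """True if no single (medoid, non-medoid) exchange lowers the cost."""
    n = dist.shape[0]
    base = pam_cost(dist, medoids)
    for mi in range(len(medoids)):
        for h in range(n):
            if h in medoids:
                continue
            trial = list(medoids)
            trial[mi] = h
            if pam_cost(dist, trial) < base - 1e-10:
                return False
    return True
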