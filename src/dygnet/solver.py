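"""ADMM solver for the per-target penalized regression.

For one target gene the fit minimizes

    F(b) = sum_t sum_{cells c in bin t} (y_c - b_{t,:} x_c^T)^2
           + lambda * || D vec(b^T) ||_1

over the T x (p-1) coefficient matrix b, where D is the binding-weighted
structural penalty matrix.  The loss sums squared residuals over every
cell, each cell using the coefficient vector of its own time bin; with
one cell per bin this reduces to the single-residual-per-time form.
Residuals are unweighted across bins.  The intercept is identically zero
because both response and predictors are standardized.

The solver is ADMM on the splitting z = D vec(b^T): the quadratic
b-update solves (2 X^T X + rho D^T D) beta = 2 X^T y + rho D^T (z - u)
through a cached sparse LU factorization, the z-update is elementwise
soft thresholding at lambda/rho, and iteration stops on the standard
primal/dual residual criteria.  Zero initialization, fixed rho, no
randomness: runs are bit-reproducible and order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .io import BindingPriorTable, ExpressionMatrix, GeneSet
from .penalty import PenaltyConfig, PenaltyMatrix, build_penalty_matrix, build_weight_vector


@dataclass(frozen=True)
class SolverConfig:
    tol_abs: float = 1e-6
    tol_rel: float = 1e-4
    max_iter: int = 5000
    admm_rho: float = 1.0
    edge_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("tol_abs", "tol_rel", "max_iter", "admm_rho", "edge_threshold"):
            if getattr(self, name) <= 0 and name != "edge_threshold":
                raise ValueError(f"{name} must be positive")
        if self.edge_threshold < 0:
            raise ValueError("edge_threshold must be >= 0")


@dataclass
class DesignBundle:
    """Per-time-bin predictor blocks and responses for one target gene."""

    X_blocks: list[np.ndarray]          # one (n_t x (p-1)) block per bin
    y_blocks: list[np.ndarray]          # matching responses
    predictor_ids: list[str]
    target_id: str

    @property
    def T(self) -> int:
        return len(self.X_blocks)

    @property
    def p_minus_1(self) -> int:
        return len(self.predictor_ids)


@dataclass
class ConvergenceReport:
    iterations: int
    converged: bool
    primal_residual: float
    dual_residual: float
    objective: float


@dataclass
class CoefficientMatrix:
    """Fitted b (T x (p-1)) for one target; intercept held at 0."""

    b: np.ndarray
    intercept: float
    target_id: str
    predictor_ids: list[str]
    report: ConvergenceReport | None = None

    def copy_with(self, b: np.ndarray) -> "CoefficientMatrix":
        return CoefficientMatrix(
            b=b, intercept=self.intercept, target_id=self.target_id,
            predictor_ids=list(self.predictor_ids), report=self.report,
        )


def assemble_design(
    expr: ExpressionMatrix, times, target: str
) -> DesignBundle:
    """Group cells by time bin; predictors are all retained genes but the target.

    Cells without a time assignment (t_hat < 1, i.e. off the chosen
    trajectory) are excluded with a warning.  Every bin 1..T must be
    non-empty.
    """
    if expr.state != "standardized":
        raise ValueError("assemble_design requires standardized expression")
    ti = expr.gene_index(target)
    pred_idx = [j for j in range(expr.n_genes) if j != ti]
    predictor_ids = [expr.gene_ids[j] for j in pred_idx]

    cell_to_t = dict(zip(times.cell_ids, times.t_hat))
    t_hat = np.array([cell_to_t.get(c, -1) for c in expr.cell_ids], dtype=int)
    n_unassigned = int((t_hat < 1).sum())
    if n_unassigned:
        warnings.warn(
            f"{n_unassigned} cell(s) have no time assignment and are excluded"
        )
    T = times.T
    X_blocks, y_blocks = [], []
    for t in range(1, T + 1):
        rows = np.flatnonzero(t_hat == t)
        if rows.size == 0:
            raise ValueError(f"time bin {t} contains no cells")
        X_blocks.append(expr.values[np.ix_(rows, pred_idx)])
        y_blocks.append(expr.values[rows, ti])
    return DesignBundle(X_blocks, y_blocks, predictor_ids, target)


def _stack_normal_equations(design: DesignBundle):
    """Block-diagonal 2 X^T X (sparse) and stacked 2 X^T y."""
    p1, T = design.p_minus_1, design.T
    blocks = []
    Xty = np.empty(p1 * T)
    for t, (X, y) in enumerate(zip(design.X_blocks, design.y_blocks)):
        blocks.append(scipy.sparse.csc_matrix(2.0 * (X.T @ X)))
        Xty[t * p1:(t + 1) * p1] = 2.0 * (X.T @ y)
    XtX2 = scipy.sparse.block_diag(blocks, format="csc")
    return XtX2, Xty


def objective_value(design: DesignBundle, D: PenaltyMatrix, lam: float, b: np.ndarray) -> float:
    """F(b) recomputed from scratch (loss + lambda * ||D vec(b^T)||_1)."""
    beta = np.asarray(b, float).reshape(-1)
    loss = 0.0
    p1 = design.p_minus_1
    for t, (X, y) in enumerate(zip(design.X_blocks, design.y_blocks)):
        r = y - X @ beta[t * p1:(t + 1) * p1]
        loss += float(r @ r)
    return loss + lam * float(np.abs(D.D @ beta).sum())


def fit_target(
    design: DesignBundle,
    D: PenaltyMatrix,
    cfg: PenaltyConfig,
    scfg: SolverConfig = SolverConfig(),
) -> CoefficientMatrix:
    """Minimize the penalized loss for one target by ADMM."""
    p1, T = design.p_minus_1, design.T
    if D.p_minus_1 != p1 or D.T != T:
        raise ValueError(
            f"penalty matrix is for (p-1={D.p_minus_1}, T={D.T}) but design "
            f"has (p-1={p1}, T={T})"
        )
    n_coef = p1 * T
    lam, rho = cfg.lam, scfg.admm_rho
    Dm = D.D.tocsr()
    DT = Dm.T.tocsr()
    m = Dm.shape[0]

    XtX2, Xty2 = _stack_normal_equations(design)
    A = (XtX2 + rho * (DT @ Dm)).tocsc()
    solve = scipy.sparse.linalg.factorized(A)

    beta = np.zeros(n_coef)
    z = np.zeros(m)
    u = np.zeros(m)  # scaled dual
    thresh = lam / rho

    converged = False
    r_norm = s_norm = np.inf
    it = 0
    first_objective = None
    for it in range(1, scfg.max_iter + 1):
        beta = solve(Xty2 + rho * (DT @ (z - u)))
        Dbeta = Dm @ beta
        v = Dbeta + u
        z_new = np.sign(v) * np.maximum(np.abs(v) - thresh, 0.0)
        s_norm = rho * float(np.linalg.norm(DT @ (z_new - z)))
        z = z_new
        u = u + Dbeta - z
        r_norm = float(np.linalg.norm(Dbeta - z))
        if first_objective is None:
            first_objective = objective_value(design, D, lam, beta)
        eps_pri = (
            np.sqrt(m) * scfg.tol_abs
            + scfg.tol_rel * max(float(np.linalg.norm(Dbeta)), float(np.linalg.norm(z)))
        )
        eps_dual = (
            np.sqrt(n_coef) * scfg.tol_abs
            + scfg.tol_rel * rho * float(np.linalg.norm(DT @ u))
        )
        if r_norm <= eps_pri and s_norm <= eps_dual:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ADMM for target {design.target_id!r} did not converge in "
            f"{scfg.max_iter} iterations (r={r_norm:.2e}, s={s_norm:.2e})"
        )
    obj = objective_value(design, D, lam, beta)
    # ADMM need not decrease F monotonically, but from zero start the final
    # iterate must not be worse than the first.
    assert first_objective is None or obj <= first_objective * (1 + 1e-9) + 1e-9
    report = ConvergenceReport(
        iterations=it, converged=converged,
        primal_residual=r_norm, dual_residual=s_norm, objective=obj,
    )
    b = beta.reshape(T, p1)
    return CoefficientMatrix(
        b=b, intercept=0.0, target_id=design.target_id,
        predictor_ids=list(design.predictor_ids), report=report,
    )


def threshold_coefficients(coef: CoefficientMatrix, tau: float) -> CoefficientMatrix:
    """Zero out entries with |b_{t,j}| < tau; others unchanged."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    b = coef.b.copy()
    b[np.abs(b) < tau] = 0.0
    return coef.copy_with(b)


def lambda_max_upper_bound(design: DesignBundle, weights: np.ndarray) -> float:
    """A lambda at which b = 0 is provably optimal.

    At b = 0 the zero solution satisfies the optimality condition as soon
    as the within-time dual coordinates can absorb the gradient:
    lambda >= max_{t,j} |2 x_{t,j}^T y_t| / w_j.
    """
    w = np.asarray(weights, float)
    best = 0.0
    for X, y in zip(design.X_blocks, design.y_blocks):
        g = np.abs(2.0 * (X.T @ y)) / w
        best = max(best, float(g.max()))
    return best


def _fit_one(
    target: str,
    expr: ExpressionMatrix,
    times,
    priors: BindingPriorTable,
    cfg: PenaltyConfig,
    scfg: SolverConfig,
) -> CoefficientMatrix:
    design = assemble_design(expr, times, target)
    wv = build_weight_vector(target, design.predictor_ids, priors, cfg)
    D = build_penalty_matrix(wv, design.T)
    return fit_target(design, D, cfg, scfg)


def fit_panel(
    targets: GeneSet,
    expr: ExpressionMatrix,
    times,
    priors: BindingPriorTable,
    cfg: PenaltyConfig = PenaltyConfig(),
    scfg: SolverConfig = SolverConfig(),
    n_jobs: int = 1,
) -> dict[str, CoefficientMatrix]:
    """Independent per-target fits (local decomposability of the network).

    Results are identical for any execution order or parallelism degree;
    targets missing from the expression matrix are skipped with a warning.
    """
    present = [g for g in targets if g in expr.gene_ids]
    missing = [g for g in targets if g not in expr.gene_ids]
    if missing:
        warnings.warn(f"skipping {len(missing)} target(s) not in expression: {missing}")
    if not present:
        return {}
    if n_jobs == 1:
        fits = [_fit_one(t, expr, times, priors, cfg, scfg) for t in present]
    else:
        from joblib import Parallel, delayed

        fits = Parallel(n_jobs=n_jobs)(
            delayed(_fit_one)(t, expr, times, priors, cfg, scfg) for t in present
        )
    return {t: f for t, f in zip(present, fits)}
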