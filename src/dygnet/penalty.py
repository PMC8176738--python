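"""Generalized-lasso penalty matrix with binding-informed row weights.

The model penalizes, for one target gene, both the size of each
coefficient at each time bin (sparsity within time) and the change in
each coefficient between adjacent bins (sparsity across time).  Both are
encoded as rows of a sparse matrix D acting on vec(b^T): within-time rows
carry a single non-zero, across-time rows carry a (+w, -w) pair for the
same predictor at adjacent times.  All 2T-1 rows belonging to predictor j
share one magnitude w_j.

w_j comes from DNA-binding evidence: a posterior binding probability
p_ji for regulator j on target i's promoter lowers w_j from 1 (no
evidence) down to a floor of 1/eta (certain binding), interpolating
proportionally to log(p_ji) because the penalty lives on the
log-likelihood scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse

from .io import NO_EVIDENCE, BindingPriorTable


@dataclass(frozen=True)
class PenaltyConfig:
    """Sparsity hyperparameters.

    lam : overall sparsity level lambda (default 20, established for this
        model class in prior work).
    eta : maximum down-weighting factor; the penalty weight floor is
        1/eta (default 4).
    p_min : smallest binding probability treated as evidence (default
        0.5; CENTIPEDE-style posteriors are strongly bimodal, so the
        exact value matters little, but it is a first-class knob).
    """

    lam: float = 20.0
    eta: float = 4.0
    p_min: float = 0.5

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lambda must be positive, got {self.lam}")
        if not self.eta > 1:
            raise ValueError(f"eta must exceed 1, got {self.eta}")
        if not (0.0 < self.p_min < 1.0):
            raise ValueError(f"p_min must lie in (0,1), got {self.p_min}")


@dataclass
class WeightVector:
    """Per-predictor penalty magnitudes in [1/eta, 1] for one target."""

    w: np.ndarray
    predictor_ids: list[str]

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1 or len(self.w) != len(self.predictor_ids):
            raise ValueError("weight vector / predictor ID length mismatch")


@dataclass
class PenaltyMatrix:
    """Sparse D of shape (2T-1)(p-1) x (p-1)T plus its index bookkeeping.

    Column order is time-major: coefficient (t, j) for t in 1..T and
    predictor j in 1..p-1 sits at column (t-1)(p-1) + (j-1) (0-based:
    t*(p-1)+j).  The first T(p-1) rows are within-time rows, the
    remaining (T-1)(p-1) across-time rows.
    """

    D: scipy.sparse.csr_matrix
    T: int
    p_minus_1: int
    weights: np.ndarray

    @property
    def m(self) -> int:
        return self.D.shape[0]

    def coef_index(self, t: int, j: int) -> int:
        """Column of coefficient for time bin t (1-based) and predictor j (0-based)."""
        return (t - 1) * self.p_minus_1 + j


def binding_weight(p_ji, cfg: PenaltyConfig) -> float:
    """Penalty magnitude for one regulator/target pair.

    Returns 1/eta + (eta-1)/eta * log(p_ji)/log(p_min) when
    p_ji >= p_min; 1.0 when the probability is below p_min or absent
    (``NO_EVIDENCE``).  Natural logarithms.  Continuous at p_min and
    non-increasing in p_ji on [p_min, 1].
    """
    if p_ji is NO_EVIDENCE:
        return 1.0
    p = float(p_ji)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"binding probability {p} outside [0, 1]")
    if p < cfg.p_min:
        return 1.0
    if p == 1.0:
        return 1.0 / cfg.eta
    return 1.0 / cfg.eta + (cfg.eta - 1.0) / cfg.eta * math.log(p) / math.log(cfg.p_min)


def build_weight_vector(
    target: str,
    predictors: list[str],
    priors: BindingPriorTable,
    cfg: PenaltyConfig,
) -> WeightVector:
    """Per-predictor weights for one target gene, keyed (predictor, target)."""
    if target in predictors:
        raise ValueError(f"target {target!r} must not appear among predictors")
    w = np.array(
        [binding_weight(priors.get(j, target), cfg) for j in predictors],
        dtype=float,
    )
    return WeightVector(w=w, predictor_ids=list(predictors))


def build_penalty_matrix(w: WeightVector | np.ndarray, T: int) -> PenaltyMatrix:
    """Assemble the sparse structural matrix D for T time bins.

    Within-time rows (one per (t, j)) hold w_j at column (t-1)(p-1)+j.
    Across-time rows (one per (t, j), t >= 2) hold +w_j at time t and
    -w_j at time t-1 for the same predictor.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    weights = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    p1 = len(weights)
    if p1 == 0:
        raise ValueError("weight vector must be non-empty")
    n_cols = p1 * T
    m = (2 * T - 1) * p1

    rows, cols, data = [], [], []
    r = 0
    for t in range(T):  # within-time rows, grouped by time
        for j in range(p1):
            rows.append(r)
            cols.append(t * p1 + j)
            data.append(weights[j])
            r += 1
    for t in range(1, T):  # across-time rows: b_{t,j} - b_{t-1,j}
        for j in range(p1):
            rows.append(r)
            cols.append(t * p1 + j)
            data.append(weights[j])
            rows.append(r)
            cols.append((t - 1) * p1 + j)
            data.append(-weights[j])
            r += 1
    assert r == m
    D = scipy.sparse.csr_matrix(
        (data, (rows, cols)), shape=(m, n_cols), dtype=float
    )
    return PenaltyMatrix(D=D, T=T, p_minus_1=p1, weights=weights.copy())
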