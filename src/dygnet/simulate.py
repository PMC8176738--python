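"""Synthetic data with the statistical structure the model assumes.

The generator produces (a) expression from a known sparse time-varying
linear model with Gaussian noise, so edge recovery can be scored against
ground truth; (b) binding-prior tables concentrated on the true
regulators, emulating bimodal footprinting posteriors; and (c)
drifting-cluster trajectories for validating the pseudotime stage.
A single global seed fans out to per-component generators through
``numpy.random.SeedSequence.spawn``, so every artifact is reproducible
bit-for-bit from one integer.

Predictors are iid standard normal by default; an optional AR(1)
correlated-block mode stresses the regime where lasso selection becomes
unstable, motivating the downstream consistency aggregation.  Dropout
and count overdispersion of real scRNA-seq are deliberately not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BindingPriorTable, ExpressionMatrix
from .pseudotime import CellTimeAssignment

#: fixed location shift applied on the log scale before expm1, so that
#: clipping raw values at zero touches only the extreme lower tail and
#: standardization removes the shift exactly.
LOG_SHIFT = 6.0


@dataclass
class GroundTruth:
    """True coefficients and metadata of a simulated regulatory model."""

    b_star: np.ndarray                # T x (p-1)
    true_regulators: np.ndarray       # predictor indices with non-zero columns
    changepoints: dict[int, int]      # regulator index -> activation bin (1-based)
    noise_sd: float
    seed: int

    @property
    def T(self) -> int:
        return self.b_star.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.b_star.shape[1]


@dataclass
class SimulatedDataset:
    expr: ExpressionMatrix
    times: CellTimeAssignment
    priors: BindingPriorTable | None
    truth: GroundTruth


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def predictor_ids(n_predictors: int) -> list[str]:
    return [f"G{j + 1:04d}" for j in range(n_predictors)]


TARGET_ID = "TARGET"


def simulate_truth(
    n_predictors: int,
    T: int,
    k: int,
    effect_range: tuple[float, float] = (0.5, 1.0),
    seed: int = 0,
    noise_sd: float = 0.5,
) -> GroundTruth:
    """Draw a sparse piecewise-constant coefficient matrix.

    k regulators are chosen uniformly without replacement; each gets a
    magnitude ~ Uniform[lo, hi] with a random sign, active from a random
    changepoint t0 onward (zero before).  Non-regulators have all-zero
    columns.
    """
    lo, hi = effect_range
    if k > n_predictors:
        raise ValueError(f"k={k} exceeds the number of predictor genes ({n_predictors})")
    if k > 0 and not (0 < lo <= hi):
        raise ValueError("effect_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    b = np.zeros((T, n_predictors))
    regs = np.sort(rng.choice(n_predictors, size=k, replace=False))
    changepoints: dict[int, int] = {}
    for j in regs:
        mag = rng.uniform(lo, hi)
        sign = rng.choice([-1.0, 1.0])
        t0 = int(rng.integers(1, T + 1))
        b[t0 - 1 :, j] = sign * mag
        changepoints[int(j)] = t0
    return GroundTruth(
        b_star=b, true_regulators=regs, changepoints=changepoints,
        noise_sd=noise_sd, seed=seed,
    )


def simulate_expression(
    truth: GroundTruth,
    cells_per_bin: int = 100,
    seed: int = 0,
    ar_rho: float = 0.0,
    ar_block: int = 10,
) -> SimulatedDataset:
    """Generate raw-scale expression from the forward model y = b_t x + eps.

    Predictors are iid standard normal per cell (or AR(1) within blocks
    of ``ar_block`` genes when ``ar_rho`` > 0).  The log-scale values are
    shifted by a constant, inverse-log1p transformed, and clipped at
    zero so the full raw -> log1p -> standardize pipeline is exercised.
    """
    if cells_per_bin < 1:
        raise ValueError("cells_per_bin must be >= 1")
    rng_x, rng_e = _rngs(seed, 2)
    T, p1 = truth.T, truth.n_predictors
    n = T * cells_per_bin
    x = rng_x.standard_normal((n, p1))
    if ar_rho > 0.0:
        for start in range(0, p1, ar_block):
            block = x[:, start : start + ar_block]
            for c in range(1, block.shape[1]):
                block[:, c] = ar_rho * block[:, c - 1] + np.sqrt(
                    1 - ar_rho**2
                ) * block[:, c]
    t_hat = np.repeat(np.arange(1, T + 1), cells_per_bin)
    eps = rng_e.normal(0.0, truth.noise_sd, size=n)
    y = np.einsum("ij,ij->i", x, truth.b_star[t_hat - 1]) + eps

    log_values = np.column_stack([y, x]) + LOG_SHIFT
    raw = np.clip(np.expm1(log_values), 0.0, None)
    cell_ids = [f"C{i + 1:05d}" for i in range(n)]
    gene_ids = [TARGET_ID] + predictor_ids(p1)
    expr = ExpressionMatrix(raw, cell_ids, gene_ids, state="raw")
    times = CellTimeAssignment(
        cell_ids=cell_ids, t_hat=t_hat, T=T, trajectory=list(range(T))
    )
    return SimulatedDataset(expr=expr, times=times, priors=None, truth=truth)


def simulate_priors(
    truth: GroundTruth,
    fidelity: float = 1.0,
    background: float = 0.0,
    seed: int = 0,
    p_min: float = 0.5,
    target_id: str = TARGET_ID,
) -> BindingPriorTable:
    """Binding priors concentrated on the true regulators.

    Each true regulator receives p ~ Uniform[0.9, 1] with probability
    ``fidelity`` (otherwise no entry); each non-regulator receives a
    sub-threshold p ~ Uniform[0, p_min) with probability ``background``
    (noise entries that downstream weighting must ignore).
    """
    for name, v in (("fidelity", fidelity), ("background", background)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = predictor_ids(truth.n_predictors)
    table = BindingPriorTable()
    reg_set = set(int(j) for j in truth.true_regulators)
    for j, gid in enumerate(ids):
        if j in reg_set:
            if rng.uniform() < fidelity:
                table.add(gid, target_id, rng.uniform(0.9, 1.0))
        else:
            if rng.uniform() < background:
                table.add(gid, target_id, rng.uniform(0.0, p_min * (1 - 1e-12)))
    return table


def simulate_trajectory(
    k_clusters: int = 8,
    cells_per_cluster: int = 62,
    drift: float = 6.0,
    dim: int = 10,
    seed: int = 0,
    noise_sd: float = 0.5,
    branch: bool = False,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Drifting-cluster trajectory for pseudotime validation.

    Cluster means advance by ``drift`` per step along a fixed random
    direction in gene space; cells scatter isotropically (sd
    ``noise_sd``) around their cluster mean.  The defaults put the
    per-step drift at 12x the within-stage scatter: developmental stages
    are modelled as discrete, well-separated phenotype clusters, the
    regime the PAM-plus-MST procedure assumes.  Note that per-gene
    standardization downstream caps the usable signal-to-noise, so the
    ratio must be generous for stages to stay separable after z-scoring.  The first gene,
    ``MARKER_STEM``, decays linearly with true time so marker-based root
    selection has a handle.  With ``branch=True`` the second half of the
    clusters forks along an orthogonal direction.  Values are emitted on
    the log scale (state ``log1p``), ready for standardization.  Returns
    the matrix and the per-cell true stage (0-based cluster order).
    """
    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    rng_dir, rng_noise = _rngs(seed, 2)
    u = rng_dir.standard_normal(dim - 1)
    u /= np.linalg.norm(u)
    v = rng_dir.standard_normal(dim - 1)
    v -= (v @ u) * u
    v /= np.linalg.norm(v)

    means = np.zeros((k_clusters, dim))
    half = k_clusters // 2
    for c in range(k_clusters):
        if branch and c >= half:
            base = means[half - 1, 1:] if half > 0 else 0.0
            means[c, 1:] = base + drift * (c - half + 1) * v
        else:
            means[c, 1:] = drift * c * u
        means[c, 0] = drift * (k_clusters - 1 - c)  # stem marker decays

    n = k_clusters * cells_per_cluster
    stages = np.repeat(np.arange(k_clusters), cells_per_cluster)
    values = means[stages] + rng_noise.normal(0.0, noise_sd, size=(n, dim))
    cell_ids = [f"C{i + 1:05d}" for i in range(n)]
    gene_ids = ["MARKER_STEM"] + [f"G{j + 1:04d}" for j in range(dim - 1)]
    expr = ExpressionMatrix(values, cell_ids, gene_ids, state="log1p")
    return expr, stages
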