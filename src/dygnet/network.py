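"""Edge extraction, consistency aggregation, and the correlation baseline.

A non-zero thresholded coefficient b_{t,j} in a target's fit becomes a
time-stamped edge regulator_j -> target at bin t, carrying the signed
coefficient.  Because lasso-type fits can select different but equally
predictive gene subsets, single edges are unstable; aggregating how
often a regulator is selected across the per-target fits of a curated
gene-set (consistency counting) is the robustness device used downstream.
The static thresholded-correlation network is provided as the
conventional co-expression baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.stats

from .io import ExpressionMatrix, GeneSet
from .solver import CoefficientMatrix


class Edge(NamedTuple):
    regulator: str
    target: str
    time: int
    coefficient: float


@dataclass
class TimeVaryingNetwork:
    """Set of (regulator, target, time, signed coefficient) edges."""

    edges: list[Edge]

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.regulator == e.target:
                raise ValueError(f"self-edge on {e.regulator!r}")
            if e.coefficient == 0.0:
                raise ValueError("zero-coefficient edge")
            if e.time < 1:
                raise ValueError(f"time bin must be >= 1, got {e.time}")

    def __len__(self) -> int:
        return len(self.edges)

    def regulators_of(self, target: str, t: int) -> set[str]:
        return {e.regulator for e in self.edges if e.target == target and e.time == t}


@dataclass
class RegulatorCounts:
    """Per-regulator counts of regulated gene-set members at a fixed time.

    Sorted by descending count, ties alphabetical; zero-count regulators
    are omitted.  ``members`` maps each regulator to the sorted list of
    set members it regulates.
    """

    time: int
    gene_set: str
    counts: list[tuple[str, int]]
    members: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class CoregulationPartition:
    """Split of a gene-set by connection to two TFs at a fixed time."""

    tf_a: str
    tf_b: str
    time: int
    both: set[str]
    only_a: set[str]
    only_b: set[str]


def edges_from_fit(
    coef: CoefficientMatrix, target: str | None = None,
    predictors: list[str] | None = None,
) -> TimeVaryingNetwork:
    """One edge per non-zero entry of a (thresholded) coefficient matrix."""
    target = target if target is not None else coef.target_id
    predictors = predictors if predictors is not None else coef.predictor_ids
    T, p1 = coef.b.shape
    if len(predictors) != p1:
        raise ValueError("predictor ID list does not match coefficient columns")
    edges = [
        Edge(predictors[j], target, t + 1, float(coef.b[t, j]))
        for t in range(T)
        for j in range(p1)
        if coef.b[t, j] != 0.0
    ]
    return TimeVaryingNetwork(edges)


def aggregate_consistency(
    nets: dict[str, TimeVaryingNetwork], gene_set: GeneSet, t: int
) -> RegulatorCounts:
    """Count, per regulator, the gene-set members it regulates at bin t.

    Only fits for targets inside the gene-set contribute; regulators
    never selected are omitted.
    """
    hits: dict[str, set[str]] = {}
    for target, net in nets.items():
        if target not in gene_set:
            continue
        for e in net.edges:
            if e.target == target and e.time == t:
                hits.setdefault(e.regulator, set()).add(target)
    counts = sorted(
        ((reg, len(tg)) for reg, tg in hits.items()),
        key=lambda rc: (-rc[1], rc[0]),
    )
    return RegulatorCounts(
        time=t,
        gene_set=gene_set.name,
        counts=counts,
        members={reg: sorted(tg) for reg, tg in hits.items()},
    )


def coregulation_partition(
    nets: dict[str, TimeVaryingNetwork],
    tf_a: str,
    tf_b: str,
    gene_set: GeneSet,
    t: int,
) -> CoregulationPartition:
    """Partition gene-set targets by which of two TFs regulates them at t."""
    if tf_a == tf_b:
        raise ValueError("tf_a and tf_b must differ")
    a_targets, b_targets = set(), set()
    for target, net in nets.items():
        if target not in gene_set:
            continue
        regs = net.regulators_of(target, t)
        if tf_a in regs:
            a_targets.add(target)
        if tf_b in regs:
            b_targets.add(target)
    return CoregulationPartition(
        tf_a=tf_a,
        tf_b=tf_b,
        time=t,
        both=a_targets & b_targets,
        only_a=a_targets - b_targets,
        only_b=b_targets - a_targets,
    )


def correlation_baseline(
    expr: ExpressionMatrix,
    target: str,
    rho_threshold: float = 0.5,
    method: str = "pearson",
) -> list[tuple[str, float]]:
    """Static co-expression edges: genes with |rho(target, j)| >= threshold.

    ``expr`` should already be restricted to the cells of one time bin;
    the inferred edge set is static (no time dependence beyond that cell
    restriction).  Returns (gene, rho) pairs sorted by gene ID.
    """
    if expr.n_cells < 3:
        raise ValueError("need at least 3 cells to estimate correlations")
    if not (0.0 < rho_threshold <= 1.0):
        raise ValueError("rho_threshold must lie in (0, 1]")
    ti = expr.gene_index(target)
    y = expr.values[:, ti]
    if np.std(y) == 0.0:
        raise ValueError(f"target {target!r} has zero variance")
    out: list[tuple[str, float]] = []
    for j, g in enumerate(expr.gene_ids):
        if j == ti:
            continue
        x = expr.values[:, j]
        if np.std(x) == 0.0:
            continue
        if method == "pearson":
            rho = float(np.corrcoef(y, x)[0, 1])
        elif method == "spearman":
            rho = float(scipy.stats.spearmanr(y, x).statistic)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        if np.isfinite(rho) and abs(rho) >= rho_threshold:
            out.append((g, rho))
    return sorted(out)
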