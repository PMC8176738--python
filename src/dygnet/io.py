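"""Input/output and expression-matrix transforms.

Canonical interchange dialect is TSV: tab-separated, header row, UTF-8,
no quoting.  Expression matrices are cells x genes with the first column
holding cell IDs; MatrixMarket input is supported with ``.rows``/``.cols``
sidecar files.  Binding priors are a 3-column TSV (regulator, target,
probability).  Networks are written as a 4-column TSV sorted by
(time, regulator, target).
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


#: sentinel returned by BindingPriorTable.get for pairs with no binding
#: evidence; downstream penalty code treats it as weight 1.
NO_EVIDENCE = None


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with IDs and a transform-state flag.

    ``state`` tracks the position in the raw -> log1p -> standardized
    pipeline so transforms cannot be applied out of order.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cell IDs x {len(self.gene_ids)} gene IDs"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell IDs")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene IDs")
        if self.state not in ("raw", "log1p", "standardized"):
            raise ValidationError(f"unknown state {self.state!r}")
        if self.state == "raw" and self.values.size and self.values.min() < 0:
            raise ValidationError("raw expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in expression matrix") from None

    def zero_variance_genes(self) -> list[str]:
        """Genes constant across all cells (candidates for exclusion)."""
        sd = self.values.std(axis=0)
        return [g for g, s in zip(self.gene_ids, sd) if s == 0.0]

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionMatrix(
            self.values[idx],
            [self.cell_ids[i] for i in idx],
            list(self.gene_ids),
            self.state,
        )


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered, duplicate-free collection of gene IDs."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.name!r} contains duplicates")

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


class BindingPriorTable:
    """Sparse map (regulator, target) -> binding probability in [0, 1].

    An absent pair means no binding evidence; :meth:`get` then returns
    :data:`NO_EVIDENCE`, which the penalty module maps to weight 1.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._entries: dict[tuple[str, str], float] = {}
        if entries:
            for (reg, tgt), p in entries.items():
                self.add(reg, tgt, p)

    def add(self, regulator: str, target: str, probability: float) -> None:
        p = float(probability)
        if not (0.0 <= p <= 1.0):
            raise ValidationError(
                f"binding probability for ({regulator}, {target}) is {p}, "
                "outside [0, 1]"
            )
        self._entries[(str(regulator), str(target))] = p

    def get(self, regulator: str, target: str):
        """Probability for the pair, or :data:`NO_EVIDENCE` if absent."""
        return self._entries.get((regulator, target), NO_EVIDENCE)

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()


@dataclass
class StandardizationReport:
    """Per-gene means/sds used for z-scoring, and dropped constant genes."""

    means: dict[str, float]
    sds: dict[str, float]
    dropped_genes: list[str] = field(default_factory=list)


def _atomic_write(path: str | Path, text: str) -> None:
    """Write text to path via a temp file + rename (atomic on POSIX)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# expression I/O


def read_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a cells x genes expression matrix.

    ``tsv``: header row of gene IDs, first column of cell IDs.
    ``mtx``: MatrixMarket cells x genes, with sidecar ``<path>.rows``
    (cell IDs) and ``<path>.cols`` (gene IDs), one ID per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if format == "tsv":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            raise ValidationError(f"{path}: duplicate gene IDs in header")
        try:
            df = pd.read_csv(
                path, sep="\t", index_col=0, header=0, float_precision="round_trip"
            )
        except Exception as exc:  # pragma: no cover - pandas names the line
            raise ValidationError(f"malformed expression TSV {path}: {exc}") from exc
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            [str(c) for c in df.index],
            [str(g) for g in df.columns],
            state="raw",
        )
    if format == "mtx":
        rows_path = path.with_suffix(path.suffix + ".rows")
        cols_path = path.with_suffix(path.suffix + ".cols")
        for side in (rows_path, cols_path):
            if not side.exists():
                raise FileNotFoundError(f"mtx sidecar file not found: {side}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        cell_ids = rows_path.read_text().split()
        gene_ids = cols_path.read_text().split()
        return ExpressionMatrix(np.asarray(mat, float), cell_ids, gene_ids, "raw")
    raise ValueError(f"unknown expression format {format!r}")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_ids)
    _atomic_write(path, df.to_csv(sep="\t", lineterminator="\n"))


def log1p_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply natural-log ``log(v + 1)`` elementwise; requires raw input."""
    if expr.state != "raw":
        raise ValidationError(
            f"log1p_transform requires state='raw', got {expr.state!r}"
        )
    if expr.values.size and expr.values.min() < 0:
        raise ValidationError("negative value encountered in raw expression")
    return ExpressionMatrix(
        np.log1p(expr.values), list(expr.cell_ids), list(expr.gene_ids), "log1p"
    )


def standardize(
    expr: ExpressionMatrix,
) -> tuple[ExpressionMatrix, StandardizationReport]:
    """Z-score each gene globally over all cells (population sd, ddof=0).

    Zero-variance genes cannot be scaled and are dropped; they are listed
    in the returned report rather than raising, since genome-wide input
    routinely contains unexpressed genes.
    """
    if expr.state != "log1p":
        raise ValidationError(
            f"standardize requires state='log1p', got {expr.state!r}"
        )
    means = expr.values.mean(axis=0)
    sds = expr.values.std(axis=0, ddof=0)
    keep = sds > 0.0
    dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene(s): "
            + ", ".join(dropped[:10])
            + ("..." if len(dropped) > 10 else "")
        )
    z = (expr.values[:, keep] - means[keep]) / sds[keep]
    kept_genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    report = StandardizationReport(
        means={g: float(m) for g, m, k in zip(expr.gene_ids, means, keep) if k},
        sds={g: float(s) for g, s, k in zip(expr.gene_ids, sds, keep) if k},
        dropped_genes=dropped,
    )
    out = ExpressionMatrix(z, list(expr.cell_ids), kept_genes, "standardized")
    return out, report


# ---------------------------------------------------------------------------
# binding priors / gene sets


def read_binding_priors(path: str | Path) -> BindingPriorTable:
    """Read a 3-column TSV (regulator, target, probability) into a table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"binding prior file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=0, float_precision="round_trip")
    if df.shape[1] != 3:
        raise ValidationError(
            f"{path}: expected 3 columns (regulator, target, probability), "
            f"got {df.shape[1]}"
        )
    table = BindingPriorTable()
    for i, (reg, tgt, p) in enumerate(df.itertuples(index=False), start=2):
        try:
            table.add(str(reg), str(tgt), float(p))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return table


def write_binding_priors(table: BindingPriorTable, path: str | Path) -> None:
    rows = sorted(table.items())
    lines = ["regulator\ttarget\tprobability"]
    lines += [f"{r}\t{t}\t{p!r}" for (r, t), p in rows]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set: one gene ID per line, blank lines ignored."""
    path = Path(path)
    members = tuple(
        line.strip() for line in path.read_text().splitlines() if line.strip()
    )
    return GeneSet(name or path.stem, members)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    _atomic_write(path, "\n".join(gene_set.members) + "\n")


# ---------------------------------------------------------------------------
# cell-time assignments and networks


def read_times(path: str | Path):
    """Read a cell -> time-bin TSV (columns cell_id, t_hat)."""
    from .pseudotime import CellTimeAssignment

    df = pd.read_csv(path, sep="\t", header=0)
    t_hat = df.iloc[:, 1].to_numpy(dtype=int)
    cell_ids = [str(c) for c in df.iloc[:, 0]]
    on_path = t_hat[t_hat > 0]
    T = int(on_path.max()) if on_path.size else 0
    return CellTimeAssignment(cell_ids=cell_ids, t_hat=t_hat, T=T, trajectory=[])


def write_times(times, path: str | Path) -> None:
    lines = ["cell_id\tt_hat"]
    lines += [f"{c}\t{t}" for c, t in zip(times.cell_ids, times.t_hat)]
    _atomic_write(path, "\n".join(lines) + "\n")


def write_network(net, path: str | Path) -> None:
    """Write edges as TSV sorted by (time, regulator, target)."""
    rows = sorted(
        net.edges, key=lambda e: (e.time, e.regulator, e.target)
    )
    lines = ["regulator\ttarget\ttime\tcoefficient"]
    lines += [
        f"{e.regulator}\t{e.target}\t{e.time}\t{e.coefficient!r}" for e in rows
    ]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_network(path: str | Path):
    from .network import Edge, TimeVaryingNetwork

    df = pd.read_csv(path, sep="\t", header=0, float_precision="round_trip")
    edges = [
        Edge(str(r.regulator), str(r.target), int(r.time), float(r.coefficient))
        for r in df.itertuples(index=False)
    ]
    return TimeVaryingNetwork(edges)
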