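"""Distance based on the Conditional Ordered List (DCOL).

DCOL(g_j | g_i) orders the samples by the value of a reference gene g_i and
takes the mean absolute difference between consecutive values of a target
gene g_j in that ordering:

    DCOL(g_j | g_i) = (1 / (n - 1)) * sum_{k=2..n} |t_(k) - t_(k-1)|

where t_(k) is the target value at the k-th position of the reference
ordering.  If g_j is any (possibly nonlinear) function of g_i plus small
noise, consecutive samples in the ordering have similar target values and
the distance is small; for independent genes it concentrates around the
mean absolute difference of a random ordering.  The measure is rank-based
in the reference and therefore invariant to strictly increasing transforms
of the conditioning gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DcolMatrix",
    "conditional_order",
    "dcol",
    "dcol_matrix",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression values with identifiers.

    Parameters
    ----------
    values
        Real matrix of shape (p, n): p genes in rows, n samples in columns.
    gene_ids
        p unique gene identifiers.
    sample_ids
        n unique sample identifiers.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        p, n = values.shape
        if p < 2:
            raise ValueError(f"need at least 2 genes, got {p}")
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match number of rows")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of columns")
        if len(set(self.gene_ids)) != p:
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene id: {dup!r}")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a genes-in-rows DataFrame (index = gene ids)."""
        return cls(df.to_numpy(dtype=float), tuple(df.index.astype(str)),
                   tuple(df.columns.astype(str)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))


@dataclass(frozen=True)
class DcolMatrix:
    """All-vs-all DCOL values: ``d[i, j] = DCOL(g_j | g_i)``.

    The matrix is generally asymmetric — predictability of j from i is not
    predictability of i from j.  The diagonal is computed but carries no
    information (a gene trivially predicts itself) and is excluded from all
    downstream inference.
    """

    d: np.ndarray
    gene_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("DCOL matrix must be square")
        if self.gene_ids and len(self.gene_ids) != d.shape[0]:
            raise ValueError("gene_ids length does not match matrix size")
        if (d < 0).any():
            raise ValueError("DCOL values must be nonnegative")


def _check_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector")
    if x.size < 3:
        raise ValueError(f"{name} must have length >= 3, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def conditional_order(reference) -> np.ndarray:
    """Permutation of sample indices that sorts `reference` ascending.

    Ties are broken stably by original column index, so the ordering (and
    hence DCOL on heavily tied data such as counts) is deterministic.
    """
    reference = _check_vector(reference, "reference")
    return np.argsort(reference, kind="stable")


def dcol(target, reference) -> float:
    """DCOL(target | reference): mean absolute adjacent difference of
    `target` after ordering samples by `reference`."""
    target = _check_vector(target, "target")
    reference = _check_vector(reference, "reference")
    if target.size != reference.size:
        raise ValueError(
            f"length mismatch: target has {target.size}, reference has {reference.size}"
        )
    ordered = target[conditional_order(reference)]
    return float(np.abs(np.diff(ordered)).mean())


def dcol_matrix(expr: ExpressionMatrix) -> DcolMatrix:
    """All ordered pairs at once: ``d[i, j] = dcol(row j, row i)``.

    For each reference gene i the sample ordering is computed once
    (O(n log n)) and applied to every target row in a single pass
    (O(p n) per reference), which is what makes the all-vs-all matrix
    affordable at thousands of genes.
    """
    values = expr.values
    p = expr.n_genes
    d = np.empty((p, p))
    for i in range(p):
        order = np.argsort(values[i], kind="stable")
        d[i] = np.abs(np.diff(values[:, order], axis=1)).mean(axis=1)
    return DcolMatrix(d, expr.gene_ids)
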