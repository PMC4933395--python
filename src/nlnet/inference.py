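"""Permutation-null inference on DCOL values.

Under independence of two genes, DCOL is the mean absolute adjacent
difference of the target gene under a uniformly random sample ordering,
and is asymptotically normal.  We estimate a gene-specific null by
permuting the columns of the whole matrix B times: every permutation
destroys all gene-gene and gene-sample structure while each gene keeps its
own marginal distribution, so the per-gene replicate DCOLs sample the null.
Observed DCOL values are converted to one-sided lower-tail p-values
(small DCOL = the target is predictable from the reference), and each
column of p-values is fed to a local-false-discovery-rate estimator: the
lfdr of a p-value is the posterior probability that the corresponding pair
is null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.isotonic import isotonic_regression

from .dcol import DcolMatrix, ExpressionMatrix

__all__ = [
    "NullParams",
    "PvalueMatrix",
    "LfdrMatrix",
    "permutation_null",
    "dcol_pvalues",
    "lfdr_per_gene",
    "lfdr_matrix",
]

#: genes whose sample sd falls below this are treated as constant and rejected
CONSTANT_SD_TOL = 1e-12

#: minimum number of p-values for a stable per-column density estimate
MIN_LFDR_SAMPLE = 50

#: the null proportion eta0 is read off the Grenander density at this point;
#: an interior point close to 1 is used because the raw last-segment slope of
#: the least concave majorant is unstable at the boundary
ETA0_EVAL_POINT = 0.9


@dataclass(frozen=True)
class NullParams:
    """Per-gene null mean and sd of DCOL from B column permutations."""

    m: np.ndarray
    s: np.ndarray
    n_perm: int
    seed: int
    gene_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if m.shape != s.shape or m.ndim != 1:
            raise ValueError("m and s must be matching 1-D vectors")
        if self.n_perm < 2:
            raise ValueError("need at least 2 permutations")
        if (s <= 0).any():
            raise ValueError("null sd must be positive for every gene")


@dataclass(frozen=True)
class PvalueMatrix:
    pv: np.ndarray
    gene_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        pv = np.asarray(self.pv, dtype=float)
        object.__setattr__(self, "pv", pv)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if pv.ndim != 2 or pv.shape[0] != pv.shape[1]:
            raise ValueError("p-value matrix must be square")
        if ((pv < 0) | (pv > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")


@dataclass(frozen=True)
class LfdrMatrix:
    """Square matrix of local false discovery rates; diagonal forced to 1."""

    l: np.ndarray
    gene_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        l = np.asarray(self.l, dtype=float)
        object.__setattr__(self, "l", l)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if l.ndim != 2 or l.shape[0] != l.shape[1]:
            raise ValueError("lfdr matrix must be square")
        if ((l < 0) | (l > 1)).any():
            raise ValueError("lfdr values must lie in [0, 1]")
        if not np.allclose(np.diag(l), 1.0):
            raise ValueError("lfdr diagonal must be 1")


def permutation_null(expr: ExpressionMatrix, n_perm: int = 500,
                     seed: int = 0) -> NullParams:
    """Estimate each gene's null DCOL mean and sd from column permutations.

    One permutation is drawn per replicate and applied to the whole matrix,
    so replicates are shared across genes within a permutation and
    independent across the B replicates.  The sd uses the B-1 denominator.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    values = expr.values
    row_sd = values.std(axis=1, ddof=1)
    if (row_sd < CONSTANT_SD_TOL).any():
        bad = expr.gene_ids[int(np.argmax(row_sd < CONSTANT_SD_TOL))]
        raise ValueError(
            f"gene {bad!r} is constant; its null sd would be zero — filter it out first"
        )
    rng = np.random.default_rng(seed)
    p, n = values.shape
    reps = np.empty((n_perm, p))
    for b in range(n_perm):
        perm = rng.permutation(n)
        reps[b] = np.abs(np.diff(values[:, perm], axis=1)).mean(axis=1)
    return NullParams(m=reps.mean(axis=0), s=reps.std(axis=0, ddof=1),
                      n_perm=n_perm, seed=seed, gene_ids=expr.gene_ids)


def dcol_pvalues(d: DcolMatrix, null: NullParams) -> PvalueMatrix:
    """One-sided p-values ``pv[i, j] = Phi((d[i, j] - m_j) / s_j)``.

    Lower tail: a DCOL far below its null mean means the target gene j is
    unusually smooth along gene i's ordering, i.e. predictable from it.
    """
    if null.gene_ids and d.gene_ids and null.gene_ids != d.gene_ids:
        raise ValueError("gene ids of DCOL matrix and null parameters differ")
    if d.d.shape[0] != null.m.size:
        raise ValueError("dimension mismatch between DCOL matrix and null parameters")
    z = (d.d - null.m[None, :]) / null.s[None, :]
    return PvalueMatrix(norm.cdf(z), d.gene_ids)


def _grenander_density(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Grenander estimate of a nonincreasing density on [0, 1].

    Returns the unique sorted p-values and the density on each ECDF gap,
    i.e. the left-slopes of the least concave majorant of the ECDF.  The
    slopes are obtained by antitonic (decreasing) weighted least squares on
    the raw ECDF-gap slopes, which is exactly the LCM construction.
    """
    x, counts = np.unique(p, return_counts=True)
    n = p.size
    if x[0] <= 0.0:
        # a literal zero would create a zero-width first gap; nudge inside
        x = x.copy()
        x[0] = min(1e-15, x[1] / 2 if x.size > 1 else 1e-15)
    cum = np.cumsum(counts) / n
    dx = np.diff(np.concatenate([[0.0], x]))
    dy = np.diff(np.concatenate([[0.0], cum]))
    f = isotonic_regression(dy / dx, sample_weight=dx, increasing=False)
    return x, f


def lfdr_per_gene(pvalues) -> np.ndarray:
    """Local false discovery rate for a vector of p-values.

    lfdr(p) = eta0 / f(p), capped at 1, where f is the Grenander
    (monotone nonincreasing) density estimate of the p-value distribution
    and eta0, the null proportion, is f evaluated near p = 1 (at
    ``ETA0_EVAL_POINT``), where alternative p-values contribute almost
    nothing.  Output is nondecreasing in p by construction.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-D vector")
    if p.size < MIN_LFDR_SAMPLE:
        raise ValueError(
            f"need at least {MIN_LFDR_SAMPLE} p-values for a stable lfdr fit, got {p.size}"
        )
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    x, f = _grenander_density(p)
    i0 = min(int(np.searchsorted(x, ETA0_EVAL_POINT)), f.size - 1)
    eta0 = min(1.0, float(f[i0]))
    lfdr_unique = np.clip(eta0 / f, 0.0, 1.0)
    return lfdr_unique[np.searchsorted(x, np.maximum(p, x[0]))]


def lfdr_matrix(pv: PvalueMatrix) -> LfdrMatrix:
    """Column-wise lfdr: column j holds the posterior null probability of
    "gene j depends on gene i".  The diagonal is excluded from each fit and
    re-inserted as 1."""
    p = pv.pv.shape[0]
    if p - 1 < MIN_LFDR_SAMPLE:
        raise ValueError(
            f"need at least {MIN_LFDR_SAMPLE + 1} genes for per-column lfdr, got {p}"
        )
    l = np.ones((p, p))
    off = ~np.eye(p, dtype=bool)
    for j in range(p):
        l[off[:, j], j] = lfdr_per_gene(pv.pv[off[:, j], j])
    return LfdrMatrix(l, pv.gene_ids)
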