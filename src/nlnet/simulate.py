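"""Synthetic expression data with hidden nonlinear modules, and the ARI.

Each module is a group of genes tied together through nonlinear link
functions, in one of three dependency designs:

* 0-dependent — a hidden controlling signal x ~ N(0,1) (not emitted as a
  gene) drives every gene in the module: y = f(x) + eps.
* 1-dependent — the first gene is N(0,1); each later gene applies a random
  link to one uniformly chosen existing gene: y_new = f(y_sel) + eps.
* 2-dependent — each later gene sums links of two distinct existing genes:
  y_new = f(y_sel1) + g(y_sel2) + eps (dependencies are weaker but more
  pervasive).

Link functions f are drawn uniformly from {linear, sine, box wave,
absolute value}.  Each link output is standardized to zero mean and unit
sample variance before noise is added, so that the noise level — defined
as noise sd divided by signal sd — means the same thing for every link.
Gaussian noise eps then has sd = noise_level * sd(signal).  A dataset
concatenates independent modules plus a fraction of pure-noise N(0,1)
genes labeled 0, and shuffles the rows.

Partition recovery is scored with the Adjusted Rand Index (ARI), the
chance-corrected pair-counting agreement between two labelings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import comb

from .dcol import ExpressionMatrix

__all__ = [
    "LINK_FUNCTIONS",
    "SimConfig",
    "SimulatedDataset",
    "link_function",
    "simulate_module",
    "simulate_dataset",
    "scenario_config",
    "adjusted_rand_index",
]

LINK_FUNCTIONS = ("linear", "sine", "boxwave", "absval")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated benchmark dataset.

    Defaults are the benchmark's scenario 1: 10 hidden modules of exactly
    100 genes each, 10% extra pure-noise genes, 100 samples.  `noise_level`
    is the sd of the additive Gaussian noise divided by the sd of the true
    signal.  Scenario 2 is the same with 20 modules.
    """

    n_modules: int = 10
    avg_module_size: int = 100
    noise_gene_frac: float = 0.10
    n_samples: int = 100
    noise_level: float = 0.2
    dependency: int = 0
    link_functions: tuple[str, ...] = LINK_FUNCTIONS
    random_sizes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.avg_module_size < 2:
            raise ValueError("avg_module_size must be >= 2")
        if self.noise_level <= 0:
            raise ValueError("noise_level must be positive")
        if self.dependency not in (0, 1, 2):
            raise ValueError("dependency must be 0, 1 or 2")
        unknown = set(self.link_functions) - set(LINK_FUNCTIONS)
        if unknown:
            raise ValueError(f"unknown link functions: {sorted(unknown)}")
        if not 0 <= self.noise_gene_frac < 1:
            raise ValueError("noise_gene_frac must be in [0, 1)")


@dataclass(frozen=True)
class SimulatedDataset:
    expr: ExpressionMatrix
    true_labels: dict[str, int]
    config: SimConfig

    def labels_array(self) -> np.ndarray:
        return np.array([self.true_labels[g] for g in self.expr.gene_ids], dtype=int)


def _standardize(y: np.ndarray) -> np.ndarray:
    y = y - y.mean()
    sd = y.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("link output is constant; cannot standardize")
    return y / sd


def link_function(name: str, x, rng: np.random.Generator | None = None,
                  standardize: bool = True) -> np.ndarray:
    """Apply a named link; standardized to unit sample variance by default.

    linear: s*x with slope sign s drawn from {-1, +1} (requires `rng`);
    sine: sin(pi*x) (period 2); boxwave: sign(sin(pi*x)), a square wave;
    absval: |x|.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("link input must be finite")
    if name == "linear":
        sign = 1.0 if rng is None else float(rng.choice([-1.0, 1.0]))
        y = sign * x
    elif name == "sine":
        y = np.sin(np.pi * x)
    elif name == "boxwave":
        y = np.sign(np.sin(np.pi * x))
    elif name == "absval":
        y = np.abs(x)
    else:
        raise ValueError(f"unknown link function {name!r}")
    return _standardize(y) if standardize else y


def simulate_module(size: int, n_samples: int, dependency: int,
                    noise_level: float, rng: np.random.Generator,
                    link_functions: tuple[str, ...] = LINK_FUNCTIONS):
    """One module's expression matrix plus a generation record.

    The record lists, per gene, the link(s) applied, the parent index
    (-1 for the hidden controller or an N(0,1) seed gene) and the clean
    signal before noise was added.
    """
    if size < 2 or (dependency == 2 and size < 3):
        raise ValueError(f"module size {size} too small for {dependency}-dependent design")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    links = tuple(link_functions)
    out = np.empty((size, n_samples))
    record: list[dict] = []

    def noisy(signal: np.ndarray) -> np.ndarray:
        return signal + rng.normal(0.0, noise_level * signal.std(ddof=1), n_samples)

    def seed_gene(g: int) -> None:
        out[g] = rng.standard_normal(n_samples)
        record.append({"gene": g, "links": [], "parents": [-1],
                       "signal": out[g].copy()})

    if dependency == 0:
        x = rng.standard_normal(n_samples)  # hidden controller, not emitted
        for g in range(size):
            f = str(rng.choice(links))
            signal = link_function(f, x, rng)
            out[g] = noisy(signal)
            record.append({"gene": g, "links": [f], "parents": [-1],
                           "signal": signal})
    elif dependency == 1:
        seed_gene(0)
        for g in range(1, size):
            parent = int(rng.integers(0, g))
            f = str(rng.choice(links))
            signal = link_function(f, out[parent], rng)
            out[g] = noisy(signal)
            record.append({"gene": g, "links": [f], "parents": [parent],
                           "signal": signal})
    else:
        seed_gene(0)
        seed_gene(1)
        for g in range(2, size):
            p1, p2 = (int(v) for v in rng.choice(g, size=2, replace=False))
            f, h = (str(rng.choice(links)) for _ in range(2))
            signal = link_function(f, out[p1], rng) + link_function(h, out[p2], rng)
            out[g] = noisy(signal)
            record.append({"gene": g, "links": [f, h], "parents": [p1, p2],
                           "signal": signal})
    return out, record


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Concatenate independent modules plus pure-noise genes; shuffle rows."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.random_sizes:
        floor = 3 if cfg.dependency == 2 else 2
        sizes = np.maximum(rng.poisson(cfg.avg_module_size, cfg.n_modules), floor)
    else:
        sizes = np.full(cfg.n_modules, cfg.avg_module_size)
    blocks = []
    labels = []
    for mod, size in enumerate(sizes, start=1):
        mat, _ = simulate_module(int(size), cfg.n_samples, cfg.dependency,
                                 cfg.noise_level, rng, cfg.link_functions)
        blocks.append(mat)
        labels.extend([mod] * int(size))
    n_module_genes = int(sizes.sum())
    n_noise = round(cfg.noise_gene_frac * n_module_genes)
    if n_noise:
        blocks.append(rng.standard_normal((n_noise, cfg.n_samples)))
        labels.extend([0] * n_noise)
    values = np.vstack(blocks)
    labels = np.asarray(labels, dtype=int)
    perm = rng.permutation(values.shape[0])
    values, labels = values[perm], labels[perm]
    width = len(str(values.shape[0]))
    gene_ids = tuple(f"g{i + 1:0{width}d}" for i in range(values.shape[0]))
    sample_ids = tuple(f"s{k + 1}" for k in range(cfg.n_samples))
    expr = ExpressionMatrix(values, gene_ids, sample_ids)
    return SimulatedDataset(expr=expr,
                            true_labels=dict(zip(gene_ids, labels.tolist())),
                            config=cfg)


def scenario_config(scenario: int, **overrides) -> SimConfig:
    """The benchmark's two module-count settings: 1 -> 10 modules (1100
    genes), 2 -> 20 modules (2200 genes)."""
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 or 2")
    cfg = SimConfig(n_modules=10 if scenario == 1 else 20)
    return replace(cfg, **overrides) if overrides else cfg


def adjusted_rand_index(a, b) -> float:
    """Permutation-model ARI between two labelings of the same items.

    Accepts aligned label sequences, or two dicts over an identical item
    set.  1 = identical partitions, ~0 = chance agreement; can be negative.
    """
    if isinstance(a, dict) or isinstance(b, dict):
        if not (isinstance(a, dict) and isinstance(b, dict)):
            raise TypeError("give either two dicts or two aligned sequences")
        if set(a) != set(b):
            raise ValueError("label dicts cover different item sets")
        items = sorted(a)
        a = [a[k] for k in items]
        b = [b[k] for k in items]
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    # pair-counting contingency table
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ct = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(ct, (ai, bi), 1)
    sum_ij = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    total = comb(a.size, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
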