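"""Empirical significance of bicluster coexpression.

The coherence of a bicluster with R genes and C conditions is summarized by

    T = (2 / (R (R-1))) * sum_{i<j} r(x_i, x_j),

the average pairwise Pearson correlation of its gene row vectors restricted
to its conditions.  T lives in [-1, 1] regardless of shape, so biclusters of
different sizes are comparable.  A row vector with zero variance contributes
r = 0 to every pair.

Significance is assessed empirically: ``n_perm`` submatrices of the same
R x C shape are drawn from the full expression matrix (rows and columns
sampled independently, without replacement, not necessarily contiguous) and

    p = #(null T >= observed T) / n_perm

is the upper-tail empirical p-value.  Null ensembles are cached per shape:
every bicluster of the same shape scored in one run shares the identical
sample set, and a shorter ensemble is always a prefix of a longer one, so
cheap screening p-values (e.g. inside the merge search) are consistent with
the final ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Bicluster, ExpressionMatrix, bicluster_sort_key

__all__ = [
    "pearson_r",
    "t_statistic",
    "NullDistribution",
    "NullCache",
    "empirical_p_from_samples",
    "empirical_pvalue",
    "score_biclusters",
    "filter_significant",
    "overlap_filter",
    "top_k_by_size",
]


def pearson_r(x, y) -> float:
    """Pearson correlation with the zero-variance convention r = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt(xc @ xc))
    ny = float(np.sqrt(yc @ yc))
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip((xc @ yc) / (nx * ny), -1.0, 1.0))


def _t_from_block(block: np.ndarray) -> float:
    """Average pairwise Pearson r of the rows of a (R, C) block.

    Uses the identity  sum_{i<j} u_i . u_j = (||sum_i u_i||^2 - sum_i
    ||u_i||^2)/2  on unit-normalized centered rows; zero-variance rows map
    to the zero vector, realising the r = 0 convention.
    """
    R = block.shape[0]
    centered = block - block.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norms[:, None] > 0, centered / norms[:, None], 0.0)
    s = unit.sum(axis=0)
    sumsq = float(s @ s)
    diag = float((unit ** 2).sum())
    return (sumsq - diag) / (R * (R - 1))


def t_statistic(rows) -> float:
    """T for an (R, C) block of row vectors; requires R >= 2 and C >= 2."""
    block = np.asarray(rows, dtype=float)
    if block.ndim != 2 or block.shape[0] < 2:
        raise ValueError("need a 2-D block with at least 2 rows")
    if block.shape[1] < 2:
        raise ValueError("need at least 2 conditions per row vector")
    return float(_t_from_block(block))


@dataclass
class NullDistribution:
    """Cached ensemble of null T values for one submatrix shape."""

    shape: tuple
    t_samples: np.ndarray
    n_perm: int
    seed_tag: int


class NullCache:
    """Per-shape cache of null T ensembles drawn from one expression matrix.

    The per-shape RNG stream is seeded from ``SeedSequence(base_seed,
    spawn_key=shape)``; extending an ensemble continues the same stream, so
    the first ``m`` samples of a size-``n >= m`` ensemble equal the
    size-``m`` ensemble exactly.
    """

    _CHUNK_CELLS = 4_000_000  # memory cap: cells per generation chunk

    def __init__(self, matrix: ExpressionMatrix, base_seed: int = 0):
        self.matrix = matrix
        self.base_seed = int(base_seed)
        self._store: dict = {}

    def get(self, R: int, C: int, n_perm: int) -> np.ndarray:
        """Null T samples for shape (R, C); first n_perm of the stream."""
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        key = (int(R), int(C))
        if key not in self._store:
            rng = np.random.default_rng(
                np.random.SeedSequence(self.base_seed, spawn_key=key)
            )
            self._store[key] = NullDistribution(
                shape=key,
                t_samples=np.empty(0),
                n_perm=0,
                seed_tag=self.base_seed,
            )
            self._store[key]._rng = rng
        dist = self._store[key]
        if dist.n_perm < n_perm:
            extra = self._draw(R, C, n_perm - dist.n_perm, dist._rng)
            dist.t_samples = np.concatenate([dist.t_samples, extra])
            dist.n_perm = len(dist.t_samples)
        return dist.t_samples[:n_perm]

    def _draw(self, R: int, C: int, n: int, rng: np.random.Generator) -> np.ndarray:
        values = self.matrix.values
        n_genes, n_cond = values.shape
        if R > n_genes or C > n_cond:
            raise ValueError("bicluster shape exceeds the matrix shape")
        out = np.empty(n)
        chunk = max(1, self._CHUNK_CELLS // max(1, R * C))
        done = 0
        while done < n:
            m = min(chunk, n - done)
            rows = self._distinct_indices(rng, m, n_genes, R)
            cols = self._distinct_indices(rng, m, n_cond, C)
            sub = values[rows[:, :, None], cols[:, None, :]]
            centered = sub - sub.mean(axis=2, keepdims=True)
            norms = np.sqrt((centered ** 2).sum(axis=2))
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(norms[..., None] > 0, centered / norms[..., None], 0.0)
            s = unit.sum(axis=1)
            sumsq = (s ** 2).sum(axis=1)
            diag = (unit ** 2).sum(axis=(1, 2))
            out[done:done + m] = (sumsq - diag) / (R * (R - 1))
            done += m
        return out

    @staticmethod
    def _distinct_indices(rng, m: int, n: int, k: int) -> np.ndarray:
        """m draws of k distinct indices from range(n), vectorized."""
        keys = rng.random((m, n))
        return np.argpartition(keys, min(k, n - 1), axis=1)[:, :k]


def empirical_p_from_samples(observed: float, null_samples: np.ndarray) -> float:
    """Upper-tail counting rule: fraction of null samples >= observed."""
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size == 0:
        raise ValueError("need at least one null sample")
    return float(np.count_nonzero(null_samples >= observed) / null_samples.size)


def empirical_pvalue(
    bic: Bicluster,
    matrix: ExpressionMatrix,
    n_perm: int,
    cache: NullCache,
) -> float:
    """Score one bicluster against its same-shape null ensemble.

    Also records ``t_stat`` and ``p_value`` on the bicluster.
    """
    block = matrix.submatrix(bic.genes, bic.conditions)
    obs = t_statistic(block)
    null = cache.get(bic.n_genes, bic.n_conditions, n_perm)
    p = empirical_p_from_samples(obs, null)
    bic.t_stat = obs
    bic.p_value = p
    return p


def score_biclusters(biclusters, matrix, n_perm, cache) -> list:
    for b in biclusters:
        empirical_pvalue(b, matrix, n_perm, cache)
    return list(biclusters)


def filter_significant(biclusters, alpha: float) -> list:
    """Keep p <= alpha, most significant first."""
    if any(b.p_value is None for b in biclusters):
        raise ValueError("filter_significant requires scored biclusters")
    kept = [b for b in biclusters if b.p_value <= alpha]
    kept.sort(key=lambda b: (b.p_value, -b.size, tuple(sorted(b.genes))))
    return kept


def overlap_filter(biclusters) -> list:
    """Evaluation-style redundancy filter.

    Processing largest-first, a bicluster is removed when *more than* 50% of
    its cells are covered by an already-kept strictly larger bicluster
    (overlap exactly 0.5 is kept).
    """
    ordered = sorted(biclusters, key=bicluster_sort_key)
    kept: list = []
    for b in ordered:
        drop = False
        for k in kept:
            if k.size <= b.size:
                continue
            inter = len(b.genes & k.genes) * len(b.conditions & k.conditions)
            if inter / b.size > 0.5:
                drop = True
                break
        if not drop:
            kept.append(b)
    return kept


def top_k_by_size(biclusters, k: int) -> list:
    """First k biclusters under cell-count-descending order."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return sorted(biclusters, key=bicluster_sort_key)[:k]
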