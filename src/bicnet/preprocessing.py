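"""Column-wise discretization of an expression matrix into a transaction DB.

Each experimental condition (column) is processed independently:

1.  *Outlier clipping.*  The column mean and (population) standard deviation
    are computed on the raw values; values outside ``Mean +/- 3SD`` are set to
    the nearest bound.  By convention the column extremes are therefore
    ``MAX = Mean + 3SD`` and ``MIN = Mean - 3SD``, so the window width is
    always ``MAX_DIFF = (MAX - MIN)/bins = 6*SD/bins``.
2.  *Low-signal removal.*  Values within ``sd_coeff*SD`` of the mean are
    regarded as undifferentiated and excluded from item generation entirely
    (neither anchors nor members of any window).
3.  *Item generation.*  Retained genes are sorted by clipped value and a
    window of width ``MAX_DIFF`` is slid gene-wise: each retained gene ``g``
    anchors the item ``{h retained : value(g) <= value(h) <= value(g) +
    MAX_DIFF}``.  Before de-duplication there is exactly one item per
    retained gene; identical gene sets within a column are collapsed to a
    single :class:`Item` (anchor multiplicity kept in ``anchor_count``).

A gene's *transaction* is the set of items, across all columns, it belongs
to.  Items of one column are independent of every other column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import DegenerateInputError, ExpressionMatrix, PipelineParams

__all__ = [
    "Item",
    "ColumnStats",
    "TransactionDB",
    "clip_outliers",
    "compute_max_diff",
    "sd_filter",
    "generate_items",
]


@dataclass(frozen=True)
class Item:
    """A per-column window of genes with similar expression values."""

    item_id: int
    condition: str
    genes: frozenset
    value_lo: float
    value_hi: float
    anchor_count: int = 1


@dataclass(frozen=True)
class ColumnStats:
    mean: float
    sd: float
    max_diff: float
    degenerate: bool = False  # SD == 0: contributes no items


@dataclass
class TransactionDB:
    """Vertical + horizontal views of the item database.

    ``item_gene_masks[i]`` is an integer bitmask over gene row indices for
    ``items[i]`` — the representation the miner consumes.  ``transactions``
    maps each gene id to the set of item ids containing it (genes in no item
    are absent).  ``clipped`` is the outlier-clipped value matrix and
    ``retained`` the per-cell survival mask of the SD filter, kept so that
    column coherence can be re-checked downstream.
    """

    matrix: ExpressionMatrix
    items: list = field(default_factory=list)
    item_gene_masks: list = field(default_factory=list)
    column_stats: dict = field(default_factory=dict)
    clipped: np.ndarray | None = None
    retained: np.ndarray | None = None

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def transactions(self) -> dict:
        tx: dict = {}
        gene_ids = self.matrix.gene_ids
        for item, mask in zip(self.items, self.item_gene_masks):
            i = 0
            m = mask
            while m:
                low = m & -m
                g = low.bit_length() - 1
                tx.setdefault(gene_ids[g], set()).add(item.item_id)
                m ^= low
        return tx

    def genes_of_mask(self, mask: int) -> frozenset:
        gene_ids = self.matrix.gene_ids
        out = []
        while mask:
            low = mask & -mask
            out.append(gene_ids[low.bit_length() - 1])
            mask ^= low
        return frozenset(out)


def clip_outliers(column_values: Sequence[float]):
    """Clip a column into ``Mean +/- 3SD``.

    Mean and SD (population, ddof=0) are computed on the *original* values;
    only values strictly outside the band move, onto the nearest bound.

    Returns ``(clipped, mean, sd)``.
    """
    v = np.asarray(column_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values per column")
    if not np.all(np.isfinite(v)):
        raise ValueError("column contains non-finite values")
    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    clipped = np.clip(v, mean - 3.0 * sd, mean + 3.0 * sd)
    return clipped, mean, sd


def compute_max_diff(sd: float, bins: int) -> float:
    """Window width of one item: ``6*SD/bins``.

    The column extremes are fixed at ``Mean +/- 3SD`` by the clipping step,
    so ``(MAX - MIN)/bins`` reduces to ``6*SD/bins`` unconditionally.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    return 6.0 * sd / bins


def sd_filter(clipped: np.ndarray, mean: float, sd: float, sd_coeff: float) -> np.ndarray:
    """Boolean mask of genes retained for this column.

    A gene survives iff ``|value - mean| >= sd_coeff * sd``; values inside
    the band are undifferentiated and take part in no item of this column.
    ``sd_coeff = 0`` retains everything.
    """
    clipped = np.asarray(clipped, dtype=float)
    return np.abs(clipped - mean) >= sd_coeff * sd


def _column_items(values: np.ndarray, gene_indices: np.ndarray, max_diff: float):
    """Slide a closed window [v, v + max_diff] over genes sorted by value.

    ``values``/``gene_indices`` are parallel arrays of the retained genes of
    one column.  Returns ``(gene_masks, bounds, anchor_counts)`` with one
    entry per *distinct* item (identical windows collapsed); masks are
    bitmasks over global gene row indices.
    """
    order = np.lexsort((gene_indices, values))
    sv = values[order]
    sg = gene_indices[order]
    n = sv.size
    masks: list = []
    bounds: list = []
    anchors: list = []
    prev = None
    for a in range(n):
        lo = int(np.searchsorted(sv, sv[a], side="left"))
        hi = int(np.searchsorted(sv, sv[a] + max_diff, side="right"))
        window = (lo, hi)
        if window == prev:
            anchors[-1] += 1
            continue
        prev = window
        mask = 0
        for g in sg[lo:hi]:
            mask |= 1 << int(g)
        masks.append(mask)
        bounds.append((float(sv[a]), float(sv[a] + max_diff)))
        anchors.append(1)
    return masks, bounds, anchors


def generate_items(matrix: ExpressionMatrix, params: PipelineParams) -> TransactionDB:
    """Build the transaction database for a matrix.

    Raises :class:`DegenerateInputError` if no column yields any item (for
    example, every column constant).
    """
    db = TransactionDB(matrix=matrix)
    clipped_all = np.empty_like(matrix.values)
    retained_all = np.zeros(matrix.values.shape, dtype=bool)
    next_id = 0
    for j, cond in enumerate(matrix.condition_ids):
        clipped, mean, sd = clip_outliers(matrix.values[:, j])
        clipped_all[:, j] = clipped
        if sd == 0.0:
            db.column_stats[cond] = ColumnStats(mean, sd, 0.0, degenerate=True)
            continue
        max_diff = compute_max_diff(sd, params.bins)
        db.column_stats[cond] = ColumnStats(mean, sd, max_diff)
        mask = sd_filter(clipped, mean, sd, params.sd_coeff)
        retained_all[:, j] = mask
        gene_idx = np.flatnonzero(mask)
        if gene_idx.size == 0:
            continue
        gmasks, bounds, anchors = _column_items(clipped[gene_idx], gene_idx, max_diff)
        for gm, (lo, hi), ac in zip(gmasks, bounds, anchors):
            db.items.append(
                Item(
                    item_id=next_id,
                    condition=cond,
                    genes=db.genes_of_mask(gm),
                    value_lo=lo,
                    value_hi=hi,
                    anchor_count=ac,
                )
            )
            db.item_gene_masks.append(gm)
            next_id += 1
    db.clipped = clipped_all
    db.retained = retained_all
    if not db.items:
        raise DegenerateInputError("no column produced any item")
    return db
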