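"""Synthetic expression matrices with implanted coherent-column biclusters.

The generator emulates the bicluster type the pipeline targets: within each
implanted condition, the block's genes sit at a common level with a small
within-column jitter, so the block passes the per-column coherence check at
the intended window count (``bins``).  The background is independent
Gaussian noise per cell; block levels are placed at least two background
standard deviations away from zero so that, at the default ``sd_coeff`` of
0.7, the implanted cells survive the low-signal filter.  Levels vary across
the implanted conditions, which makes the block's gene row vectors strongly
correlated and its coherence statistic T near-maximal.

What this deliberately does *not* simulate: probe effects, batch structure,
heavy-tailed noise or correlated background genes, so recovery results on
these fixtures are a best case for real expression data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Bicluster, ExpressionMatrix
from .preprocessing import clip_outliers, compute_max_diff

__all__ = [
    "ImplantBlock",
    "ImplantSpec",
    "generate",
    "single_block_spec",
    "three_overlapping_biclusters",
    "score_recovery",
]


@dataclass(frozen=True)
class ImplantBlock:
    """One coherent block: gene rows x condition columns at given levels.

    ``levels`` holds one center value per implanted condition; ``jitter`` is
    the half-width of the uniform perturbation added per cell, so the
    within-column value range of the block is at most ``2 * jitter``.
    """

    gene_indices: tuple
    condition_indices: tuple
    levels: tuple
    jitter: float = 0.0

    def __post_init__(self):
        if len(self.levels) != len(self.condition_indices):
            raise ValueError("need one level per implanted condition")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


@dataclass(frozen=True)
class ImplantSpec:
    n_genes: int
    n_conditions: int
    blocks: tuple = ()
    noise_sd: float = 1.0
    seed: int = 0
    bins: int = 7  # target window count the blocks must stay coherent under
    allow_overlap: bool = False


def _gene_id(i: int) -> str:
    return f"g{i + 1:04d}"


def _condition_id(j: int) -> str:
    return f"c{j + 1:02d}"


def generate(spec: ImplantSpec):
    """Sample a matrix and return it with the ground-truth block list.

    The truth is returned as unscored :class:`Bicluster` objects (gene ids x
    condition ids).  After implanting, every block is checked to satisfy
    max - min <= MAX_DIFF (computed from the final clipped column SD at
    ``spec.bins``) in each of its columns; a violating spec is an error, not
    a silent bad fixture.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_conditions))

    occupied: set = set()
    for block in spec.blocks:
        cells = {(i, j) for i in block.gene_indices for j in block.condition_indices}
        if not spec.allow_overlap and cells & occupied:
            raise ValueError("overlapping blocks require allow_overlap=True")
        occupied |= cells
        for level, j in zip(block.levels, block.condition_indices):
            if not (0 <= j < spec.n_conditions):
                raise ValueError("block condition index out of bounds")
            for i in block.gene_indices:
                if not (0 <= i < spec.n_genes):
                    raise ValueError("block gene index out of bounds")
                values[i, j] = level + rng.uniform(-block.jitter, block.jitter)

    matrix = ExpressionMatrix(
        values,
        [_gene_id(i) for i in range(spec.n_genes)],
        [_condition_id(j) for j in range(spec.n_conditions)],
    )

    truth = []
    for block in spec.blocks:
        for j in block.condition_indices:
            clipped, _, sd = clip_outliers(values[:, j])
            md = compute_max_diff(sd, spec.bins)
            block_vals = clipped[list(block.gene_indices), ]
            if block_vals.max() - block_vals.min() > md:
                raise ValueError(
                    f"implanted block is incoherent in column {j}: jitter too "
                    f"large for bins={spec.bins} (range "
                    f"{block_vals.max() - block_vals.min():.3g} > MAX_DIFF {md:.3g})"
                )
        truth.append(
            Bicluster(
                genes=frozenset(_gene_id(i) for i in block.gene_indices),
                conditions=frozenset(_condition_id(j) for j in block.condition_indices),
            )
        )
    return matrix, truth


def single_block_spec(
    n_genes: int = 200,
    n_conditions: int = 20,
    block_genes: int = 15,
    block_conditions: int = 4,
    levels: tuple = (2.5, -2.5, 3.0, -3.0),
    jitter: float = 0.2,
    seed: int = 0,
) -> ImplantSpec:
    """The standard recovery benchmark: one coherent block in pure noise.

    Defaults: a 15 x 4 block inside a 200 x 20 standard-normal matrix, with
    alternating-sign levels 2.5-3 background SDs out and jitter well inside
    MAX_DIFF at bins = 7.
    """
    if len(levels) != block_conditions:
        raise ValueError("need one level per block condition")
    return ImplantSpec(
        n_genes=n_genes,
        n_conditions=n_conditions,
        blocks=(
            ImplantBlock(
                gene_indices=tuple(range(block_genes)),
                condition_indices=tuple(range(block_conditions)),
                levels=tuple(levels),
                jitter=jitter,
            ),
        ),
        seed=seed,
    )


def three_overlapping_biclusters(group_size: int = 4):
    """Three mutually overlapping biclusters over five gene groups.

    Gene groups a..e (``group_size`` genes each) are arranged so that their
    membership signatures are {B1}, {B1,B2}, {B1,B2,B3}, {B2,B3} and {B3}:
    B1 covers a+b+c, B2 covers b+c+d, B3 covers c+d+e, over staggered
    condition sets.  The resulting gene set network has 5 nodes and 7 edges,
    with weight 2 between the {B1,B2} and {B1,B2,B3} nodes.
    """
    def genes(lo, hi):
        return frozenset(_gene_id(i) for i in range(lo * group_size, hi * group_size))

    def conds(idxs):
        return frozenset(_condition_id(j) for j in idxs)

    b1 = Bicluster(genes=genes(0, 3), conditions=conds([0, 1, 2]))
    b2 = Bicluster(genes=genes(1, 4), conditions=conds([1, 2, 3]))
    b3 = Bicluster(genes=genes(2, 5), conditions=conds([2, 3, 4]))
    return [b1, b2, b3]


def three_block_matrix():
    """A deterministic 20 x 6 matrix whose maximal coherent biclusters are
    exactly the three of :func:`three_overlapping_biclusters` (at min_row=10,
    min_col=2, bins=5, sd_coeff=0).

    Five gene groups a..e (4 genes each); each bicluster owns two private
    conditions, in which its 12 member genes sit at a common level and the
    two non-member groups at +/-10 — beyond MAX_DIFF = 6*SD/5 ~ 7.6 — so no
    other gene set of >= 10 genes is coherent in >= 2 columns.  Levels are
    shifted by +3 in each bicluster's second condition, which makes member
    rows perfectly correlated.  Returns ``(matrix, truth)`` with the truth
    blocks carrying the expected signatures {B1}, {B1,B2}, {B1,B2,B3},
    {B2,B3}, {B3} over groups a..e.
    """
    levels = {
        #       c1    c2    c3    c4    c5    c6
        "a": [  0.0,  3.0, 10.0, 13.0, 10.0, 13.0],
        "b": [  0.0,  3.0,  0.0,  3.0, -10.0, -7.0],
        "c": [  0.0,  3.0,  0.0,  3.0,  0.0,  3.0],
        "d": [ 10.0, 13.0,  0.0,  3.0,  0.0,  3.0],
        "e": [-10.0, -7.0, -10.0, -7.0,  0.0,  3.0],
    }
    group_size = 4
    values = np.empty((5 * group_size, 6))
    for gi, grp in enumerate("abcde"):
        for k in range(group_size):
            values[gi * group_size + k, :] = levels[grp]
    matrix = ExpressionMatrix(
        values,
        [_gene_id(i) for i in range(5 * group_size)],
        [_condition_id(j) for j in range(6)],
    )
    b1, b2, b3 = three_overlapping_biclusters(group_size)
    truth = [
        Bicluster(genes=b1.genes, conditions=frozenset({"c01", "c02"})),
        Bicluster(genes=b2.genes, conditions=frozenset({"c03", "c04"})),
        Bicluster(genes=b3.genes, conditions=frozenset({"c05", "c06"})),
    ]
    return matrix, truth


def score_recovery(found, truth) -> list:
    """Per truth block: gene/condition recall and gene precision of the
    best-matching found bicluster (by shared cell count)."""
    report = []
    for t in truth:
        best = None
        best_cells = -1
        for f in found:
            cells = len(t.genes & f.genes) * len(t.conditions & f.conditions)
            if cells > best_cells:
                best, best_cells = f, cells
        if best is None or best_cells == 0:
            report.append({
                "gene_recall": 0.0, "condition_recall": 0.0, "gene_precision": 0.0,
                "best_match": None,
            })
            continue
        report.append({
            "gene_recall": len(t.genes & best.genes) / len(t.genes),
            "condition_recall": len(t.conditions & best.conditions) / len(t.conditions),
            "gene_precision": len(t.genes & best.genes) / len(best.genes),
            "best_match": best,
        })
    return report
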