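"""Exact enumeration of maximal coherent biclusters over the transaction DB.

A gene set ``G`` is *coherent* in a column when all its (clipped, retained)
values fit inside one window of width MAX_DIFF, i.e. some item of that
column contains ``G``.  Write ``C(G)`` for the set of columns with such an
item.  The miner enumerates exactly the biclusters

    (G, C(G))   with |G| >= min_row,  |C(G)| >= min_col,

where ``G`` is *maximal*: no gene can be added without losing a column.
Because column coverage is antitone in the gene set, a single-gene extension
test is a complete maximality test, and no two outputs can be in strict
containment on both axes simultaneously.

In frequent-itemset terms each output corresponds to the closed itemset
``T(G)`` = {all items containing G}, whose support (gene intersection) is
exactly ``G`` and whose distinct columns are ``C(G)``.  The search runs over
genes rather than items: a depth-first set-enumeration with bitmask
intersections, pruned by the antitone constraint |C| >= min_col and by a
cardinality lookahead against min_row, with parent-equivalence absorption of
genes contained in every item of the current closure.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Bicluster, PipelineParams, bicluster_sort_key
from .preprocessing import TransactionDB

__all__ = ["FrequentItemset", "mine_maximal", "itemsets_to_biclusters"]


@dataclass(frozen=True)
class FrequentItemset:
    """A closed itemset: all items containing ``support_genes``.

    ``support_genes`` equals the intersection of the member items' gene sets,
    and ``conditions`` the member items' distinct columns.
    """

    item_ids: frozenset
    support_genes: frozenset
    conditions: frozenset


def mine_maximal(db: TransactionDB, min_row: int, min_col: int = 2) -> list:
    """Enumerate maximal coherent gene sets with their column coverage.

    Returns :class:`FrequentItemset` closures for every maximal gene set
    ``G`` with ``|G| >= min_row`` covering at least ``min_col`` columns.
    ``min_col`` only prunes the search: because column coverage is antitone
    in the gene set, the surviving outputs are identical to post-filtering a
    ``min_col=2`` enumeration (2 being the minimum for any bicluster).
    Output order: support size descending, then sorted gene tuple.
    """
    n_genes = db.matrix.n_genes
    n_items = len(db.items)
    if n_items == 0:
        return []

    # vertical layout: per gene, bitmask of items containing it
    items_of_gene = [0] * n_genes
    for item_pos, gmask in enumerate(db.item_gene_masks):
        bit = 1 << item_pos
        m = gmask
        while m:
            low = m & -m
            items_of_gene[low.bit_length() - 1] |= bit
            m ^= low

    cond_ids = list(db.matrix.condition_ids)
    cond_pos = {c: j for j, c in enumerate(cond_ids)}
    col_items = [0] * len(cond_ids)  # per column, bitmask of its items
    for item_pos, it in enumerate(db.items):
        col_items[cond_pos[it.condition]] |= 1 << item_pos

    n_cols = len(cond_ids)

    def columns_of(t_mask: int) -> int:
        c = 0
        for j in range(n_cols):
            if t_mask & col_items[j]:
                c |= 1 << j
        return c

    all_items_mask = (1 << n_items) - 1
    min_cols_considered = max(2, min_col)  # >= 2 columns by definition

    results: dict = {}

    def is_maximal(g_mask: int, t_mask: int, c_mask: int) -> bool:
        for g in range(n_genes):
            if g_mask >> g & 1:
                continue
            if columns_of(t_mask & items_of_gene[g]) == c_mask:
                return False
        return True

    def dfs(g_mask: int, g_count: int, t_mask: int, c_mask: int, candidates: list):
        # absorb candidates present in every item of the closure
        feas = []
        for g in candidates:
            t2 = t_mask & items_of_gene[g]
            if t2 == t_mask:
                g_mask |= 1 << g
                g_count += 1
                continue
            c2 = columns_of(t2)
            if c2.bit_count() >= min_cols_considered:
                feas.append((g, t2, c2))
        if g_count + len(feas) < min_row:
            return
        if g_count >= min_row and is_maximal(g_mask, t_mask, c_mask):
            results.setdefault(g_mask, (t_mask, c_mask))
        for i, (g, t2, c2) in enumerate(feas):
            dfs(g_mask | (1 << g), g_count + 1, t2, c2,
                [h for h, _, _ in feas[i + 1:]])

    dfs(0, 0, all_items_mask, columns_of(all_items_mask), list(range(n_genes)))

    out = []
    for g_mask, (t_mask, c_mask) in results.items():
        out.append(
            FrequentItemset(
                item_ids=frozenset(
                    db.items[i].item_id for i in range(n_items) if t_mask >> i & 1
                ),
                support_genes=db.genes_of_mask(g_mask),
                conditions=frozenset(
                    cond_ids[j] for j in range(n_cols) if c_mask >> j & 1
                ),
            )
        )
    out.sort(key=lambda fs: (-len(fs.support_genes), tuple(sorted(fs.support_genes))))
    return out


def itemsets_to_biclusters(
    itemsets,
    db: TransactionDB,
    params: PipelineParams,
) -> list:
    """Project maximal itemsets to candidate biclusters.

    Itemsets spanning fewer than ``min_col`` distinct conditions are dropped;
    duplicate (genes, conditions) projections are collapsed.  Each output is
    checked against the column-coherence contract (value range of member
    genes <= MAX_DIFF in every member column, on the clipped matrix).
    """
    seen = set()
    out = []
    for fs in itemsets:
        key = (fs.support_genes, fs.conditions)
        if len(fs.conditions) < params.min_col or key in seen:
            continue
        seen.add(key)
        out.append(Bicluster(genes=fs.support_genes, conditions=fs.conditions))
    for b in out:
        _assert_coherent(b, db)
    out.sort(key=bicluster_sort_key)
    return out


def _assert_coherent(b: Bicluster, db: TransactionDB, rtol: float = 1e-9) -> None:
    rows = db.matrix.gene_index(b.genes)
    for cond in b.conditions:
        j = db.matrix.condition_index([cond])[0]
        vals = db.clipped[rows, j]
        md = db.column_stats[cond].max_diff
        if vals.max() - vals.min() > md * (1 + rtol):
            raise AssertionError(
                f"bicluster violates column coherence on {cond!r}: "
                f"range {vals.max() - vals.min():.6g} > MAX_DIFF {md:.6g}"
            )
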