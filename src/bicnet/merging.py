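"""Merging of redundant biclusters that share an identical condition set.

Exhaustive enumeration produces heavily overlapping biclusters.  Merging
collapses each *merge group* — biclusters with exactly the same condition
set, connected through gene overlap — into a single larger bicluster while
keeping the empirical p-value at or below ``alpha``:

1. the group's *seed* is its member with the smallest p-value;
2. a centroid vector ``v`` is formed as the per-condition mean of the seed
   genes' expression over the group's conditions;
3. the remaining genes of the group's union are ranked by Pearson
   correlation to ``v`` (descending), and a binary search over prefix
   lengths finds the largest prefix whose union with the seed still has
   p <= alpha.

The significance predicate over the prefix length need not be monotone;
binary search then returns a feasible prefix that a monotone predicate
would make the largest one (an exhaustive prefix scan documents this in the
test suite).  Screening p-values inside the search use a reduced
permutation count (a prefix of the per-shape null cache); the final merged
bicluster is re-scored at the full count, and shrunk if the re-score ever
lands above ``alpha``, so the output contract p <= alpha is unconditional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Bicluster, ExpressionMatrix, PipelineParams, bicluster_sort_key
from .significance import NullCache, empirical_pvalue, pearson_r

__all__ = [
    "MergeGroup",
    "build_merge_groups",
    "largest_feasible_prefix",
    "merge_group",
    "merge_all",
]


@dataclass
class MergeGroup:
    conditions: frozenset
    members: list  # biclusters with exactly these conditions, gene-connected

    @property
    def union_genes(self) -> frozenset:
        out: frozenset = frozenset()
        for b in self.members:
            out |= b.genes
        return out


def build_merge_groups(biclusters) -> list:
    """Partition by exact condition set, then split each partition into
    connected components of the share-a-gene relation."""
    by_conditions: dict = {}
    for b in biclusters:
        by_conditions.setdefault(b.conditions, []).append(b)
    groups = []
    for conds in sorted(by_conditions, key=lambda c: tuple(sorted(c))):
        members = sorted(by_conditions[conds], key=bicluster_sort_key)
        for component in _gene_overlap_components(members):
            groups.append(MergeGroup(conditions=conds, members=component))
    return groups


def _gene_overlap_components(members) -> list:
    n = len(members)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if members[i].genes & members[j].genes:
                parent[find(i)] = find(j)
    comps: dict = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(members[i])
    return [comps[r] for r in sorted(comps)]


def largest_feasible_prefix(feasible, n: int) -> int:
    """Binary search for the largest k in [0, n] with feasible(k) True.

    Assumes feasible(0) holds.  For a monotone predicate (True up to some
    k*, False beyond) this returns exactly k*; otherwise it returns some
    feasible k, favouring long prefixes.
    """
    lo, hi = 0, n
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if feasible(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def merge_group(
    group: MergeGroup,
    matrix: ExpressionMatrix,
    params: PipelineParams,
    cache: NullCache,
) -> Bicluster:
    """Merge one group into a single bicluster with p <= alpha."""
    members = sorted(
        group.members,
        key=lambda b: (
            b.p_value if b.p_value is not None else float("inf"),
            -b.size,
            tuple(sorted(b.genes)),
        ),
    )
    seed = members[0]
    if seed.p_value is None:
        raise ValueError("merge requires scored biclusters")
    candidates = sorted(group.union_genes - seed.genes)
    if not candidates:
        return seed

    conds = sorted(group.conditions)
    col_idx = matrix.condition_index(conds)
    centroid = matrix.submatrix(seed.genes, conds).mean(axis=0)
    corr = {
        g: pearson_r(matrix.values[matrix.gene_index([g])[0], col_idx], centroid)
        for g in candidates
    }
    candidates.sort(key=lambda g: (-corr[g], g))

    n_search = min(params.search_n_perm, params.n_perm)
    seed_genes = seed.genes

    def merged_at(k: int) -> Bicluster:
        return Bicluster(
            genes=seed_genes | frozenset(candidates[:k]),
            conditions=group.conditions,
        )

    def feasible(k: int) -> bool:
        if k == 0:
            return True
        b = merged_at(k)
        return empirical_pvalue(b, matrix, n_search, cache) <= params.alpha

    k = largest_feasible_prefix(feasible, len(candidates))
    merged = merged_at(k)
    empirical_pvalue(merged, matrix, params.n_perm, cache)
    # screening used a null prefix; guarantee the contract at full n_perm
    while merged.p_value > params.alpha and k > 0:
        k -= 1
        merged = merged_at(k)
        empirical_pvalue(merged, matrix, params.n_perm, cache)
    if k == 0:
        return seed
    return merged


def merge_all(biclusters, matrix, params, cache) -> list:
    """One merged bicluster per group, de-duplicated, every p <= alpha."""
    merged = [
        merge_group(g, matrix, params, cache)
        for g in build_merge_groups(biclusters)
    ]
    seen = set()
    out = []
    for b in sorted(merged, key=bicluster_sort_key):
        key = (b.genes, b.conditions)
        if key in seen:
            continue
        seen.add(key)
        out.append(b)
    return out
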