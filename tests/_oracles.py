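"""Independent brute-force oracles used to check the fast implementations.

These deliberately avoid the package's algorithmic code paths: exhaustive
subset enumeration, literal double loops, and per-gene signature tallies.
They only reuse the package's *definitions* (clipping arithmetic) where the
quantity under test is downstream of them.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from bicnet.preprocessing import clip_outliers, compute_max_diff, sd_filter


def maximal_coherent_submatrices(matrix, params):
    """All maximal coherent (gene set, condition set) pairs by exhaustion.

    A pair is coherent when, in every selected column, the genes survive the
    SD filter and their clipped values span at most MAX_DIFF.  Maximality is
    checked by explicit domination over all candidate pairs.
    Feasible up to ~12 genes.
    """
    n, m = matrix.values.shape
    cols = []
    for j in range(m):
        clipped, mean, sd = clip_outliers(matrix.values[:, j])
        if sd == 0:
            cols.append(None)
            continue
        md = compute_max_diff(sd, params.bins)
        mask = sd_filter(clipped, mean, sd, params.sd_coeff)
        cols.append((clipped, md, mask))
    candidates = {}
    for r in range(params.min_row, n + 1):
        for genes in itertools.combinations(range(n), r):
            ok = []
            for j in range(m):
                if cols[j] is None:
                    continue
                clipped, md, mask = cols[j]
                if not all(mask[g] for g in genes):
                    continue
                vals = clipped[list(genes)]
                if vals.max() - vals.min() <= md:
                    ok.append(j)
            if len(ok) >= params.min_col:
                candidates[frozenset(genes)] = frozenset(ok)
    out = set()
    for genes, conds in candidates.items():
        dominated = any(
            g2 > genes and c2 >= conds
            for g2, c2 in candidates.items()
            if g2 != genes
        )
        if not dominated:
            out.add((
                frozenset(matrix.gene_ids[g] for g in genes),
                frozenset(matrix.condition_ids[j] for j in conds),
            ))
    return out


def pairwise_average_correlation(rows) -> float:
    """Literal double loop over unordered row pairs; zero-variance rows
    contribute r = 0."""
    rows = np.asarray(rows, dtype=float)
    R = rows.shape[0]
    total = 0.0
    for i in range(R):
        for j in range(i + 1, R):
            x, y = rows[i], rows[j]
            xc, yc = x - x.mean(), y - y.mean()
            nx = math.sqrt(float(xc @ xc))
            ny = math.sqrt(float(yc @ yc))
            total += 0.0 if nx == 0 or ny == 0 else float(xc @ yc) / (nx * ny)
    return total * 2.0 / (R * (R - 1))


def network_from_signatures(biclusters):
    """Signature-tally network oracle.

    Returns (node gene-partition, edge weights) where nodes are frozensets
    of genes keyed by their bicluster-membership signature and edges map
    frozenset({genes_u, genes_v}) -> weight.
    """
    signature = {}
    for idx, b in enumerate(biclusters):
        for g in b.genes:
            signature.setdefault(g, set()).add(idx)
    nodes = {}
    for g, sig in signature.items():
        nodes.setdefault(frozenset(sig), set()).add(g)
    node_list = [(sig, frozenset(genes)) for sig, genes in nodes.items()]
    edges = {}
    for (s1, g1), (s2, g2) in itertools.combinations(node_list, 2):
        w = len(s1 & s2)
        if w >= 1:
            edges[frozenset((g1, g2))] = w
    return {g for _, g in node_list}, edges


def largest_feasible_prefix_by_scan(feasible, n: int) -> int:
    """Exhaustive scan for the largest feasible k (0 assumed feasible)."""
    best = 0
    for k in range(n + 1):
        if feasible(k):
            best = k
    return best
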