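"""Model/Results front end for the full biclustering pipeline.

:class:`CoherentBiclustering` is constructed from an expression matrix (or
DataFrame / TSV file) plus the run parameters; :meth:`fit` executes

    preprocess -> mine maximal itemsets -> candidate biclusters
    -> empirical significance filter (p <= alpha) -> merge -> gene set networks

and returns a :class:`BiclusteringResults` holding every intermediate count,
the merged biclusters with their T statistics and p-values, the networks,
and writers for the standard output files.  A fixed ``seed`` makes the whole
fit bit-for-bit reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .core import (
    Bicluster,
    ExpressionMatrix,
    PipelineParams,
    read_expression_matrix,
    write_biclusters,
    write_biclusters_jsonl,
)
from .merging import build_merge_groups, merge_all
from .mining import itemsets_to_biclusters, mine_maximal
from .network import build_network, write_graphml, write_network_tables
from .preprocessing import generate_items
from .significance import NullCache, filter_significant, score_biclusters

logger = logging.getLogger("bicnet")

__all__ = ["CoherentBiclustering", "BiclusteringResults"]


class CoherentBiclustering:
    """Coherent-column biclustering of a genes x conditions matrix.

    Parameters mirror :class:`~bicnet.core.PipelineParams`; see there for
    meanings and defaults (min_row=30, min_col=3, bins=7, sd_coeff=0.7,
    alpha=0.05, n_perm=100000).

    Examples
    --------
    >>> from bicnet import CoherentBiclustering, fixtures
    >>> matrix, truth = fixtures.generate(fixtures.single_block_spec(seed=7))
    >>> model = CoherentBiclustering(matrix, min_row=10, n_perm=1000)
    >>> res = model.fit(seed=7)
    >>> len(res.biclusters) >= 1
    True
    """

    def __init__(self, matrix: ExpressionMatrix, **params):
        if not isinstance(matrix, ExpressionMatrix):
            raise TypeError(
                "matrix must be an ExpressionMatrix; use from_dataframe/from_tsv"
            )
        self.matrix = matrix
        self.params = PipelineParams(**params)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **params) -> "CoherentBiclustering":
        return cls(ExpressionMatrix.from_dataframe(df), **params)

    @classmethod
    def from_tsv(
        cls, path, missing_policy: str = "reject", **params
    ) -> "CoherentBiclustering":
        return cls(read_expression_matrix(path, missing_policy), **params)

    def fit(self, seed: int | None = None) -> "BiclusteringResults":
        """Run the full pipeline; ``seed`` overrides ``params.seed``."""
        params = self.params if seed is None else self.params.replace(seed=int(seed))
        matrix = self.matrix
        cache = NullCache(matrix, base_seed=params.seed)

        if params.min_row > matrix.n_genes:
            logger.info("min_row exceeds gene count; trivially empty result")
            return BiclusteringResults(self, params, [], [], [], [], 0)

        db = generate_items(matrix, params)
        itemsets = mine_maximal(db, params.min_row, params.min_col)
        candidates = itemsets_to_biclusters(itemsets, db, params)
        logger.info(
            "%d items, %d maximal itemsets, %d candidate biclusters",
            db.n_items, len(itemsets), len(candidates),
        )
        scored = score_biclusters(candidates, matrix, params.n_perm, cache)
        significant = filter_significant(scored, params.alpha)
        merged = merge_all(significant, matrix, params, cache)
        networks = build_network(merged) if merged else []
        return BiclusteringResults(
            self, params, scored, significant, merged, networks, db.n_items
        )


class BiclusteringResults:
    """Estimates and diagnostics of one fitted biclustering run.

    Attributes
    ----------
    raw_biclusters
        All scored candidates from maximal itemset mining.
    significant_biclusters
        Candidates surviving the p <= alpha filter, most significant first.
    biclusters
        The merged biclusters (the headline output), each with ``t_stat``
        and ``p_value``, every p <= alpha.
    networks
        Gene set networks (connected components, largest first) built from
        the merged biclusters.
    """

    def __init__(self, model, params, raw, significant, merged, networks, n_items):
        self.model = model
        self.params = params
        self.raw_biclusters = raw
        self.significant_biclusters = significant
        self.biclusters = merged
        self.networks = networks
        self.n_items = n_items

    @property
    def merge_groups(self):
        return build_merge_groups(self.significant_biclusters)

    def summary(self) -> str:
        """Plain-text run summary, statsmodels-style."""
        m = self.model.matrix
        p = self.params
        lines = [
            "Coherent-column biclustering results",
            "=" * 52,
            f"matrix:                {m.n_genes} genes x {m.n_conditions} conditions",
            f"params:                min_row={p.min_row} min_col={p.min_col} "
            f"bins={p.bins} sd_coeff={p.sd_coeff}",
            f"                       alpha={p.alpha} n_perm={p.n_perm} seed={p.seed}",
            f"items generated:       {self.n_items}",
            f"candidate biclusters:  {len(self.raw_biclusters)}",
            f"significant (p<=a):    {len(self.significant_biclusters)}",
            f"merged biclusters:     {len(self.biclusters)}",
            f"gene set networks:     {len(self.networks)}"
            + (f" (nodes: {', '.join(str(n.n_nodes) for n in self.networks)})"
               if self.networks else ""),
        ]
        if self.biclusters:
            lines.append("-" * 52)
            lines.append("top merged biclusters (by size):")
            lines.append("  genes x conds      T        p")
            for b in self.biclusters[:10]:
                lines.append(
                    f"  {b.n_genes:5d} x {b.n_conditions:<5d}"
                    f"  {b.t_stat:8.4f}  {b.p_value:8.5f}"
                )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Merged biclusters as a tidy DataFrame."""
        return pd.DataFrame(
            [
                {
                    "n_genes": b.n_genes,
                    "n_conditions": b.n_conditions,
                    "size": b.size,
                    "t_stat": b.t_stat,
                    "p_value": b.p_value,
                    "genes": ",".join(b.sorted_genes()),
                    "conditions": ",".join(b.sorted_conditions()),
                }
                for b in self.biclusters
            ]
        )

    def save(self, out_dir, order: str = "by_size") -> None:
        """Write the standard output bundle into ``out_dir``.

        biclusters.tsv / biclusters.jsonl (merged), candidates.tsv (all
        significant, pre-merge), networks.graphml, nodes.tsv / edges.tsv and
        per-node gene lists, plus params.json echoing the run parameters.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_biclusters(self.biclusters, out_dir / "biclusters.tsv", order=order)
        write_biclusters_jsonl(self.biclusters, out_dir / "biclusters.jsonl", order=order)
        write_biclusters(
            self.significant_biclusters, out_dir / "candidates.tsv", order=order
        )
        if self.networks:
            write_graphml(self.networks, out_dir / "networks.graphml")
            write_network_tables(self.networks, out_dir / "network")
        (out_dir / "params.json").write_text(
            json.dumps(asdict(self.params), indent=2) + "\n"
        )
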