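"""Core containers for coherent-column biclustering.

The whole package operates on a single input object, :class:`ExpressionMatrix`
(genes x experimental conditions, real-valued), and produces
:class:`Bicluster` objects: pairs of a gene set and a condition set such that,
within every selected condition, the member genes' expression values differ by
at most a per-condition coherence width (``MAX_DIFF``).  Run-wide knobs live in
:class:`PipelineParams`.

Files are exchanged as plain tab-separated text: the matrix as a TSV with a
header row of condition names and a first column of gene identifiers;
biclusters as TSV or JSON-lines records.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("bicnet")

__all__ = [
    "ExpressionMatrix",
    "PipelineParams",
    "Bicluster",
    "MatrixFormatError",
    "DegenerateInputError",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_biclusters",
    "write_biclusters_jsonl",
    "read_biclusters_jsonl",
    "bicluster_sort_key",
]


class MatrixFormatError(ValueError):
    """The input file violates the expected TSV matrix layout."""


class DegenerateInputError(ValueError):
    """Input too small or empty after cleaning to be analysed."""


class ExpressionMatrix:
    """A named genes x conditions matrix of finite real expression values.

    Parameters
    ----------
    values
        2-D array-like, one row per gene, one column per condition.
    gene_ids, condition_ids
        Unique, ordered identifiers for rows and columns.

    Invariants enforced at construction: at least 2 genes and 2 conditions,
    no duplicate identifiers, every value finite.
    """

    def __init__(
        self,
        values: np.ndarray,
        gene_ids: Sequence[str],
        condition_ids: Sequence[str],
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise MatrixFormatError("expression values must form a 2-D matrix")
        gene_ids = tuple(str(g) for g in gene_ids)
        condition_ids = tuple(str(c) for c in condition_ids)
        if values.shape != (len(gene_ids), len(condition_ids)):
            raise MatrixFormatError(
                f"shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(condition_ids)} conditions"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise MatrixFormatError("duplicate gene identifiers")
        if len(set(condition_ids)) != len(condition_ids):
            raise MatrixFormatError("duplicate condition identifiers")
        if values.shape[0] < 2 or values.shape[1] < 2:
            raise DegenerateInputError(
                "need at least 2 genes and 2 conditions, "
                f"got {values.shape[0]} x {values.shape[1]}"
            )
        if not np.all(np.isfinite(values)):
            raise MatrixFormatError("expression values must all be finite")
        self.values = values
        self.values.setflags(write=False)
        self.gene_ids = gene_ids
        self.condition_ids = condition_ids
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}
        self._condition_index = {c: j for j, c in enumerate(condition_ids)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices for the given gene ids, in matrix (row) order."""
        idx = sorted(self._gene_index[g] for g in genes)
        return np.asarray(idx, dtype=int)

    def condition_index(self, conditions: Iterable[str]) -> np.ndarray:
        """Column indices for the given condition ids, in matrix order."""
        idx = sorted(self._condition_index[c] for c in conditions)
        return np.asarray(idx, dtype=int)

    def submatrix(self, genes: Iterable[str], conditions: Iterable[str]) -> np.ndarray:
        """Dense value block for a gene set x condition set, in matrix order."""
        return self.values[np.ix_(self.gene_index(genes), self.condition_index(conditions))]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), df.index, df.columns)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.array(self.values), index=list(self.gene_ids), columns=list(self.condition_ids)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_conditions} conditions)"


@dataclass(frozen=True)
class PipelineParams:
    """Run-wide parameters.

    Attributes
    ----------
    min_row
        Minimum number of genes (rows) a bicluster must contain.
    min_col
        Minimum number of experimental conditions (columns).
    bins
        Number of windows spanning a column's value range; the per-column
        coherence width is ``MAX_DIFF = 6*SD/bins`` after outlier clipping.
    sd_coeff
        Values within ``sd_coeff*SD`` of the column mean are treated as
        undifferentiated and removed before item generation.
    alpha
        Significance level on the empirical p-value used both to filter
        candidate biclusters and as the ceiling while merging.
    n_perm
        Number of random same-shape submatrices drawn to build each null
        distribution of the coherence statistic T.
    search_n_perm
        Cheaper permutation count used inside the merge binary search;
        capped at ``n_perm``. The final merged bicluster is re-scored at
        ``n_perm``.
    seed
        Base seed for every source of randomness in a run.
    """

    min_row: int = 30
    min_col: int = 3
    bins: int = 7
    sd_coeff: float = 0.7
    alpha: float = 0.05
    n_perm: int = 100_000
    search_n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_row < 2:
            raise ValueError("min_row must be >= 2")
        if self.min_col < 2:
            raise ValueError("min_col must be >= 2")
        if self.bins < 1:
            raise ValueError("bins must be >= 1")
        if self.sd_coeff < 0:
            raise ValueError("sd_coeff must be non-negative")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_perm < 1 or self.search_n_perm < 1:
            raise ValueError("permutation counts must be positive")

    def replace(self, **kw) -> "PipelineParams":
        return replace(self, **kw)


@dataclass
class Bicluster:
    """A (gene set, condition set) pair, optionally scored.

    ``t_stat`` is the average pairwise Pearson correlation of the member
    genes' expression row vectors restricted to the member conditions;
    ``p_value`` its upper-tail empirical p-value. Both are ``None`` until the
    bicluster has been scored.
    """

    genes: frozenset
    conditions: frozenset
    t_stat: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        self.conditions = frozenset(self.conditions)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def size(self) -> int:
        """Cell count |genes| x |conditions| — the notion of bicluster size."""
        return len(self.genes) * len(self.conditions)

    def cells(self) -> frozenset:
        return frozenset((g, c) for g in self.genes for c in self.conditions)

    def sorted_genes(self) -> list:
        return sorted(self.genes)

    def sorted_conditions(self) -> list:
        return sorted(self.conditions)


def bicluster_sort_key(b: Bicluster):
    """Global deterministic ordering: cell count desc, then p-value asc,
    then lexicographically smallest gene list."""
    p = b.p_value if b.p_value is not None else float("inf")
    return (-b.size, p, tuple(sorted(b.genes)), tuple(sorted(b.conditions)))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_matrix(path, missing_policy: str = "reject") -> ExpressionMatrix:
    """Read a TSV expression matrix (header = condition names, first column =
    gene identifiers).

    ``missing_policy`` is one of ``"reject"`` (any missing or non-numeric cell
    is an error) and ``"drop_rows"`` (offending gene rows are removed and
    logged).
    """
    if missing_policy not in ("reject", "drop_rows"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise MatrixFormatError(f"duplicate gene identifiers: {dups[:5]}")
    if df.columns.has_duplicates:
        raise MatrixFormatError("duplicate condition names in header")
    def _exact_float(x):
        # python float() round-trips repr() output exactly; pandas' fast
        # parser does not
        try:
            v = float(x)
        except (TypeError, ValueError):
            return np.nan
        return v

    numeric = df.apply(lambda col: col.map(_exact_float))
    bad_rows = numeric.isna().any(axis=1) | ~np.isfinite(numeric.fillna(0.0)).all(axis=1)
    if bad_rows.any():
        if missing_policy == "reject":
            raise MatrixFormatError(
                f"{int(bad_rows.sum())} rows contain missing/non-numeric values "
                f"(first: {numeric.index[bad_rows][0]!r}); "
                "use missing_policy='drop_rows' to discard them"
            )
        for g in numeric.index[bad_rows]:
            logger.warning("dropping gene %r: missing or non-numeric value", g)
        numeric = numeric.loc[~bad_rows]
    if numeric.shape[0] < 2 or numeric.shape[1] < 2:
        raise DegenerateInputError(
            f"matrix is {numeric.shape[0]} x {numeric.shape[1]} after cleaning; "
            "need at least 2 x 2"
        )
    return ExpressionMatrix.from_dataframe(numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write the standard TSV dialect; values round-trip exactly (repr)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\t" + "\t".join(matrix.condition_ids) + "\n")
        for i, g in enumerate(matrix.gene_ids):
            row = "\t".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{g}\t{row}\n")


_BICLUSTER_COLUMNS = [
    "genes", "conditions", "n_genes", "n_conditions", "size", "t_stat", "p_value",
]


def _ordered(biclusters: Sequence[Bicluster], order: str) -> list:
    if order == "by_size":
        return sorted(biclusters, key=bicluster_sort_key)
    if order == "by_pvalue":
        for b in biclusters:
            if b.p_value is None:
                raise ValueError("order='by_pvalue' requires scored biclusters")
        return sorted(
            biclusters,
            key=lambda b: (b.p_value, -b.size, tuple(sorted(b.genes))),
        )
    raise ValueError(f"unknown order {order!r}")


def write_biclusters(biclusters: Sequence[Bicluster], path, order: str = "by_size") -> None:
    """Write one TSV record per bicluster (gene list, condition list, shape,
    statistic, p-value), largest-first or most-significant-first."""
    rows = []
    for b in _ordered(biclusters, order):
        rows.append({
            "genes": ",".join(b.sorted_genes()),
            "conditions": ",".join(b.sorted_conditions()),
            "n_genes": b.n_genes,
            "n_conditions": b.n_conditions,
            "size": b.size,
            "t_stat": "" if b.t_stat is None else repr(float(b.t_stat)),
            "p_value": "" if b.p_value is None else repr(float(b.p_value)),
        })
    pd.DataFrame(rows, columns=_BICLUSTER_COLUMNS).to_csv(path, sep="\t", index=False)


def write_biclusters_jsonl(biclusters: Sequence[Bicluster], path, order: str = "by_size") -> None:
    with Path(path).open("w") as fh:
        for b in _ordered(biclusters, order):
            rec = {
                "genes": b.sorted_genes(),
                "conditions": b.sorted_conditions(),
                "t_stat": None if b.t_stat is None else float(b.t_stat),
                "p_value": None if b.p_value is None else float(b.p_value),
            }
            fh.write(json.dumps(rec) + "\n")


def read_biclusters_jsonl(path) -> list:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            out.append(
                Bicluster(
                    genes=frozenset(rec["genes"]),
                    conditions=frozenset(rec["conditions"]),
                    t_stat=rec.get("t_stat"),
                    p_value=rec.get("p_value"),
                )
            )
    return out
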