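"""Pairwise Pearson correlation and the Mutual Rank coexpression measure.

For a gene pair (a, b), rank_a(b) is the 1-based position of b when all
genes other than a are sorted by descending correlation with a (ties broken
by ascending gene ID). The Mutual Rank is the geometric mean
MR(a, b) = sqrt(rank_a(b) * rank_b(a)); it is symmetric and lies in
[1, N-1] for N genes, with MR = 1 exactly for mutually best pairs. Lower
MR means stronger coexpression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .exprio import ExpressionMatrix

__all__ = [
    "CorrelationTable",
    "MutualRankTable",
    "CoexpressedGeneList",
    "pearson_all_pairs",
    "asymmetric_rank",
    "mutual_rank",
    "coexpressed_list",
]


@dataclass
class CorrelationTable:
    """Symmetric Pearson correlation matrix over a fixed gene order."""

    gene_ids: list[str]
    r: np.ndarray  # N x N, symmetric, unit diagonal

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.r.shape != (n, n):
            raise DataError("correlation matrix shape does not match gene list")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise DataError("correlation outside [-1, 1]")
        if len(set(self.gene_ids)) != n:
            raise DataError("duplicate gene IDs in correlation table")

    def index_of(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise DataError(f"unknown gene: {gene}") from None


@dataclass
class MutualRankTable:
    """Symmetric MR values plus the asymmetric ranks they derive from."""

    gene_ids: list[str]
    mr: np.ndarray      # N x N symmetric, 0 on the diagonal
    ranks: np.ndarray   # ranks[i, j] = rank of j in i's list (0 on diagonal)
    r: np.ndarray       # the underlying correlations
    _order: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise DataError(f"unknown gene: {gene}") from None

    def list_order(self) -> np.ndarray:
        """Row i: indices of all genes except i, ascending MR (ties by gene ID).

        Cached; this is the ordering of every coexpressed gene list at once.
        """
        if self._order is None:
            n = self.n_genes
            id_rank = np.argsort(np.argsort(np.asarray(self.gene_ids)))
            order = np.empty((n, n - 1), dtype=np.int64)
            idx = np.arange(n)
            for i in range(n):
                others = idx[idx != i]
                o = np.lexsort((id_rank[others], self.mr[i, others]))
                order[i] = others[o]
            self._order = order
        return self._order


@dataclass
class CoexpressedGeneList:
    """All genes ranked by ascending MR with one guide gene."""

    guide_gene: str
    entries: list[tuple[str, float, float]]  # (gene_id, mr, r), ascending MR

    def __len__(self) -> int:
        return len(self.entries)

    def gene_ids(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    def top(self, k: int) -> list[str]:
        return [g for g, _, _ in self.entries[:k]]


def pearson_all_pairs(expr: ExpressionMatrix) -> CorrelationTable:
    """Pearson correlation for every gene pair across all samples at once."""
    x = expr.values.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise DataError("need at least 3 samples for correlation")
    sd = x.std(axis=1)
    flat = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
    if flat:
        raise DataError(f"zero-variance gene(s), correlation undefined: {flat[:5]}")
    r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return CorrelationTable(list(expr.gene_ids), r)


def _rank_matrix(c: CorrelationTable) -> np.ndarray:
    """ranks[i, j]: 1-based rank of gene j in gene i's list; 0 on the diagonal.

    For each guide i, the other N-1 genes are sorted by descending r with i,
    ties broken by ascending gene ID.
    """
    n = len(c.gene_ids)
    id_rank = np.argsort(np.argsort(np.asarray(c.gene_ids)))
    ranks = np.zeros((n, n), dtype=np.int64)
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        order = np.lexsort((id_rank[others], -c.r[i, others]))
        ranks[i, others[order]] = np.arange(1, n)
    return ranks


def asymmetric_rank(c: CorrelationTable, guide: str, target: str) -> int:
    """1-based rank of ``target`` in ``guide``'s descending-correlation list."""
    gi, ti = c.index_of(guide), c.index_of(target)
    if gi == ti:
        raise DataError("guide and target must differ")
    r_row = c.r[gi]
    r_t = r_row[ti]
    rank = 1
    for j, gene in enumerate(c.gene_ids):
        if j in (gi, ti):
            continue
        if r_row[j] > r_t or (r_row[j] == r_t and gene < target):
            rank += 1
    return rank


def mutual_rank(c: CorrelationTable) -> MutualRankTable:
    """MR(a, b) = sqrt(rank_a(b) * rank_b(a)) for every unordered pair."""
    ranks = _rank_matrix(c)
    mr = np.sqrt(ranks.astype(float) * ranks.T.astype(float))
    return MutualRankTable(list(c.gene_ids), mr, ranks, c.r.copy())


def coexpressed_list(mrt: MutualRankTable, guide: str) -> CoexpressedGeneList:
    """All other genes sorted by ascending MR; MR ties broken by gene ID."""
    gi = mrt.index_of(guide)
    order = mrt.list_order()[gi]
    entries = [(mrt.gene_ids[j], float(mrt.mr[gi, j]), float(mrt.r[gi, j]))
               for j in order]
    return CoexpressedGeneList(guide, entries)
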