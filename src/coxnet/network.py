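"""Top-k coexpression networks and cross-platform common-edge counting.

A coexpression edge links a gene to one of its k lowest-MR partners
(k = 3 by default). Edges are stored undirected: a pair selected from both
endpoints counts once. An edge of platform A is "common" with platform B
when some combination of its endpoints' correspondents (same gene within a
species, ortholog-group members across species) is an edge of B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import DataError
from .exprio import OrthologMap, Platform
from .coexpression import MutualRankTable

__all__ = [
    "EdgeSet",
    "CommonEdgeSummary",
    "top_k_edges",
    "map_gene",
    "gene_correspondence",
    "common_edges",
]


@dataclass
class EdgeSet:
    """Undirected top-k coexpression edges of one platform."""

    platform: str
    edges: dict[tuple[str, str], float]  # (gene_a, gene_b) with gene_a < gene_b -> MR
    k: int

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if not a < b:
                raise DataError(f"edge key not ordered: ({a}, {b})")

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a < b else (b, a)) in self.edges

    def gene_ids(self) -> set[str]:
        return {g for e in self.edges for g in e}


@dataclass
class CommonEdgeSummary:
    """Edges of platform A reproduced in platform B (A is the denominator)."""

    platform_a: str
    platform_b: str
    edges_a: int
    shared: int

    @property
    def ratio(self) -> float:
        return self.shared / self.edges_a if self.edges_a else 0.0


def top_k_edges(mrt: MutualRankTable, k: int = 3, platform: str = "") -> EdgeSet:
    """Union over genes of each gene's k lowest-MR partners, de-duplicated."""
    n = mrt.n_genes
    if not 1 <= k <= n - 1:
        raise DataError(f"k must be in [1, {n - 1}], got {k}")
    order = mrt.list_order()
    edges: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in order[i, :k]:
            a, b = mrt.gene_ids[i], mrt.gene_ids[j]
            key = (a, b) if a < b else (b, a)
            edges.setdefault(key, float(mrt.mr[i, j]))
    return EdgeSet(platform=platform, edges=edges, k=k)


def map_gene(omap: OrthologMap, from_platform: Platform, gene: str,
             to_platform: Platform) -> set[str]:
    """Correspondents of ``gene`` on the target platform.

    Same species: the identical gene, if present in the target universe.
    Different species: all target-platform genes sharing the ortholog
    group. The empty set signals "no correspondent".
    """
    if from_platform.species == to_platform.species:
        return {gene} if gene in to_platform.gene_universe else set()
    group = omap.group(from_platform.dataset_id, gene)
    if group is None:
        return set()
    return omap.genes_in_group(to_platform.dataset_id, group) & to_platform.gene_universe


def gene_correspondence(omap: OrthologMap, from_platform: Platform,
                        to_platform: Platform) -> Callable[[str], set[str]]:
    """Per-gene correspondence function from platform A into platform B."""
    def corr(gene: str) -> set[str]:
        return map_gene(omap, from_platform, gene, to_platform)
    return corr


def common_edges(a: EdgeSet, b: EdgeSet, omap: OrthologMap,
                 platform_a: Platform, platform_b: Platform) -> CommonEdgeSummary:
    """Count edges of ``a`` that appear in ``b`` after gene mapping.

    An edge (x, y) of A is shared when some x' in map(x), y' in map(y)
    with (x', y') an edge of B; paralogs expand the match set. The summary
    is asymmetric: A's edge count is the denominator.
    """
    corr = gene_correspondence(omap, platform_a, platform_b)
    cache: dict[str, set[str]] = {}

    def mapped(g: str) -> set[str]:
        if g not in cache:
            cache[g] = corr(g)
        return cache[g]

    shared = 0
    for x, y in a.edges:
        xs, ys = mapped(x), mapped(y)
        if any((xp, yp) in b for xp in xs for yp in ys):
            shared += 1
    return CommonEdgeSummary(a.platform, b.platform, len(a), shared)
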