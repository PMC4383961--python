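"""COXSIM concordance, maxCOXSIM, the size-matched null, and star ratings.

COXSIM compares two coexpressed gene lists. For depth i, n(i) is the number
of genes among the top i of the guide list whose correspondents (same gene
within a species, orthologs across species) appear among the top i of the
reference list. Then

    COXSIM_k = sum_{i=1..k} n(i) / sum_{i=1..k} i,

a weighted concordance in [0, 1] that rewards agreement near the top of the
lists. The depth k is the top 1% of the guide list by default. maxCOXSIM is
the maximum over all admissible reference guide genes (orthologs on
cross-species platforms; the identical gene on same-species platforms).

Significance is assessed against a null in which both lists are uniformly
random orderings joined by a random one-to-one correspondence. Under that
null the correspondent positions of the guide's top-k genes are a uniform
random injection into the N reference positions, so n(i) is hypergeometric
with E n(i) = i^2 / N. The distribution of the integer numerator
S = sum_i n(i) is computed EXACTLY by dynamic programming over partial
permutations of the k x k top-list grid (matched pairs live on L-shaped
layers max(depth, position) = i and contribute k + 1 - i each), which
yields P-values to full floating-point depth — far below the three-star
threshold of 1e-32 — without tail extrapolation. A seeded Monte-Carlo
sampler of the same null is kept alongside for diagnostics and
cross-validation of the exact distribution. The star rating thresholds the
P-value of maxCOXSIM at 1e-4, 1e-16 and 1e-32 (one, two, three stars).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from .errors import ConfigError, DataError
from .exprio import OrthologMap, Platform
from .coexpression import CoexpressedGeneList, MutualRankTable
from .network import map_gene

__all__ = [
    "CoxsimConfig",
    "SupportabilityResult",
    "NullModel",
    "exact_null_sf",
    "overlap_counts",
    "coxsim",
    "resolve_k",
    "max_coxsim",
    "null_distribution",
    "p_value",
    "stars",
    "assess_supportability",
]


@dataclass
class CoxsimConfig:
    """Parameters of the supportability assessment.

    k_fraction : depth of list comparison as a fraction of the guide list
        (default 0.01, i.e. the top 1%).
    star_thresholds : strictly decreasing P-value cutoffs for 1, 2, 3 stars.
    null_reps : Monte-Carlo replicates for the null distribution.
    sidak : correct the maxCOXSIM P-value for the number of references
        tried, P_max = 1 - (1 - p)^n_refs. On by default.
    """

    k_fraction: float = 0.01
    star_thresholds: tuple[float, float, float] = (1e-4, 1e-16, 1e-32)
    null_reps: int = 10_000
    seed: int = 0
    sidak: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.k_fraction <= 1:
            raise ConfigError("k_fraction must be in (0, 1]")
        t = self.star_thresholds
        if not (t[0] > t[1] > t[2] > 0):
            raise ConfigError("star thresholds must be strictly decreasing")
        if self.null_reps < 100:
            raise ConfigError("null_reps must be >= 100")


@dataclass
class SupportabilityResult:
    """Supportability of one guide gene's coexpressed list."""

    guide_gene: str
    best_reference: tuple[str, str] | None  # (platform, gene) or None
    max_coxsim: float
    p_value: float
    stars: int
    n_refs: int = 0


def _as_gene_seq(lst) -> list[str]:
    if isinstance(lst, CoexpressedGeneList):
        return lst.gene_ids()
    return list(lst)


def _as_corr_fn(mapping) -> Callable[[str], set[str]]:
    if callable(mapping):
        return lambda g: set(mapping(g))
    if isinstance(mapping, Mapping):
        return lambda g: set(mapping.get(g, ()))
    raise DataError("correspondence must be a mapping or callable")


def overlap_counts(list_g, list_r, mapping, k: int) -> np.ndarray:
    """n(i) for i = 1..k: guide top-i genes with a correspondent in reference top-i.

    ``mapping`` sends a guide-platform gene to its set of reference-platform
    correspondents (dict of sets, or a callable).
    """
    genes_g, genes_r = _as_gene_seq(list_g), _as_gene_seq(list_r)
    if k > len(genes_g) or k > len(genes_r):
        raise DataError(f"k={k} exceeds a list length "
                        f"({len(genes_g)}, {len(genes_r)})")
    corr = _as_corr_fn(mapping)
    pos_r = {g: i for i, g in enumerate(genes_r[:k], start=1)}
    n = np.zeros(k, dtype=np.int64)
    # match_depth[j]: smallest i at which guide gene j (position j+1) is matched
    for j, g in enumerate(genes_g[:k]):
        positions = [pos_r[t] for t in corr(g) if t in pos_r]
        if positions:
            depth = max(j + 1, min(positions))
            n[depth - 1:] += 1
    return n


def coxsim(list_g, list_r, mapping, k: int) -> float:
    """Weighted list concordance: sum_i n(i) over the maximum sum_i i."""
    n = overlap_counts(list_g, list_r, mapping, k)
    return float(n.sum()) / (k * (k + 1) / 2)


def resolve_k(n_genes_g: int, k_fraction: float = 0.01) -> int:
    """Comparison depth: round-half-up of fraction x list length, at least 1."""
    if n_genes_g < 1:
        raise DataError("list must contain at least one gene")
    k = int(np.floor(k_fraction * n_genes_g + 0.5))
    return max(1, min(k, n_genes_g))


def _candidate_references(guide: str, own_platform: Platform,
                          ref_platform: Platform, ref_genes: set[str],
                          omap: OrthologMap) -> set[str]:
    cands = map_gene(omap, own_platform, guide, ref_platform)
    return cands & ref_genes


def max_coxsim(guide: str, own_platform: Platform, own_mrt: MutualRankTable,
               references: Iterable[tuple[Platform, MutualRankTable]],
               omap: OrthologMap, cfg: CoxsimConfig | None = None,
               ) -> tuple[tuple[str, str] | None, float, int]:
    """Best reference guide gene and its COXSIM; also the number tried.

    Enumerates every admissible reference guide gene over all reference
    platforms, computes COXSIM for each, and returns
    ``((platform, gene), value, n_refs)``. With no admissible reference the
    result is ``(None, nan, 0)`` — the "no reference" case.
    """
    cfg = cfg or CoxsimConfig()
    gi = own_mrt.index_of(guide)
    order_g = own_mrt.list_order()[gi]
    n_g = len(order_g)
    k = resolve_k(n_g, cfg.k_fraction)
    top_g = [own_mrt.gene_ids[j] for j in order_g[:k]]

    best: tuple[str, str] | None = None
    best_val = float("nan")
    n_refs = 0
    for ref_platform, ref_mrt in references:
        ref_genes = set(ref_mrt.gene_ids)
        corr = {g: map_gene(omap, own_platform, g, ref_platform) & ref_genes
                for g in top_g}
        for ref_gene in sorted(_candidate_references(
                guide, own_platform, ref_platform, ref_genes, omap)):
            ri = ref_mrt.index_of(ref_gene)
            order_r = ref_mrt.list_order()[ri]
            if k > len(order_r):
                continue
            top_r = [ref_mrt.gene_ids[j] for j in order_r[:k]]
            val = coxsim(top_g, top_r, corr, k)
            n_refs += 1
            if best is None or val > best_val:
                best = (ref_platform.dataset_id, ref_gene)
                best_val = val
    return best, best_val, n_refs


def exact_null_sf(k: int, n_genes_r: int) -> np.ndarray:
    """Exact survival function of the null numerator S = sum_i n(i).

    Returns ``sf`` with ``sf[s] = P(S >= s)`` for s = 0 .. k(k+1)/2.

    Under the null the correspondent positions of the guide's top-k genes
    form a uniform random injection into the N = n_genes_r reference
    positions; matched pairs are the ones landing within the reference
    top-k. A pair at (depth d, position p) contributes k + 1 - max(d, p)
    to S. The set of matched pairs is a partial permutation of the k x k
    grid, built up layer by layer over max(d, p) = i: given t pairs already
    inside the (i-1) x (i-1) box, layer i can take the corner cell (i, i),
    one of the i-1-t free cells in row i or column i, or one of each.
    Probability weights 1/(N - t) per added pair and the exit factors for
    the k - t unmatched genes make the recursion an exact distribution
    (mass sums to 1 up to float rounding).
    """
    n = n_genes_r
    if k < 1 or k > n:
        raise DataError(f"degenerate sizes: k={k}, N={n}")
    smax = k * (k + 1) // 2
    h = np.zeros((k + 1, smax + 1))
    h[0, 0] = 1.0
    for i in range(1, k + 1):
        new = np.zeros_like(h)
        sc = k + 1 - i
        for t in range(0, i):
            row = h[t]
            if not row.any():
                continue
            free = i - 1 - t
            new[t] += row
            w1 = (1 + 2 * free) / (n - t)
            new[t + 1, sc:] += row[: smax + 1 - sc] * w1
            if free > 0 and t + 2 <= k:
                w2 = free * free / ((n - t) * (n - t - 1))
                new[t + 2, 2 * sc:] += row[: smax + 1 - 2 * sc] * w2
        new[i:] += h[i:]
        h = new
    # the k - t guide genes without a top-k match land outside the top-k
    for t in range(0, k + 1):
        f = 1.0
        for j in range(0, k - t):
            f *= (n - k - j) / (n - t - j)
        h[t] *= f
    pmf = h.sum(axis=0)
    return np.cumsum(pmf[::-1])[::-1]


@dataclass
class NullModel:
    """Null distribution of COXSIM for size-matched random lists.

    ``exact_sf[s]`` is the exact P(S >= s) for the integer numerator;
    ``samples`` holds seeded Monte-Carlo COXSIM draws of the same null for
    diagnostics and cross-checks.
    """

    k: int
    n_genes_g: int
    n_genes_r: int
    n_refs: int
    reps: int
    seed: int
    samples: np.ndarray = field(repr=False)
    exact_sf: np.ndarray = field(repr=False)

    @property
    def denom(self) -> float:
        return self.k * (self.k + 1) / 2

    @property
    def analytic_mean(self) -> float:
        """E COXSIM = (sum_i i^2 / N) / (sum_i i) = (2k+1)/(3N) exactly."""
        i = np.arange(1, self.k + 1)
        return float(np.sum(i**2) / self.n_genes_r / self.denom)

    def sf(self, observed: float) -> float:
        """P(COXSIM >= observed) under the null, from the exact distribution."""
        s_obs = int(np.ceil(observed * self.denom - 1e-9))
        s_obs = max(0, min(s_obs, len(self.exact_sf) - 1))
        if s_obs == 0:
            return 1.0
        return float(min(1.0, self.exact_sf[s_obs]))


def null_distribution(n_genes_g: int, n_genes_r: int, n_refs: int, k: int,
                      cfg: CoxsimConfig | None = None) -> NullModel:
    """Null of COXSIM for random lists of the stated sizes.

    Computes the exact distribution of the numerator (see
    :func:`exact_null_sf`) and draws ``cfg.null_reps`` seeded Monte-Carlo
    replicates of the same null. Each replicate corresponds to two
    uniformly random ranked lists joined by a random one-to-one
    correspondence; only the correspondent positions of the guide's top-k
    genes matter, so the replicate is sampled in that reduced form: the
    number of matches m is Hypergeometric(N, k, k), matched guide depths
    and reference positions are uniform m-subsets of 1..k joined by a
    uniform bijection, and the numerator is the sum over matched pairs of
    (k + 1 - max(depth, position)).
    """
    cfg = cfg or CoxsimConfig()
    if k < 1 or k > min(n_genes_g, n_genes_r):
        raise DataError(f"degenerate sizes: k={k}, lists {n_genes_g}, {n_genes_r}")
    rng = np.random.default_rng(cfg.seed)
    denom = k * (k + 1) / 2
    m = rng.hypergeometric(k, n_genes_r - k, k, size=cfg.null_reps)
    sums = np.zeros(cfg.null_reps, dtype=np.int64)
    for t in range(cfg.null_reps):
        mt = int(m[t])
        if mt == 0:
            continue
        depths = rng.permutation(k)[:mt] + 1      # guide depths of matched genes
        positions = rng.permutation(k)[:mt] + 1   # their reference positions
        sums[t] = np.sum(k + 1 - np.maximum(depths, positions))
    samples = sums / denom
    return NullModel(k=k, n_genes_g=n_genes_g, n_genes_r=n_genes_r,
                     n_refs=n_refs, reps=cfg.null_reps, seed=cfg.seed,
                     samples=samples, exact_sf=exact_null_sf(k, n_genes_r))


def p_value(observed: float, null: NullModel, n_refs: int = 1) -> float:
    """P-value of an observed (max)COXSIM against the null.

    The per-reference tail probability comes from the exact null
    distribution and is corrected for maximization over
    ``n_refs`` references with the Sidak formula
    P_max = 1 - (1 - p)^n_refs, computed stably for tiny p; the result is
    clamped to (0, 1].
    """
    if not 0 <= observed <= 1 + 1e-12:
        raise DataError(f"observed COXSIM outside [0, 1]: {observed}")
    p = null.sf(observed)
    if n_refs > 1:
        p = float(-np.expm1(n_refs * np.log1p(-min(p, 1 - 1e-16))))
    return float(min(max(p, 1e-300), 1.0))


def stars(p: float, cfg: CoxsimConfig | None = None) -> int:
    """Star rating from a P-value: strict thresholds, 1e-4 / 1e-16 / 1e-32."""
    cfg = cfg or CoxsimConfig()
    one, two, three = cfg.star_thresholds
    if p < three:
        return 3
    if p < two:
        return 2
    if p < one:
        return 1
    return 0


def assess_supportability(guides: Sequence[str], own_platform: Platform,
                          own_mrt: MutualRankTable,
                          references: Sequence[tuple[Platform, MutualRankTable]],
                          omap: OrthologMap,
                          cfg: CoxsimConfig | None = None,
                          ) -> list[SupportabilityResult]:
    """Supportability (maxCOXSIM, P-value, stars) for a set of guide genes.

    Null models are built once per distinct (k, reference list length) and
    shared across guides. Guides without any admissible reference are
    reported with the "no reference" sentinel (best_reference None).
    """
    cfg = cfg or CoxsimConfig()
    null_cache: dict[tuple[int, int], NullModel] = {}
    results = []
    n_g = own_mrt.n_genes - 1
    k = resolve_k(n_g, cfg.k_fraction)
    ref_sizes = {p.dataset_id: mrt.n_genes - 1 for p, mrt in references}
    for guide in guides:
        best, val, n_refs = max_coxsim(guide, own_platform, own_mrt,
                                       references, omap, cfg)
        if best is None:
            results.append(SupportabilityResult(guide, None, float("nan"),
                                                float("nan"), 0, 0))
            continue
        n_r = ref_sizes[best[0]]
        key = (k, n_r)
        if key not in null_cache:
            null_cache[key] = null_distribution(n_g, n_r, n_refs, k, cfg)
        p = p_value(val, null_cache[key], n_refs if cfg.sidak else 1)
        results.append(SupportabilityResult(guide, best, val, p,
                                            stars(p, cfg), n_refs))
    return results
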