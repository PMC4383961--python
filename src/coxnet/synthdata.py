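"""Seeded synthetic count matrices with planted coexpression modules.

The generator emulates the statistical structure the pipeline assumes:
groups of genes sharing an expression program. Each module has one latent
factor per sample; a module gene's log2 abundance is its baseline plus
``within_module_corr`` times the factor plus independent Gaussian noise,
with mild per-experiment offsets so that per-experiment normalization and
centering have observable effect. Log-scale abundances are exponentiated,
scaled to a target library size per run and Poisson-sampled, giving the
mean-variance coupling of real counts. Everything is determined by the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .exprio import CountMatrix, OrthologMap

__all__ = [
    "SynthConfig",
    "generate_counts",
    "generate_counts_with_truth",
    "generate_platform_pair",
]


@dataclass
class SynthConfig:
    """Shape and signal strength of a synthetic platform.

    within_module_corr is the target pairwise log2-scale correlation between
    genes of the same module: the shared factor carries that fraction of the
    biological variance and independent noise the rest, so the realized
    correlation matches the parameter (up to Poisson sampling noise).
    noise_sd is the total biological standard deviation per gene (log2
    units). library_size_mean is the expected total counts per run.
    """

    n_genes: int = 1000
    n_samples: int = 200
    n_experiments: int = 10
    n_modules: int = 10
    module_size: int = 20
    within_module_corr: float = 0.8
    noise_sd: float = 0.6
    library_size_mean: float = 2e7
    seed: int = 0

    def __post_init__(self) -> None:
        # coerce types so YAML-sourced values (e.g. "1.0e6") behave
        for f in ("n_genes", "n_samples", "n_experiments", "n_modules",
                  "module_size", "seed"):
            setattr(self, f, int(getattr(self, f)))
        for f in ("within_module_corr", "noise_sd", "library_size_mean"):
            setattr(self, f, float(getattr(self, f)))
        if min(self.n_genes, self.n_samples, self.n_experiments,
               self.n_modules, self.module_size) < 1:
            raise ConfigError("all sizes must be >= 1")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigError("modules do not fit into the gene universe")
        if not 0 <= self.within_module_corr < 1:
            raise ConfigError("within_module_corr must be in [0, 1)")
        if self.n_experiments > self.n_samples:
            raise ConfigError("more experiments than samples")


def _experiment_blocks(cfg: SynthConfig, prefix: str) -> tuple[list[str], dict[str, str]]:
    runs = [f"{prefix}r{i:04d}" for i in range(cfg.n_samples)]
    bounds = np.linspace(0, cfg.n_samples, cfg.n_experiments + 1).astype(int)
    experiment_of = {}
    for e in range(cfg.n_experiments):
        for i in range(bounds[e], bounds[e + 1]):
            experiment_of[runs[i]] = f"{prefix}e{e:02d}"
    return runs, experiment_of


def _module_membership(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """module index per gene, -1 for background; seeded random placement."""
    membership = np.full(cfg.n_genes, -1, dtype=np.int64)
    chosen = rng.permutation(cfg.n_genes)[: cfg.n_modules * cfg.module_size]
    for m in range(cfg.n_modules):
        membership[chosen[m * cfg.module_size:(m + 1) * cfg.module_size]] = m
    return membership


def _sample_counts(cfg: SynthConfig, membership: np.ndarray,
                   rng: np.random.Generator, prefix: str) -> CountMatrix:
    runs, experiment_of = _experiment_blocks(cfg, prefix)
    genes = [f"{prefix}g{i:04d}" for i in range(cfg.n_genes)]
    exp_index = np.array([int(experiment_of[r][-2:]) for r in runs])

    base = rng.normal(5.0, 1.5, size=cfg.n_genes)           # log2 baseline
    exp_shift = rng.normal(0.0, 0.3, size=cfg.n_experiments)  # depth-like offsets
    gene_exp_shift = rng.normal(0.0, 0.2,
                                size=(cfg.n_genes, cfg.n_experiments))
    factors = rng.normal(size=(cfg.n_modules, cfg.n_samples))
    noise = rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_samples))

    # variance split: module genes share sqrt(c) of the biological sd with
    # their factor and keep sqrt(1-c) as independent noise, so the pairwise
    # log-scale correlation within a module equals within_module_corr
    c = cfg.within_module_corr
    scale_factor = cfg.noise_sd * np.sqrt(c)
    scale_noise = np.where(membership >= 0,
                           cfg.noise_sd * np.sqrt(1.0 - c), cfg.noise_sd)
    z = base[:, None] + exp_shift[exp_index][None, :] \
        + gene_exp_shift[:, exp_index] + scale_noise[:, None] * noise
    in_module = membership >= 0
    if in_module.any():
        z[in_module] += scale_factor * factors[membership[in_module]]

    lam = np.exp2(z)
    lib = cfg.library_size_mean * rng.lognormal(mean=-0.005, sigma=0.1,
                                                size=cfg.n_samples)
    lam *= lib / lam.sum(axis=0)
    counts = rng.poisson(lam).astype(np.int64)
    frame = pd.DataFrame(counts, index=genes, columns=runs)
    return CountMatrix(frame, experiment_of)


def generate_counts_with_truth(cfg: SynthConfig, prefix: str = "",
                               rng: np.random.Generator | None = None,
                               membership: np.ndarray | None = None,
                               ) -> tuple[CountMatrix, pd.Series]:
    """Counts plus the planted module of each gene (-1 = background)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if membership is None:
        membership = _module_membership(cfg, rng)
    m = _sample_counts(cfg, membership, rng, prefix)
    truth = pd.Series(membership, index=m.gene_ids, name="module")
    return m, truth


def generate_counts(cfg: SynthConfig) -> CountMatrix:
    """Synthetic count matrix with planted modules; truth kept out of the data."""
    m, _ = generate_counts_with_truth(cfg)
    return m


def generate_platform_pair(cfg: SynthConfig, shared_module_fraction: float = 1.0,
                           ortholog_coverage: float = 1.0,
                           ) -> tuple[CountMatrix, CountMatrix, OrthologMap, pd.DataFrame]:
    """Two platforms with (partially) shared modules and an ortholog map.

    Shared modules reuse the same gene memberships (by ortholog pairing)
    with fresh samples and factors; the remaining modules are placed on
    background genes independently per platform. The map links a
    ``ortholog_coverage`` fraction of genes one-to-one between the
    platforms (dataset IDs "SynA" and "SynB", distinct species). The truth
    table records every gene's platform and planted module.
    """
    if not (0 <= shared_module_fraction <= 1 and 0 <= ortholog_coverage <= 1):
        raise ConfigError("fractions must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    n_shared = int(round(shared_module_fraction * cfg.n_modules))

    membership_a = _module_membership(cfg, rng)
    membership_b = np.full(cfg.n_genes, -1, dtype=np.int64)
    shared_mask = membership_a < n_shared  # background (-1) stays background
    membership_b[(membership_a >= 0) & shared_mask] = \
        membership_a[(membership_a >= 0) & shared_mask]
    # platform B's own (unshared) modules go on genes that are background in A
    free = np.flatnonzero(membership_b < 0)
    free = free[membership_a[free] < 0]
    free = rng.permutation(free)
    for m in range(n_shared, cfg.n_modules):
        take, free = free[:cfg.module_size], free[cfg.module_size:]
        membership_b[take] = m

    counts_a, truth_a = generate_counts_with_truth(
        cfg, prefix="a", rng=rng, membership=membership_a)
    counts_b, truth_b = generate_counts_with_truth(
        cfg, prefix="b", rng=rng, membership=membership_b)

    covered = rng.random(cfg.n_genes) < ortholog_coverage
    group_of: dict[tuple[str, str], str] = {}
    for i in np.flatnonzero(covered):
        grp = f"OG{i:05d}"
        group_of[("SynA", f"ag{i:04d}")] = grp
        group_of[("SynB", f"bg{i:04d}")] = grp
    omap = OrthologMap(group_of)

    truth = pd.concat([
        pd.DataFrame({"platform": "SynA", "gene_id": truth_a.index,
                      "module": truth_a.to_numpy()}),
        pd.DataFrame({"platform": "SynB", "gene_id": truth_b.index,
                      "module": truth_b.to_numpy()}),
    ], ignore_index=True)
    return counts_a, counts_b, omap, truth
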