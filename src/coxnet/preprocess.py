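"""Count-matrix preprocessing for RNA-seq coexpression.

The pipeline, in fixed order: drop shallow runs (total mapped counts must
strictly exceed a threshold), drop low-expression genes (mean count across
the surviving runs strictly below a threshold), log2(count + pseudocount),
quantile-normalize within each experiment, then subtract each gene's mean
within each experiment. Gene filtering uses only the runs that survive the
run filter, and every distribution-level step operates per experiment, so
cross-experiment batch structure never leaks into the reference quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .exprio import CountMatrix, ExpressionMatrix

__all__ = [
    "PreprocessConfig",
    "filter_runs",
    "filter_genes",
    "log_transform",
    "quantile_normalize",
    "center_genes",
    "preprocess_pipeline",
]


@dataclass
class PreprocessConfig:
    """Thresholds for the preprocessing pipeline.

    min_total_mapped : runs with column totals <= this are dropped
        (default 10 000 000 mapped counts).
    min_mean_count : genes with mean count < this across surviving runs
        are dropped (default 30).
    pseudocount : added before the base-2 log (default 1).
    """

    min_total_mapped: float = 10_000_000
    min_mean_count: float = 30.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.min_total_mapped < 0 or self.min_mean_count < 0 or self.pseudocount < 0:
            raise ConfigError("preprocess thresholds must be >= 0")


def filter_runs(m: CountMatrix, min_total_mapped: float) -> CountMatrix:
    """Keep runs whose total counts strictly exceed ``min_total_mapped``."""
    totals = m.counts.sum(axis=0)
    keep = totals.index[totals.to_numpy() > min_total_mapped]
    if len(keep) == 0:
        raise DataError(f"no runs survive filter (total > {min_total_mapped:g})")
    return m.subset_runs(keep)


def filter_genes(m: CountMatrix, min_mean_count: float) -> CountMatrix:
    """Drop genes whose mean count across runs is strictly below threshold."""
    if m.n_runs == 0:
        raise DataError("gene filter needs at least one run")
    means = m.counts.mean(axis=1)
    keep = means.index[~(means.to_numpy() < min_mean_count)]
    if len(keep) == 0:
        raise DataError(f"no genes survive filter (mean >= {min_mean_count:g})")
    return m.subset_genes(keep)


def log_transform(m: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(count + pseudocount); experiment grouping is carried over."""
    vals = m.counts.to_numpy(dtype=float)
    if pseudocount <= 0 and np.any(vals <= 0):
        raise DataError("pseudocount <= 0 with zero counts: log undefined")
    out = pd.DataFrame(np.log2(vals + pseudocount),
                       index=m.counts.index, columns=m.counts.columns)
    return ExpressionMatrix(out, dict(m.experiment_of))


def _quantile_normalize_group(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize one genes x samples block in place-free form.

    Every column is forced onto the mean-of-order-statistics reference.
    Tied values within a column receive the mean of the reference values
    over their tied rank positions.
    """
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x, dtype=float)
    n = x.shape[0]
    for j in range(x.shape[1]):
        ord_j = order[:, j]
        sorted_vals = x[ord_j, j]
        # boundaries of runs of tied values in the sorted column
        starts = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
        ends = np.r_[starts[1:], n]
        csum = np.r_[0.0, np.cumsum(ref)]
        tie_means = (csum[ends] - csum[starts]) / (ends - starts)
        expanded = np.repeat(tie_means, ends - starts)
        out[ord_j, j] = expanded
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization applied independently within each experiment."""
    vals = m.values.to_numpy(dtype=float).copy()
    col_idx = {s: i for i, s in enumerate(m.sample_ids)}
    for _, samples in m.experiment_groups().items():
        cols = [col_idx[s] for s in samples]
        vals[:, cols] = _quantile_normalize_group(vals[:, cols])
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, dict(m.experiment_of))


def center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean expression within each experiment."""
    vals = m.values.to_numpy(dtype=float).copy()
    col_idx = {s: i for i, s in enumerate(m.sample_ids)}
    for _, samples in m.experiment_groups().items():
        cols = [col_idx[s] for s in samples]
        vals[:, cols] -= vals[:, cols].mean(axis=1, keepdims=True)
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, dict(m.experiment_of))


def preprocess_pipeline(m: CountMatrix, cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Run filter -> gene filter -> log2 -> per-experiment quantile norm -> centering."""
    cfg = cfg or PreprocessConfig()
    m = filter_runs(m, cfg.min_total_mapped)
    m = filter_genes(m, cfg.min_mean_count)
    expr = log_transform(m, cfg.pseudocount)
    expr = quantile_normalize(expr)
    return center_genes(expr)
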