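import numpy as np
import pandas as pd
import pytest

from coxnet import CountMatrix, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_counts(values, gene_ids=None, run_ids=None, experiments=None):
    """Build a CountMatrix from a nested list / array."""
    arr = np.asarray(values)
    genes = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    runs = run_ids or [f"r{j}" for j in range(arr.shape[1])]
    exps = experiments or {r: "e0" for r in runs}
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=runs), exps)


def make_expr(values, gene_ids=None, sample_ids=None, experiments=None):
    arr = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    exps = experiments or {s: "e0" for s in samples}
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), exps)


@pytest.fixture
def small_counts():
    """3 genes x 4 runs across two experiments."""
    return make_counts(
        [[10, 20, 30, 40], [5, 5, 5, 5], [100, 200, 150, 120]],
        experiments={"r0": "e0", "r1": "e0", "r2": "e1", "r3": "e1"},
    )


def random_expr(rng, n_genes, n_samples, n_experiments=1):
    vals = rng.normal(size=(n_genes, n_samples))
    samples = [f"s{j}" for j in range(n_samples)]
    bounds = np.linspace(0, n_samples, n_experiments + 1).astype(int)
    exps = {}
    for e in range(n_experiments):
        for j in range(bounds[e], bounds[e + 1]):
            exps[samples[j]] = f"e{e}"
    return make_expr(vals, sample_ids=samples, experiments=exps)
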