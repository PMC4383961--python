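"""Readers, writers and core data containers.

All on-disk formats are tab-separated UTF-8 text with a mandatory header
row; lines starting with ``#`` are treated as comments and skipped.
Readers validate invariants and reject bad input rather than repairing it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "OrthologMap",
    "Platform",
    "read_count_matrix",
    "read_grouping",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_edge_list",
    "write_edge_list",
    "write_coexpressed_list",
    "write_supportability",
]

_READ_OPTS = dict(sep="\t", comment="#", dtype=str)


@dataclass
class CountMatrix:
    """Raw nonnegative gene x run count matrix with experiment grouping.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer counts, genes on the index, run IDs on the columns.
    experiment_of : mapping of run_id -> experiment_id
        Every run must be assigned to exactly one experiment.
    """

    counts: pd.DataFrame
    experiment_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise DataError(f"duplicate gene IDs: {list(dups)[:5]}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise DataError(f"duplicate run IDs: {list(dups)[:5]}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise DataError("counts must be numeric")
        if np.any(~np.isfinite(vals)):
            raise DataError("counts must be finite")
        if np.any(vals < 0):
            raise DataError("negative count in matrix")
        missing = [r for r in self.counts.columns if r not in self.experiment_of]
        if missing:
            raise DataError(f"run(s) missing from grouping: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_runs(self) -> int:
        return self.counts.shape[1]

    def subset_runs(self, run_ids: Iterable[str]) -> "CountMatrix":
        keep = [r for r in self.run_ids if r in set(run_ids)]
        return CountMatrix(self.counts[keep], {r: self.experiment_of[r] for r in keep})

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        keep = set(gene_ids)
        return CountMatrix(self.counts.loc[[g for g in self.gene_ids if g in keep]],
                           dict(self.experiment_of))


@dataclass
class ExpressionMatrix:
    """Normalized log2-scale gene x sample expression values."""

    values: pd.DataFrame
    experiment_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise DataError("duplicate gene or sample IDs")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or np.any(~np.isfinite(vals)):
            raise DataError("expression values must be finite numbers")
        missing = [s for s in self.values.columns if s not in self.experiment_of]
        if missing:
            raise DataError(f"sample(s) missing from grouping: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def experiment_groups(self) -> dict[str, list[str]]:
        """Sample IDs grouped by experiment, in column order."""
        groups: dict[str, list[str]] = {}
        for s in self.sample_ids:
            groups.setdefault(self.experiment_of[s], []).append(s)
        return groups


@dataclass
class OrthologMap:
    """Cross-platform gene correspondence through ortholog groups.

    A ``(platform_id, gene_id)`` pair maps to at most one group; within a
    platform a group may hold several genes (paralogs). Two genes on two
    platforms correspond when they share a group.
    """

    group_of: dict[tuple[str, str], str]
    _members: dict[tuple[str, str], set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._members = {}
        for (platform, gene), grp in self.group_of.items():
            self._members.setdefault((platform, grp), set()).add(gene)

    def group(self, platform: str, gene: str) -> str | None:
        return self.group_of.get((platform, gene))

    def genes_in_group(self, platform: str, group: str) -> set[str]:
        return set(self._members.get((platform, group), set()))

    def __len__(self) -> int:
        return len(self.group_of)


@dataclass
class Platform:
    """One coexpression dataset: a short label, a species, a gene universe."""

    dataset_id: str
    species: str
    gene_universe: set[str]

    def __post_init__(self) -> None:
        self.gene_universe = set(self.gene_universe)
        if not self.gene_universe:
            raise DataError(f"platform {self.dataset_id}: empty gene universe")


def _read_table(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, **kwargs)
    except FileNotFoundError:
        raise DataError(f"cannot read file: {path}") from None
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"malformed TSV {path}: {exc}") from None


def read_grouping(path) -> dict[str, str]:
    """Read a two-column (run_id, experiment_id) grouping TSV."""
    tab = _read_table(path, **_READ_OPTS)
    if tab.shape[1] < 2:
        raise DataError(f"grouping file {path} needs two columns")
    runs, exps = tab.iloc[:, 0], tab.iloc[:, 1]
    if runs.duplicated().any():
        raise DataError(f"duplicate run in grouping: {runs[runs.duplicated()].iloc[0]}")
    return dict(zip(runs, exps))


def read_count_matrix(path, grouping_path) -> CountMatrix:
    """Read a counts TSV (header = run IDs, first column = gene IDs) plus grouping."""
    tab = _read_table(path, sep="\t", comment="#", index_col=0)
    num = tab.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        bad = tab.to_numpy()[num.isna().to_numpy()][0]
        raise DataError(f"non-numeric count value: {bad!r}")
    if (num.to_numpy() < 0).any():
        raise DataError("negative count in matrix")
    num.index = num.index.astype(str)
    num.columns = num.columns.astype(str)
    return CountMatrix(num, read_grouping(grouping_path))


def read_expression_matrix(path, grouping_path) -> ExpressionMatrix:
    tab = _read_table(path, sep="\t", comment="#", index_col=0)
    num = tab.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        raise DataError(f"non-numeric expression value in {path}")
    num.index = num.index.astype(str)
    num.columns = num.columns.astype(str)
    return ExpressionMatrix(num, read_grouping(grouping_path))


def write_expression_matrix(expr: ExpressionMatrix, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out = expr.values.copy()
        out.index.name = "gene_id"
        out.to_csv(fh, sep="\t", float_format="%.6g")


def write_grouping(experiment_of: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("run_id\texperiment_id\n")
        for run, exp in experiment_of.items():
            fh.write(f"{run}\t{exp}\n")


def write_count_matrix(m: CountMatrix, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out = m.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(fh, sep="\t")


def read_ortholog_map(path) -> OrthologMap:
    """Read a three-column (platform_id, gene_id, group_id) ortholog TSV."""
    tab = _read_table(path, **_READ_OPTS)
    if tab.shape[0] == 0:
        raise DataError(f"ortholog map {path}: no entries")
    if tab.shape[1] < 3:
        raise DataError(f"ortholog map {path} needs three columns")
    group_of: dict[tuple[str, str], str] = {}
    for platform, gene, grp in tab.iloc[:, :3].itertuples(index=False):
        key = (platform, gene)
        if key in group_of and group_of[key] != grp:
            raise DataError(
                f"conflicting group for {platform}:{gene}: {group_of[key]} vs {grp}")
        group_of[key] = grp
    return OrthologMap(group_of)


def write_ortholog_map(omap: OrthologMap, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("platform_id\tgene_id\tgroup_id\n")
        for (platform, gene), grp in sorted(omap.group_of.items()):
            fh.write(f"{platform}\t{gene}\t{grp}\n")


def write_edge_list(edges, path, header_lines: Iterable[str] = ()) -> None:
    """Write an EdgeSet as a (gene_a, gene_b, mutual_rank) TSV.

    Within a row gene_a < gene_b lexicographically; rows sorted by ascending
    MR then gene_a. Platform and k are recorded on comment lines so the file
    round-trips.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"#platform={edges.platform}\tk={edges.k}\n")
        fh.write("gene_a\tgene_b\tmutual_rank\n")
        rows = sorted(edges.edges.items(), key=lambda kv: (kv[1], kv[0]))
        for (a, b), mr in rows:
            fh.write(f"{a}\t{b}\t{mr:.6g}\n")


def read_edge_list(path):
    """Read an edge-list TSV written by :func:`write_edge_list`."""
    from .network import EdgeSet  # deferred: avoids import cycle

    platform, k = "", 0
    try:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    except FileNotFoundError:
        raise DataError(f"cannot read file: {path}") from None
    for line in text.splitlines():
        if line.startswith("#platform="):
            fields = dict(f.split("=", 1) for f in line[1:].split("\t"))
            platform = fields.get("platform", "")
            k = int(fields.get("k", 0))
    tab = _read_table(io.StringIO(text), sep="\t", comment="#")
    edges = {}
    for a, b, mr in tab.itertuples(index=False):
        a, b = str(a), str(b)
        if a >= b:
            raise DataError(f"edge list rows must have gene_a < gene_b ({a}, {b})")
        edges[(a, b)] = float(mr)
    return EdgeSet(platform=platform, edges=edges, k=k)


def write_coexpressed_list(cl, path, header_lines: Iterable[str] = ()) -> None:
    """Write a coexpressed-gene list as (rank, gene_id, mutual_rank, correlation)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"#guide={cl.guide_gene}\n")
        fh.write("rank\tgene_id\tmutual_rank\tcorrelation\n")
        for i, (gene, mr, r) in enumerate(cl.entries, start=1):
            fh.write(f"{i}\t{gene}\t{mr:.6g}\t{r:.6g}\n")


def write_supportability(results, path, header_lines: Iterable[str] = ()) -> None:
    """Write SupportabilityResult rows as a TSV report.

    Genes without any reference get 'no reference' in the stars column.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tbest_reference_platform\tbest_reference_gene\t"
                 "max_coxsim\tp_value\tstars\n")
        for res in results:
            if res.best_reference is None:
                fh.write(f"{res.guide_gene}\tNA\tNA\tNA\tNA\tno reference\n")
            else:
                plat, gene = res.best_reference
                fh.write(f"{res.guide_gene}\t{plat}\t{gene}\t"
                         f"{res.max_coxsim:.6g}\t{res.p_value:.6g}\t{res.stars}\n")
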