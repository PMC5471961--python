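"""Tabular I/O and universe reconciliation.

All tables are tab-separated text.  Expression files carry a header row of
sample identifiers and a first column of gene identifiers; connectivity can
be given either as a genes x TFs 0/1 matrix (header row of TF identifiers)
or as a two-column TF/gene edge list.  Output files start with a single
``#`` comment line recording the tool version and the writing parameters,
which readers skip.

Identifier matching between expression and connectivity inputs is
case-insensitive and whitespace-stripped; the expression file's casing wins
in aligned outputs.  Gene symbols routinely differ in case between human
and mouse sources, so exact-case matching would silently drop genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._version import __version__
from .errors import ValidationError

logger = logging.getLogger(__name__)


def _canon(identifier: str) -> str:
    return str(identifier).strip().casefold()


def _check_unique(ids, what: str) -> None:
    seen: dict[str, str] = {}
    for raw in ids:
        key = _canon(raw)
        if key in seen:
            raise ValidationError(
                f"duplicate {what} identifier {raw!r} (clashes with {seen[key]!r})"
            )
        seen[key] = raw


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes x samples, for one condition."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class ConnectivityMatrix:
    """Binary genes x TFs topology: entry (g, f) is 1 iff TF f has a
    binding site upstream of gene g."""

    gene_ids: list[str]
    tf_ids: list[str]
    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        if self.entries.ndim != 2 or self.entries.shape != (
            len(self.gene_ids),
            len(self.tf_ids),
        ):
            raise ValidationError(
                f"connectivity shape {self.entries.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.tf_ids)} TFs"
            )
        if self.entries.size and not np.isin(self.entries, (0, 1)).all():
            raise ValidationError("connectivity entries must be 0 or 1")
        self.entries = self.entries.astype(np.int8)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.tf_ids, "TF")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)


@dataclass
class TFAnnotation:
    """Functional-group annotation for TFs.

    Maps each TF to a (group_index, group_name) pair used to order and
    color plots.  TFs absent from the table fall into the trailing
    "Unknown" group.
    """

    groups: dict[str, tuple[int, str]] = field(default_factory=dict)
    unknown_index: int = 10**6

    def __post_init__(self) -> None:
        self.groups = {_canon(tf): (int(i), str(name)) for tf, (i, name) in self.groups.items()}

    def group_of(self, tf_id: str) -> tuple[int, str]:
        return self.groups.get(_canon(tf_id), (self.unknown_index, "Unknown"))

    def sort_key(self, tf_id: str) -> tuple[int, str]:
        idx, _ = self.group_of(tf_id)
        return (idx, tf_id)

    def order(self, tf_ids) -> list[str]:
        """TF identifiers sorted by (group index, id)."""
        return sorted(tf_ids, key=self.sort_key)


@dataclass
class AlignmentReport:
    dropped_expression_genes: list[str]
    dropped_connectivity_genes: list[str]
    dropped_tfs: list[str]
    n_genes: int
    n_tfs: int

    @property
    def empty(self) -> bool:
        return not (
            self.dropped_expression_genes
            or self.dropped_connectivity_genes
            or self.dropped_tfs
        )


def _header_line(kind: str, **params) -> str:
    extra = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# tfcircuit {__version__} {kind}" + (f" {extra}" if extra else "")


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, comment="#", dtype=str, keep_default_na=False
        )
    except FileNotFoundError:
        raise ValidationError(f"input file not found: {path}") from None
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty table: {path}") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"empty table: {path}")
    return df


def _to_float(df: pd.DataFrame, path) -> np.ndarray:
    try:
        return df.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric cell {cell!r} at gene {df.index[i]!r}, "
                        f"column {col!r} in {path}"
                    ) from None
        raise


def read_expression(path, label: str = "", log2_offset: float | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    Values are used verbatim (the upstream pipeline is expected to have
    normalized and log-transformed them already).  For raw counts, pass
    ``log2_offset`` to apply ``log2(x + offset)`` at read time.
    """
    df = _read_table(path)
    values = _to_float(df, path)
    if log2_offset is not None:
        values = np.log2(values + log2_offset)
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
        label=label or str(path),
    )


def read_connectivity(path, dialect: str = "matrix") -> ConnectivityMatrix:
    """Read binary TF-gene topology.

    ``matrix`` dialect: genes x TFs table of 0/1 cells, file order kept.
    ``edge_list`` dialect: two unnamed columns (TF, gene), one edge per
    line; duplicate edges collapse; gene and TF orders are sorted.
    """
    if dialect == "matrix":
        df = _read_table(path)
        values = _to_float(df, path)
        if values.size and not np.isin(values, (0.0, 1.0)).all():
            bad = values[~np.isin(values, (0.0, 1.0))][0]
            raise ValidationError(f"connectivity matrix cell {bad!r} is not 0/1 in {path}")
        return ConnectivityMatrix(
            gene_ids=[str(g) for g in df.index],
            tf_ids=[str(t) for t in df.columns],
            entries=values.astype(np.int8),
        )
    if dialect == "edge_list":
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        except (FileNotFoundError, pd.errors.EmptyDataError):
            raise ValidationError(f"missing or empty edge list: {path}") from None
        if df.shape[1] < 2:
            raise ValidationError(f"edge list must have two columns (TF, gene): {path}")
        tfs = sorted({str(t) for t in df[0]})
        genes = sorted({str(g) for g in df[1]})
        tf_pos = {t: j for j, t in enumerate(tfs)}
        gene_pos = {g: i for i, g in enumerate(genes)}
        entries = np.zeros((len(genes), len(tfs)), dtype=np.int8)
        for t, g in zip(df[0], df[1]):
            entries[gene_pos[str(g)], tf_pos[str(t)]] = 1
        return ConnectivityMatrix(gene_ids=genes, tf_ids=tfs, entries=entries)
    raise ValidationError(f"unknown connectivity dialect {dialect!r}")


def read_annotation(path) -> TFAnnotation:
    """Read a TF functional-group table with columns tf_id, group_index, group_name."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"tf_id", "group_index", "group_name"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"annotation file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    groups: dict[str, tuple[int, str]] = {}
    for _, row in df.iterrows():
        key = _canon(row["tf_id"])
        entry = (int(row["group_index"]), str(row["group_name"]))
        if key in groups and groups[key] != entry:
            raise ValidationError(f"TF {row['tf_id']!r} annotated with two different groups")
        groups[key] = entry
    return TFAnnotation(groups={k: v for k, v in groups.items()})


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    with open(path, "w") as fh:
        fh.write(_header_line("expression", label=expr.label or "-") + "\n")
        df.to_csv(fh, sep="\t", lineterminator="\n")


def write_connectivity(conn: ConnectivityMatrix, path) -> None:
    df = pd.DataFrame(conn.entries, index=conn.gene_ids, columns=conn.tf_ids)
    with open(path, "w") as fh:
        fh.write(_header_line("connectivity", dialect="matrix") + "\n")
        df.to_csv(fh, sep="\t", lineterminator="\n")


def write_edge_list(conn: ConnectivityMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line("connectivity", dialect="edge_list") + "\n")
        rows, cols = np.nonzero(conn.entries)
        for g, f in zip(rows, cols):
            fh.write(f"{conn.tf_ids[f]}\t{conn.gene_ids[g]}\n")


def write_matrix(values: np.ndarray, row_ids, col_ids, path, kind: str = "matrix", **params) -> None:
    """Generic labeled-matrix writer used for W, c, D and friends."""
    df = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    with open(path, "w") as fh:
        fh.write(_header_line(kind, **params) + "\n")
        df.to_csv(fh, sep="\t", lineterminator="\n")


def read_matrix(path) -> pd.DataFrame:
    """Read back a labeled matrix written by :func:`write_matrix`."""
    df = _read_table(path)
    return df.astype(float)


def align_inputs(
    expr: ExpressionMatrix, conn: ConnectivityMatrix
) -> tuple[ExpressionMatrix, ConnectivityMatrix, AlignmentReport]:
    """Restrict both inputs to the shared gene universe.

    Genes present in only one input are dropped (and reported).  Genes with
    no TF connections are kept: they still inform the baseline and the
    noise variance.  TF columns left without any target are dropped, since
    a TF with no connected gene has an unidentifiable concentration.
    """
    expr_keys = {_canon(g): i for i, g in enumerate(expr.gene_ids)}
    conn_keys = {_canon(g): i for i, g in enumerate(conn.gene_ids)}
    shared = [g for g in expr.gene_ids if _canon(g) in conn_keys]
    if not shared:
        raise ValidationError("no genes shared between expression and connectivity inputs")

    dropped_expr = [g for g in expr.gene_ids if _canon(g) not in conn_keys]
    dropped_conn = [g for g in conn.gene_ids if _canon(g) not in expr_keys]

    expr_rows = [expr_keys[_canon(g)] for g in shared]
    conn_rows = [conn_keys[_canon(g)] for g in shared]
    new_entries = conn.entries[conn_rows, :]

    keep_tf = new_entries.sum(axis=0) > 0
    dropped_tfs = [t for t, k in zip(conn.tf_ids, keep_tf) if not k]
    if dropped_tfs:
        logger.warning(
            "dropping %d TF(s) with no targets in the shared gene universe: %s",
            len(dropped_tfs),
            ", ".join(dropped_tfs),
        )

    expr_out = ExpressionMatrix(
        gene_ids=list(shared),
        sample_ids=list(expr.sample_ids),
        values=expr.values[expr_rows, :],
        label=expr.label,
    )
    conn_out = ConnectivityMatrix(
        gene_ids=list(shared),
        tf_ids=[t for t, k in zip(conn.tf_ids, keep_tf) if k],
        entries=new_entries[:, keep_tf],
    )
    report = AlignmentReport(
        dropped_expression_genes=dropped_expr,
        dropped_connectivity_genes=dropped_conn,
        dropped_tfs=dropped_tfs,
        n_genes=conn_out.n_genes,
        n_tfs=conn_out.n_tfs,
    )
    return expr_out, conn_out, report
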