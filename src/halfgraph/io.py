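"""Tabular I/O for expression matrices, fitted networks and diagnostics.

The canonical tabular dialect is TSV: tab-separated, UTF-8, '.' decimal, a
header row of sample ids and a first column of variable ids.  Expression
matrices are variables x samples (genes in rows) by default; a transposed
file loads identically with ``orientation="variables-in-columns"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "load_matrix",
    "save_matrix",
    "load_square_matrix",
    "save_square_matrix",
    "top_variance_filter",
    "write_network",
    "partial_correlations",
]


@dataclass
class ExpressionMatrix:
    """A labeled p x n expression matrix (variables in rows)."""

    values: np.ndarray
    var_ids: list
    sample_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D")
        p, n = self.values.shape
        if p < 2 or n < 2:
            raise ValueError(f"need at least 2 variables and 2 samples, got {p} x {n}")
        if len(self.var_ids) != p or len(self.sample_ids) != n:
            raise ValueError("label lengths do not match matrix shape")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


def _sep_for(fmt: str | None, path) -> str:
    if fmt is None:
        fmt = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    return "\t" if fmt == "tsv" else ","


def load_matrix(
    path,
    fmt: str | None = None,
    orientation: str = "variables-in-rows",
    impute_mean: bool = False,
) -> ExpressionMatrix:
    """Load a labeled numeric matrix from TSV/CSV.

    Missing cells are an error naming the offending variable and sample unless
    ``impute_mean`` replaces them by the row (variable) mean.  Duplicate ids
    and non-numeric cells raise distinct errors.
    """
    sep = _sep_for(fmt, path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "variables-in-columns":
        df = df.T
    elif orientation != "variables-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate variable ids: {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from None
    if np.isnan(values).any():
        if impute_mean:
            row_means = np.nanmean(values, axis=1, keepdims=True)
            values = np.where(np.isnan(values), row_means, values)
        else:
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at variable {df.index[i]!r}, sample {df.columns[j]!r} "
                "(use impute_mean to fill with row means)"
            )
    return ExpressionMatrix(
        values=values,
        var_ids=[str(v) for v in df.index],
        sample_ids=[str(s) for s in df.columns],
    )


def save_matrix(X: ExpressionMatrix, path, fmt: str | None = None) -> None:
    sep = _sep_for(fmt, path)
    pd.DataFrame(X.values, index=X.var_ids, columns=X.sample_ids).to_csv(path, sep=sep)


def save_square_matrix(M, ids, path) -> None:
    """Write a labeled square matrix (e.g. Omega, L, a frequency matrix) as TSV."""
    pd.DataFrame(np.asarray(M), index=ids, columns=ids).to_csv(path, sep="\t")


def load_square_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(v) for v in df.index]


def top_variance_filter(X: ExpressionMatrix, m: int) -> ExpressionMatrix:
    """Keep the m rows with largest sample variance (ties: original order).

    The standard pre-filter before network estimation on genome-wide
    expression: variables that barely vary carry no partial-correlation
    signal.  Selection is invariant to sample reordering.
    """
    if not 1 <= m <= X.p:
        raise ValueError(f"m must lie in [1, {X.p}], got {m}")
    var = X.values.var(axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")[:m]
    keep = np.sort(order)
    return ExpressionMatrix(
        values=X.values[keep],
        var_ids=[X.var_ids[i] for i in keep],
        sample_ids=list(X.sample_ids),
    )


def partial_correlations(Omega) -> np.ndarray:
    """Partial correlation matrix ``rho_ij = -omega_ij / sqrt(omega_ii omega_jj)``."""
    Omega = np.asarray(Omega, dtype=float)
    d = np.sqrt(np.diag(Omega))
    rho = -Omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def write_network(est, ids, path, fmt: str = "edgelist") -> None:
    """Export a fitted precision estimate.

    ``edgelist``: TSV rows (id_i, id_j, omega_ij, partial correlation);
    ``matrix``: Omega and L as two TSVs (`<path>.omega.tsv`, `<path>.lowrank.tsv`);
    ``graphml``: a weighted graph with partial correlations as edge weights.
    """
    Omega = est.Omega
    if fmt == "matrix":
        save_square_matrix(Omega, ids, f"{path}.omega.tsv")
        save_square_matrix(est.L, ids, f"{path}.lowrank.tsv")
        return
    rho = partial_correlations(Omega)
    edges = sorted(est.support)
    if fmt == "edgelist":
        rows = [
            {
                "source": ids[i],
                "target": ids[j],
                "omega": Omega[i, j],
                "partial_correlation": rho[i, j],
            }
            for i, j in edges
        ]
        pd.DataFrame(rows, columns=["source", "target", "omega", "partial_correlation"]).to_csv(
            path, sep="\t", index=False
        )
        return
    if fmt == "graphml":
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(ids)
        for i, j in edges:
            G.add_edge(ids[i], ids[j], omega=float(Omega[i, j]), weight=float(rho[i, j]))
        nx.write_graphml(G, path)
        return
    raise ValueError(f"unknown network format {fmt!r}")
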