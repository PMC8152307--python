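"""Readers and writers for the tabular and graph formats the pipeline touches.

Expression matrices are TSV/CSV with gene IDs in the first column and sample
IDs in the header; regulator lists are plain text, one ID per line; gold
standards are two-column tables (regulator, target); networks are written as
edge CSVs or GraphML. All parsing is locale-independent (decimal point only).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import EDGE_COLUMNS, CountMatrix, GoldStandard, TestedNetwork

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_regulators",
    "read_gold_standard",
    "write_network",
    "read_network",
]


def _infer_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path: str | Path, delimiter: str | None = None, normalized: bool = False
) -> CountMatrix:
    """Read a gene x sample expression table.

    The first column holds gene IDs, the header row sample IDs. ``delimiter``
    defaults to "," for ``.csv`` files and tab otherwise. Duplicate gene IDs,
    negative values and non-numeric cells are hard errors naming the culprit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter or _infer_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    counts = df.index.value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise ValueError(f"duplicate gene IDs in {path.name}: {sorted(dups)}")

    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            # numpy's string parser is exact to the ulp (pd.to_numeric is not)
            numeric[col] = df[col].to_numpy().astype(np.float64)
        except (ValueError, TypeError):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            gene = df.index[bad.to_numpy()][0]
            raise ValueError(
                f"non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, "
                f"sample {col!r} in {path.name}"
            ) from None
    numeric.index.name = None
    if numeric.isna().to_numpy().any():
        gene, col = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at gene {numeric.index[gene]!r}, "
            f"sample {numeric.columns[col]!r} in {path.name}"
        )
    return CountMatrix(values=numeric, normalized=normalized)


def write_expression_matrix(
    counts: CountMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a CountMatrix as TSV/CSV (gene IDs first column, samples header)."""
    path = Path(path)
    sep = delimiter or _infer_delimiter(path)
    # %.17g keeps doubles exact through a write/read cycle
    counts.values.to_csv(path, sep=sep, index_label="gene", float_format="%.17g")


def read_regulators(path: str | Path) -> frozenset[str]:
    """Read a regulator list: one gene ID per line, blank lines ignored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids = {line.strip() for line in path.read_text().splitlines()}
    ids.discard("")
    if not ids:
        raise ValueError(f"regulator list {path.name} is empty")
    return frozenset(ids)


def read_gold_standard(path: str | Path, delimiter: str | None = None) -> GoldStandard:
    """Read validated regulator->target pairs from a two-column table.

    A header row naming the columns ``regulator`` and ``target`` is accepted
    but optional. Every regulator appearing in the file is taken to carry
    validation information.
    """
    path = Path(path)
    sep = delimiter or _infer_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"gold standard {path.name} needs two columns")
    first = [str(v).strip().lower() for v in df.iloc[0, :2]]
    if first == ["regulator", "target"]:
        df = df.iloc[1:]
    pairs = frozenset(
        (str(r).strip(), str(t).strip()) for r, t in zip(df.iloc[:, 0], df.iloc[:, 1])
    )
    if not pairs:
        raise ValueError(f"gold standard {path.name} is empty")
    return GoldStandard(
        validated_pairs=pairs,
        informative_regulators=frozenset(r for r, _ in pairs),
    )


def write_network(
    net: TestedNetwork, path: str | Path, format: str = "edge_csv", final_only: bool = True
) -> None:
    """Write a tested network as an edge CSV or GraphML file.

    edge_csv columns: regulator, target, importance, pvalue, fdr. Numeric
    columns are written at full precision so a round-trip reproduces them to
    better than 1e-12. ``final_only`` restricts output to the FDR-selected
    final network; pass False to export every tested edge.
    """
    edges = net.final_edges if final_only else net.edges
    if len(edges) == 0:
        raise ValueError("refusing to write an empty network")
    path = Path(path)
    if format == "edge_csv":
        edges.loc[:, EDGE_COLUMNS].to_csv(path, index=False, float_format="%.17g")
    elif format == "graphml":
        g = nx.DiGraph()
        for row in edges.itertuples(index=False):
            g.add_edge(
                row.regulator,
                row.target,
                importance=float(row.importance),
                pvalue=_nan_to_none(row.pvalue),
                fdr=_nan_to_none(row.fdr),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def _nan_to_none(x: float) -> float:
    # GraphML has no NaN literal; untested edges export p-value 1.0
    return 1.0 if pd.isna(x) else float(x)


def read_network(path: str | Path) -> TestedNetwork:
    """Read an edge CSV back into a TestedNetwork (testing metadata unknown)."""
    df = pd.read_csv(path, dtype={"regulator": str, "target": str})
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge CSV {Path(path).name} missing columns {missing}")
    n_perm = 0 if df["pvalue"].isna().all() else -1  # -1: tested, B unknown
    return TestedNetwork(
        edges=df.loc[:, EDGE_COLUMNS],
        fdr_threshold=1.0,
        n_permutations=n_perm,
    )
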