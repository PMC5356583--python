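"""Readers/writers for the plain-text formats the pipeline exchanges.

Matrices are TSV with genes in rows and a header row of sample (or tissue)
identifiers; survival tables are TSV with a ``sample`` column; networks are
3-column edge lists or GraphML; gene sets are GMT.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_survival_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="sample")


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_edge_list(
    edges: Mapping[tuple[str, str], float], path: str | Path, value_name: str = "weight"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"regulator\ttarget\t{value_name}\n")
        for (u, v), w in sorted(edges.items()):
            fh.write(f"{u}\t{v}\t{w:.6g}\n")


def read_edge_list(path: str | Path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r.iloc[0]), str(r.iloc[1])): float(r.iloc[2]) for _, r in df.iterrows()
    }


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection (set name, description, members)."""
    from gseapy.parser import read_gmt as _read_gmt

    sets = _read_gmt(str(path))
    return {name: list(members) for name, members in sets.items()}


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write(name + "\tna\t" + "\t".join(members) + "\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))
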