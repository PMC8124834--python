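"""Bipartite miRNA-target network and reverse-expression screening.

Targets of downregulated miRNAs lose repression, so genes whose own
expression is UP in the tumor microenvironment are the interesting ones.
The network is built from a local table of experimentally supported
miRNA->gene interactions (validated-interaction export format: columns
``mirna``, ``gene``, ``evidence``); the packaged table is a synthetic
stand-in suitable for tests and demonstrations, and users supply their
own export for real analyses.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable
from pathlib import Path

import networkx as nx
import pandas as pd

from .catalog import normalize_mirna_name
from .dem import DEMParams, call_dems
from .expression import TME_CELL_TYPES

__all__ = [
    "load_interactions",
    "packaged_interactions_path",
    "build_network",
    "mirna_partners",
    "reverse_expression_screen",
    "export_network",
    "read_network",
]


def packaged_interactions_path() -> Path:
    """Path of the packaged synthetic interaction table."""
    from importlib import resources

    return Path(
        str(
            resources.files("geromir.data").joinpath(
                "mirna_gene_interactions.synthetic.tsv"
            )
        )
    )


def load_interactions(path: str | Path) -> pd.DataFrame:
    """Load an interaction table; normalize miRNA names, drop duplicate pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"mirna", "gene"} - set(df.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    if "evidence" not in df.columns:
        df["evidence"] = ""
    df = df[["mirna", "gene", "evidence"]].copy()
    df["mirna"] = df["mirna"].map(normalize_mirna_name)
    df["gene"] = df["gene"].str.strip()
    df = df.drop_duplicates(subset=["mirna", "gene"], keep="first")
    return df.reset_index(drop=True)


def _assert_bipartite(graph: nx.Graph) -> None:
    mirnas = {n for n, d in graph.nodes(data=True) if d.get("kind") == "mirna"}
    genes = {n for n, d in graph.nodes(data=True) if d.get("kind") == "gene"}
    if mirnas & genes:
        raise ValueError(f"node sets not disjoint: {sorted(mirnas & genes)[:5]}")
    if mirnas | genes != set(graph.nodes):
        raise ValueError("every node must be labelled mirna or gene")
    for u, v in graph.edges:
        ku, kv = graph.nodes[u]["kind"], graph.nodes[v]["kind"]
        if {ku, kv} != {"mirna", "gene"}:
            raise ValueError(f"edge within one partition: ({u}, {v})")


def build_network(
    down_geromirs: Iterable[str], interactions: pd.DataFrame
) -> nx.Graph:
    """Bipartite graph of downregulated miRNAs and their gene targets.

    Edges are exactly the interaction rows whose miRNA is in
    ``down_geromirs``; node sets are derived from the retained edges, so
    there are no isolated miRNA nodes.  An empty network is valid.
    """
    down = {normalize_mirna_name(m) for m in down_geromirs}
    kept = interactions[interactions["mirna"].isin(down)]
    graph = nx.Graph()
    for row in kept.itertuples(index=False):
        graph.add_node(row.mirna, kind="mirna", bipartite=0)
        graph.add_node(row.gene, kind="gene", bipartite=1)
        graph.add_edge(row.mirna, row.gene, evidence=row.evidence)
    _assert_bipartite(graph)
    return graph


def mirna_partners(graph: nx.Graph, gene: str) -> frozenset[str]:
    """The miRNA neighbors of a gene node (case-insensitive gene lookup)."""
    target = gene.lower()
    for node, data in graph.nodes(data=True):
        if data.get("kind") == "gene" and str(node).lower() == target:
            return frozenset(graph.neighbors(node))
    return frozenset()


def reverse_expression_screen(
    graph: nx.Graph,
    gene_matrix: pd.DataFrame,
    annot: pd.DataFrame,
    params: DEMParams = DEMParams(),
    cell_types: tuple[str, ...] | set[str] = TME_CELL_TYPES,
) -> pd.DataFrame:
    """Network gene targets that are UPREGULATED in the TME.

    Applies the same fold-change/significance rule as the miRNA layer to
    the gene matrix and keeps the up-called genes that are nodes of the
    network.  Gene symbols are matched case-insensitively with the
    matrix capitalization preserved.  Returns a table with columns gene,
    mean_C, mean_T, log2_fc, p_value, linked_mirnas.
    """
    gene_nodes = {
        str(n).lower(): n
        for n, d in graph.nodes(data=True)
        if d.get("kind") == "gene"
    }
    columns = ["gene", "mean_C", "mean_T", "log2_fc", "p_value", "linked_mirnas"]
    present = {str(f).lower() for f in gene_matrix.index}
    if gene_nodes and not (set(gene_nodes) & present):
        warnings.warn("no network gene appears in the expression matrix",
                      stacklevel=2)
        return pd.DataFrame(columns=columns)
    dems = call_dems(gene_matrix, annot, params, cell_types)
    up = dems.records[dems.records["direction"] == "up"]
    rows = []
    for rec in up.itertuples(index=False):
        node = gene_nodes.get(str(rec.feature_id).lower())
        if node is None:
            continue
        linked = sorted(graph.neighbors(node))
        rows.append(
            (rec.feature_id, rec.mean_C, rec.mean_T, rec.log2_fc,
             rec.p_value, ",".join(linked))
        )
    return pd.DataFrame(rows, columns=columns)


def export_network(
    graph: nx.Graph,
    graphml_path: str | Path,
    edgelist_path: str | Path | None = None,
) -> None:
    """Write GraphML (with the bipartite node attribute) and an edge-list TSV."""
    _assert_bipartite(graph)
    nx.write_graphml(graph, str(graphml_path))
    if edgelist_path is not None:
        rows = [
            (u, v, d.get("evidence", ""))
            if graph.nodes[u]["kind"] == "mirna"
            else (v, u, d.get("evidence", ""))
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["mirna", "gene", "evidence"]).sort_values(
            ["mirna", "gene"]
        ).to_csv(edgelist_path, sep="\t", index=False)


def read_network(graphml_path: str | Path) -> nx.Graph:
    """Re-import a GraphML network, re-asserting bipartiteness."""
    graph = nx.read_graphml(str(graphml_path))
    graph = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    for _, data in graph.nodes(data=True):
        data["bipartite"] = int(data.get("bipartite", 0))
    _assert_bipartite(graph)
    return graph
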