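"""Projection of burden-significant genes onto a weighted interaction network
and extraction of the module anchored by training-positive genes.

The network is a STRING-dialect edge list (protein1, protein2,
combined_score with confidence 0-1000).  Edges below a confidence threshold
(default 700, the conventional "high confidence" cutoff) are dropped at
load.  The module rule: induce the subgraph on the significant genes, keep
nodes that are training positives or adjacent to one, and return the union
of connected components that contain at least one training positive.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import matplotlib
matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd

EDGE_COLUMNS = ("protein1", "protein2", "combined_score")


def load_edges(
    path: str,
    score_threshold: int = 700,
    aliases: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Read a STRING-dialect edge list into an undirected weighted graph.

    Whitespace- or tab-delimited with a header naming the three standard
    columns.  Self-loops are dropped, duplicate undirected pairs collapse to
    the higher score, and edges with score < ``score_threshold`` are
    excluded.  ``aliases`` optionally maps protein identifiers to gene
    symbols.  Malformed rows raise ``ValueError`` naming the 1-based file
    line.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str, comment=None)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    bad = df.index[scores.isna() | df["protein1"].isna() | df["protein2"].isna()]
    if len(bad):
        raise ValueError(f"{path}: malformed row at line {int(bad[0]) + 2}")

    graph = nx.Graph()
    for p1, p2, score in zip(df["protein1"], df["protein2"], scores):
        if aliases is not None:
            p1 = aliases.get(p1, p1)
            p2 = aliases.get(p2, p2)
        if p1 == p2:
            continue
        score = float(score)
        if score < score_threshold:
            continue
        a, b = sorted((p1, p2))
        if graph.has_edge(a, b):
            graph[a][b]["weight"] = max(graph[a][b]["weight"], score)
        else:
            graph.add_edge(a, b, weight=score)
    graph.graph["score_threshold"] = score_threshold
    return graph


def extract_module(
    graph: nx.Graph,
    significant_genes: Iterable[str],
    training_positives: Iterable[str],
    include_all_positives: bool = False,
) -> nx.Graph:
    """Extract the training-positive-anchored module among significant genes.

    Steps: (1) induce the subgraph on the significant genes (plus, in
    permissive mode, every training positive present in the network);
    (2) keep nodes that are training positives or adjacent to one within the
    induced subgraph; (3) return the union of connected components holding
    >= 1 training positive.  Nodes carry ``is_training_positive``.
    Empty inputs yield an empty graph.
    """
    significant = set(significant_genes)
    positives = set(training_positives)
    nodes = set(graph.nodes) & (significant | positives if include_all_positives else significant)
    induced = graph.subgraph(nodes)

    anchored = {
        n
        for n in induced.nodes
        if n in positives or any(nb in positives for nb in induced.neighbors(n))
    }
    pruned = induced.subgraph(anchored)
    keep: set[str] = set()
    for component in nx.connected_components(pruned):
        if component & positives:
            keep.update(component)

    module = nx.Graph(pruned.subgraph(keep))
    nx.set_node_attributes(
        module, {n: (n in positives) for n in module.nodes}, "is_training_positive"
    )
    return module


def score_color(score: float, cmap_name: str = "viridis_r"):
    """RGBA shade for a combined evidence score in [0, 1]; 1.0 maps to the
    darkest end of the scale."""
    score = min(1.0, max(0.0, float(score)))
    return plt.get_cmap(cmap_name)(score)


def annotate_and_export(
    module: nx.Graph,
    evidence_scores: Mapping[str, float] | pd.DataFrame,
    outdir: str,
    groups: Mapping[str, str] | None = None,
    basename: str = "module",
    figure: bool = True,
) -> dict[str, str]:
    """Write node/edge tables, GraphML and a rendered figure for a module.

    ``evidence_scores`` is a gene -> combined score mapping (or a DataFrame
    with gene/combined_score columns); module nodes without a score get 0 and
    are flagged.  Node shading encodes the score; training-positive genes get
    a square glyph.  An empty module writes empty tables and no figure.
    """
    if isinstance(evidence_scores, pd.DataFrame):
        evidence_scores = dict(
            zip(evidence_scores["gene"], evidence_scores["combined_score"])
        )
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    rows = []
    for n in sorted(module.nodes):
        rows.append(
            {
                "gene": n,
                "combined_score": float(evidence_scores.get(n, 0.0)),
                "score_missing": n not in evidence_scores,
                "is_training_positive": bool(
                    module.nodes[n].get("is_training_positive", False)
                ),
                "group": (groups or {}).get(n, ""),
            }
        )
    node_df = pd.DataFrame(
        rows,
        columns=["gene", "combined_score", "score_missing", "is_training_positive", "group"],
    )
    edge_df = pd.DataFrame(
        [
            {"gene1": a, "gene2": b, "score": d.get("weight", 0.0)}
            for a, b, d in sorted(module.edges(data=True))
        ],
        columns=["gene1", "gene2", "score"],
    )
    paths["nodes"] = os.path.join(outdir, f"{basename}_nodes.tsv")
    paths["edges"] = os.path.join(outdir, f"{basename}_edges.tsv")
    node_df.to_csv(paths["nodes"], sep="\t", index=False)
    edge_df.to_csv(paths["edges"], sep="\t", index=False)

    if len(module):
        annotated = nx.Graph(module)
        for row in rows:
            annotated.nodes[row["gene"]]["combined_score"] = row["combined_score"]
            annotated.nodes[row["gene"]]["group"] = row["group"]
        paths["graphml"] = os.path.join(outdir, f"{basename}.graphml")
        nx.write_graphml(annotated, paths["graphml"])

        if figure:
            pos = nx.spring_layout(module, seed=0)
            fig, ax = plt.subplots(figsize=(8, 8))
            nx.draw_networkx_edges(module, pos, ax=ax, alpha=0.4)
            for marker, is_pos in (("s", True), ("o", False)):
                sub = [r for r in rows if r["is_training_positive"] == is_pos]
                if not sub:
                    continue
                ax.scatter(
                    [pos[r["gene"]][0] for r in sub],
                    [pos[r["gene"]][1] for r in sub],
                    c=[score_color(r["combined_score"]) for r in sub],
                    marker=marker,
                    s=300,
                    edgecolors="black",
                    zorder=2,
                )
            for r in rows:
                ax.annotate(r["gene"], pos[r["gene"]], fontsize=6, ha="center", va="center")
            ax.set_axis_off()
            paths["figure"] = os.path.join(outdir, f"{basename}.png")
            fig.savefig(paths["figure"], dpi=150)
            plt.close(fig)
    return paths
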