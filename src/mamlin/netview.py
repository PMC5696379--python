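"""DE-overlaid protein-interaction subnetworks.

Differentially expressed mouse genes (FDR below a cut, default 0.001) are
mapped to human orthologs, the induced subgraph of a curated human
interaction edge list is taken (direct interactions only), and nodes are
classified as signal transduction (ST), transcription factor (TF), dual,
or other from a GO-derived function map.  Exports are node/edge TSV plus
SIF lines for downstream network tools.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


@dataclass
class AnnotatedNetwork:
    graph: nx.Graph = field(default_factory=nx.Graph)
    provenance: str = ""

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def node_table(self) -> pd.DataFrame:
        rows = [{"human_id": n,
                 "mouse_ids": ",".join(d.get("mouse_ids", [])),
                 "direction": d.get("direction", ""),
                 "function": d.get("function", "other")}
                for n, d in sorted(self.graph.nodes(data=True))]
        return pd.DataFrame(rows, columns=["human_id", "mouse_ids", "direction", "function"])

    def edge_table(self) -> pd.DataFrame:
        rows = [{"id_a": min(a, b), "id_b": max(a, b)} for a, b in self.graph.edges]
        rows.sort(key=lambda r: (r["id_a"], r["id_b"]))
        return pd.DataFrame(rows, columns=["id_a", "id_b"])


def map_orthologs(de: pd.DataFrame, ortholog_map: dict[str, list[str]],
                  fdr_cut: float = 0.001) -> pd.DataFrame:
    """Mouse DE genes below ``fdr_cut`` mapped to human orthologs.

    One-to-many mappings expand to one row per human id, flagged
    ambiguous; unmapped genes are reported in an ``unmapped`` attribute on
    the result rather than silently dropped.
    """
    if not ortholog_map:
        raise ValueError("empty ortholog map")
    hits = de[de["fdr"] < fdr_cut]
    rows, unmapped = [], []
    for rec in hits.itertuples(index=False):
        human = ortholog_map.get(rec.gene_id)
        if not human:
            unmapped.append(rec.gene_id)
            continue
        for h in human:
            rows.append({"mouse_id": rec.gene_id, "human_id": h,
                         "log2fc": rec.log2fc, "fdr": rec.fdr,
                         "ambiguous": len(human) > 1})
    out = pd.DataFrame(rows, columns=["mouse_id", "human_id", "log2fc", "fdr", "ambiguous"])
    out.attrs["unmapped"] = unmapped
    return out


def build_de_subnetwork(mapped: pd.DataFrame,
                        edges: list[tuple[str, str]]) -> AnnotatedNetwork:
    """Induced subgraph of the interaction list on the mapped human ids.

    Isolated mapped nodes are retained with degree 0.  Node direction
    comes from the log2FC sign; a human id fed by mouse genes with
    conflicting signs is marked ambiguous.
    """
    if mapped.empty:
        raise ValueError("no mapped DE genes")
    g = nx.Graph()
    for human_id, sub in mapped.groupby("human_id"):
        signs = set("up" if x > 0 else "down" for x in sub["log2fc"])
        direction = signs.pop() if len(signs) == 1 else "ambiguous"
        g.add_node(human_id, mouse_ids=sorted(set(sub["mouse_id"])),
                   direction=direction, function="other")
    for a, b in edges:
        if a in g and b in g and a != b:
            g.add_edge(a, b)
    return AnnotatedNetwork(graph=g, provenance="build_de_subnetwork")


def classify_node_function(net: AnnotatedNetwork,
                           function_map: dict[str, set[str]]) -> AnnotatedNetwork:
    """Annotate nodes as ST, TF, dual, or other from the GO-derived map."""
    for n in net.graph.nodes:
        toks = function_map.get(n, set())
        if toks >= {"ST", "TF"}:
            fn = "dual"
        elif "ST" in toks:
            fn = "ST"
        elif "TF" in toks:
            fn = "TF"
        else:
            fn = "other"
        net.graph.nodes[n]["function"] = fn
    return net


def st_tf_view(net: AnnotatedNetwork) -> AnnotatedNetwork:
    """Subnetwork restricted to signal-transduction / TF / dual nodes."""
    keep = [n for n, d in net.graph.nodes(data=True)
            if d.get("function") in ("ST", "TF", "dual")]
    return AnnotatedNetwork(graph=net.graph.subgraph(keep).copy(),
                            provenance=net.provenance + "+st_tf_view")


def export_network(net: AnnotatedNetwork, prefix: str) -> None:
    """Write ``<prefix>_nodes.tsv``, ``<prefix>_edges.tsv`` and ``<prefix>.sif``."""
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    net.node_table().to_csv(prefix + "_nodes.tsv", sep="\t", index=False)
    net.edge_table().to_csv(prefix + "_edges.tsv", sep="\t", index=False)
    with open(prefix + ".sif", "w") as fh:
        for rec in net.edge_table().itertuples(index=False):
            fh.write(f"{rec.id_a}\tpp\t{rec.id_b}\n")


def import_network(prefix: str) -> AnnotatedNetwork:
    """Rebuild a network from its exported node/edge tables."""
    nodes = pd.read_csv(prefix + "_nodes.tsv", sep="\t", dtype=str).fillna("")
    edges = pd.read_csv(prefix + "_edges.tsv", sep="\t", dtype=str)
    g = nx.Graph()
    for rec in nodes.itertuples(index=False):
        g.add_node(rec.human_id,
                   mouse_ids=[m for m in rec.mouse_ids.split(",") if m],
                   direction=rec.direction, function=rec.function or "other")
    for rec in edges.itertuples(index=False):
        g.add_edge(rec.id_a, rec.id_b)
    return AnnotatedNetwork(graph=g, provenance=f"import:{prefix}")
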