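"""Drug-protein / protein-protein interactome and MOA subnetwork mining.

The interactome is an undirected simple graph whose nodes are compounds and
proteins and whose edges are typed (DPI joins compound-protein, PPI joins
protein-protein) and provenance-tracked: an edge reported by several source
datasets is stored once with the union of source labels.

Mechanism-of-action (MOA) subnetworks keep every simple path from a drug of
the MOA to the target gene with at most ``max_edges`` edges whose first hop
is a DPI and whose remaining hops are PPIs — the default bound of 3 edges is
the 4-node chain drug <=> drug target <=> neighbour of target <=> target
gene, emphasising the most direct drug-target associations.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "MoaSubnetwork",
    "build_interactome",
    "interactome_summary",
    "find_moa_paths",
    "extract_moa_subnetwork",
    "merge_subnetworks",
    "export_network",
    "import_network",
]

COMPOUND = "compound"
PROTEIN = "protein"
DPI = "DPI"
PPI = "PPI"


@dataclass
class MoaSubnetwork:
    """Node/edge subset of an interactome induced by drug->target paths."""

    moa_label: str
    drugs: set[str]
    target_gene: str
    graph: nx.Graph
    paths: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


def _norm(identifier: str) -> str:
    return str(identifier).strip().upper()


def build_interactome(
    dpi: pd.DataFrame, ppi_sets: list[pd.DataFrame]
) -> nx.Graph:
    """Union DPI and PPI edge lists into one provenance-tracked graph.

    ``dpi`` needs columns ``compound_id, protein_symbol`` (optional
    ``source``, ``moa_label``); each PPI table needs ``protein_a, protein_b``
    (optional ``source``).  Identifiers are case-normalised; duplicate edges
    merge with unioned provenance; self-loops are dropped.  An identifier
    appearing both as compound and protein is a hard error.
    """
    g = nx.Graph()

    def add_edge(u, v, edge_type, source, moa=None):
        u, v = _norm(u), _norm(v)
        if u == v:
            return
        if g.has_edge(u, v):
            data = g.edges[u, v]
            if data["edge_type"] != edge_type:
                raise ValueError(
                    f"edge {u}-{v} reported as both {data['edge_type']} and {edge_type}"
                )
            data["provenance"].add(source)
            if moa:
                data.setdefault("moa", set()).add(moa)
        else:
            attrs = {"edge_type": edge_type, "provenance": {source}}
            if moa:
                attrs["moa"] = {moa}
            g.add_edge(u, v, **attrs)

    compound_ids: set[str] = set()
    protein_ids: set[str] = set()

    for row in dpi.itertuples(index=False):
        d = row._asdict()
        source = d.get("source", "DPI")
        moa = d.get("moa_label")
        c, p = _norm(d["compound_id"]), _norm(d["protein_symbol"])
        compound_ids.add(c)
        protein_ids.add(p)
        add_edge(c, p, DPI, source, moa if isinstance(moa, str) else None)

    for i, ppi in enumerate(ppi_sets):
        for row in ppi.itertuples(index=False):
            d = row._asdict()
            source = d.get("source", f"PPI{i + 1}")
            a, b = _norm(d["protein_a"]), _norm(d["protein_b"])
            protein_ids.update((a, b))
            add_edge(a, b, PPI, source)

    clash = compound_ids & protein_ids
    if clash:
        raise ValueError(
            f"identifiers typed as both compound and protein: {sorted(clash)}"
        )
    for n in g.nodes:
        g.nodes[n]["node_type"] = COMPOUND if n in compound_ids else PROTEIN
    return g


def interactome_summary(g: nx.Graph) -> dict[str, int]:
    """Counts of compounds, proteins, DPI and PPI edges."""
    types = nx.get_node_attributes(g, "node_type")
    etypes = [d["edge_type"] for _, _, d in g.edges(data=True)]
    return {
        "compounds": sum(1 for t in types.values() if t == COMPOUND),
        "proteins": sum(1 for t in types.values() if t == PROTEIN),
        "dpi_edges": etypes.count(DPI),
        "ppi_edges": etypes.count(PPI),
    }


def find_moa_paths(
    net: nx.Graph, drug: str, target_gene: str, max_edges: int = 3
) -> list[tuple[str, ...]]:
    """All simple drug->target paths with <= max_edges edges, DPI-first.

    The first hop must be a DPI edge of the drug; all subsequent hops must be
    PPI edges.  Paths are returned in deterministic (lexicographic) order.
    """
    drug, target_gene = _norm(drug), _norm(target_gene)
    if target_gene not in net:
        raise KeyError(f"target gene {target_gene!r} not in interactome")
    if drug not in net:
        return []
    ppi_only = net.edge_subgraph(
        [(u, v) for u, v, d in net.edges(data=True) if d["edge_type"] == PPI]
    )
    paths: list[tuple[str, ...]] = []
    for first in sorted(net.neighbors(drug)):
        if net.edges[drug, first]["edge_type"] != DPI:
            continue
        if first == target_gene:
            paths.append((drug, target_gene))
            continue
        if max_edges < 2 or first not in ppi_only:
            continue
        if target_gene not in ppi_only:
            continue
        for tail in nx.all_simple_paths(
            ppi_only, first, target_gene, cutoff=max_edges - 1
        ):
            if drug not in tail:
                paths.append((drug, *tail))
    return sorted(paths)


def extract_moa_subnetwork(
    net: nx.Graph,
    moa_drugs: set[str],
    target_gene: str,
    max_edges: int = 3,
    moa_label: str = "",
) -> MoaSubnetwork:
    """Union of all qualifying drug->target paths for one MOA's drugs.

    Every retained node lies on at least one path; a drug with no qualifying
    route within the edge bound contributes nothing.  An empty subnetwork is
    returned (not an error) when no path qualifies.
    """
    target_gene = _norm(target_gene)
    drugs = {_norm(d) for d in moa_drugs}
    bad = {
        d for d in drugs
        if d in net and net.nodes[d].get("node_type") != COMPOUND
    }
    if bad:
        raise ValueError(f"MOA members are not compound nodes: {sorted(bad)}")
    all_paths: list[tuple[str, ...]] = []
    for drug in sorted(drugs):
        all_paths.extend(find_moa_paths(net, drug, target_gene, max_edges))
    sub = nx.Graph()
    for path in all_paths:
        for u, v in zip(path, path[1:]):
            sub.add_node(u, **net.nodes[u])
            sub.add_node(v, **net.nodes[v])
            sub.add_edge(u, v, **net.edges[u, v])
    return MoaSubnetwork(
        moa_label=moa_label,
        drugs=drugs,
        target_gene=target_gene,
        graph=sub,
        paths=all_paths,
    )


def merge_subnetworks(subnets: list[MoaSubnetwork]) -> nx.Graph:
    """Node/edge union of MOA subnetworks; idempotent, provenance preserved."""
    merged = nx.Graph()
    for sn in subnets:
        for n, attrs in sn.graph.nodes(data=True):
            merged.add_node(n, **attrs)
        for u, v, attrs in sn.graph.edges(data=True):
            if merged.has_edge(u, v):
                merged.edges[u, v]["provenance"] = set(
                    merged.edges[u, v]["provenance"]
                ) | set(attrs["provenance"])
            else:
                merged.add_edge(u, v, **attrs)
    return merged


# ---------------------------------------------------------------------------
# Export / import (SIF, GraphML, edge-TSV)
# ---------------------------------------------------------------------------

def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, MoaSubnetwork) else net

def export_network(net, path, fmt: str) -> Path:
    """Write a graph as SIF, GraphML or edge-TSV.

    GraphML and edge-TSV round-trip node types and provenance exactly via
    :func:`import_network`; SIF keeps the edge type as the interaction label.
    """
    g = _as_graph(net)
    path = Path(path)
    if fmt == "SIF":
        if g.number_of_edges() == 0:
            raise ValueError("SIF export requires a non-empty graph")
        lines = [
            f"{u}\t{d['edge_type']}\t{v}"
            for u, v, d in sorted(g.edges(data=True))
        ]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "GraphML":
        h = nx.Graph()
        for n, a in g.nodes(data=True):
            h.add_node(n, node_type=a.get("node_type", PROTEIN))
        for u, v, a in g.edges(data=True):
            h.add_edge(
                u, v,
                edge_type=a["edge_type"],
                provenance="|".join(sorted(a.get("provenance", set()))),
            )
        nx.write_graphml(h, path)
    elif fmt == "edge-TSV":
        rows = [
            {
                "source": u,
                "target": v,
                "edge_type": d["edge_type"],
                "provenance": "|".join(sorted(d.get("provenance", set()))),
            }
            for u, v, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(
            rows, columns=["source", "target", "edge_type", "provenance"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")
    return path


def import_network(path, fmt: str) -> nx.Graph:
    """Read a graph written by :func:`export_network`."""
    path = Path(path)
    g = nx.Graph()
    if fmt == "GraphML":
        raw = nx.read_graphml(path)
        for n, a in raw.nodes(data=True):
            g.add_node(n, node_type=a.get("node_type", PROTEIN))
        for u, v, a in raw.edges(data=True):
            g.add_edge(
                u, v,
                edge_type=a["edge_type"],
                provenance=set(a.get("provenance", "").split("|")) - {""},
            )
    elif fmt == "edge-TSV":
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples(index=False):
            g.add_edge(
                row.source, row.target,
                edge_type=row.edge_type,
                provenance=set(str(row.provenance).split("|")) - {"", "nan"},
            )
        for n in g.nodes:
            kinds = {g.edges[n, nb]["edge_type"] for nb in g.neighbors(n)}
            is_compound = kinds == {DPI}
            g.nodes[n]["node_type"] = COMPOUND if is_compound else PROTEIN
    elif fmt == "SIF":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            u, etype, v = line.split("\t")
            g.add_edge(u, v, edge_type=etype, provenance=set())
    else:
        raise ValueError(f"unknown import format: {fmt!r}")
    return g
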