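"""Bipartite contig <-> reference-protein annotation networks.

An edge joins a contig to a reference protein when any ORF of the
contig hits the protein strictly below the e-value ceiling (multiple
ORFs collapse to one edge keeping the best e-value).  Contigs shorter
than the length floor or with fewer than the required number of
distinct protein hits are excluded, then orphaned proteins drop out.
Both filters commute because hit counts are computed on qualifying
edges only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .debruijn import Contig, ParameterError
from .io import HitRecord
from .orfs import Orf


class ReferentialError(ValueError):
    """A hit references an ORF (or an ORF a contig) that does not exist."""


@dataclass
class BipartiteNetwork:
    contig_nodes: frozenset[str]
    protein_nodes: frozenset[str]
    edges: dict[tuple[str, str], float]  # (contig, protein) -> best e-value

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BipartiteNetwork)
            and self.contig_nodes == other.contig_nodes
            and self.protein_nodes == other.protein_nodes
            and self.edges == other.edges
        )


def _contig_lengths(contigs) -> dict[str, int]:
    if isinstance(contigs, dict):
        return dict(contigs)
    out = {}
    for c in contigs:
        if isinstance(c, Contig):
            out[c.contig_id] = len(c)
        else:
            cid, seq = c
            out[cid] = len(seq)
    return out


def build_bipartite(contigs, orfs: list[Orf], hits: list[HitRecord],
                    evalue_max: float = 1e-50, min_contig_len: int = 3000,
                    min_hits: int = 5) -> BipartiteNetwork:
    """Filtered contig <-> protein network from an ORF hit table.

    Strict inequality at the e-value ceiling; ``min_hits`` counts
    distinct reference proteins hit per contig.
    """
    lengths = _contig_lengths(contigs)
    contig_of: dict[str, str] = {}
    for o in orfs:
        if o.contig_id not in lengths:
            raise ReferentialError(f"ORF {o.orf_id} references unknown contig {o.contig_id}")
        contig_of[o.orf_id] = o.contig_id
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.orf_id not in contig_of:
            raise ReferentialError(f"hit references unknown ORF {h.orf_id}")
        if h.evalue >= evalue_max:
            continue
        key = (contig_of[h.orf_id], h.protein_id)
        if key not in best or h.evalue < best[key]:
            best[key] = h.evalue
    per_contig: dict[str, set[str]] = {}
    for (cid, pid) in best:
        per_contig.setdefault(cid, set()).add(pid)
    keep_contigs = {
        cid
        for cid, prots in per_contig.items()
        if lengths[cid] >= min_contig_len and len(prots) >= min_hits
    }
    edges = {
        (cid, pid): ev for (cid, pid), ev in best.items() if cid in keep_contigs
    }
    return BipartiteNetwork(
        contig_nodes=frozenset(cid for cid, _pid in edges),
        protein_nodes=frozenset(pid for _cid, pid in edges),
        edges=edges,
    )


def export_network(network: BipartiteNetwork, path, format: str = "SIF") -> None:
    """Write the network as Cytoscape SIF or as GraphML (sorted, so output
    is deterministic)."""
    fmt = format.upper()
    if fmt == "SIF":
        with open(path, "w") as fh:
            for cid, pid in sorted(network.edges):
                fh.write(f"{cid} hits {pid}\n")
    elif fmt == "GRAPHML":
        g = nx.Graph()
        for cid in sorted(network.contig_nodes):
            g.add_node(cid, kind="contig")
        for pid in sorted(network.protein_nodes):
            g.add_node(pid, kind="protein")
        for (cid, pid), ev in sorted(network.edges.items()):
            g.add_edge(cid, pid, evalue=float(ev))
        nx.write_graphml(g, path)
    else:
        raise ParameterError(f"unknown network format {format!r} (SIF or GraphML)")


def read_graphml(path) -> BipartiteNetwork:
    g = nx.read_graphml(path)
    contig_nodes = frozenset(n for n, d in g.nodes(data=True) if d.get("kind") == "contig")
    protein_nodes = frozenset(n for n, d in g.nodes(data=True) if d.get("kind") == "protein")
    edges = {}
    for u, v, d in g.edges(data=True):
        cid, pid = (u, v) if u in contig_nodes else (v, u)
        edges[(cid, pid)] = float(d["evalue"])
    return BipartiteNetwork(contig_nodes, protein_nodes, edges)
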