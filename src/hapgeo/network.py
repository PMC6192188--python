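"""Minimum spanning haplotype networks.

For shallow intraspecific divergence a minimum spanning network (MSN)
summarises haplotype relationships: a minimum spanning tree over the
substitution distances plus every alternative edge that ties it, so all
co-minimal connections are shown.  Median (Steiner) vertex inference is
deliberately not attempted; for a handful of observed haplotypes the
MSN carries the same signal.
"""

from __future__ import annotations

import json

import networkx as nx

from .errors import InputError
from .haplotypes import DistanceMatrix, HaplotypeTable

__all__ = ["build_msn", "export_network", "read_network_tsv"]


def build_msn(dist: DistanceMatrix, table: HaplotypeTable | None = None) -> nx.Graph:
    """Minimum spanning network over the haplotype distance matrix.

    Kruskal's algorithm with deterministic lexicographic tie-breaking
    builds the MST (edge attribute ``in_mst=True``); every non-tree edge
    whose weight equals the maximum edge weight on the MST path between
    its endpoints is retained as a co-minimal alternative
    (``in_mst=False``).  Node attributes carry total counts and the
    per-population composition when ``table`` is given.
    """
    ids = dist.ids
    d = dist.matrix
    g = nx.Graph()
    for h in ids:
        attrs = {}
        if table is not None and h in table.haplotype_ids:
            attrs["count"] = int(table.total_counts[h])
            attrs["populations"] = {
                p: int(c) for p, c in table.counts[h].items() if c > 0
            }
        g.add_node(h, **attrs)
    k = len(ids)
    if k == 1:
        return g

    edges = sorted(
        ((float(d[i, j]), ids[i], ids[j]) for i in range(k) for j in range(i + 1, k)),
        key=lambda e: (e[0], e[1], e[2]),
    )
    mst = nx.Graph()
    mst.add_nodes_from(ids)
    parent = {h: h for h in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            mst.add_edge(a, b, weight=w)
            g.add_edge(a, b, weight=w, in_mst=True)

    for w, a, b in edges:
        if g.has_edge(a, b):
            continue
        path = nx.shortest_path(mst, a, b)
        max_on_path = max(
            mst[u][v]["weight"] for u, v in zip(path[:-1], path[1:])
        )
        if w <= max_on_path:  # co-minimal: could replace that MST edge
            g.add_edge(a, b, weight=w, in_mst=False)
    return g


def export_network(net: nx.Graph, path, fmt: str = "tsv") -> None:
    """Write the network as an annotated edge list (TSV) or as GML."""
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("#nodes\n")
            fh.write("node\tcount\tpopulations\n")
            for node, attrs in sorted(net.nodes(data=True)):
                comp = json.dumps(attrs.get("populations", {}), sort_keys=True)
                fh.write(f"{node}\t{attrs.get('count', '')}\t{comp}\n")
            fh.write("#edges\n")
            fh.write("from\tto\tweight\tin_mst\n")
            for a, b, attrs in sorted(net.edges(data=True)):
                fh.write(f"{a}\t{b}\t{attrs['weight']:g}\t{int(attrs['in_mst'])}\n")
    elif fmt == "gml":
        out = nx.Graph()
        for node, attrs in net.nodes(data=True):
            flat = {k: (json.dumps(v) if isinstance(v, dict) else v) for k, v in attrs.items()}
            out.add_node(node, **flat)
        for a, b, attrs in net.edges(data=True):
            out.add_edge(a, b, weight=float(attrs["weight"]), in_mst=int(attrs["in_mst"]))
        nx.write_gml(out, path)
    else:
        raise InputError(f"unknown network format {fmt!r}")


def read_network_tsv(path) -> nx.Graph:
    """Re-read a TSV written by :func:`export_network` (round-trippable)."""
    g = nx.Graph()
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line == "#nodes":
                section = "nodes"
                next(fh)
                continue
            if line == "#edges":
                section = "edges"
                next(fh)
                continue
            if not line:
                continue
            fields = line.split("\t")
            if section == "nodes":
                node, count, comp = fields
                attrs = {}
                if count:
                    attrs["count"] = int(count)
                pops = json.loads(comp)
                if pops:
                    attrs["populations"] = pops
                g.add_node(node, **attrs)
            elif section == "edges":
                a, b, w, in_mst = fields
                g.add_edge(a, b, weight=float(w), in_mst=bool(int(in_mst)))
    return g
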