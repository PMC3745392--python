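"""Minimum spanning haplotype networks and two-layer comparison.

The network is the union of all minimum spanning trees over the
haplotype distance matrix (tie-inclusive Kruskal): an edge of weight w
joins the network iff its endpoints lie in different components of the
graph formed by all strictly lighter edges.  Edges of weight w imply
``w - 1`` unobserved intermediate haplotypes, annotated per edge.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from hapaudit.haplotyping import Haplotype
from hapaudit.io_formats import CountTable


def build_msn(haplotypes: list[Haplotype], d: np.ndarray) -> nx.Graph:
    """Minimum spanning network over haplotypes.

    ``d`` is a symmetric matrix of mutational steps with zero diagonal.
    Returns a :class:`networkx.Graph` whose nodes are haplotype labels
    (attributes ``seq``, ``count``) and whose edges carry ``weight``
    (steps) and ``intermediates`` (= weight - 1).
    """
    d = np.asarray(d)
    k = len(haplotypes)
    if d.shape != (k, k):
        raise ValueError(f"distance matrix {d.shape} does not match {k} haplotypes")
    if (d != d.T).any() or np.diag(d).any():
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    g = nx.Graph()
    for h in haplotypes:
        g.add_node(h.label, seq=h.seq, count=h.count)
    if k < 2:
        return g

    # deterministic order: weight, then lexicographic endpoint labels
    edges = sorted(
        (
            (float(d[i, j]), haplotypes[i].label, haplotypes[j].label)
            for i in range(k)
            for j in range(i + 1, k)
        ),
        key=lambda e: (e[0], e[1], e[2]),
    )

    uf = nx.utils.UnionFind(h.label for h in haplotypes)
    i = 0
    while i < len(edges):
        w = edges[i][0]
        tier = []
        while i < len(edges) and edges[i][0] == w:
            tier.append(edges[i])
            i += 1
        # include every tier edge bridging components of the lighter graph
        keep = [(u, v) for _, u, v in tier if uf[u] != uf[v]]
        for u, v in keep:
            g.add_edge(u, v, weight=w, intermediates=int(w) - 1)
        for u, v in keep:
            uf.union(u, v)
    return g


def compare_layers(
    net: nx.Graph, table_a: CountTable, table_b: CountTable,
    layer_names: tuple[str, str] = ("A", "B"),
) -> nx.Graph:
    """Annotate network nodes with per-layer counts and sharing category.

    Each table maps haplotype ids (node labels) to per-layer totals; a
    node is ``shared`` when counted in both layers, ``<layer>-only`` when
    counted in exactly one, and ``inferred`` when in neither (it exists
    only as a connector).  Table rows must all be network nodes.
    """
    name_a, name_b = layer_names
    totals = {}
    for name, table in ((name_a, table_a), (name_b, table_b)):
        missing = set(table.haplotype_ids) - set(net.nodes)
        if missing:
            raise KeyError(f"layer {name}: haplotypes not in network: {sorted(missing)}")
        totals[name] = dict(zip(table.haplotype_ids, table.row_totals()))

    g = net.copy()
    for node in g.nodes:
        ca = int(totals[name_a].get(node, 0))
        cb = int(totals[name_b].get(node, 0))
        if ca and cb:
            category = "shared"
        elif ca:
            category = f"{name_a}-only"
        elif cb:
            category = f"{name_b}-only"
        else:
            category = "inferred"
        g.nodes[node].update(
            {f"count_{name_a}": ca, f"count_{name_b}": cb, "category": category}
        )
    g.graph["layers"] = list(layer_names)
    g.graph["summary"] = layer_summary(g, layer_names)
    return g


def layer_summary(g: nx.Graph, layer_names=("A", "B")) -> dict[str, int]:
    cats = [g.nodes[n].get("category") for n in g.nodes]
    name_a, name_b = layer_names
    return {
        "shared": cats.count("shared"),
        f"{name_a}_only": cats.count(f"{name_a}-only"),
        f"{name_b}_only": cats.count(f"{name_b}-only"),
        "inferred_nodes": cats.count("inferred"),
        "inferred_intermediates": int(
            sum(data.get("intermediates", 0) for _, _, data in g.edges(data=True))
        ),
    }


def write_graphml(g: nx.Graph, path) -> None:
    out = g.copy()
    out.graph.pop("summary", None)  # dict attrs are not GraphML-serializable
    out.graph.pop("layers", None)
    nx.write_graphml(out, path)


def write_dot(g: nx.Graph, path) -> None:
    """Minimal DOT export (no pygraphviz dependency)."""
    with open(path, "w") as fh:
        fh.write("graph haplonet {\n")
        for node, data in g.nodes(data=True):
            attrs = [f'label="{node}"']
            if "category" in data:
                attrs.append(f'category="{data["category"]}"')
            fh.write(f'  "{node}" [{", ".join(attrs)}];\n')
        for u, v, data in g.edges(data=True):
            fh.write(
                f'  "{u}" -- "{v}" [weight={data["weight"]:g}, '
                f'intermediates={data["intermediates"]}];\n'
            )
        fh.write("}\n")


def plot_network(g: nx.Graph, path, seed: int = 0) -> None:
    """Static spring-layout rendering (best effort, for inspection only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(g, seed=seed)
    sizes = [100 + 60 * g.nodes[n].get("count", 1) for n in g.nodes]
    colors = {
        "shared": "#7f7fff", "inferred": "#333333",
    }
    node_colors = [
        colors.get(g.nodes[n].get("category", ""), "#cccccc") for n in g.nodes
    ]
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx(
        g, pos=pos, ax=ax, node_size=sizes, node_color=node_colors, font_size=6
    )
    ax.set_axis_off()
    fig.savefig(path, dpi=150)
    plt.close(fig)
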