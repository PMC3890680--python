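"""Minimum-spanning haplotype networks over nucleotide differences.

The network is the union of ALL minimum spanning trees of the complete
graph whose edge weights are integer Hamming distances over comparable
(unambiguous) sites — the epsilon = 0 minimum-spanning network.  Unlike
median-joining this never infers unsampled intermediate haplotypes; it
preserves exactly what the analysis needs from a network figure: which
haplotypes group together and how many mutational steps separate the
groups.  One canonical MST (deterministic Kruskal, ties broken by input
order) is flagged ``in_mst`` on the edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx

from coibarcode.errors import AlignmentError
from coibarcode.haplotypes import HaplotypeTable
from coibarcode.seqio import UNAMBIGUOUS


def hamming_steps(a: str, b: str) -> int:
    """Mutational steps between two aligned sequences: the number of
    differing sites among positions where both are unambiguous A/C/G/T."""
    if len(a) != len(b):
        raise AlignmentError(
            f"sequences have unequal lengths {len(a)} and {len(b)}"
        )
    return sum(
        1
        for x, y in zip(a, b)
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS and x != y
    )


@dataclass(frozen=True)
class HaploNetwork:
    """Connected haplotype graph: nodes carry counts and optional species
    labels, edges carry integer step counts and the canonical-MST flag."""

    graph: nx.Graph

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, int, bool]]:
        return [
            (u, v, d["steps"], d["in_mst"])
            for u, v, d in self.graph.edges(data=True)
        ]

    def mst_weight(self) -> int:
        return sum(
            d["steps"] for _, _, d in self.graph.edges(data=True) if d["in_mst"]
        )

    def write_graphml(self, path: str | Path) -> Path:
        path = Path(path)
        nx.write_graphml(self.graph, path)
        return path

    def write_dot(self, path: str | Path) -> Path:
        """Plain DOT output; node label shows name and count, edge label
        the step count, solid edges are the canonical MST."""
        path = Path(path)
        lines = ["graph haplonetwork {"]
        for n, d in self.graph.nodes(data=True):
            label = f"{n} (n={d['count']})"
            if d.get("species"):
                label += f"\\n{d['species']}"
            lines.append(f'  "{n}" [label="{label}"];')
        for u, v, d in self.graph.edges(data=True):
            style = "solid" if d["in_mst"] else "dashed"
            lines.append(
                f'  "{u}" -- "{v}" [label="{d["steps"]}", style={style}];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
        return path


def build_network(
    tab: HaplotypeTable, labels: dict[str, str] | None = None
) -> HaploNetwork:
    """Union of all MSTs of the complete Hamming graph of a haplotype table.

    Kruskal over exact integer weights, processed in weight groups: an
    edge belongs to some MST iff its endpoints lie in different
    components once every strictly lighter edge group has been merged.
    Within each group, ties for the canonical MST break by input order,
    so the result is deterministic.
    """
    if len(tab) < 2:
        raise AlignmentError("a network needs at least 2 haplotypes")
    names = tab.names()
    seqs = dict(zip(names, tab.seqs()))
    g = nx.Graph()
    for h in tab:
        g.add_node(h.name, count=h.count, species=(labels or {}).get(h.name, ""))

    all_edges = [
        (names[i], names[j], hamming_steps(seqs[names[i]], seqs[names[j]]))
        for i, j in combinations(range(len(names)), 2)
    ]
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_weight: dict[int, list[tuple[str, str, int]]] = {}
    for e in all_edges:
        by_weight.setdefault(e[2], []).append(e)

    for w in sorted(by_weight):
        group = by_weight[w]
        # an edge is in SOME MST iff it bridges components formed by
        # strictly lighter edges
        bridging = [
            e for e in group if find(e[0]) != find(e[1])
        ]
        for u, v, steps in bridging:
            g.add_edge(u, v, steps=steps, in_mst=False)
        for u, v, steps in bridging:  # canonical MST: first tie wins
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[rv] = ru
                g.edges[u, v]["in_mst"] = True

    assert nx.is_connected(g)
    return HaploNetwork(g)


def plot_network(net: HaploNetwork, path: str | Path, seed: int = 0) -> Path:
    """Static rendering: node area proportional to haplotype count,
    edge labels give mutational steps.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = net.graph
    pos = nx.spring_layout(g, seed=seed, weight=None)
    counts = [g.nodes[n]["count"] for n in g.nodes]
    sizes = [100 + 40 * c for c in counts]
    fig, ax = plt.subplots(figsize=(6, 6))
    mst_edges = [(u, v) for u, v, d in g.edges(data=True) if d["in_mst"]]
    alt_edges = [(u, v) for u, v, d in g.edges(data=True) if not d["in_mst"]]
    nx.draw_networkx_edges(g, pos, edgelist=mst_edges, ax=ax)
    nx.draw_networkx_edges(g, pos, edgelist=alt_edges, style="dashed", ax=ax)
    nx.draw_networkx_nodes(g, pos, node_size=sizes, ax=ax)
    nx.draw_networkx_labels(g, pos, font_size=8, ax=ax)
    nx.draw_networkx_edge_labels(
        g,
        pos,
        edge_labels={(u, v): d["steps"] for u, v, d in g.edges(data=True)},
        font_size=7,
        ax=ax,
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
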