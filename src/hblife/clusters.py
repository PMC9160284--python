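"""Molecule-level hydrogen-bond graphs and cluster topology.

Each frame's bonded triplets collapse to an undirected graph on molecules
(parallel donor–acceptor triplets between the same molecule pair become one
edge).  Connected components of size ≥ 2 are clusters; their shape class is
decided by the cycle rank c = E − V + 1 and the degree sequence:

=============  =========================================
class          rule
=============  =========================================
dimer          2 nodes
chain          c = 0, max degree ≤ 2
branched-tree  c = 0, max degree ≥ 3
ring           c = 1, all degrees = 2 (the "loop")
lasso          c = 1, some degree-1 node
multi-cycle    c ≥ 2
=============  =========================================

Chains, rings ("loops") and lassos are the shapes mono-ol clusters are known
to adopt; the dimer is the elementary unit all clusters are assembled from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .detect import BondTriplet
from .topology import SystemTopology

__all__ = [
    "ClusterRecord",
    "build_graph",
    "find_clusters",
    "classify_topology",
    "size_distribution",
    "TOPOLOGY_CLASSES",
]

TOPOLOGY_CLASSES = ("dimer", "chain", "ring", "lasso", "branched-tree", "multi-cycle")


@dataclass
class ClusterRecord:
    """One connected component of the per-frame molecular H-bond graph."""

    frame_time: float
    members: frozenset[int]
    edges: frozenset[tuple[int, int]]
    topology_class: str
    species_counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def build_graph(
    bonds: Iterable[BondTriplet],
    topo: SystemTopology | None = None,
) -> nx.Graph:
    """Molecule-level undirected graph of one frame's bonded set.

    Nodes are molecule indices appearing in any triplet; one edge per bonded
    molecule pair regardless of how many donor–hydrogen–acceptor triplets
    link the two molecules.  Molecule indices are taken from ``topo`` when
    given, else triplets must already carry molecule ids in ``donor``/
    ``acceptor`` fields.
    """
    g = nx.Graph()
    for b in bonds:
        if topo is not None:
            u = int(topo.mol_of_atom[b.donor])
            v = int(topo.mol_of_atom[b.acceptor])
        else:
            u, v = int(b.donor), int(b.acceptor)
        if u == v:
            continue
        g.add_edge(u, v)
    return g


def classify_topology(graph: nx.Graph) -> str:
    """Shape class of one connected cluster graph (see module docstring)."""
    if graph.number_of_nodes() < 2:
        raise ValueError("a cluster has at least 2 molecules")
    if not nx.is_connected(graph):
        raise ValueError("classify_topology expects a connected graph")
    v = graph.number_of_nodes()
    if v == 2:
        return "dimer"
    e = graph.number_of_edges()
    cycle_rank = e - v + 1
    degrees = [d for _, d in graph.degree()]
    if cycle_rank == 0:
        return "chain" if max(degrees) <= 2 else "branched-tree"
    if cycle_rank == 1:
        return "ring" if min(degrees) == 2 else "lasso"
    return "multi-cycle"


def find_clusters(
    graph: nx.Graph,
    frame_time: float = 0.0,
    topo: SystemTopology | None = None,
) -> list[ClusterRecord]:
    """Connected components of size ≥ 2, each with its topology class.

    Components are returned sorted by (size, smallest member) for
    deterministic output.
    """
    records: list[ClusterRecord] = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        sub = graph.subgraph(comp)
        counts: dict[str, int] = {}
        if topo is not None:
            for mol in comp:
                lab = topo.species_of_mol[mol]
                counts[lab] = counts.get(lab, 0) + 1
        records.append(
            ClusterRecord(
                frame_time=frame_time,
                members=frozenset(int(n) for n in comp),
                edges=frozenset(tuple(sorted((int(a), int(b)))) for a, b in sub.edges()),
                topology_class=classify_topology(sub),
                species_counts=counts,
            )
        )
    records.sort(key=lambda r: (r.size, min(r.members)))
    return records


def size_distribution(clusters: Iterable[ClusterRecord], n_frames: int | None = None):
    """Histogram of cluster sizes and class frequencies over frames.

    Returns a DataFrame with one row per (size, topology class, species
    composition) and a ``per_frame`` column (count normalized by the number
    of distinct frame times unless ``n_frames`` is given).
    """
    import pandas as pd

    clusters = list(clusters)
    if n_frames is None:
        n_frames = max(1, len({c.frame_time for c in clusters}))
    rows: dict[tuple, int] = {}
    for c in clusters:
        comp = ",".join(f"{k}:{v}" for k, v in sorted(c.species_counts.items()))
        key = (c.size, c.topology_class, comp)
        rows[key] = rows.get(key, 0) + 1
    table = pd.DataFrame(
        [
            {"size": s, "topology_class": t, "composition": comp,
             "count": n, "per_frame": n / n_frames}
            for (s, t, comp), n in sorted(rows.items())
        ],
        columns=["size", "topology_class", "composition", "count", "per_frame"],
    )
    return table


def clusters_frame(records: Sequence[ClusterRecord]):
    """Per-frame cluster table: frame time, cluster id, size, class and
    member species counts (CSV-ready)."""
    import pandas as pd

    rows = []
    for i, c in enumerate(records):
        rows.append(
            {
                "frame_time": c.frame_time,
                "cluster_id": i,
                "size": c.size,
                "topology_class": c.topology_class,
                "composition": ",".join(f"{k}:{v}" for k, v in sorted(c.species_counts.items())),
            }
        )
    return pd.DataFrame(
        rows, columns=["frame_time", "cluster_id", "size", "topology_class", "composition"]
    )
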