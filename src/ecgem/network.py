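"""Metabolite-graph construction and connectivity indices.

Every metabolite of a model (including enzyme species and isozyme
pseudo-metabolites of an expanded model) is a node; two nodes are joined by
an edge when they co-occur in at least one reaction, giving a simple
undirected graph.  Ubiquitous cofactors ("currency metabolites": ATP, NADH,
water, protons, ...) dominate connectivity and can be excluded before edges
are formed.

The reported indices are the usual connectivity statistics of such graphs:
node/edge counts, mean degree, diameter/radius/characteristic path length
(on the largest connected component, since the full graph may be
disconnected), mean local clustering (degree<2 nodes count as 0), density
``mean(k)/(n-1)``, degree heterogeneity ``std(k)/mean(k)`` (population
standard deviation), and centralization ``max(k)/n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np

from .expansion import ECModel
from .model_core import MetKind, Model

__all__ = [
    "CURRENCY_DEFAULT",
    "NetworkMetrics",
    "build_graph",
    "metrics",
    "top_degree",
    "write_edgelist",
]

#: Default currency-metabolite names, matched case-insensitively against
#: metabolite names and compartment-stripped ids in every compartment.
CURRENCY_DEFAULT: Tuple[str, ...] = (
    "atp", "adp", "amp", "h2o", "h", "h+", "pi", "ppi",
    "nad", "nad+", "nadh", "nadp", "nadp+", "nadph",
    "co2", "o2", "coa",
)


@dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    avg_neighbors: float
    diameter: int
    radius: int
    char_path_length: float
    clustering: float
    density: float
    heterogeneity: float
    centralization: float


def _base_name(model: Model, mid: str) -> str:
    met = model.metabolite(mid)
    name = (met.name or mid).lower()
    # strip a trailing compartment tag: "atp_c", "atp[c]"
    for pattern in (f"_{met.compartment}", f"[{met.compartment}]"):
        if name.endswith(pattern.lower()):
            name = name[: -len(pattern)]
    return name


def build_graph(
    target: Union[Model, ECModel],
    exclude_currency: Union[bool, Sequence[str]] = False,
) -> nx.Graph:
    """Build the undirected metabolite co-occurrence graph.

    ``exclude_currency`` may be ``True`` (use :data:`CURRENCY_DEFAULT`), a
    custom name list, or ``False``.  Excluded metabolites are dropped before
    edge formation; isolated nodes (participating in no retained reaction
    pair) are dropped as well.  Node attributes carry ``kind`` and
    ``compartment``.
    """
    model = target.model if isinstance(target, ECModel) else target
    if exclude_currency is True:
        currency = {c.lower() for c in CURRENCY_DEFAULT}
    elif exclude_currency:
        currency = {c.lower() for c in exclude_currency}
    else:
        currency = set()

    def keep(mid: str) -> bool:
        return _base_name(model, mid) not in currency

    G = nx.Graph()
    for rxn in model.reactions:
        members = sorted(m for m in rxn.stoich if keep(m))
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                G.add_edge(a, b)
    for node in G.nodes:
        met = model.metabolite(node)
        G.nodes[node]["kind"] = met.kind.value
        G.nodes[node]["compartment"] = met.compartment
    return G


def metrics(G: nx.Graph) -> NetworkMetrics:
    """Connectivity indices of a metabolite graph (see module docstring)."""
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    n = G.number_of_nodes()
    e = G.number_of_edges()
    degrees = np.array([d for _, d in G.degree()], dtype=float)
    mean_k = degrees.mean()

    lcc_nodes = max(nx.connected_components(G), key=len)
    lcc = G.subgraph(lcc_nodes)
    if lcc.number_of_nodes() > 1:
        ecc = nx.eccentricity(lcc)
        diameter = max(ecc.values())
        radius = min(ecc.values())
        char_path = nx.average_shortest_path_length(lcc)
    else:
        diameter = radius = 0
        char_path = 0.0

    clustering = nx.average_clustering(G)  # degree<2 nodes contribute 0
    density = mean_k / (n - 1) if n > 1 else 0.0
    heterogeneity = (
        math.sqrt(degrees.var()) / mean_k if mean_k > 0 else 0.0
    )
    centralization = degrees.max() / n

    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        avg_neighbors=float(mean_k),
        diameter=int(diameter),
        radius=int(radius),
        char_path_length=float(char_path),
        clustering=float(clustering),
        density=float(density),
        heterogeneity=float(heterogeneity),
        centralization=float(centralization),
    )


def top_degree(
    G: nx.Graph,
    k: int,
    role_filter: Optional[str] = None,
) -> List[Tuple[str, int]]:
    """Top-k nodes by degree, ties broken lexicographically by node id.

    ``role_filter`` restricts the ranking to one metabolite kind
    (``"chemical"``, ``"enzyme"`` or ``"arm"``).  ``k`` beyond the node
    count returns the full ranking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nodes = [
        (node, deg) for node, deg in G.degree()
        if role_filter is None or G.nodes[node].get("kind") == role_filter
    ]
    nodes.sort(key=lambda t: (-t[1], t[0]))
    return nodes[:k]


def write_edgelist(G: nx.Graph, path: str) -> None:
    """Write the graph as a two-column TSV edge list (sorted)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in sorted(tuple(sorted(edge)) for edge in G.edges):
            fh.write(f"{a}\t{b}\n")
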