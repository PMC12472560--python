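"""Topology panel for co-occurrence networks.

Produces the standard descriptor set: node and edge counts, average degree,
density, mean local clustering, characteristic path length and diameter (on
the largest connected component, both raw and normalised by node count), and
the modularity of a deterministic greedy partition.

Path length and diameter are emitted both raw (in hops) and divided by the
node count: published network tables sometimes print sub-1 "path length" and
"diameter" values, which are only meaningful as normalised quantities, so
both conventions are available and the reporting choice is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ValidationError, logger
from .network import CoOccurrenceNetwork


def average_degree(nodes: int, edges: int) -> float:
    """Closed form 2E/N."""
    if nodes <= 0:
        return 0.0
    return 2.0 * edges / nodes


def density(nodes: int, edges: int) -> float:
    """Closed form 2E / (N(N−1))."""
    if nodes <= 1:
        return 0.0
    return 2.0 * edges / (nodes * (nodes - 1))


@dataclass
class TopologySummary:
    group: str | None
    nodes: int
    edges: int
    average_degree: float
    density: float
    clustering_coefficient: float
    path_length: float
    diameter: float
    path_length_normalized: float
    diameter_normalized: float
    modularity: float

    def as_series(self) -> pd.Series:
        return pd.Series(asdict(self))


def _greedy_communities(g: nx.Graph) -> list[set]:
    """CNM greedy modularity communities on a graph rebuilt with sorted nodes
    (lexicographic tie-break, deterministic)."""
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes()))
    h.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in g.edges()))
    return [set(c) for c in nx.community.greedy_modularity_communities(h)]


def summarize(net: CoOccurrenceNetwork) -> TopologySummary:
    """Compute the full topology panel for one network.

    Empty networks yield an all-zero summary with a warning.  Path metrics
    use unweighted shortest paths on the largest connected component.
    """
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        logger.warning("summarize: empty network (group=%s)", net.group)
        return TopologySummary(net.group, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    clustering = nx.average_clustering(g)  # C_i = 0 for degree < 2
    giant = g.subgraph(max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)[0])))
    if giant.number_of_nodes() > 1:
        path_length = nx.average_shortest_path_length(giant)
        diam = float(nx.diameter(giant))
    else:
        path_length, diam = 0.0, 0.0
    comms = _greedy_communities(g)
    q = nx.community.modularity(g, comms) if e > 0 else 0.0
    return TopologySummary(
        group=net.group,
        nodes=n,
        edges=e,
        average_degree=average_degree(n, e),
        density=density(n, e),
        clustering_coefficient=float(clustering),
        path_length=float(path_length),
        diameter=diam,
        path_length_normalized=float(path_length) / n,
        diameter_normalized=diam / n,
        modularity=float(q),
    )


def compare_topology(
    summaries: list[TopologySummary],
    control: str | None = None,
) -> pd.DataFrame:
    """Side-by-side topology table with deltas against a designated control.

    The control defaults to the first summary's group.
    """
    if len(summaries) < 2:
        raise ValidationError("compare_topology needs >= 2 summaries")
    frame = pd.DataFrame([s.as_series() for s in summaries]).set_index("group")
    if control is None:
        control = frame.index[0]
    if control not in frame.index:
        raise ValidationError(f"control group {control!r} not among summaries")
    numeric = frame.astype(float)
    deltas = numeric.subtract(numeric.loc[control], axis=1)
    deltas.index = [f"{g} - {control}" for g in deltas.index]
    return pd.concat([numeric, deltas])
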